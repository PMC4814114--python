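"""BW anchor assignment, anchor-shift search, and Cα superposition.

Given gapless TM helices, a single residue per helix — the n.50 *anchor* —
fully determines the Ballesteros–Weinstein label of every TM residue:
``index = 50 + (author_index - anchor_index)``.  Aligning a new receptor to
the class-A frame therefore reduces to picking seven anchors.

The search scores each candidate anchor set by the number of inter-helical
contacts it shares with a panel of reference structures, summed over the
panel (a contact matched in 20 references contributes 20).  Because shifting
the anchor of helix n only relabels contacts that involve helix n, the score
decomposes over helix pairs; the search exploits this to run an exact
coordinate ascent (default) or an exhaustive joint scan over small windows.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from gross.contacts import (
    BWPosition,
    Contact,
    ContactParams,
    ContactSet,
    ResiduePair,
    detect_residue_contacts,
    label_contacts,
)
from gross.structure import HELICES, TMBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BWAnchor:
    """Author residue numbers labeled n.50, one per helix (1..7)."""

    anchors: Mapping[int, int]
    anchor_aa: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        anchors = {int(n): int(i) for n, i in dict(self.anchors).items()}
        if set(anchors) != set(HELICES):
            raise ValueError(f"anchors must cover helices 1..7, got {sorted(anchors)}")
        object.__setattr__(self, "anchors", anchors)

    def __getitem__(self, helix: int) -> int:
        return self.anchors[helix]

    def shifted(self, shifts: Mapping[int, int]) -> "BWAnchor":
        """New anchors with per-helix shifts added (anchor' = anchor + shift)."""
        new = dict(self.anchors)
        for n, s in shifts.items():
            new[n] = new[n] + s
        return BWAnchor(new)

    def validate_in_bundle(self, bundle: TMBundle) -> None:
        for n in HELICES:
            lo, hi = bundle.tm_range(n)
            if not lo <= self.anchors[n] <= hi:
                raise ValueError(
                    f"{bundle.structure_id}: anchor {self.anchors[n]} for TM{n} outside range {lo}..{hi}"
                )


@dataclass(frozen=True)
class AnchorCandidate:
    """One anchor set evaluated by the search."""

    anchors: BWAnchor
    shifts: Mapping[int, int]
    cumulative_common: int
    rmsd: float = math.nan

    @property
    def total_shift(self) -> int:
        return sum(abs(s) for s in self.shifts.values())


def bw_label(
    anchors: BWAnchor | Mapping[int, int],
    helix: int,
    author_index: int,
    tm_range: tuple[int, int] | None = None,
) -> BWPosition:
    """BW position of a residue: n.50 at the anchor, contiguous along the helix."""
    if tm_range is not None and not tm_range[0] <= author_index <= tm_range[1]:
        raise ValueError(f"residue {author_index} outside TM{helix} range {tm_range[0]}..{tm_range[1]}")
    anchor = anchors[helix]
    return BWPosition(helix, 50 + author_index - anchor)


def count_common(set_a: ContactSet, set_b: ContactSet) -> int:
    """Number of contacts with identical BW labels in both structures."""
    return len(set_a.contacts & set_b.contacts)


# ---------------------------------------------------------------------------
# superposition


def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns (rotation, translation, rmsd) with ``moving @ R.T + t ≈ fixed``;
    the rotation is proper (det +1).
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("superposition needs two equal (N, 3) coordinate arrays")
    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    h = (moving - cm).T @ (fixed - cf)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cf - rot @ cm
    moved = moving @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fixed) ** 2, axis=1))))
    return rot, trans, rmsd


def paired_ca(
    bundle_a: TMBundle,
    bundle_b: TMBundle,
    anchors_a: BWAnchor,
    anchors_b: BWAnchor,
    helices: Iterable[int] = HELICES,
) -> tuple[np.ndarray, np.ndarray]:
    """Cα coordinates paired by BW label over the maximal overlap of each TM."""
    pa: list[np.ndarray] = []
    pb: list[np.ndarray] = []
    for n in helices:
        lo_a, hi_a = bundle_a.tm_range(n)
        lo_b, hi_b = bundle_b.tm_range(n)
        bw_lo = max(50 + lo_a - anchors_a[n], 50 + lo_b - anchors_b[n])
        bw_hi = min(50 + hi_a - anchors_a[n], 50 + hi_b - anchors_b[n])
        for bw in range(bw_lo, bw_hi + 1):
            res_a = bundle_a.residue(n, anchors_a[n] + bw - 50)
            res_b = bundle_b.residue(n, anchors_b[n] + bw - 50)
            if res_a is None or res_b is None or res_a.ca is None or res_b.ca is None:
                continue
            pa.append(res_a.ca.position)
            pb.append(res_b.ca.position)
    return np.array(pa).reshape(-1, 3), np.array(pb).reshape(-1, 3)


def superpose_rmsd(
    bundle_a: TMBundle,
    bundle_b: TMBundle,
    anchors_a: BWAnchor,
    anchors_b: BWAnchor,
    helices: Iterable[int] = HELICES,
) -> float:
    """Optimal Cα RMSD over the BW-paired, maximally overlapping TM spans."""
    pa, pb = paired_ca(bundle_a, bundle_b, anchors_a, anchors_b, helices)
    if len(pa) < 3:
        raise ValueError(f"need >=3 paired C-alpha positions, got {len(pa)}")
    _rot, _trans, rmsd = kabsch(pb, pa)
    return rmsd


# ---------------------------------------------------------------------------
# anchor search


def _pair_tables(
    residue_contacts: Mapping[ResiduePair, object],
    initial: BWAnchor,
    references: Sequence[ContactSet],
    window: int,
    bounds: Mapping[int, tuple[int, int]],
) -> tuple[dict[tuple[int, int], np.ndarray], dict[int, np.ndarray]]:
    """Per-helix-pair score tables f[(m, n)][sm + w, sn + w].

    Score of shift vector s is the sum of table entries — exact because a
    contact between helices (m, n) relabels under (sm, sn) alone.  Also
    returns, per helix, a boolean mask of admissible shifts (anchor stays
    inside the TM range).
    """
    ref_counts: dict[tuple[int, int], Counter] = {}
    for ref in references:
        for c in ref.contacts:
            key = (c.a.helix, c.b.helix)
            ref_counts.setdefault(key, Counter())[(c.a.index, c.b.index)] += 1

    target_pairs: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for (a, b) in residue_contacts:
        (hm, rm), (hn, rn) = a, b
        target_pairs.setdefault((hm, hn), []).append(
            (50 + rm - initial[hm], 50 + rn - initial[hn])
        )

    shifts = range(-window, window + 1)
    tables: dict[tuple[int, int], np.ndarray] = {}
    for key, offsets in target_pairs.items():
        counts = ref_counts.get(key)
        table = np.zeros((2 * window + 1, 2 * window + 1), dtype=np.int64)
        if counts:
            for i, sm in enumerate(shifts):
                for j, sn in enumerate(shifts):
                    table[i, j] = sum(counts[(om - sm, on - sn)] for om, on in offsets)
        tables[key] = table

    admissible: dict[int, np.ndarray] = {}
    for n in HELICES:
        lo, hi = bounds[n]
        admissible[n] = np.array([lo <= initial[n] + s <= hi for s in shifts])
        if not admissible[n].any():
            raise ValueError(f"no admissible anchor shift for TM{n} within window {window}")
    return tables, admissible


def _score_of(tables: Mapping[tuple[int, int], np.ndarray], shifts: Mapping[int, int], window: int) -> int:
    return int(sum(t[shifts[m] + window, shifts[n] + window] for (m, n), t in tables.items()))


def search_anchors(
    target: TMBundle,
    initial: BWAnchor,
    references: Sequence[ContactSet],
    window: int = 10,
    params: ContactParams | None = None,
    mode: str = "coordinate",
    primary_reference: tuple[TMBundle, BWAnchor] | None = None,
    pinned: Mapping[int, int] | None = None,
    max_rounds: int = 20,
    top_k_rmsd: int = 20,
) -> list[AnchorCandidate]:
    """Rank anchor candidates by cumulative common contacts with the references.

    ``mode='coordinate'`` scans each helix exhaustively with the other six
    fixed and iterates to convergence — exact when per-helix effects add,
    which they do whenever the references constrain each helix pair
    independently.  ``mode='joint'`` enumerates the full shift grid (use
    windows <= 4).  Shifts that push an anchor outside its TM range are
    skipped.  ``pinned`` forces selected helices to a fixed shift (logged),
    for cases where an alignment is chosen for cross-receptor consistency
    rather than raw score.

    Ties are broken by lower RMSD against ``primary_reference`` (when given),
    then by smaller total absolute shift.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if mode not in ("coordinate", "joint"):
        raise ValueError(f"unknown mode {mode!r}")
    initial.validate_in_bundle(target)

    residue_contacts = detect_residue_contacts(target, params)
    bounds = {n: target.tm_range(n) for n in HELICES}
    tables, admissible = _pair_tables(residue_contacts, initial, references, window, bounds)

    pinned = dict(pinned or {})
    for n, s in pinned.items():
        logger.info("TM%d anchor pinned to shift %+d", n, s)
        mask = np.zeros_like(admissible[n])
        mask[s + window] = admissible[n][s + window]
        if not mask.any():
            raise ValueError(f"pinned shift {s:+d} for TM{n} is not admissible")
        admissible[n] = mask

    seen: dict[tuple[int, ...], int] = {}

    def record(shifts: Mapping[int, int]) -> None:
        key = tuple(shifts[n] for n in HELICES)
        if key not in seen:
            seen[key] = _score_of(tables, shifts, window)

    if mode == "joint":
        if (2 * window + 1) ** 7 > 10_000_000:
            raise ValueError("joint mode is exhaustive; use window <= 4")
        axes = [
            [s for s in range(-window, window + 1) if admissible[n][s + window]]
            for n in HELICES
        ]
        # tensor sum of the pairwise tables over the admissible grid
        shape = [len(a) for a in axes]
        total = np.zeros(shape, dtype=np.int64)
        idx = {n: np.array(a) + window for n, a in zip(HELICES, axes)}
        for (m, n_), table in tables.items():
            sub = table[np.ix_(idx[m], idx[n_])]
            expand = [None] * 7
            expand[m - 1] = slice(None)
            expand[n_ - 1] = slice(None)
            total = total + sub[tuple(expand)]
        order = np.argsort(total, axis=None)[::-1][: max(top_k_rmsd * 3, 50)]
        for flat in order:
            multi = np.unravel_index(flat, shape)
            record({n: axes[k][multi[k]] for k, n in enumerate(HELICES)})
    else:
        shifts = {n: 0 if admissible[n][window] else int(np.nonzero(admissible[n])[0][0]) - window
                  for n in HELICES}
        record(shifts)
        for _round in range(max_rounds):
            changed = False
            for n in HELICES:
                best_s, best_score = shifts[n], -1
                for s in range(-window, window + 1):
                    if not admissible[n][s + window]:
                        continue
                    trial = dict(shifts)
                    trial[n] = s
                    score = _score_of(tables, trial, window)
                    record(trial)
                    if score > best_score or (score == best_score and abs(s) < abs(best_s)):
                        best_s, best_score = s, score
                if best_s != shifts[n]:
                    shifts[n] = best_s
                    changed = True
            if not changed:
                break

    candidates = [
        AnchorCandidate(
            anchors=initial.shifted(dict(zip(HELICES, key))),
            shifts=dict(zip(HELICES, key)),
            cumulative_common=score,
        )
        for key, score in seen.items()
    ]
    candidates.sort(key=lambda c: (-c.cumulative_common, c.total_shift))

    if primary_reference is not None:
        ref_bundle, ref_anchors = primary_reference
        head = candidates[:top_k_rmsd]
        rescored = []
        for cand in head:
            try:
                rmsd = superpose_rmsd(target, ref_bundle, cand.anchors, ref_anchors)
            except ValueError:
                rmsd = math.inf
            rescored.append(replace(cand, rmsd=rmsd))
        rescored.sort(key=lambda c: (-c.cumulative_common, c.rmsd, c.total_shift))
        candidates = rescored + candidates[top_k_rmsd:]

    return candidates


def labeled_contact_set(
    bundle: TMBundle, anchors: BWAnchor, params: ContactParams | None = None
) -> ContactSet:
    """Convenience: detect and BW-label a bundle's contacts in one call."""
    return label_contacts(detect_residue_contacts(bundle, params), anchors, bundle.structure_id)
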