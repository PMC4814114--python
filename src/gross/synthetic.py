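"""Synthetic 7-TM fixtures: idealized bundles, planted perturbations, families.

Every stage of the pipeline is testable without structure downloads by
generating idealized bundles whose ground truth is known by construction:

* :func:`make_bundle` builds seven ideal α-helices (1.5 Å rise and 100° turn
  per residue for Cα, with Cβ/Cγ pseudo-atoms standing in for side-chain
  bulk: none for Gly, Cβ only for Ala) on a ring.  With the default ring
  radius the bundle yields an inter-helical contact set of the same order of
  magnitude as a receptor crystal structure (~200).
* :func:`renumber` shifts author numbering per helix without touching
  coordinates — the planted-shift scenario for the anchor search.
* :func:`perturb` applies known rigid per-helix moves — the planted-transform
  scenario for the move decomposition.
* :func:`make_family` mutates ancestor sequences into families with
  controlled similarity — the scenario for similarity scans and the tree.

All generators are deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from gross.alignment import BWAnchor
from gross.moves import fit_axis, _rotation_between
from gross.similarity import AlignmentEntry
from gross.structure import (
    HELICES,
    AtomRecord,
    ResidueRecord,
    TMAnnotation,
    TMBundle,
    write_bundle_pdb,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

CA_RISE = 1.5          # Å per residue along the axis
CA_TURN = 100.0        # degrees per residue
CA_RADIUS = 2.3        # Å, Cα distance from the helix axis
CB_OFFSET = 1.53       # Å, Cβ further out along the radial direction
CG_OFFSET = 3.06       # Å, Cγ pseudo-atom further out still


@dataclass(frozen=True)
class BundleSpec:
    """Geometry and sequence recipe for one idealized 7-helix bundle."""

    structure_id: str = "synthetic"
    helix_lengths: tuple[int, ...] = (26,) * 7
    ring_radius: float = 9.0
    tilts: tuple[float, ...] = (0.0,) * 7         # degrees from the bundle axis
    phases: tuple[float, ...] = (0.0,) * 7        # degrees, helical phase offset
    sequences: tuple[str, ...] | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    start_numbers: tuple[int, ...] = (101, 201, 301, 401, 501, 601, 701)

    def __post_init__(self) -> None:
        if len(self.helix_lengths) != 7 or any(l < 10 for l in self.helix_lengths):
            raise ValueError("need 7 helix lengths, each >= 10")
        if self.sequences is not None and any(
            len(s) != l for s, l in zip(self.sequences, self.helix_lengths)
        ):
            raise ValueError("sequence lengths must match helix lengths")
        # adjacent helix centers on the ring must stay > 4 Å apart
        min_sep = 2.0 * self.ring_radius * math.sin(math.pi / 7)
        if min_sep <= 4.0:
            raise ValueError(f"ring radius {self.ring_radius} packs helices closer than 4 Å")


@dataclass(frozen=True)
class SyntheticBundle:
    """A generated bundle together with its ground-truth annotation and anchors."""

    bundle: TMBundle
    annotation: TMAnnotation
    anchors: BWAnchor
    spec: BundleSpec

    def write_pdb(self, path: str | Path) -> None:
        write_bundle_pdb(self.bundle, path)


def _helix_coords(
    length: int, center: np.ndarray, azimuth: float, tilt_deg: float, phase_deg: float
) -> tuple[np.ndarray, np.ndarray]:
    """(Cα, radial-unit) coordinate arrays for one ideal helix."""
    z_hat = np.array([0.0, 0.0, 1.0])
    r_hat = np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
    t_hat = np.array([-math.sin(azimuth), math.cos(azimuth), 0.0])
    tilt = math.radians(tilt_deg)
    axis = math.cos(tilt) * z_hat + math.sin(tilt) * r_hat
    u = math.cos(tilt) * r_hat - math.sin(tilt) * z_hat   # unit, perpendicular to axis
    v = np.cross(axis, u)

    ca = np.empty((length, 3))
    radial = np.empty((length, 3))
    for i in range(length):
        z = (i - (length - 1) / 2.0) * CA_RISE
        theta = math.radians(phase_deg + i * CA_TURN)
        r = math.cos(theta) * u + math.sin(theta) * v
        ca[i] = center + axis * z + CA_RADIUS * r
        radial[i] = r
    return ca, radial


def make_bundle(spec: BundleSpec) -> SyntheticBundle:
    """Build an idealized bundle; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    sequences = spec.sequences or tuple(
        "".join(rng.choice(list(AA20), size=l)) for l in spec.helix_lengths
    )

    helices: dict[int, tuple[ResidueRecord, ...]] = {}
    ranges: dict[int, tuple[int, int]] = {}
    anchors: dict[int, int] = {}
    for k, n in enumerate(HELICES):
        length = spec.helix_lengths[k]
        azimuth = 2.0 * math.pi * k / 7.0
        center = spec.ring_radius * np.array([math.cos(azimuth), math.sin(azimuth), 0.0])
        ca, radial = _helix_coords(length, center, azimuth, spec.tilts[k], spec.phases[k])
        cb = ca + CB_OFFSET * radial
        cg = ca + CG_OFFSET * radial
        if spec.noise_sigma > 0:
            ca = ca + rng.normal(0.0, spec.noise_sigma, ca.shape)
            cb = cb + rng.normal(0.0, spec.noise_sigma, cb.shape)
            cg = cg + rng.normal(0.0, spec.noise_sigma, cg.shape)
        start = spec.start_numbers[k]
        residues = []
        for i in range(length):
            aa = sequences[k][i]
            atoms = [AtomRecord("CA", "C", ca[i])]
            if aa != "G":
                atoms.append(AtomRecord("CB", "C", cb[i]))
            if aa not in ("G", "A"):
                atoms.append(AtomRecord("CG", "C", cg[i]))
            residues.append(ResidueRecord(author_index=start + i, aa=aa, atoms=tuple(atoms)))
        helices[n] = tuple(residues)
        ranges[n] = (start, start + length - 1)
        anchors[n] = start + length // 2

    bundle = TMBundle(structure_id=spec.structure_id, helices=helices)
    return SyntheticBundle(
        bundle=bundle,
        annotation=TMAnnotation(ranges),
        anchors=BWAnchor(anchors),
        spec=spec,
    )


def renumber(sb: SyntheticBundle, offsets: Mapping[int, int]) -> SyntheticBundle:
    """Shift author numbering per helix; coordinates untouched.

    The true anchors shift with the residues, so an anchor search primed with
    the *old* anchor values must recover exactly these offsets.
    """
    new_helices: dict[int, tuple[ResidueRecord, ...]] = {}
    new_ranges: dict[int, tuple[int, int]] = {}
    new_anchors: dict[int, int] = {}
    for n in HELICES:
        off = int(offsets.get(n, 0))
        new_helices[n] = tuple(
            replace(r, author_index=r.author_index + off) for r in sb.bundle.helix(n)
        )
        s, e = sb.annotation[n]
        new_ranges[n] = (s + off, e + off)
        new_anchors[n] = sb.anchors[n] + off
    return SyntheticBundle(
        bundle=replace(sb.bundle, helices=new_helices),
        annotation=TMAnnotation(new_ranges),
        anchors=BWAnchor(new_anchors),
        spec=sb.spec,
    )


@dataclass(frozen=True)
class RigidPerturbation:
    """Planted per-helix move, in the same frame that decomposition reports."""

    t_axial: float = 0.0
    t_perp: float = 0.0
    tilt: float = 0.0   # degrees
    spin: float = 0.0   # degrees


def _transform_residues(
    residues: Sequence[ResidueRecord], rot: np.ndarray, pivot: np.ndarray, trans: np.ndarray
) -> tuple[ResidueRecord, ...]:
    out = []
    for res in residues:
        atoms = tuple(
            replace(a, position=rot @ (a.position - pivot) + pivot + trans)
            for a in res.atoms
        )
        out.append(replace(res, atoms=atoms))
    return tuple(out)


def _axis_angle(axis: np.ndarray, degrees: float) -> np.ndarray:
    a = axis / np.linalg.norm(axis)
    t = math.radians(degrees)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + math.sin(t) * k + (1 - math.cos(t)) * (k @ k)


def perturb(
    sb: SyntheticBundle,
    moves: Mapping[int, RigidPerturbation],
    global_rotation: np.ndarray | None = None,
    global_translation: np.ndarray | None = None,
) -> SyntheticBundle:
    """Apply known rigid per-helix moves, then an optional whole-bundle motion.

    Per helix, about its own fitted axis and centroid: spin, then tilt about a
    fixed perpendicular direction, then translation (axial plus perpendicular
    along that same direction).  The perpendicular direction is the outward
    radial of the bundle, projected off the axis — deterministic, so planted
    moves are exactly recoverable.
    """
    new_helices: dict[int, tuple[ResidueRecord, ...]] = {}
    for n in HELICES:
        residues = sb.bundle.helix(n)
        mv = moves.get(n)
        if mv is None:
            new_helices[n] = residues
            continue
        ca = np.array([r.ca.position for r in residues])
        axis = fit_axis(ca)
        d = axis.direction
        radial = axis.centroid.copy()
        radial[2] = 0.0
        if np.linalg.norm(radial) < 1e-9:
            radial = np.array([1.0, 0.0, 0.0])
        perp = radial - np.dot(radial, d) * d
        perp = perp / np.linalg.norm(perp)
        rot = _axis_angle(perp, mv.tilt) @ _axis_angle(d, mv.spin)
        trans = mv.t_axial * d + mv.t_perp * perp
        new_helices[n] = _transform_residues(residues, rot, axis.centroid, trans)

    bundle = replace(sb.bundle, helices=new_helices)
    if global_rotation is not None or global_translation is not None:
        rot = np.eye(3) if global_rotation is None else np.asarray(global_rotation, dtype=float)
        trans = np.zeros(3) if global_translation is None else np.asarray(global_translation, dtype=float)
        helices = {
            n: _transform_residues(bundle.helix(n), rot, np.zeros(3), trans) for n in HELICES
        }
        bundle = replace(bundle, helices=helices)
    return SyntheticBundle(bundle=bundle, annotation=sb.annotation, anchors=sb.anchors, spec=sb.spec)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


# ---------------------------------------------------------------------------
# sequence families


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for sequence families of controlled similarity."""

    n_families: int = 4
    n_members: int = 8
    helix_lengths: tuple[int, ...] = (26,) * 7
    substitution_prob: float = 0.1
    seed: int = 0
    ancestors: tuple[str, ...] | None = None   # concatenated TM sequences
    linker: str = "GSGS"

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitution_prob <= 1.0:
            raise ValueError("substitution_prob must be in [0, 1]")
        if self.ancestors is not None:
            total = sum(self.helix_lengths)
            if any(len(a) != total for a in self.ancestors):
                raise ValueError("each ancestor must cover the concatenated TM length")


def _entry_from_tm_sequence(ac: str, class_label: str, tm_seq: str, spec: FamilySpec) -> AlignmentEntry:
    """Assemble a full entry: linker loops between the seven TM segments."""
    linker = spec.linker
    seq_parts = [linker]
    anchors: dict[int, int] = {}
    ranges: dict[int, tuple[int, int]] = {}
    cursor = len(linker)
    offset = 0
    for k, n in enumerate(HELICES):
        length = spec.helix_lengths[k]
        segment = tm_seq[offset : offset + length]
        offset += length
        start = cursor + 1
        end = cursor + length
        anchors[n] = start + length // 2
        ranges[n] = (start, end)
        seq_parts.append(segment)
        seq_parts.append(linker)
        cursor = end + len(linker)
    return AlignmentEntry(
        uniprot_ac=ac,
        class_label=class_label,
        anchors=anchors,
        tm_ranges=ranges,
        sequence="".join(seq_parts),
    )


def mutate_sequence(rng: np.random.Generator, sequence: str, prob: float) -> str:
    """Per-site substitution with the given probability, uniform over the other 19."""
    out = []
    for aa in sequence:
        if rng.random() < prob:
            choices = [c for c in AA20 if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def make_family(spec: FamilySpec) -> list[AlignmentEntry]:
    """Generate ``n_families`` x ``n_members`` alignment entries.

    Family f's members are seeded mutations of ancestor f; entry ids are
    ``F{f}M{m}``, class labels ``FAM{f}``.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    total = sum(spec.helix_lengths)
    ancestors = spec.ancestors or tuple(
        "".join(rng.choice(list(AA20), size=total)) for _ in range(spec.n_families)
    )
    entries = []
    for f, ancestor in enumerate(ancestors):
        for m in range(spec.n_members):
            tm_seq = mutate_sequence(rng, ancestor, spec.substitution_prob)
            entries.append(_entry_from_tm_sequence(f"F{f}M{m}", f"FAM{f}", tm_seq, spec))
    return entries
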