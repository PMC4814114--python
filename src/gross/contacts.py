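"""Inter-helical heavy-atom contacts and conserved-contact sets.

A residue pair on two different TM helices is *in contact* when any two of
their heavy atoms lie closer than the sum of their van der Waals radii plus a
slack (0.6 Å by default).  Contacts are chemically nonspecific — backbone and
side-chain atoms count alike — which is what lets the same contact be traced
across receptors whose residues are not conserved.  Canonically a contact is
an unordered pair of Ballesteros–Weinstein positions, e.g. ``2.45-3.42``.

Conserved sets:

* the class-A conserved contacts are those present in at least ``min_count``
  of the class-A structures (40 contacts at 23-of-24 in the reference study);
* CHICOs (Conserved inter-HelIcal COntacts) are the subset of those also
  present in every structure from the other classes — the superfamily fold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from gross.structure import HELICES, TMBundle

logger = logging.getLogger(__name__)

#: Bondi van der Waals radii (Å) for elements seen in protein heavy atoms.
BONDI_RADII: Mapping[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class ContactParams:
    """Distance rule: heavy atoms closer than r(a) + r(b) + slack."""

    slack: float = 0.6
    vdw_radii: Mapping[str, float] | None = None
    default_radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.slack < 0:
            raise ValueError("slack must be >= 0")
        radii = dict(BONDI_RADII if self.vdw_radii is None else self.vdw_radii)
        if any(r <= 0 for r in radii.values()) or self.default_radius <= 0:
            raise ValueError("vdW radii must be positive")
        object.__setattr__(self, "vdw_radii", radii)

    def radius(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), self.default_radius)


@dataclass(frozen=True, order=True)
class BWPosition:
    """Ballesteros–Weinstein position n.index (helix 1..7, index e.g. 50)."""

    helix: int
    index: int

    def __post_init__(self) -> None:
        if self.helix not in HELICES:
            raise ValueError(f"helix must be 1..7, got {self.helix}")

    def __str__(self) -> str:
        return f"{self.helix}.{self.index}"

    @classmethod
    def parse(cls, text: str) -> "BWPosition":
        helix, index = text.split(".")
        return cls(int(helix), int(index))


@dataclass(frozen=True, order=True)
class Contact:
    """Unordered inter-helical pair of BW positions, stored with a.helix < b.helix."""

    a: BWPosition
    b: BWPosition

    def __post_init__(self) -> None:
        if self.a.helix == self.b.helix:
            raise ValueError(f"contact must span two helices, got {self.a} and {self.b}")
        if self.a.helix > self.b.helix:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)

    def __str__(self) -> str:
        return f"{self.a}-{self.b}"

    @classmethod
    def parse(cls, text: str) -> "Contact":
        a, b = text.split("-")
        return cls(BWPosition.parse(a), BWPosition.parse(b))

    @property
    def positions(self) -> tuple[BWPosition, BWPosition]:
        return self.a, self.b


@dataclass(frozen=True)
class ContactDetail:
    """Closest heavy-atom distance and number of qualifying atom pairs."""

    min_distance: float
    n_atom_pairs: int


@dataclass(frozen=True)
class ContactSet:
    """All inter-helical contacts of one structure, BW-labeled."""

    structure_id: str
    contacts: frozenset[Contact]
    details: Mapping[Contact, ContactDetail] | None = None

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, contact: Contact) -> bool:
        return contact in self.contacts


ResiduePair = tuple[tuple[int, int], tuple[int, int]]  # ((helix, author_idx), (helix, author_idx))


def detect_residue_contacts(
    bundle: TMBundle, params: ContactParams | None = None
) -> dict[ResiduePair, ContactDetail]:
    """Inter-helical residue-pair contacts in author numbering.

    Anchor-independent: BW labels are attached afterwards, so an anchor search
    can relabel the same geometric contacts under many candidate numberings.
    Residues without heavy atoms are skipped with a logged warning.
    """
    params = params or ContactParams()

    positions: list[np.ndarray] = []
    radii: list[float] = []
    helix_of: list[int] = []
    resid_of: list[int] = []
    for n in HELICES:
        for res in bundle.helix(n):
            heavy = res.heavy_atoms()
            if not heavy:
                logger.warning("%s TM%d residue %d has no heavy atoms; skipped",
                               bundle.structure_id, n, res.author_index)
                continue
            for atom in heavy:
                positions.append(atom.position)
                radii.append(params.radius(atom.element))
                helix_of.append(n)
                resid_of.append(res.author_index)

    xyz = np.asarray(positions)
    rad = np.asarray(radii)
    hel = np.asarray(helix_of)
    rid = np.asarray(resid_of)

    dists = cdist(xyz, xyz)
    thresh = rad[:, None] + rad[None, :] + params.slack
    ii, jj = np.nonzero((dists < thresh) & (hel[:, None] != hel[None, :]))
    keep = ii < jj

    found: dict[ResiduePair, list[float]] = {}
    for i, j in zip(ii[keep], jj[keep]):
        a = (int(hel[i]), int(rid[i]))
        b = (int(hel[j]), int(rid[j]))
        if a[0] > b[0]:
            a, b = b, a
        found.setdefault((a, b), []).append(float(dists[i, j]))

    return {
        pair: ContactDetail(min_distance=min(d), n_atom_pairs=len(d))
        for pair, d in found.items()
    }


def label_contacts(
    residue_contacts: Mapping[ResiduePair, ContactDetail],
    anchors: "BWAnchorLike",
    structure_id: str,
) -> ContactSet:
    """Attach BW labels (via per-helix n.50 anchors) to residue-pair contacts."""
    contacts: dict[Contact, ContactDetail] = {}
    for ((ha, ra), (hb, rb)), detail in residue_contacts.items():
        bw_a = BWPosition(ha, 50 + ra - anchors[ha])
        bw_b = BWPosition(hb, 50 + rb - anchors[hb])
        contacts[Contact(bw_a, bw_b)] = detail
    return ContactSet(structure_id=structure_id, contacts=frozenset(contacts), details=contacts)


def detect_contacts(
    bundle: TMBundle, anchors: "BWAnchorLike", params: ContactParams | None = None
) -> ContactSet:
    """BW-labeled inter-helical contact set of one bundle.

    ``anchors`` is anything indexable by helix number returning the author
    index of that helix's n.50 residue (a :class:`gross.alignment.BWAnchor`
    or a plain mapping).
    """
    return label_contacts(detect_residue_contacts(bundle, params), anchors, bundle.structure_id)


def conserved_contacts(
    sets: Sequence[ContactSet], min_count: int
) -> list[tuple[Contact, int]]:
    """Contacts present in at least ``min_count`` of the given sets.

    Returns (contact, occurrence count) sorted by helix pair then BW indices.
    """
    if not sets:
        raise ValueError("conserved_contacts needs at least one contact set")
    counts: Counter[Contact] = Counter()
    for cs in sets:
        counts.update(cs.contacts)
    kept = [(c, k) for c, k in counts.items() if k >= min_count]
    kept.sort(key=lambda item: (item[0].a.helix, item[0].b.helix, item[0].a.index, item[0].b.index))
    return kept


def chico_contacts(
    classA_conserved: Iterable[Contact],
    non_classA_sets: Sequence[ContactSet],
    min_count: int | None = None,
) -> list[Contact]:
    """Class-A conserved contacts also present in the other classes' structures.

    By default a contact must appear in *every* non-class-A set; ``min_count``
    relaxes this to at-least-that-many sets.
    """
    if min_count is None:
        min_count = len(non_classA_sets)
    counts: Counter[Contact] = Counter()
    for cs in non_classA_sets:
        counts.update(cs.contacts)
    kept = [c for c in classA_conserved if counts[c] >= min_count]
    kept.sort(key=lambda c: (c.a.helix, c.b.helix, c.a.index, c.b.index))
    return kept


def contacts_to_tsv(contact_set: ContactSet, path: str | Path) -> None:
    """Write one structure's contacts: structure_id, bw_a, bw_b, min_distance, n_atom_pairs."""
    rows = []
    for contact in sorted(contact_set.contacts):
        detail = (contact_set.details or {}).get(contact)
        rows.append(
            {
                "structure_id": contact_set.structure_id,
                "bw_a": str(contact.a),
                "bw_b": str(contact.b),
                "min_distance": round(detail.min_distance, 3) if detail else np.nan,
                "n_atom_pairs": detail.n_atom_pairs if detail else 0,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# typing helper: anything indexable by helix -> author anchor index
BWAnchorLike = Mapping[int, int]
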