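"""Activation analysis: contacts that rewire between inactive and active states.

For receptors crystallized in both conformations, comparing the two contact
sets per receptor across the panel splits contacts into three disjoint
categories: present in every structure of both states (the conserved core),
present in all inactive structures but no active one, and the reverse.
Residues participating in either changed category are the NACHOs — native
activation hot-spot residues; mutations there are prime candidates for
constitutive activity or loss of signaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from gross.contacts import BWPosition, Contact, ContactSet


@dataclass(frozen=True)
class StateComparison:
    """Disjoint contact categories from an inactive/active panel."""

    common: frozenset[Contact]
    inactive_only: frozenset[Contact]
    active_only: frozenset[Contact]
    nacho_residues: tuple[BWPosition, ...]

    def changed(self) -> frozenset[Contact]:
        return self.inactive_only | self.active_only


def _present_counts(sets: Sequence[ContactSet]) -> dict[Contact, int]:
    counts: dict[Contact, int] = {}
    for cs in sets:
        for c in cs.contacts:
            counts[c] = counts.get(c, 0) + 1
    return counts


def compare_states(
    inactive: Sequence[ContactSet],
    active: Sequence[ContactSet],
    min_present: int | None = None,
) -> StateComparison:
    """Classify contacts by conformational state.

    Strict rule (default): a contact is *inactive-only* if present in every
    inactive structure and absent from every active one (and vice versa).
    ``min_present`` relaxes "every" to at-least-that-many structures of the
    state; absence from the other state stays absolute.
    """
    if not inactive or not active:
        raise ValueError("need at least one contact set per state")
    n_inact = len(inactive)
    n_act = len(active)
    need_inact = n_inact if min_present is None else min(min_present, n_inact)
    need_act = n_act if min_present is None else min(min_present, n_act)

    count_i = _present_counts(inactive)
    count_a = _present_counts(active)

    common = frozenset(
        c for c in set(count_i) & set(count_a)
        if count_i[c] == n_inact and count_a[c] == n_act
    )
    inactive_only = frozenset(
        c for c, k in count_i.items() if k >= need_inact and count_a.get(c, 0) == 0
    )
    active_only = frozenset(
        c for c, k in count_a.items() if k >= need_act and count_i.get(c, 0) == 0
    )

    roster: set[BWPosition] = set()
    for c in inactive_only | active_only:
        roster.update(c.positions)
    nacho = tuple(sorted(roster, key=lambda p: (p.helix, p.index)))
    return StateComparison(
        common=common,
        inactive_only=inactive_only,
        active_only=active_only,
        nacho_residues=nacho,
    )


@dataclass(frozen=True)
class NachoReport:
    """Tabular view of a state comparison."""

    table: pd.DataFrame          # one row per changed or common contact
    residues: tuple[BWPosition, ...]
    n_changed_contacts: int
    n_residues: int


def nacho_report(comparison: StateComparison) -> NachoReport:
    """Per-contact category table plus the deduplicated NACHO residue roster."""
    rows = []
    for category, contacts in (
        ("common", comparison.common),
        ("inactive_only", comparison.inactive_only),
        ("active_only", comparison.active_only),
    ):
        for c in sorted(contacts):
            rows.append(
                {
                    "category": category,
                    "contact": str(c),
                    "residue_a": str(c.a),
                    "residue_b": str(c.b),
                }
            )
    table = pd.DataFrame(rows, columns=["category", "contact", "residue_a", "residue_b"])
    changed = comparison.changed()
    return NachoReport(
        table=table,
        residues=comparison.nacho_residues,
        n_changed_contacts=len(changed),
        n_residues=len(comparison.nacho_residues),
    )
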