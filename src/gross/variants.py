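"""Natural-variant mapping to BW positions and CHICO/NACHO-based scoring.

Each point substitution is mapped through the alignment table to a BW
position (or none, if it falls in a loop), then placed relative to the
conserved-contact (CHICO) and activation hot-spot (NACHO) residue rosters:

    score = d_nacho + d_chico - mult_nacho - mult_chico + blosum62(wt, mut)

where d_* is the sequence distance (|ΔBW index|) to the nearest roster
residue on the same helix, mult_* the number of roster contacts that nearest
residue participates in, and the matrix entry is taken with its sign.  Lower
scores flag variants more likely to disrupt the fold or the activation
switch.  A helix with no roster residue contributes a documented sentinel
distance of +20 (keeps the ordering total and finite).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from gross.contacts import BWPosition, Contact
from gross.similarity import AlignmentEntry, SubstitutionMatrix
from gross.structure import HELICES

logger = logging.getLogger(__name__)

#: Distance substituted when the variant's helix carries no roster residue.
NO_ROSTER_DISTANCE = 20


@dataclass(frozen=True)
class RawVariant:
    """A point substitution as read from the variant table."""

    uniprot_ac: str
    position: int          # 1-based sequence index
    wt_aa: str
    mut_aa: str
    disease_note: str = ""


@dataclass(frozen=True)
class VariantRecord:
    """A mapped variant with roster distances, multiplicities and score."""

    uniprot_ac: str
    position: int
    wt_aa: str
    mut_aa: str
    disease_note: str = ""
    class_label: str = ""
    bw: BWPosition | None = None
    wt_matches: bool = True
    d_nacho: int | None = None
    d_chico: int | None = None
    mult_nacho: int = 0
    mult_chico: int = 0
    no_roster_flag: bool = False
    score: float | None = None

    @property
    def in_tm(self) -> bool:
        return self.bw is not None

    @property
    def has_disease(self) -> bool:
        return bool(self.disease_note and str(self.disease_note).strip())

    @property
    def on_chico(self) -> bool:
        return self.d_chico == 0

    @property
    def on_nacho(self) -> bool:
        return self.d_nacho == 0


Roster = Mapping[BWPosition, int]


def roster_from_contacts(contacts: Iterable[Contact]) -> dict[BWPosition, int]:
    """Residue roster with multiplicities: contacts each residue participates in."""
    counts: Counter[BWPosition] = Counter()
    for c in contacts:
        counts[c.a] += 1
        counts[c.b] += 1
    return dict(counts)


def map_variant(v: RawVariant, entry: AlignmentEntry) -> VariantRecord:
    """Attach the BW position (or none, for loop residues) to a raw variant."""
    if v.uniprot_ac != entry.uniprot_ac:
        raise ValueError(f"variant accession {v.uniprot_ac} does not match entry {entry.uniprot_ac}")
    if not 1 <= v.position <= len(entry.sequence):
        raise ValueError(f"{v.uniprot_ac}: position {v.position} outside sequence of length {len(entry.sequence)}")
    wt_matches = entry.sequence[v.position - 1] == v.wt_aa
    if not wt_matches:
        logger.warning("%s position %d: table has %s, variant claims %s",
                       v.uniprot_ac, v.position, entry.sequence[v.position - 1], v.wt_aa)
    bw = None
    for n in HELICES:
        s, e = entry.tm_ranges[n]
        if s <= v.position <= e:
            bw = BWPosition(n, 50 + v.position - entry.anchors[n])
            break
    return VariantRecord(
        uniprot_ac=v.uniprot_ac,
        position=v.position,
        wt_aa=v.wt_aa,
        mut_aa=v.mut_aa,
        disease_note=v.disease_note,
        class_label=entry.class_label,
        bw=bw,
        wt_matches=wt_matches,
    )


def _nearest(bw: BWPosition, roster: Roster) -> tuple[int, int, bool]:
    """(distance, multiplicity at the nearest roster residue, no-roster flag).

    Nearest is by |ΔBW index| on the same helix; distance ties resolve to the
    residue with the larger multiplicity (then lower index, for determinism).
    """
    on_helix = [(p, m) for p, m in roster.items() if p.helix == bw.helix]
    if not on_helix:
        return NO_ROSTER_DISTANCE, 0, True
    best = min(on_helix, key=lambda pm: (abs(pm[0].index - bw.index), -pm[1], pm[0].index))
    return abs(best[0].index - bw.index), best[1], False


def score_variant(
    v: VariantRecord,
    chico: Roster,
    nacho: Roster,
    matrix: SubstitutionMatrix | None = None,
) -> VariantRecord:
    """Fill in roster distances, multiplicities and the five-term score."""
    if v.bw is None:
        raise ValueError(f"{v.uniprot_ac} position {v.position}: not in a TM region, cannot score")
    matrix = matrix or SubstitutionMatrix.blosum62()
    d_n, m_n, flag_n = _nearest(v.bw, nacho)
    d_c, m_c, flag_c = _nearest(v.bw, chico)
    score = d_n + d_c - m_n - m_c + matrix.score(v.wt_aa, v.mut_aa)
    return replace(
        v,
        d_nacho=d_n,
        d_chico=d_c,
        mult_nacho=m_n,
        mult_chico=m_c,
        no_roster_flag=flag_n or flag_c,
        score=float(score),
    )


def annotate_variants(
    raw: Sequence[RawVariant],
    entries: Mapping[str, AlignmentEntry],
    chico: Roster,
    nacho: Roster,
    matrix: SubstitutionMatrix | None = None,
) -> list[VariantRecord]:
    """Map and (for TM variants) score a variant cohort.

    Variants whose accession is absent from the alignment table raise a
    KeyError — the table defines the universe of receptors.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    out = []
    for v in raw:
        if v.uniprot_ac not in entries:
            raise KeyError(f"accession {v.uniprot_ac} absent from the alignment table")
        rec = map_variant(v, entries[v.uniprot_ac])
        if rec.in_tm:
            rec = score_variant(rec, chico, nacho, matrix)
        out.append(rec)
    return out


def summarize(
    records: Sequence[VariantRecord],
    exclude_classes: Sequence[str] = ("Olfactory", "Other"),
) -> pd.DataFrame:
    """Cohort summary: counts, disease-annotated counts and percentages.

    Rows: all, tm, non_tm, chico, chico_only, nacho, nacho_only, both.
    ``all`` covers every record; the remaining rows exclude the listed
    classes (olfactory and unassigned receptors by default).  Percentages
    are rounded to one decimal.
    """
    excluded = set(exclude_classes)
    kept = [r for r in records if r.class_label not in excluded]

    def row(name: str, rs: Sequence[VariantRecord]) -> dict[str, object]:
        n = len(rs)
        dis = sum(1 for r in rs if r.has_disease)
        return {
            "subset": name,
            "count": n,
            "disease_annotated": dis,
            "percent_disease": round(100.0 * dis / n, 1) if n else 0.0,
        }

    tm = [r for r in kept if r.in_tm]
    non_tm = [r for r in kept if not r.in_tm]
    chico = [r for r in tm if r.on_chico]
    nacho = [r for r in tm if r.on_nacho]
    both = [r for r in tm if r.on_chico and r.on_nacho]
    chico_only = [r for r in tm if r.on_chico and not r.on_nacho]
    nacho_only = [r for r in tm if r.on_nacho and not r.on_chico]

    return pd.DataFrame(
        [
            row("all", list(records)),
            row("excluding_filtered", kept),
            row("tm", tm),
            row("non_tm", non_tm),
            row("chico", chico),
            row("chico_only", chico_only),
            row("nacho", nacho),
            row("nacho_only", nacho_only),
            row("both", both),
        ]
    )


def rank_variants(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Scored TM variants as a table, most-disruptive (lowest score) first."""
    rows = []
    for r in records:
        if r.score is None:
            continue
        rows.append(
            {
                "uniprot_ac": r.uniprot_ac,
                "class": r.class_label,
                "position": r.position,
                "wt": r.wt_aa,
                "mut": r.mut_aa,
                "bw": str(r.bw),
                "d_nacho": r.d_nacho,
                "d_chico": r.d_chico,
                "mult_nacho": r.mult_nacho,
                "mult_chico": r.mult_chico,
                "score": r.score,
                "disease": r.disease_note,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["score", "uniprot_ac", "position"]).reset_index(drop=True)
    return df


def read_variants_csv(path: str | Path) -> list[RawVariant]:
    """Read a variant CSV: uniprot_ac, position, wt, mut, annotation."""
    df = pd.read_csv(path).fillna({"annotation": ""})
    return [
        RawVariant(
            uniprot_ac=str(row["uniprot_ac"]),
            position=int(row["position"]),
            wt_aa=str(row["wt"]),
            mut_aa=str(row["mut"]),
            disease_note=str(row.get("annotation", "") or ""),
        )
        for _, row in df.iterrows()
    ]
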