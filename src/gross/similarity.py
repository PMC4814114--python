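"""TM-only pairwise sequence similarity and alignment-table handling.

Percent similarity between two receptors is computed column-by-column over
the gapless TM alignment: two residues are similar when their substitution
matrix entry (BLOSUM62 by default) is positive, and the similarity is
100 x (similar columns) / (columns compared).  Loops are ignored throughout.

An :class:`AlignmentEntry` is one row of the superfamily alignment table:
accession, class, the seven n.50 anchors as 1-based sequence indices, the
seven TM ranges, and the full sequence.  Because the TMs are gapless, the
anchors alone determine every BW label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from gross.structure import HELICES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric amino-acid pair scores (integer-valued log-odds)."""

    name: str
    scores: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        scores = dict(self.scores)
        for (a, b), v in list(scores.items()):
            back = scores.get((b, a))
            if back is None:
                scores[(b, a)] = v
            elif back != v:
                raise ValueError(f"{self.name}: asymmetric entry {a}-{b}")
        object.__setattr__(self, "scores", scores)

    def score(self, a: str, b: str) -> float:
        """Matrix entry; unknown letters (e.g. 'X' absent from the file) score 0."""
        return self.scores.get((a.upper(), b.upper()), 0.0)

    def similar(self, a: str, b: str) -> bool:
        return self.score(a, b) > 0

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        return cls._from_biopython("BLOSUM62")

    @classmethod
    def _from_biopython(cls, name: str) -> "SubstitutionMatrix":
        mat = substitution_matrices.load(name)
        scores = {
            (a, b): float(mat[a, b])
            for a in mat.alphabet
            for b in mat.alphabet
        }
        return cls(name=name, scores=scores)

    @classmethod
    def from_file(cls, path: str | Path, name: str = "custom") -> "SubstitutionMatrix":
        """Read a whitespace-separated square matrix with a header row of letters.

        Rows may optionally repeat the letter in the first column (NCBI style);
        lines starting with '#' are comments.
        """
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        letters = lines[0].split()
        scores: dict[tuple[str, str], float] = {}
        for i, line in enumerate(lines[1 : len(letters) + 1]):
            fields = line.split()
            if fields and fields[0].isalpha() and len(fields[0]) == 1 and len(fields) == len(letters) + 1:
                fields = fields[1:]
            if len(fields) != len(letters):
                raise ValueError(f"{path}: row {i} has {len(fields)} values, expected {len(letters)}")
            for j, value in enumerate(fields):
                scores[(letters[i], letters[j])] = float(value)
        return cls(name=name, scores=scores)


@dataclass(frozen=True)
class AlignmentEntry:
    """One protein of the superfamily TM alignment (sequence-index anchors)."""

    uniprot_ac: str
    class_label: str
    anchors: Mapping[int, int]            # helix -> 1-based sequence index of n.50
    tm_ranges: Mapping[int, tuple[int, int]]  # helix -> 1-based inclusive range
    sequence: str
    validate: bool = True

    def __post_init__(self) -> None:
        anchors = {int(n): int(i) for n, i in dict(self.anchors).items()}
        ranges = {int(n): (int(s), int(e)) for n, (s, e) in dict(self.tm_ranges).items()}
        if set(anchors) != set(HELICES) or set(ranges) != set(HELICES):
            raise ValueError(f"{self.uniprot_ac}: anchors and ranges must cover helices 1..7")
        object.__setattr__(self, "anchors", anchors)
        object.__setattr__(self, "tm_ranges", ranges)
        if not self.validate:
            return
        prev_end = None
        for n in HELICES:
            s, e = ranges[n]
            if s > e or s < 1 or e > len(self.sequence):
                raise ValueError(f"{self.uniprot_ac}: TM{n} range {s}..{e} invalid for sequence length {len(self.sequence)}")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.uniprot_ac}: TM{n} range overlaps TM{n - 1}")
            prev_end = e
            if not s <= anchors[n] <= e:
                raise ValueError(f"{self.uniprot_ac}: anchor {anchors[n]} outside TM{n} range {s}..{e}")

    def bw_extent(self, helix: int) -> tuple[int, int]:
        """BW index range covered by this protein's TM helix."""
        s, e = self.tm_ranges[helix]
        a = self.anchors[helix]
        return 50 + s - a, 50 + e - a

    def residue_at_bw(self, helix: int, bw_index: int) -> str | None:
        """One-letter residue at BW position n.bw_index, or None outside the TM."""
        lo, hi = self.bw_extent(helix)
        if not lo <= bw_index <= hi:
            return None
        pos = self.anchors[helix] + bw_index - 50  # 1-based
        return self.sequence[pos - 1]

    def shifted_anchor(self, helix: int, offset: int) -> "AlignmentEntry":
        """Copy with one anchor moved (validation off: scans probe off-range shifts)."""
        anchors = dict(self.anchors)
        anchors[helix] += offset
        return replace(self, anchors=anchors, validate=False)


TMSpans = Mapping[int, tuple[int, int]]


def shared_spans(a: AlignmentEntry, b: AlignmentEntry) -> dict[int, tuple[int, int]]:
    """Per-helix BW span covered by both proteins."""
    out = {}
    for n in HELICES:
        lo = max(a.bw_extent(n)[0], b.bw_extent(n)[0])
        hi = min(a.bw_extent(n)[1], b.bw_extent(n)[1])
        out[n] = (lo, hi)
    return out


def average_tm_spans(entries: Sequence[AlignmentEntry]) -> dict[int, tuple[int, int]]:
    """Class-average TM extent in BW indices (rounded mean over entries)."""
    out = {}
    for n in HELICES:
        los = [e.bw_extent(n)[0] for e in entries]
        his = [e.bw_extent(n)[1] for e in entries]
        out[n] = (int(round(np.mean(los))), int(round(np.mean(his))))
    return out


def tm_similarity(
    a: AlignmentEntry,
    b: AlignmentEntry,
    tm_spans: TMSpans | None = None,
    matrix: SubstitutionMatrix | None = None,
    helices: Iterable[int] = HELICES,
) -> float:
    """Percent of aligned TM columns whose matrix score is positive.

    Columns are the BW positions of ``tm_spans`` (default: the extent both
    proteins share); a requested span exceeding either protein's TM is
    clipped to the shared extent.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    spans = tm_spans or shared_spans(a, b)
    similar = 0
    total = 0
    for n in helices:
        lo, hi = spans[n]
        lo_c = max(lo, a.bw_extent(n)[0], b.bw_extent(n)[0])
        hi_c = min(hi, a.bw_extent(n)[1], b.bw_extent(n)[1])
        if (lo_c, hi_c) != (lo, hi):
            logger.debug("TM%d span %d..%d clipped to %d..%d for %s/%s",
                         n, lo, hi, lo_c, hi_c, a.uniprot_ac, b.uniprot_ac)
        for bw in range(lo_c, hi_c + 1):
            ra = a.residue_at_bw(n, bw)
            rb = b.residue_at_bw(n, bw)
            if ra is None or rb is None:
                continue
            total += 1
            if matrix.similar(ra, rb):
                similar += 1
    if total == 0:
        raise ValueError(f"no comparable TM columns between {a.uniprot_ac} and {b.uniprot_ac}")
    return 100.0 * similar / total


def group_shift_scan(
    group_a: Sequence[AlignmentEntry],
    group_b: Sequence[AlignmentEntry],
    helix: int,
    offsets: Iterable[int] = range(-5, 6),
    matrix: SubstitutionMatrix | None = None,
    tm_spans: TMSpans | None = None,
) -> dict[int, float]:
    """Mean cross-pair similarity of one helix as group B's anchor is shifted.

    The robustness scan behind chemosensory-receptor placement: if the adopted
    alignment is right, offset 0 should maximize the mean similarity.
    Self-pairs (same accession in both groups) are excluded.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    matrix = matrix or SubstitutionMatrix.blosum62()
    out: dict[int, float] = {}
    for offset in offsets:
        values = []
        for ea in group_a:
            for eb in group_b:
                if ea.uniprot_ac == eb.uniprot_ac:
                    continue
                shifted = eb.shifted_anchor(helix, offset)
                try:
                    values.append(
                        tm_similarity(ea, shifted, tm_spans=tm_spans, matrix=matrix, helices=(helix,))
                    )
                except ValueError:
                    continue  # offset emptied the comparable span for this pair
        if not values:
            raise ValueError(f"offset {offset:+d} empties the comparable span on TM{helix}")
        out[offset] = float(np.mean(values))
    return out


# ---------------------------------------------------------------------------
# alignment-table I/O


def read_alignment_csv(path: str | Path, sequences: Mapping[str, str] | None = None) -> list[AlignmentEntry]:
    """Read the alignment table CSV.

    Columns: uniprot_ac, class, bw150_idx..bw750_idx, tm1_start..tm7_end and
    optionally sequence.  When the CSV lacks a sequence column, ``sequences``
    (accession -> sequence, e.g. from FASTA) must supply it.
    """
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        ac = str(row["uniprot_ac"])
        if "sequence" in df.columns and isinstance(row["sequence"], str):
            seq = row["sequence"]
        elif sequences is not None and ac in sequences:
            seq = sequences[ac]
        else:
            raise ValueError(f"{ac}: no sequence in CSV and none supplied")
        entries.append(
            AlignmentEntry(
                uniprot_ac=ac,
                class_label=str(row["class"]),
                anchors={n: int(row[f"bw{n}50_idx"]) for n in HELICES},
                tm_ranges={n: (int(row[f"tm{n}_start"]), int(row[f"tm{n}_end"])) for n in HELICES},
                sequence=seq,
            )
        )
    return entries


def write_alignment_csv(entries: Sequence[AlignmentEntry], path: str | Path, include_sequence: bool = True) -> None:
    rows = []
    for e in entries:
        row: dict[str, object] = {"uniprot_ac": e.uniprot_ac, "class": e.class_label}
        for n in HELICES:
            row[f"bw{n}50_idx"] = e.anchors[n]
            row[f"tm{n}_start"], row[f"tm{n}_end"] = e.tm_ranges[n]
        if include_sequence:
            row["sequence"] = e.sequence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def global_spans(entries: Sequence[AlignmentEntry]) -> dict[int, tuple[int, int]]:
    """Widest BW span per helix over all entries (the FASTA column layout)."""
    out = {}
    for n in HELICES:
        out[n] = (
            min(e.bw_extent(n)[0] for e in entries),
            max(e.bw_extent(n)[1] for e in entries),
        )
    return out


def write_tm_fasta(entries: Sequence[AlignmentEntry], path: str | Path, spans: TMSpans | None = None) -> dict[int, tuple[int, int]]:
    """Write the TM-only alignment as FASTA with '-' padding outside each TM.

    Columns are the BW positions of ``spans`` (default: the widest span over
    the entries), concatenated helix 1..7, so every record has equal length
    and BW columns line up superfamily-wide.  Returns the span layout used.
    """
    spans = dict(spans or global_spans(entries))
    with open(path, "w") as fh:
        for e in entries:
            parts = []
            for n in HELICES:
                lo, hi = spans[n]
                parts.append("".join(e.residue_at_bw(n, bw) or "-" for bw in range(lo, hi + 1)))
            fh.write(f">{e.uniprot_ac}|{e.class_label}\n{''.join(parts)}\n")
    return spans


def read_tm_fasta(path: str | Path, spans: TMSpans) -> list[AlignmentEntry]:
    """Read a TM-only FASTA written by :func:`write_tm_fasta`.

    The reconstructed entries carry the concatenated un-padded TM residues as
    their sequence (loops are not recoverable from the TM-only file), with
    anchors and ranges recomputed in that coordinate system.
    """
    entries = []
    widths = {n: spans[n][1] - spans[n][0] + 1 for n in HELICES}
    for record in SeqIO.parse(str(path), "fasta"):
        header = record.id
        ac, _, class_label = header.partition("|")
        text = str(record.seq)
        if len(text) != sum(widths.values()):
            raise ValueError(f"{ac}: record length {len(text)} does not match span layout")
        seq_parts: list[str] = []
        anchors: dict[int, int] = {}
        ranges: dict[int, tuple[int, int]] = {}
        cursor = 0
        consumed = 0
        for n in HELICES:
            lo, _hi = spans[n]
            block = text[cursor : cursor + widths[n]]
            cursor += widths[n]
            core = block.strip("-")
            if not core or "-" in core:
                raise ValueError(f"{ac}: TM{n} block is empty or gapped inside the TM")
            first_bw = lo + block.index(core[0])
            start = consumed + 1
            end = consumed + len(core)
            anchors[n] = start + (50 - first_bw)
            ranges[n] = (start, end)
            seq_parts.append(core)
            consumed = end
        entries.append(
            AlignmentEntry(
                uniprot_ac=ac,
                class_label=class_label,
                anchors=anchors,
                tm_ranges=ranges,
                sequence="".join(seq_parts),
                validate=False,
            )
        )
    return entries
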