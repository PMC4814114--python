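"""Variant mapping, CHICO/NACHO scoring, cohort summaries."""

import numpy as np
import pytest

from gross.contacts import BWPosition
from gross.similarity import AlignmentEntry, SubstitutionMatrix
from gross.variants import (
    NO_ROSTER_DISTANCE,
    RawVariant,
    annotate_variants,
    map_variant,
    rank_variants,
    read_variants_csv,
    roster_from_contacts,
    score_variant,
    summarize,
)

from conftest import contact


@pytest.fixture(scope="module")
def blosum():
    return SubstitutionMatrix.blosum62()


@pytest.fixture
def entry():
    # helix n occupies positions 20n+1 .. 20n+15, anchor at 20n+8 (-> n.50)
    seq = list("G" * 170)
    anchors, ranges = {}, {}
    for n in range(1, 8):
        start = 20 * n + 1
        anchors[n] = start + 7
        ranges[n] = (start, start + 14)
        for i in range(15):
            seq[start - 1 + i] = "ACDEFHIKLMNPQRS"[i]
    return AlignmentEntry("P00001", "A", anchors, ranges, "".join(seq))


def test_map_variant_tm_and_loop(entry):
    # position = anchor of TM3 -> 3.50
    v = map_variant(RawVariant("P00001", 68, "K", "R"), entry)
    assert str(v.bw) == "3.50"
    assert v.wt_matches
    # four residues before the anchor -> 3.46
    v2 = map_variant(RawVariant("P00001", 64, "E", "A"), entry)
    assert str(v2.bw) == "3.46"
    # a loop position maps to no BW label
    v3 = map_variant(RawVariant("P00001", 10, "G", "A"), entry)
    assert v3.bw is None
    with pytest.raises(ValueError):
        map_variant(RawVariant("P00001", 9999, "A", "V"), entry)


def test_wt_mismatch_flagged_not_fatal(entry):
    v = map_variant(RawVariant("P00001", 68, "W", "R"), entry)
    assert not v.wt_matches


def test_score_hand_evaluated_cases(entry, blosum):
    # roster {3.50} with multiplicity 2 on both lists; variant at 3.46, A->V:
    # 4 + 4 - 2 - 2 + blosum62(A, V) = 4 + 0 = 4
    roster = {BWPosition(3, 50): 2}
    v = map_variant(RawVariant("P00001", 64, "E", "A"), entry)
    v = score_variant(
        type(v)(**{**v.__dict__, "wt_aa": "A", "mut_aa": "V"}), roster, roster, blosum
    )
    assert v.d_nacho == 4 and v.d_chico == 4
    assert v.mult_nacho == 2 and v.mult_chico == 2
    assert v.score == pytest.approx(4 + 4 - 2 - 2 + blosum.score("A", "V"))

    # variant sitting on both rosters: distance terms vanish
    v0 = map_variant(RawVariant("P00001", 68, "K", "R"), entry)
    v0 = score_variant(v0, roster, roster, blosum)
    assert v0.d_nacho == 0 and v0.d_chico == 0
    assert v0.score == pytest.approx(0 + 0 - 2 - 2 + blosum.score("K", "R"))


def test_score_sentinel_when_helix_has_no_roster_residue(entry, blosum):
    roster = {BWPosition(6, 36): 1}
    v = map_variant(RawVariant("P00001", 68, "K", "R"), entry)  # on TM3
    v = score_variant(v, roster, roster, blosum)
    assert v.d_nacho == NO_ROSTER_DISTANCE and v.d_chico == NO_ROSTER_DISTANCE
    assert v.no_roster_flag


def test_score_monotonic_in_distance_and_multiplicity(entry, blosum):
    v = map_variant(RawVariant("P00001", 64, "E", "A"), entry)
    base = score_variant(v, {BWPosition(3, 50): 1}, {BWPosition(3, 50): 1}, blosum).score
    closer = score_variant(v, {BWPosition(3, 47): 1}, {BWPosition(3, 50): 1}, blosum).score
    assert closer < base  # smaller distance -> lower (more urgent) score
    heavier = score_variant(v, {BWPosition(3, 50): 4}, {BWPosition(3, 50): 1}, blosum).score
    assert heavier < base  # higher multiplicity -> lower score


def test_nearest_roster_tie_prefers_higher_multiplicity(entry, blosum):
    v = map_variant(RawVariant("P00001", 64, "E", "A"), entry)  # 3.46
    roster = {BWPosition(3, 44): 1, BWPosition(3, 48): 3}  # both at distance 2
    scored = score_variant(v, roster, roster, blosum)
    assert scored.d_nacho == 2 and scored.mult_nacho == 3


def test_roster_from_contacts_multiplicities():
    contacts = [contact(3, 46, 6, 37), contact(3, 46, 7, 53), contact(2, 45, 3, 42)]
    roster = roster_from_contacts(contacts)
    assert roster[BWPosition(3, 46)] == 2
    assert roster[BWPosition(6, 37)] == 1
    assert len(roster) == 5


def _synthetic_cohort(entry, rng, n=120):
    raw = []
    for k in range(n):
        pos = int(rng.integers(1, len(entry.sequence) + 1))
        note = "disease X" if rng.random() < 0.4 else ""
        raw.append(RawVariant("P00001", pos, entry.sequence[pos - 1], "A", note))
    return raw


def test_summary_partition_identities(entry, blosum, rng):
    chico = {BWPosition(3, 50): 2, BWPosition(2, 45): 1}
    nacho = {BWPosition(3, 46): 1, BWPosition(6, 37): 2}
    raw = _synthetic_cohort(entry, rng)
    records = annotate_variants(raw, {"P00001": entry}, chico, nacho, blosum)
    table = summarize(records, exclude_classes=()).set_index("subset")

    # brute-force tallies
    assert table.loc["all", "count"] == len(raw)
    assert table.loc["tm", "count"] + table.loc["non_tm", "count"] == table.loc["all", "count"]
    assert (
        table.loc["chico_only", "count"]
        + table.loc["nacho_only", "count"]
        + table.loc["both", "count"]
        <= table.loc["tm", "count"]
    )
    assert table.loc["chico", "count"] == table.loc["chico_only", "count"] + table.loc["both", "count"]
    assert table.loc["nacho", "count"] == table.loc["nacho_only", "count"] + table.loc["both", "count"]

    for subset in table.index:
        row = table.loc[subset]
        if row["count"]:
            assert row["percent_disease"] == pytest.approx(
                round(100.0 * row["disease_annotated"] / row["count"], 1)
            )

    # brute-force recount of the TM subset
    tm_count = sum(1 for r in records if r.in_tm)
    assert table.loc["tm", "count"] == tm_count


def test_summary_empty_cohort_is_all_zero():
    table = summarize([]).set_index("subset")
    assert (table["count"] == 0).all()
    assert (table["percent_disease"] == 0.0).all()


def test_class_exclusion_filters_summary(entry, blosum, rng):
    olfactory_entry = AlignmentEntry(
        "OLF1", "Olfactory", entry.anchors, entry.tm_ranges, entry.sequence
    )
    raw = [RawVariant("OLF1", 68, "K", "R", "anosmia")]
    records = annotate_variants(raw, {"OLF1": olfactory_entry}, {}, {}, blosum)
    table = summarize(records).set_index("subset")
    assert table.loc["all", "count"] == 1
    assert table.loc["tm", "count"] == 0  # olfactory excluded below the 'all' row


def test_ranking_sorted_by_score(entry, blosum, rng):
    chico = {BWPosition(n, 50): 2 for n in range(1, 8)}
    nacho = {BWPosition(n, 46): 1 for n in range(1, 8)}
    raw = _synthetic_cohort(entry, rng, n=60)
    records = annotate_variants(raw, {"P00001": entry}, chico, nacho, blosum)
    ranked = rank_variants(records)
    scores = ranked["score"].to_numpy()
    assert (np.diff(scores) >= 0).all()
    assert len(ranked) == sum(1 for r in records if r.in_tm)


def test_variant_csv_reader(tmp_path):
    path = tmp_path / "v.csv"
    path.write_text("uniprot_ac,position,wt,mut,annotation\nP1,10,A,V,dwarfism\nP2,3,G,R,\n")
    raw = read_variants_csv(path)
    assert raw[0] == RawVariant("P1", 10, "A", "V", "dwarfism")
    assert raw[1].disease_note == ""


def test_unknown_accession_rejected(entry, blosum):
    with pytest.raises(KeyError):
        annotate_variants([RawVariant("NOPE", 5, "G", "A")], {"P00001": entry}, {}, {}, blosum)
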