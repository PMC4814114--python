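"""BW labeling, common-contact counting, anchor search, superposition."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gross.alignment import (
    BWAnchor,
    bw_label,
    count_common,
    kabsch,
    search_anchors,
    superpose_rmsd,
)
from gross.contacts import ContactSet, detect_contacts
from gross.synthetic import (
    BundleSpec,
    RigidPerturbation,
    make_bundle,
    perturb,
    random_rotation,
    renumber,
)

from conftest import contact, contact_set


def test_bw_label_arithmetic():
    anchors = BWAnchor({1: 134, 2: 200, 3: 300, 4: 400, 5: 500, 6: 600, 7: 700})
    assert str(bw_label(anchors, 1, 134)) == "1.50"
    assert str(bw_label(anchors, 1, 130)) == "1.46"
    assert str(bw_label(anchors, 1, 140)) == "1.56"
    with pytest.raises(ValueError):
        bw_label(anchors, 1, 99, tm_range=(120, 150))


def test_count_common_is_symmetric_intersection(rng):
    universe = [
        contact(a, i, b, j)
        for a, b in itertools.combinations(range(1, 8), 2)
        for i, j in [(44, 41), (50, 50), (47, 39), (42, 55)]
    ]
    planted = rng.choice(len(universe), size=9, replace=False)
    shared = [universe[i] for i in planted]
    only_a = [c for i, c in enumerate(universe) if i not in planted and rng.random() < 0.3]
    only_b = [c for i, c in enumerate(universe) if i not in planted and c not in only_a and rng.random() < 0.3]
    set_a = ContactSet("A", frozenset(shared + only_a))
    set_b = ContactSet("B", frozenset(shared + only_b))
    assert count_common(set_a, set_b) == len(shared)
    assert count_common(set_a, set_b) == count_common(set_b, set_a)
    assert count_common(set_a, set_b) <= min(len(set_a), len(set_b))
    assert count_common(set_a, set_a) == len(set_a)
    assert count_common(set_a, ContactSet("E", frozenset())) == 0


class TestSearchAnchors:
    def test_window_zero_returns_initial(self, default_bundle):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        cands = search_anchors(default_bundle.bundle, default_bundle.anchors, [cs], window=0)
        assert len(cands) == 1
        assert cands[0].shifts == {n: 0 for n in range(1, 8)}
        assert cands[0].cumulative_common == len(cs)

    def test_self_search_top_ranked_at_zero_shift(self, default_bundle):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        cands = search_anchors(default_bundle.bundle, default_bundle.anchors, [cs], window=4)
        assert cands[0].shifts == {n: 0 for n in range(1, 8)}
        assert cands[0].cumulative_common == len(cs)

    @pytest.mark.parametrize("helix", range(1, 8))
    @pytest.mark.parametrize("offset", [-4, -2, -1, 1, 2, 4])
    def test_planted_single_helix_shift_recovered(self, helix, offset, default_bundle):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        shifted = renumber(default_bundle, {helix: offset})
        cands = search_anchors(shifted.bundle, default_bundle.anchors, [cs], window=4)
        assert dict(cands[0].anchors.anchors) == dict(shifted.anchors.anchors)
        assert cands[0].cumulative_common == len(cs)

    def test_planted_multi_helix_shift_recovered_joint_and_coordinate(self, default_bundle):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        offsets = {2: 3, 5: -2, 7: 1}
        shifted = renumber(default_bundle, offsets)
        for mode in ("coordinate", "joint"):
            cands = search_anchors(shifted.bundle, default_bundle.anchors, [cs], window=3, mode=mode)
            assert dict(cands[0].anchors.anchors) == dict(shifted.anchors.anchors), mode

    def test_score_invariant_under_rigid_motion(self, default_bundle, rng):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        moved = perturb(
            default_bundle, {},
            global_rotation=random_rotation(rng),
            global_translation=rng.normal(size=3) * 8,
        )
        a = search_anchors(default_bundle.bundle, default_bundle.anchors, [cs], window=2)
        b = search_anchors(moved.bundle, moved.anchors, [cs], window=2)
        assert a[0].cumulative_common == b[0].cumulative_common
        assert a[0].shifts == b[0].shifts

    def test_cumulative_score_counts_reference_multiplicity(self, default_bundle):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        triple = [cs, cs, cs]
        cands = search_anchors(default_bundle.bundle, default_bundle.anchors, triple, window=1)
        assert cands[0].cumulative_common == 3 * len(cs)

    def test_pinned_anchor_respected(self, default_bundle):
        cs = detect_contacts(default_bundle.bundle, default_bundle.anchors)
        cands = search_anchors(
            default_bundle.bundle, default_bundle.anchors, [cs], window=2, pinned={4: 1}
        )
        assert cands[0].shifts[4] == 1


class TestSuperposition:
    def test_self_rmsd_zero(self, default_bundle):
        rmsd = superpose_rmsd(
            default_bundle.bundle, default_bundle.bundle,
            default_bundle.anchors, default_bundle.anchors,
        )
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_copy_rmsd_zero(self, default_bundle, rng):
        moved = perturb(
            default_bundle, {},
            global_rotation=random_rotation(rng),
            global_translation=rng.normal(size=3) * 5,
        )
        rmsd = superpose_rmsd(default_bundle.bundle, moved.bundle,
                              default_bundle.anchors, moved.anchors)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rmsd_matches_independent_kabsch_oracle(self, default_bundle):
        # one helix translated 2 Å after optimal fit; oracle = scipy quaternion
        # superposition, an implementation independent of the SVD route
        moved = perturb(default_bundle, {3: RigidPerturbation(t_perp=2.0)})
        rmsd = superpose_rmsd(default_bundle.bundle, moved.bundle,
                              default_bundle.anchors, moved.anchors)
        from gross.alignment import paired_ca

        pa, pb = paired_ca(default_bundle.bundle, moved.bundle,
                           default_bundle.anchors, moved.anchors)
        rot, oracle_rssd = Rotation.align_vectors(pa - pa.mean(0), pb - pb.mean(0))
        oracle_rmsd = oracle_rssd / math.sqrt(len(pa))
        assert rmsd == pytest.approx(oracle_rmsd, abs=1e-6)
        assert rmsd > 0.1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.ones((3, 3)))


def test_kabsch_recovers_known_transform(rng):
    pts = rng.normal(size=(30, 3)) * 5
    rot_true = random_rotation(rng)
    trans_true = rng.normal(size=3)
    moved = pts @ rot_true.T + trans_true
    rot, trans, rmsd = kabsch(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(rot, rot_true, atol=1e-9)
    assert np.allclose(trans, trans_true, atol=1e-9)
    assert np.linalg.det(rot) == pytest.approx(1.0)
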