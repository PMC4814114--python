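"""Helix-axis fitting and rigid-body move decomposition."""

import math

import numpy as np
import pytest

from gross.moves import decompose_move, fit_axis, pairwise_moves
from gross.synthetic import (
    BundleSpec,
    RigidPerturbation,
    make_bundle,
    perturb,
    random_rotation,
)


def ideal_helix(length=20, rise=1.5, turn=100.0, radius=2.3):
    coords = np.empty((length, 3))
    for i in range(length):
        theta = math.radians(i * turn)
        coords[i] = [radius * math.cos(theta), radius * math.sin(theta), i * rise]
    return coords


class TestFitAxis:
    def test_axis_of_z_aligned_helix(self):
        axis = fit_axis(ideal_helix())
        assert np.allclose(axis.direction, [0, 0, 1], atol=1e-6)

    def test_equivariance_under_rotation(self, rng):
        coords = ideal_helix()
        rot = random_rotation(rng)
        rotated = coords @ rot.T
        axis = fit_axis(rotated)
        expected = rot @ np.array([0.0, 0.0, 1.0])
        assert np.allclose(axis.direction, expected, atol=1e-6)

    def test_noisy_axis_within_two_degrees(self, rng):
        coords = ideal_helix(length=26) + rng.normal(0, 0.2, (26, 3))
        axis = fit_axis(coords)
        angle = math.degrees(math.acos(abs(float(axis.direction @ [0, 0, 1]))))
        assert angle < 2.0

    def test_orientation_follows_residue_order(self):
        coords = ideal_helix()
        up = fit_axis(coords)
        down = fit_axis(coords[::-1])
        assert float(up.direction @ down.direction) == pytest.approx(-1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_axis(ideal_helix(length=3))


class TestDecomposeMove:
    def test_identity_gives_zeros(self, default_bundle):
        mv = decompose_move(
            default_bundle.bundle, default_bundle.bundle,
            default_bundle.anchors, default_bundle.anchors, helix=4,
        )
        assert mv.t_axial == pytest.approx(0.0, abs=1e-9)
        assert mv.t_perp == pytest.approx(0.0, abs=1e-9)
        assert mv.tilt == pytest.approx(0.0, abs=1e-6)
        assert mv.spin == pytest.approx(0.0, abs=1e-6)
        assert mv.residual_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_whole_bundle_motion_reports_zeros(self, default_bundle, rng):
        moved = perturb(
            default_bundle, {},
            global_rotation=random_rotation(rng),
            global_translation=rng.normal(size=3) * 10,
        )
        for helix in (1, 4, 7):
            mv = decompose_move(default_bundle.bundle, moved.bundle,
                                default_bundle.anchors, moved.anchors, helix)
            assert abs(mv.t_axial) < 1e-9 and mv.t_perp < 1e-9
            assert mv.tilt < 1e-6 and abs(mv.spin) < 1e-6

    def test_planted_transform_recovered_to_1e3(self, default_bundle, rng):
        planted = RigidPerturbation(t_axial=1.2, t_perp=0.8, tilt=6.0, spin=25.0)
        moved = perturb(
            default_bundle, {6: planted},
            global_rotation=random_rotation(rng),
            global_translation=rng.normal(size=3) * 5,
        )
        # superpose on the six unmoved helices so the global fit cannot
        # absorb part of the planted move
        mv = decompose_move(
            default_bundle.bundle, moved.bundle,
            default_bundle.anchors, moved.anchors, helix=6,
            superpose_helices=(1, 2, 3, 4, 5, 7),
        )
        assert mv.t_axial == pytest.approx(planted.t_axial, abs=1e-3)
        assert mv.t_perp == pytest.approx(planted.t_perp, abs=1e-3)
        assert mv.tilt == pytest.approx(planted.tilt, abs=1e-3)
        assert mv.spin == pytest.approx(planted.spin, abs=1e-3)

    def test_axial_spin_only_move_recovered(self, default_bundle):
        moved = perturb(default_bundle, {6: RigidPerturbation(t_axial=1.2, spin=25.0)})
        mv = decompose_move(default_bundle.bundle, moved.bundle,
                            default_bundle.anchors, moved.anchors, helix=6,
                            presuperpose=False)
        assert mv.t_axial == pytest.approx(1.2, abs=1e-3)
        assert mv.t_perp == pytest.approx(0.0, abs=1e-3)
        assert mv.tilt == pytest.approx(0.0, abs=1e-3)
        assert mv.spin == pytest.approx(25.0, abs=1e-3)
        assert mv.residual_rmsd == pytest.approx(0.0, abs=1e-6)

    def test_swap_negates_axial_and_spin_preserves_tilt(self, default_bundle):
        moved = perturb(default_bundle, {2: RigidPerturbation(t_axial=0.9, tilt=4.0, spin=-18.0)})
        fwd = decompose_move(default_bundle.bundle, moved.bundle,
                             default_bundle.anchors, moved.anchors, 2,
                             superpose_helices=(1, 3, 4, 5, 6, 7))
        rev = decompose_move(moved.bundle, default_bundle.bundle,
                             moved.anchors, default_bundle.anchors, 2,
                             superpose_helices=(1, 3, 4, 5, 6, 7))
        assert fwd.t_axial == pytest.approx(-rev.t_axial, abs=1e-2)
        assert fwd.spin == pytest.approx(-rev.spin, abs=0.2)
        assert fwd.tilt == pytest.approx(rev.tilt, abs=0.2)

    def test_pythagorean_translation_decomposition(self, default_bundle, rng):
        moved = perturb(default_bundle, {5: RigidPerturbation(t_axial=1.1, t_perp=0.7, tilt=3.0)})
        mv = decompose_move(default_bundle.bundle, moved.bundle,
                            default_bundle.anchors, moved.anchors, 5,
                            presuperpose=False)
        assert mv.t_total**2 == pytest.approx(mv.t_axial**2 + mv.t_perp**2, abs=1e-6)

    def test_per_helix_fit_beats_global_residual(self, default_bundle):
        moved = perturb(default_bundle, {3: RigidPerturbation(t_perp=1.5, spin=15.0)})
        from gross.alignment import kabsch, paired_ca

        pa_all, pb_all = paired_ca(default_bundle.bundle, moved.bundle,
                                   default_bundle.anchors, moved.anchors)
        rot, trans, _ = kabsch(pb_all, pa_all)
        pa, pb = paired_ca(default_bundle.bundle, moved.bundle,
                           default_bundle.anchors, moved.anchors, (3,))
        global_rmsd = float(np.sqrt(np.mean(np.sum((pb @ rot.T + trans - pa) ** 2, axis=1))))
        mv = decompose_move(default_bundle.bundle, moved.bundle,
                            default_bundle.anchors, moved.anchors, 3)
        assert mv.residual_rmsd <= global_rmsd + 1e-9


def test_pairwise_moves_table_shape(default_bundle):
    moved = perturb(default_bundle, {6: RigidPerturbation(spin=10.0)})
    other = perturb(default_bundle, {2: RigidPerturbation(t_axial=0.5)})
    df = pairwise_moves([
        (default_bundle.bundle, default_bundle.anchors),
        (moved.bundle, moved.anchors),
        (other.bundle, other.anchors),
    ])
    assert len(df) == 3 * 7
    assert set(df.columns) >= {"structure_a", "structure_b", "helix",
                               "t_axial", "t_perp", "tilt", "spin", "residual_rmsd"}
    assert (df.tilt >= 0).all() and (df.tilt <= 180).all()
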