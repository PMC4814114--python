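"""Rigid-body decomposition of per-helix differences between two structures.

After superposing two TM bundles globally (least squares over all BW-paired
Cα atoms), the residual motion of each helix is described as a rigid move in
the helix's own frame:

* ``t_axial``  — centroid displacement projected on the helix axis (Å, signed);
* ``t_perp``   — norm of the perpendicular component (Å);
* ``tilt``     — angle between the two helix axes (deg, 0..180);
* ``spin``     — rotation about the axis, after removing translation and
  tilt, that best maps the paired Cα atoms (deg, signed, (-180, 180]);
* ``residual_rmsd`` — Cα RMSD after the full per-helix rigid fit (Å).

The helix axis is the first principal component of the Cα cloud, oriented
from the first to the last paired residue so the sign convention is shared
by both structures.  These move sizes bound how far a helix must travel
between a template and a target — the practical currency of homology-model
refinement — and, for active/inactive pairs, quantify the activation motion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from gross.alignment import BWAnchor, kabsch, paired_ca
from gross.structure import HELICES, TMBundle


@dataclass(frozen=True)
class HelixAxis:
    """Unit direction plus centroid of one helix."""

    direction: np.ndarray
    centroid: np.ndarray

    def __post_init__(self) -> None:
        direction = np.asarray(self.direction, dtype=float)
        centroid = np.asarray(self.centroid, dtype=float)
        norm = np.linalg.norm(direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-9):
            direction = direction / norm
        object.__setattr__(self, "direction", direction)
        object.__setattr__(self, "centroid", centroid)


@dataclass(frozen=True)
class HelixMove:
    """Rigid move of one helix between two globally superposed structures."""

    t_axial: float
    t_perp: float
    tilt: float
    spin: float
    residual_rmsd: float

    def __post_init__(self) -> None:
        for name in ("t_axial", "t_perp", "tilt", "spin", "residual_rmsd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.tilt <= 180.0:
            raise ValueError(f"tilt {self.tilt} outside [0, 180]")
        if not -180.0 < self.spin <= 180.0:
            raise ValueError(f"spin {self.spin} outside (-180, 180]")

    @property
    def t_total(self) -> float:
        return math.hypot(self.t_axial, self.t_perp)


def fit_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Axis of a helix's Cα trace.

    A helix maps onto itself under a screw motion of one residue step, so the
    least-squares rotation superposing the trace onto itself shifted by one
    residue has the helix axis as its rotation axis — exact for ideal
    geometry, and robust to coordinate noise because the whole trace enters
    the fit.  Falls back to the first principal component if the fitted
    rotation degenerates (near-straight trace).  The direction is oriented
    from the first toward the last residue, which makes the sign convention
    consistent between paired helices of two structures.
    """
    coords = np.asarray(ca_coords, dtype=float).reshape(-1, 3)
    if len(coords) < 4:
        raise ValueError(f"axis fit needs >=4 C-alpha positions, got {len(coords)}")
    centroid = coords.mean(axis=0)
    chord = coords[-1] - coords[0]

    rot, _trans, _rmsd = kabsch(coords[:-1], coords[1:])
    skew = np.array([rot[2, 1] - rot[1, 2], rot[0, 2] - rot[2, 0], rot[1, 0] - rot[0, 1]])
    norm = np.linalg.norm(skew)
    if norm > 1e-8:
        direction = skew / norm
    else:
        _u, _s, vt = np.linalg.svd(coords - centroid, full_matrices=False)
        direction = vt[0]
    if np.dot(direction, chord) < 0:
        direction = -direction
    return HelixAxis(direction=direction, centroid=centroid)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    s = np.linalg.norm(v)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180 deg about any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / (s * s))


def decompose_move(
    bundle_a: TMBundle,
    bundle_b: TMBundle,
    anchors_a: BWAnchor,
    anchors_b: BWAnchor,
    helix: int,
    presuperpose: bool = True,
    superpose_helices: Iterable[int] = HELICES,
) -> HelixMove:
    """Rigid move taking helix ``helix`` of A onto the same helix of B.

    B is first superposed globally onto A over all BW-paired TM Cα atoms
    (``superpose_helices`` restricts the fit, e.g. to exclude a bending
    helix); the move is then measured in helix A's axis frame.  Signs:
    positive ``t_axial``/``spin`` describe the motion A → B; swapping the
    bundles negates both and preserves tilt.
    """
    pa_all, pb_all = paired_ca(bundle_a, bundle_b, anchors_a, anchors_b, superpose_helices)
    pa, pb = paired_ca(bundle_a, bundle_b, anchors_a, anchors_b, (helix,))
    if len(pa) < 4:
        raise ValueError(f"TM{helix}: need >=4 paired residues, got {len(pa)}")

    if presuperpose:
        if len(pa_all) < 3:
            raise ValueError("global superposition needs >=3 paired residues")
        rot, trans, _ = kabsch(pb_all, pa_all)
        pb = pb @ rot.T + trans

    axis_a = fit_axis(pa)
    axis_b = fit_axis(pb)

    t_vec = axis_b.centroid - axis_a.centroid
    t_axial = float(np.dot(t_vec, axis_a.direction))
    t_perp = float(np.linalg.norm(t_vec - t_axial * axis_a.direction))

    cos_tilt = float(np.clip(np.dot(axis_a.direction, axis_b.direction), -1.0, 1.0))
    tilt = math.degrees(math.acos(cos_tilt))

    # remove translation and tilt, then fit the spin about A's axis
    qa = pa - axis_a.centroid
    qb = (pb - axis_b.centroid) @ _rotation_between(axis_b.direction, axis_a.direction).T
    d = axis_a.direction
    qa_p = qa - np.outer(qa @ d, d)
    qb_p = qb - np.outer(qb @ d, d)
    # least-squares angle rotating A's projections onto B's: the spin A -> B
    sin_term = float(np.sum(np.cross(qa_p, qb_p) @ d))
    cos_term = float(np.sum(qa_p * qb_p))
    spin = math.degrees(math.atan2(sin_term, cos_term))
    if spin <= -180.0:
        spin += 360.0

    _rot_h, _t_h, residual = kabsch(pb, pa)

    return HelixMove(
        t_axial=t_axial,
        t_perp=t_perp,
        tilt=tilt,
        spin=spin,
        residual_rmsd=residual,
    )


def pairwise_moves(
    structures: Sequence[tuple[TMBundle, BWAnchor]],
    similarities: pd.DataFrame | None = None,
    helices: Iterable[int] = HELICES,
) -> pd.DataFrame:
    """Per-helix rigid moves for every pair of structures.

    Returns a long table (pair, helix, t_axial, t_perp, t_total, tilt, spin,
    residual_rmsd, and similarity when a matrix of percent similarities
    indexed by structure_id is supplied) — the scatter data behind move-size
    versus similarity plots.
    """
    rows = []
    for (ba, aa), (bb, ab) in combinations(structures, 2):
        for n in helices:
            mv = decompose_move(ba, bb, aa, ab, n)
            row = {
                "structure_a": ba.structure_id,
                "structure_b": bb.structure_id,
                "helix": n,
                "t_axial": mv.t_axial,
                "t_perp": mv.t_perp,
                "t_total": mv.t_total,
                "tilt": mv.tilt,
                "spin": mv.spin,
                "residual_rmsd": mv.residual_rmsd,
            }
            if similarities is not None:
                row["similarity"] = float(similarities.loc[ba.structure_id, bb.structure_id])
            rows.append(row)
    return pd.DataFrame(rows)
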