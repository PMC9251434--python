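"""Recovery of rigid-body modes from conformer ensembles.

Conformers are least-squares superposed onto a reference using an anchor
group (by default the two proximal core-particle rings), decomposed by
PCA of the flattened coordinates, and individual group motions are
reduced to screw-axis descriptors: rotation angle, axis, the pivot (the
point on the screw axis nearest the group centroid), translation along
the axis, and the largest single-bead displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import BeadModel

__all__ = [
    "MotionDescriptor",
    "align_ensemble",
    "principal_modes",
    "decompose_rigid_motion",
    "classify_mode",
    "StructureMismatchError",
    "DegenerateGeometryError",
]

DEFAULT_ANCHOR = ("cp_alpha_proximal", "cp_beta_1")

#: classification thresholds (artifact choices; the motions themselves are
#: named in the literature but without numeric cutoffs)
ANGLE_MIN_DEG = 2.0
DISPLACEMENT_MIN_A = 0.5
AXIS_CONE_DEG = 15.0
PERP_CONE_DEG = 75.0


class StructureMismatchError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class MotionDescriptor:
    """Screw-axis summary of one group's rigid motion."""

    rotation_angle: float  # degrees, in [0, 180]
    rotation_axis: np.ndarray  # unit 3-vector
    pivot: np.ndarray  # point on the screw axis closest to the group centroid
    translation_along_axis: float  # Angstrom (signed along rotation_axis)
    max_displacement: float  # Angstrom
    group: str | tuple[str, ...] | None = None


def _check_compatible(conformer: BeadModel, reference: BeadModel) -> None:
    if len(conformer) != len(reference) or not np.array_equal(
        conformer.bead_ids, reference.bead_ids
    ) or not np.array_equal(conformer.groups, reference.groups):
        raise StructureMismatchError(
            "conformer bead ids/groups do not match the reference"
        )


def _superpose(moving: np.ndarray, target: np.ndarray):
    """Least-squares rigid fit: returns (R, t) with moving @ R.T + t ~ target."""
    cm = moving.mean(axis=0)
    ct = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, moving - cm)
    rmat = rot.as_matrix()
    return rmat, ct - rmat @ cm


def align_ensemble(
    conformers: list[BeadModel],
    reference: BeadModel,
    anchor_group=DEFAULT_ANCHOR,
) -> np.ndarray:
    """Superpose each conformer onto the reference via the anchor beads.

    Returns an (n_conformers, 3 * n_beads) matrix of flattened aligned
    coordinates, in the reference frame.
    """
    mask = reference.group_mask(anchor_group)
    if mask.sum() < 3:
        raise DegenerateGeometryError("anchor group has fewer than 3 beads")
    rows = []
    for conf in conformers:
        _check_compatible(conf, reference)
        rmat, t = _superpose(conf.positions[mask], reference.positions[mask])
        rows.append((conf.positions @ rmat.T + t).ravel())
    return np.asarray(rows)


def principal_modes(aligned: np.ndarray, k: int):
    """Mean-centered PCA of the aligned coordinate matrix.

    Returns (components (k, 3m), variances (k,), projections (n, k)).
    Variances are non-increasing; with full rank k the projections
    reproduce the centered data exactly.
    """
    aligned = np.asarray(aligned, dtype=float)
    n = aligned.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 conformers")
    if k > min(n - 1, aligned.shape[1]):
        raise ValueError("k exceeds the available rank")
    centered = aligned - aligned.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / (n - 1)
    return vt[:k], variances[:k], u[:, :k] * s[:k]


def decompose_rigid_motion(
    reference: BeadModel, moved: BeadModel, group
) -> MotionDescriptor:
    """Optimal rigid motion of ``group`` between two conformers.

    The rotation comes from least-squares superposition, the angle from
    its trace; the screw axis and pivot from the rotation plus residual
    translation.  Constructed rigid motions are recovered exactly (up to
    floating point).
    """
    _check_compatible(moved, reference)
    mask = reference.group_mask(group)
    p = reference.positions[mask]
    q = moved.positions[mask]
    if len(p) < 3:
        raise DegenerateGeometryError("group needs >= 3 beads")
    # non-collinearity: at least 2 significant principal extents
    ev = np.linalg.svd(p - p.mean(axis=0), compute_uv=False)
    if ev[1] < 1e-9:
        raise DegenerateGeometryError("group beads are collinear")

    rmat, tvec = _superpose(p, q)  # x -> R x + t
    rot = Rotation.from_matrix(rmat)
    angle_deg = float(np.rad2deg(rot.magnitude()))
    centroid = p.mean(axis=0)
    disp = q - p
    max_disp = float(np.linalg.norm(disp, axis=1).max())

    if angle_deg < 1e-7:
        d = q.mean(axis=0) - centroid
        norm = np.linalg.norm(d)
        axis = d / norm if norm > 1e-12 else np.array([0.0, 0.0, 1.0])
        return MotionDescriptor(
            rotation_angle=angle_deg,
            rotation_axis=axis,
            pivot=centroid.copy(),
            translation_along_axis=float(norm),
            max_displacement=max_disp,
            group=group,
        )

    axis = rot.as_rotvec()
    axis = axis / np.linalg.norm(axis)
    t_along = float(np.dot(axis, tvec))
    d_perp = tvec - t_along * axis
    # point on the screw axis: (I - R) p0 = d_perp, minimum-norm solution,
    # then slide along the axis to the point nearest the group centroid
    p0, *_ = np.linalg.lstsq(np.eye(3) - rmat, d_perp, rcond=None)
    pivot = p0 + axis * np.dot(centroid - p0, axis)
    return MotionDescriptor(
        rotation_angle=angle_deg,
        rotation_axis=axis,
        pivot=pivot,
        translation_along_axis=t_along,
        max_displacement=max_disp,
        group=group,
    )


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


def classify_mode(descriptor: MotionDescriptor, barrel_axis) -> str:
    """Label a motion as rotation / tilt / compression / translation / mixed.

    Rotation and tilt require an angle of at least 2 deg with the screw
    axis within 15 deg of (either direction of) the barrel axis, or at
    least 75 deg from it, respectively; an axial screw translation above
    0.5 A makes the motion mixed.  Small-angle motions are compressions
    when a core-particle group translates anti-parallel (within 15 deg)
    to the barrel axis, otherwise plain translations.
    """
    barrel_axis = np.asarray(barrel_axis, dtype=float)
    barrel_axis = barrel_axis / np.linalg.norm(barrel_axis)
    groups = descriptor.group
    if isinstance(groups, str):
        groups = (groups,)
    on_cp = bool(groups) and all(g.startswith("cp_") for g in groups)

    if descriptor.rotation_angle >= ANGLE_MIN_DEG:
        if abs(descriptor.translation_along_axis) >= DISPLACEMENT_MIN_A:
            return "mixed"
        axis_angle = _angle_between_deg(descriptor.rotation_axis, barrel_axis)
        axis_angle = min(axis_angle, 180.0 - axis_angle)
        if axis_angle <= AXIS_CONE_DEG:
            return "rotation"
        if axis_angle >= PERP_CONE_DEG:
            return "tilt"
        return "mixed"

    if descriptor.max_displacement >= DISPLACEMENT_MIN_A:
        t_dir = descriptor.rotation_axis  # translation direction for angle ~ 0
        if on_cp and _angle_between_deg(t_dir, -barrel_axis) <= AXIS_CONE_DEG:
            return "compression"
        return "translation"
    return "translation"
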