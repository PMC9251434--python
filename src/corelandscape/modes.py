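"""Rigid-body conformational modes and their forward application.

The default catalogue mirrors the motions seen in the 26S proteasome:

* lid rotation about the barrel axis (pivot at the RPN11 marker, 0-35 deg),
* lid tilt about an axis perpendicular to the barrel (4-10 deg),
* core-particle compression — axial translation of the two distal CP
  rings toward the proximal face (0-12 A),
* RPN1 swing — free translation of the RPN1 cluster (1-25 A).

Amplitude 0 is always accepted as the resting reference, even for modes
whose observed amplitude range starts above zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .assembly import BeadModel, ConfigurationError, GROUPS

__all__ = ["ModeSpec", "define_modes", "apply_modes", "AmplitudeError"]


class AmplitudeError(ValueError):
    """Amplitude outside a mode's allowed range."""


@dataclass(frozen=True)
class ModeSpec:
    """One named rigid-body motion of a bead group.

    ``axis`` must be unit-norm.  Rotation/tilt amplitudes are in degrees,
    translation/compression amplitudes in Angstrom.
    """

    name: str
    kind: str  # rotation | tilt | translation | compression
    affected_groups: tuple[str, ...]
    pivot: tuple[float, float, float]
    axis: tuple[float, float, float]
    amplitude_range: tuple[float, float]

    def __post_init__(self):
        if self.kind not in ("rotation", "tilt", "translation", "compression"):
            raise ConfigurationError(f"unknown mode kind {self.kind!r}")
        unknown = set(self.affected_groups) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown group label(s): {sorted(unknown)}")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ConfigurationError(f"mode {self.name!r}: axis must be unit-norm")
        lo, hi = self.amplitude_range
        if lo > hi:
            raise ConfigurationError(f"mode {self.name!r}: amplitude min > max")

    @property
    def is_angular(self) -> bool:
        return self.kind in ("rotation", "tilt")

    def check_amplitude(self, amplitude: float) -> None:
        lo, hi = self.amplitude_range
        if amplitude == 0.0:
            return  # resting reference always valid
        if not (lo <= amplitude <= hi):
            raise AmplitudeError(
                f"mode {self.name!r}: amplitude {amplitude} outside [{lo}, {hi}]"
            )


def define_modes(
    reference: BeadModel, custom: list[ModeSpec] | None = None
) -> list[ModeSpec]:
    """Return the mode catalogue for ``reference``.

    With ``custom`` given (possibly empty), its specs are validated against
    the reference's groups and returned verbatim.  Otherwise the default
    four-mode catalogue is constructed from the reference geometry.
    """
    if custom is not None:
        for m in custom:
            for g in m.affected_groups:
                if not np.any(reference.groups == g):
                    raise ConfigurationError(
                        f"mode {m.name!r} references group {g!r} "
                        "absent from the reference"
                    )
        return list(custom)

    axis = reference.barrel_axis / np.linalg.norm(reference.barrel_axis)
    rpn11 = reference.positions[reference.group_mask("rpn11_marker")].mean(axis=0)
    lid_c = reference.positions[reference.group_mask("lid")].mean(axis=0)
    base_c = reference.positions[reference.group_mask("base_atpase")].mean(axis=0)
    # tilt pivot: centroid of the gap between lid and base (open question in
    # the source data; the surrogate uses the midpoint without claiming
    # fidelity)
    tilt_pivot = (lid_c + base_c) / 2.0
    tilt_axis = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(tilt_axis, axis)) > 0.99:  # barrel axis along x: pick y
        tilt_axis = np.array([0.0, 1.0, 0.0])
    tilt_axis = tilt_axis - np.dot(tilt_axis, axis) * axis
    tilt_axis /= np.linalg.norm(tilt_axis)
    swing_axis = np.cross(axis, tilt_axis)

    return [
        ModeSpec(
            "lid_rotation",
            "rotation",
            ("lid",),
            tuple(rpn11),
            tuple(axis),
            (0.0, 35.0),
        ),
        ModeSpec(
            "lid_tilt",
            "tilt",
            ("lid",),
            tuple(tilt_pivot),
            tuple(tilt_axis),
            (4.0, 10.0),
        ),
        ModeSpec(
            "cp_compression",
            "compression",
            ("cp_alpha_distal", "cp_beta_2"),
            tuple(reference.axis_origin),
            tuple(-axis),
            (0.0, 12.0),
        ),
        ModeSpec(
            "rpn1_swing",
            "translation",
            ("rpn1",),
            tuple(reference.positions[reference.group_mask("rpn1")].mean(axis=0)),
            tuple(swing_axis),
            (1.0, 25.0),
        ),
    ]


def mode_transform(mode: ModeSpec, amplitude: float):
    """(rotation matrix, translation vector) of ``mode`` at ``amplitude``."""
    if mode.is_angular:
        rot = Rotation.from_rotvec(np.deg2rad(amplitude) * np.asarray(mode.axis))
        rmat = rot.as_matrix()
        pivot = np.asarray(mode.pivot)
        return rmat, pivot - rmat @ pivot
    return np.eye(3), amplitude * np.asarray(mode.axis)


def apply_modes(
    reference: BeadModel,
    modes: list[ModeSpec],
    amplitudes: dict[str, float] | list[float],
) -> BeadModel:
    """Apply one amplitude per mode, in catalogue order.

    Affected groups move rigidly; unaffected beads are bit-identical to the
    reference.  Amplitudes outside a mode's range raise ``AmplitudeError``.
    """
    if not isinstance(amplitudes, dict):
        if len(amplitudes) != len(modes):
            raise ValueError("one amplitude per mode required")
        amplitudes = {m.name: a for m, a in zip(modes, amplitudes)}
    unknown = set(amplitudes) - {m.name for m in modes}
    if unknown:
        raise ValueError(f"amplitudes for unknown modes: {sorted(unknown)}")

    out = reference.copy()
    for mode in modes:
        amp = float(amplitudes.get(mode.name, 0.0))
        mode.check_amplitude(amp)
        if amp == 0.0:
            continue
        rmat, tvec = mode_transform(mode, amp)
        m = out.group_mask(mode.affected_groups)
        out.positions[m] = out.positions[m] @ rmat.T + tvec
    return out
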