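"""Coarse-grained surrogate of a 26S-proteasome-like assembly.

The reference structure is a bead model of the 20S core particle (CP) —
four stacked heptameric rings forming a closed barrel with an annular
"gate" in the distal alpha-ring and optional drilled wall pores — plus a
schematic 19S regulatory particle (RP): lid, AAA-ATPase base, the mobile
RPN1 subunit and an RPN11 marker at the lid/base interface.

Geometry is fixed at a proteasome-like scale (outer radius 55 A, four
15 A ring segments, 10 A wall, 2.5 A beads) so that gates and pores fall
in the 4-17 A regime where constriction measurements are meaningful.
The barrel axis is +z; the RP-occupied (proximal) face is at low z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GROUPS",
    "CP_GROUPS",
    "PoreSpec",
    "AssemblyConfig",
    "BeadModel",
    "build_reference_assembly",
    "default_pore_set",
    "default_config",
    "ConfigurationError",
]

GROUPS = (
    "cp_alpha_proximal",
    "cp_beta_1",
    "cp_beta_2",
    "cp_alpha_distal",
    "lid",
    "base_atpase",
    "rpn1",
    "rpn11_marker",
)
CP_GROUPS = GROUPS[:4]

#: residue composition for pseudo-residue assignment: 10% each of D/E/K/R,
#: 30% hydrophobic, 30% polar-neutral (exercises charge and hydropathy).
_HYDROPHOBIC = "AVLIFM"
_POLAR = "STNQG"
_RESIDUE_POOL = (
    list("DEKR")
    + [aa for aa in _HYDROPHOBIC]
    + [aa for aa in _POLAR]
)
_RESIDUE_WEIGHTS = (
    [0.10] * 4
    + [0.30 / len(_HYDROPHOBIC)] * len(_HYDROPHOBIC)
    + [0.30 / len(_POLAR)] * len(_POLAR)
)


class ConfigurationError(ValueError):
    """Raised for non-physical or inconsistent assembly parameters."""


@dataclass(frozen=True)
class PoreSpec:
    """A radial channel drilled through the barrel side wall.

    The channel axis points radially outward at ``azimuth_deg`` and axial
    position ``z``.  Its cross-section is an ellipse with ``semi_long``
    along z and ``semi_short`` along the wall tangent (swap via
    ``long_axis='tangent'``).  A circular pore has equal semi-axes.
    """

    z: float
    azimuth_deg: float
    semi_long: float
    semi_short: float
    long_axis: str = "z"

    def __post_init__(self):
        if self.semi_long < self.semi_short:
            raise ConfigurationError(
                "pore semi_long must be >= semi_short "
                f"({self.semi_long} < {self.semi_short})"
            )
        if min(self.semi_long, self.semi_short) <= 0:
            raise ConfigurationError("pore semi-axes must be positive")
        if self.long_axis not in ("z", "tangent"):
            raise ConfigurationError("long_axis must be 'z' or 'tangent'")

    @classmethod
    def circular(cls, z: float, azimuth_deg: float, diameter: float) -> "PoreSpec":
        return cls(z, azimuth_deg, diameter / 2.0, diameter / 2.0)


@dataclass(frozen=True)
class AssemblyConfig:
    """Parameters of the surrogate assembly (lengths in Angstrom)."""

    barrel_outer_radius: float = 55.0
    wall_thickness: float = 10.0
    ring_spacing: float = 15.0  # axial height of each of the 4 CP rings
    bead_radius: float = 2.5
    bead_spacing: float = 2.6  # target lattice spacing within the wall
    gate_diameter: float = 0.0  # inner diameter of distal annular gate; 0 = closed
    pores: tuple[PoreSpec, ...] = ()
    probe_radius: float = 1.4  # solvent probe assumed when sizing drill clearance
    include_rp: bool = True
    seed: int = 20220311  # pseudo-residue assignment

    @property
    def clearance(self) -> float:
        """Drill margin so the *solvent* channel matches the requested axes."""
        return self.bead_radius + self.probe_radius

    @property
    def barrel_inner_radius(self) -> float:
        return self.barrel_outer_radius - self.wall_thickness

    @property
    def barrel_height(self) -> float:
        return 4.0 * self.ring_spacing

    def validate(self) -> list[str]:
        errors = []
        if self.barrel_outer_radius <= 0:
            errors.append("barrel_outer_radius must be positive")
        if self.wall_thickness < 2 * self.bead_radius:
            errors.append("wall thinner than one bead diameter")
        if self.barrel_inner_radius <= 0:
            errors.append("wall_thickness leaves no interior cavity")
        if self.ring_spacing <= 0:
            errors.append("ring_spacing must be positive")
        if self.bead_radius <= 0:
            errors.append("bead_radius must be positive")
        if self.bead_spacing <= 0:
            errors.append("bead_spacing must be positive")
        if self.gate_diameter < 0:
            errors.append("gate_diameter must be >= 0")
        if (
            self.gate_diameter > 0
            and self.gate_diameter / 2 + self.clearance >= self.barrel_inner_radius
        ):
            errors.append("gate_diameter too large for the barrel interior")
        for k, p in enumerate(self.pores):
            if p.semi_long + self.clearance > self.barrel_height / 2:
                errors.append(f"pore {k} larger than the barrel wall")
        return errors


@dataclass
class BeadModel:
    """Labelled bead assembly: ids, group labels, positions, radii, residues."""

    bead_ids: np.ndarray  # (n,) int
    groups: np.ndarray  # (n,) str
    positions: np.ndarray  # (n, 3) float, Angstrom
    radii: np.ndarray  # (n,) float, Angstrom
    pseudo_residues: np.ndarray  # (n,) one-letter codes
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(np.unique(self.bead_ids)) != len(self.bead_ids):
            raise ValueError("bead ids must be unique")
        if np.any(self.radii <= 0):
            raise ValueError("all bead radii must be positive")

    def __len__(self) -> int:
        return len(self.bead_ids)

    @property
    def barrel_axis(self) -> np.ndarray:
        return np.asarray(self.meta.get("barrel_axis", (0.0, 0.0, 1.0)))

    @property
    def axis_origin(self) -> np.ndarray:
        return np.asarray(self.meta.get("axis_origin", (0.0, 0.0, 0.0)))

    def group_mask(self, group) -> np.ndarray:
        names = (group,) if isinstance(group, str) else tuple(group)
        unknown = set(names) - set(GROUPS)
        if unknown:
            raise ConfigurationError(f"unknown group label(s): {sorted(unknown)}")
        return np.isin(self.groups, names)

    def select(self, group) -> "BeadModel":
        m = self.group_mask(group)
        return BeadModel(
            self.bead_ids[m].copy(),
            self.groups[m].copy(),
            self.positions[m].copy(),
            self.radii[m].copy(),
            self.pseudo_residues[m].copy(),
            dict(self.meta),
        )

    def copy(self) -> "BeadModel":
        return BeadModel(
            self.bead_ids.copy(),
            self.groups.copy(),
            self.positions.copy(),
            self.radii.copy(),
            self.pseudo_residues.copy(),
            dict(self.meta),
        )

    def transformed(self, rotation=None, translation=None) -> "BeadModel":
        """Globally rigidly transformed copy (rotation then translation)."""
        out = self.copy()
        pos = out.positions
        axis = out.barrel_axis.astype(float)
        origin = out.axis_origin.astype(float)
        if rotation is not None:
            rot = np.asarray(rotation, dtype=float)
            pos = pos @ rot.T
            axis = rot @ axis
            origin = rot @ origin
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
            origin = origin + np.asarray(translation, dtype=float)
        out.positions = pos
        out.meta["barrel_axis"] = axis
        out.meta["axis_origin"] = origin
        return out


def _ring_count(radius: float, spacing: float) -> int:
    """Bead count on a circle: nearest multiple of 7 to the spacing target."""
    n = max(7, int(round(2 * np.pi * radius / spacing / 7.0)) * 7)
    return n


def _circle(radius: float, n: int, z: float) -> np.ndarray:
    theta = 2 * np.pi * np.arange(n) / n
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.full(n, z)]
    )


def _wall_beads(cfg: AssemblyConfig) -> np.ndarray:
    """Side-wall lattice: two radial layers x axial levels x 7-fold circles."""
    r_in = cfg.barrel_inner_radius + cfg.bead_radius
    r_out = cfg.barrel_outer_radius - cfg.bead_radius
    n_z = max(2, int(round(cfg.barrel_height / 2.5)))
    dz = cfg.barrel_height / n_z
    z_levels = dz / 2 + dz * np.arange(n_z)
    layers = [r_in, r_out] if r_out - r_in > 1e-9 else [r_in]
    pts = []
    for r in layers:
        n = _ring_count(r, cfg.bead_spacing)
        for z in z_levels:
            pts.append(_circle(r, n, z))
    return np.vstack(pts)


def _cap_beads(cfg: AssemblyConfig, distal: bool) -> np.ndarray:
    """End cap: concentric 7-fold circles at two axial levels.

    The distal cap carries the annular gate: circles start at the gate rim
    (hole radius + clearance) and an exact rim circle is always included so
    the measured solvent opening equals the configured diameter.
    """
    hole = cfg.gate_diameter / 2.0 if distal else 0.0
    rho_min = hole + cfg.clearance if hole > 0 else 0.0
    rho_max = cfg.barrel_inner_radius + cfg.bead_radius
    dz = 2.5
    if distal:
        z_levels = [cfg.barrel_height - 1.5 * dz, cfg.barrel_height - 0.5 * dz]
    else:
        z_levels = [0.5 * dz, 1.5 * dz]
    radii = []
    if hole > 0:
        radii.append(rho_min)  # exact gate rim
        r = rho_min + cfg.bead_spacing
    else:
        r = 2.2
    while r < rho_max:
        radii.append(r)
        r += cfg.bead_spacing
    pts = []
    for z in z_levels:
        for r in radii:
            pts.append(_circle(r, _ring_count(r, cfg.bead_spacing), z))
    return np.vstack(pts)


def _pore_frame(cfg: AssemblyConfig, p: PoreSpec):
    """Local frame of a drilled channel: radial dir, axial (u) and tangent (v)."""
    th = np.deg2rad(p.azimuth_deg)
    radial = np.array([np.cos(th), np.sin(th), 0.0])
    tangent = np.array([-np.sin(th), np.cos(th), 0.0])
    zhat = np.array([0.0, 0.0, 1.0])
    center = radial * (cfg.barrel_outer_radius + cfg.barrel_inner_radius) / 2.0
    center[2] = p.z
    if p.long_axis == "z":
        a_dir, b_dir = zhat, tangent
    else:
        a_dir, b_dir = tangent, zhat
    return center, radial, a_dir, b_dir


def _drill(cfg: AssemblyConfig, wall: np.ndarray) -> np.ndarray:
    """Remove wall beads inside each pore's clearance-offset ellipse."""
    keep = np.ones(len(wall), dtype=bool)
    for p in cfg.pores:
        center, radial, a_dir, b_dir = _pore_frame(cfg, p)
        rel = wall - center
        u = rel @ a_dir
        v = rel @ b_dir
        a = p.semi_long + cfg.clearance
        b = p.semi_short + cfg.clearance
        inside = (u / a) ** 2 + (v / b) ** 2 < 1.0
        # only the near side of the barrel: the channel must not emerge
        # through the diametrically opposite wall
        near = rel @ radial > -cfg.wall_thickness
        keep &= ~(inside & near)
    return wall[keep]


def _pore_rims(cfg: AssemblyConfig) -> np.ndarray:
    """Beads lining each channel exactly on the clearance-offset ellipse.

    Without this rim the channel size would be quantized by the wall
    lattice (~bead_spacing error); with it the nearest bead surface sits
    exactly at the requested solvent semi-axes.
    """
    pts = []
    for p in cfg.pores:
        center, radial, a_dir, b_dir = _pore_frame(cfg, p)
        a = p.semi_long + cfg.clearance
        b = p.semi_short + cfg.clearance
        perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
        n_phi = max(12, int(np.ceil(perimeter / 1.6)))
        phi = 2 * np.pi * np.arange(n_phi) / n_phi
        half_wall = cfg.wall_thickness / 2.0 + cfg.bead_radius
        n_r = max(5, int(np.ceil(2 * half_wall / 1.8)) + 1)
        for t in np.linspace(-half_wall, half_wall, n_r):
            ring = (
                center
                + radial * t
                + np.outer(a * np.cos(phi), a_dir)
                + np.outer(b * np.sin(phi), b_dir)
            )
            pts.append(ring)
    return np.vstack(pts) if pts else np.empty((0, 3))


def _rp_beads(cfg: AssemblyConfig):
    """Schematic regulatory particle below the proximal face (z < 0)."""
    lid = np.vstack(
        [
            _circle(40.0, 28, -24.0),
            _circle(40.0, 28, -30.0),
            _circle(32.0, 21, -36.0),
            _circle(20.0, 14, -41.0),
        ]
    )
    base = np.vstack(
        [
            _circle(34.0, 21, -4.0),
            _circle(34.0, 21, -9.0),
            _circle(28.0, 14, -14.0),
        ]
    )
    rpn11 = np.array(
        [[3.0, 0.0, -19.0], [-1.5, 2.6, -19.0], [-1.5, -2.6, -19.0], [0.0, 0.0, -16.0]]
    )
    # RPN1: compact off-axis cluster at the periphery, free to swing
    g = np.mgrid[0:2, 0:2, 0:2].reshape(3, -1).T * 4.0
    rpn1 = g - g.mean(axis=0) + np.array([56.0, 0.0, -10.0])
    return lid, base, rpn1, rpn11


def build_reference_assembly(config: AssemblyConfig | None = None) -> BeadModel:
    """Construct the reference bead assembly from ``config``.

    Returns a closed shell (no interior-exterior solvent path) when the
    gate diameter is 0 and no pores are requested.
    """
    cfg = config or AssemblyConfig()
    errors = cfg.validate()
    if errors:
        raise ConfigurationError("; ".join(errors))

    wall = _drill(cfg, _wall_beads(cfg))
    rims = _pore_rims(cfg)
    cap_prox = _cap_beads(cfg, distal=False)
    cap_dist = _cap_beads(cfg, distal=True)

    cp_pos = np.vstack([wall, rims, cap_prox, cap_dist])
    # ring-group assignment by axial quarter
    edges = cfg.ring_spacing * np.arange(1, 4)
    ring_idx = np.searchsorted(edges, cp_pos[:, 2], side="right")
    cp_groups = np.array(CP_GROUPS, dtype=object)[ring_idx]

    positions = [cp_pos]
    groups = [cp_groups]
    if cfg.include_rp:
        lid, base, rpn1, rpn11 = _rp_beads(cfg)
        positions += [lid, base, rpn1, rpn11]
        groups += [
            np.full(len(lid), "lid", dtype=object),
            np.full(len(base), "base_atpase", dtype=object),
            np.full(len(rpn1), "rpn1", dtype=object),
            np.full(len(rpn11), "rpn11_marker", dtype=object),
        ]
    pos = np.vstack(positions)
    grp = np.concatenate(groups).astype(object)
    n = len(pos)

    rng = np.random.default_rng(cfg.seed)
    residues = rng.choice(_RESIDUE_POOL, size=n, p=_RESIDUE_WEIGHTS)

    meta = {
        "barrel_axis": np.array([0.0, 0.0, 1.0]),
        "axis_origin": np.zeros(3),
        "inner_radius": cfg.barrel_inner_radius,
        "outer_radius": cfg.barrel_outer_radius,
        "barrel_height": cfg.barrel_height,
        "cap_thickness": 5.0 + 2 * cfg.bead_radius,
        "cap_centers_z": (2.5, cfg.barrel_height - 2.5),
        "gate_diameter": cfg.gate_diameter,
        "bead_radius": cfg.bead_radius,
        "n_pores": len(cfg.pores),
    }
    return BeadModel(
        bead_ids=np.arange(n),
        groups=grp,
        positions=pos,
        radii=np.full(n, cfg.bead_radius),
        pseudo_residues=residues.astype(object),
        meta=meta,
    )


# Default drilled-pore census: 30 channels in three staggered rows, spanning
# the 4-17 A diameter regime.  The middle row hosts the large pores,
# including the featured 11.3 x 7.9 A elliptical channel; row staggering
# keeps every pair of drill footprints disjoint on the 60-A-tall wall.
_MIDDLE_DIAMETERS = [17.0, None, 12.0, 10.0, 9.0, 8.5, 6.5, 5.5, 4.8, 4.0]
_TOP_DIAMETERS = [round(float(x), 2) for x in np.linspace(4.0, 6.8, 10)]
_BOTTOM_DIAMETERS = [round(float(x), 2) for x in np.linspace(4.2, 6.5, 10)]


def default_pore_set() -> tuple[PoreSpec, ...]:
    """The default 30-channel wall-pore construction (diameters 4-17 A)."""
    pores = []
    for k, d in enumerate(_BOTTOM_DIAMETERS):
        pores.append(PoreSpec.circular(14.0, k * 36.0, d))
    for k, d in enumerate(_MIDDLE_DIAMETERS):
        az = 18.0 + k * 36.0
        if d is None:
            pores.append(PoreSpec(30.0, az, 11.3 / 2, 7.9 / 2))
        else:
            pores.append(PoreSpec.circular(30.0, az, d))
    for k, d in enumerate(_TOP_DIAMETERS):
        pores.append(PoreSpec.circular(46.0, k * 36.0, d))
    return tuple(pores)


def infer_barrel_meta(model: BeadModel) -> dict:
    """Reconstruct barrel-frame metadata from the bead geometry.

    Used when a model comes back from a PDB file, which stores no
    construction metadata.  The barrel axis is the line through the
    proximal and distal ring centroids; radial bounds come from the
    mid-barrel wall beads (no caps there), cap planes from the axial
    extremes of the core beads.
    """
    cp = model.select(CP_GROUPS)
    prox = cp.positions[cp.groups == "cp_alpha_proximal"].mean(axis=0)
    dist = cp.positions[cp.groups == "cp_alpha_distal"].mean(axis=0)
    axis = dist - prox
    axis = axis / np.linalg.norm(axis)
    bead_radius = float(model.radii.min())
    proj = cp.positions @ axis
    z_min, z_max = proj.min(), proj.max()
    dz_half = 1.25  # half of the construction's axial lattice step
    origin = np.zeros(3) + axis * 0.0
    # place z = 0 one half-step below the lowest bead plane
    origin = (z_min - dz_half) * axis
    rel = cp.positions - origin
    z_rel = rel @ axis
    rho = np.linalg.norm(rel - np.outer(z_rel, axis), axis=1)
    height = (z_max - z_min) + 2 * dz_half
    mid = (z_rel > height / 3) & (z_rel < 2 * height / 3)
    # wall radii from the dominant radial layers: pore-rim beads are few and
    # must not widen the estimate
    r_round = np.round(rho[mid] * 2) / 2
    values, counts = np.unique(r_round, return_counts=True)
    common = values[counts >= 0.5 * counts.max()]
    inner_radius = float(common.min() - bead_radius)
    outer_radius = float(common.max() + bead_radius)
    meta = {
        "barrel_axis": axis,
        "axis_origin": origin,
        "inner_radius": inner_radius,
        "outer_radius": outer_radius,
        "barrel_height": float(height),
        "cap_thickness": 5.0 + 2 * bead_radius,
        "cap_centers_z": (2 * dz_half, float(height) - 2 * dz_half),
        "bead_radius": bead_radius,
    }
    return meta


def default_config() -> AssemblyConfig:
    """Reference configuration: 14 A open distal gate and the 30-pore census."""
    return AssemblyConfig(gate_diameter=14.0, pores=default_pore_set())
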