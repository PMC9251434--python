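"""Grid-based pore and gate geometry of a closed barrel assembly.

The structure is rasterized onto a cubic voxel grid (a voxel is occupied
when it lies within bead radius + probe radius of any bead center;
probe 1.4 A emulates a water-sized solvent probe).  Wall pores are
solvent channels crossing the barrel wall radially between the interior
cavity and the exterior; the axial gate corridor through the distal
alpha-ring is excluded from the pore census and measured separately as
the largest axis-centered inscribed circle of the distal-plane opening.

Constriction sizes follow the inscribed-sphere convention: d_min is
twice the largest inscribed-sphere radius at the channel's tightest
cross-section (from the Euclidean distance transform of the solvent),
d_max the longest chord of that same cross-section perpendicular to the
channel direction.  Channels with d_min strictly above 7 A are flagged
as large enough to release peptides carrying bulky side chains.

This detection procedure is a definition made by this package, not a
reproduction of any published workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE
from scipy import ndimage
from scipy.spatial import cKDTree

from .assembly import BeadModel

__all__ = [
    "OccupancyGrid",
    "Pore",
    "rasterize",
    "detect_pores",
    "measure_pore",
    "measure_gate",
    "characterize_pore",
    "filter_releasing",
    "analyze_pores",
    "ResolutionError",
    "RELEASE_DIAMETER_A",
]

RELEASE_DIAMETER_A = 7.0  # strict threshold: bulky residues need d_min > 7 A
FORMAL_CHARGE = {"D": -1, "E": -1, "K": 1, "R": 1}
LINING_DISTANCE_A = 4.0

_FACE_CONN = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


class ResolutionError(ValueError):
    pass


@dataclass
class OccupancyGrid:
    """Boolean occupancy over a padded cubic grid around a structure."""

    occupied: np.ndarray  # (nx, ny, nz) bool
    origin: np.ndarray  # corner of voxel (0,0,0), Angstrom
    spacing: float
    probe_radius: float
    structure: BeadModel
    _cache: dict = field(default_factory=dict, repr=False)

    def voxel_centers_1d(self):
        nx, ny, nz = self.occupied.shape
        ax = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        ay = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        az = self.origin[2] + (np.arange(nz) + 0.5) * self.spacing
        return ax, ay, az

    def axial_coords(self):
        """(z_along_axis, rho) of every voxel center, in the barrel frame."""
        if "axial" not in self._cache:
            axis = self.structure.barrel_axis.astype(float)
            axis = axis / np.linalg.norm(axis)
            origin = self.structure.axis_origin.astype(float)
            ax, ay, az = self.voxel_centers_1d()
            rx = (ax - origin[0]).astype(np.float32)
            ry = (ay - origin[1]).astype(np.float32)
            rz = (az - origin[2]).astype(np.float32)
            zax = (
                rx[:, None, None] * axis[0]
                + ry[None, :, None] * axis[1]
                + rz[None, None, :] * axis[2]
            )
            r2 = (
                rx[:, None, None] ** 2
                + ry[None, :, None] ** 2
                + rz[None, None, :] ** 2
            )
            rho = np.sqrt(np.maximum(r2 - zax**2, 0.0))
            self._cache["axial"] = (zax, rho)
        return self._cache["axial"]

    @property
    def bead_tree(self) -> cKDTree:
        if "tree" not in self._cache:
            self._cache["tree"] = cKDTree(self.structure.positions)
        return self._cache["tree"]

    def surface_distance(self, points: np.ndarray) -> np.ndarray:
        """Exact distance (A) from points to the probe-inflated bead surface.

        Distances are measured to the actual bead geometry rather than to
        occupied voxel centers, so inscribed-sphere radii carry no
        obstacle-quantization error and are rotation invariant.
        """
        dist, idx = self.bead_tree.query(points)
        reach = self.structure.radii[idx] + self.probe_radius
        return dist - reach

    def index_of(self, point) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return tuple(np.clip(idx, 0, np.array(self.occupied.shape) - 1))


@dataclass
class Pore:
    """One wall channel and its measurements."""

    pore_id: int
    voxels: np.ndarray  # (k, 3) int indices
    constriction_center: np.ndarray | None = None  # Angstrom
    d_min: float = np.nan
    d_max: float = np.nan
    channel_direction: np.ndarray | None = None
    lining_residues: list[str] = field(default_factory=list)
    net_formal_charge: int = 0
    mean_hydropathy: float = np.nan
    hydropathy_class: str = "unknown"

    @property
    def releasing(self) -> bool:
        return bool(self.d_min > RELEASE_DIAMETER_A)


def rasterize(
    structure: BeadModel, spacing: float = 0.5, probe_radius: float = 1.4
) -> OccupancyGrid:
    """Occupancy grid: voxel occupied iff within (bead radius + probe) of a bead.

    The grid is padded by at least two solvent voxels on every side.
    """
    if spacing <= 0 or probe_radius < 0:
        raise ValueError("spacing must be > 0 and probe_radius >= 0")
    if len(structure) and spacing > 2 * structure.radii.min():
        raise ResolutionError(
            f"spacing {spacing} A exceeds the smallest bead diameter "
            f"({2 * structure.radii.min()} A); refine the grid"
        )
    pos = structure.positions
    if len(structure) == 0:
        origin = np.zeros(3)
        shape = (8, 8, 8)
        return OccupancyGrid(
            np.zeros(shape, dtype=bool), origin, spacing, probe_radius, structure
        )
    reach = structure.radii + probe_radius
    pad = 2.5 * spacing
    lo = (pos - reach[:, None]).min(axis=0) - pad
    hi = (pos + reach[:, None]).max(axis=0) + pad
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    occupied = np.zeros(tuple(shape), dtype=bool)

    for center, r in zip(pos, reach):
        i0 = np.floor((center - r - lo) / spacing).astype(int)
        i1 = np.ceil((center + r - lo) / spacing).astype(int) + 1
        i0 = np.maximum(i0, 0)
        i1 = np.minimum(i1, shape)
        gx = lo[0] + (np.arange(i0[0], i1[0]) + 0.5) * spacing
        gy = lo[1] + (np.arange(i0[1], i1[1]) + 0.5) * spacing
        gz = lo[2] + (np.arange(i0[2], i1[2]) + 0.5) * spacing
        d2 = (
            (gx - center[0])[:, None, None] ** 2
            + (gy - center[1])[None, :, None] ** 2
            + (gz - center[2])[None, None, :] ** 2
        )
        occupied[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]] |= d2 <= r * r
    return OccupancyGrid(occupied, lo, spacing, probe_radius, structure)


def _wall_zone(grid: OccupancyGrid):
    """Mask of voxels inside the barrel side wall (between caps, radially)."""
    meta = grid.structure.meta
    r_eff = meta["bead_radius"] + grid.probe_radius
    rho_in = meta["inner_radius"] + meta["bead_radius"] - r_eff
    rho_out = meta["outer_radius"] - meta["bead_radius"] + r_eff
    cap_half = meta["cap_thickness"] / 2.0
    z_lo = meta["cap_centers_z"][0] + cap_half
    z_hi = meta["cap_centers_z"][1] - cap_half
    zax, rho = grid.axial_coords()
    zone = (rho > rho_in) & (rho < rho_out) & (zax > z_lo) & (zax < z_hi)
    return zone, rho_in, rho_out


def _interior_point(grid: OccupancyGrid):
    meta = grid.structure.meta
    axis = grid.structure.barrel_axis / np.linalg.norm(grid.structure.barrel_axis)
    return grid.structure.axis_origin + axis * (meta["barrel_height"] / 2.0)


def detect_pores(grid: OccupancyGrid, barrel_axis=None) -> list[Pore]:
    """Find wall channels linking the interior cavity to the exterior.

    Channels are 6-connected solvent components within the side-wall
    zone that span the wall radially; the axial gate corridor (inside
    the inner radius / within the cap planes) never enters the zone and
    is reported separately by :func:`measure_gate`.  Pores are ordered
    by constriction position along the axis, then azimuth.
    """
    if grid.occupied[grid.index_of(_interior_point(grid))]:
        raise ValueError("structure has no interior cavity")
    zone, rho_in, rho_out = _wall_zone(grid)
    solvent = ~grid.occupied
    labels, n_lab = ndimage.label(solvent & zone, structure=_FACE_CONN)
    if n_lab == 0:
        return []
    _zax, rho = grid.axial_coords()
    s = grid.spacing
    pores = []
    for lab, box in enumerate(ndimage.find_objects(labels), start=1):
        if box is None:
            continue
        mask = labels[box] == lab
        rr = rho[box][mask]
        if rr.min() <= rho_in + 1.5 * s and rr.max() >= rho_out - 1.5 * s:
            voxels = np.argwhere(mask) + [sl.start for sl in box]
            pores.append(Pore(pore_id=-1, voxels=voxels))
    for p in pores:
        measure_pore(p, grid)
    axis = grid.structure.barrel_axis / np.linalg.norm(grid.structure.barrel_axis)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def sort_key(p: Pore):
        c = p.constriction_center - grid.structure.axis_origin
        az = np.arctan2(np.dot(c, e2), np.dot(c, e1)) % (2 * np.pi)
        return (round(float(np.dot(c, axis)), 3), round(float(az), 6))

    pores.sort(key=sort_key)
    for k, p in enumerate(pores):
        p.pore_id = k
    return pores


def _widest_path_bottleneck(voxels: np.ndarray, edt: np.ndarray, sources, targets):
    """Maximin bottleneck: the widest 6-connected route through the channel.

    Returns (bottleneck_radius, index of the bottleneck voxel): over all
    paths from any source to any target, the one whose narrowest point is
    widest; the bottleneck voxel is that narrowest point.
    """
    import heapq

    lo = voxels.min(axis=0)
    shape = voxels.max(axis=0) - lo + 1
    ids = np.full(shape, -1, dtype=int)
    ids[tuple((voxels - lo).T)] = np.arange(len(voxels))
    offsets = np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    best = np.full(len(voxels), -np.inf)
    prev = np.full(len(voxels), -1, dtype=int)
    heap = []
    for k in np.flatnonzero(sources):
        best[k] = edt[k]
        heapq.heappush(heap, (-edt[k], int(k)))
    target_ids = set(np.flatnonzero(targets).tolist())
    local = voxels - lo
    end = None
    while heap:
        neg, k = heapq.heappop(heap)
        width = -neg
        if width < best[k]:
            continue
        if k in target_ids:
            end = k
            break
        for off in offsets:
            nb = local[k] + off
            if np.any(nb < 0) or np.any(nb >= shape):
                continue
            j = ids[tuple(nb)]
            if j < 0:
                continue
            cand = min(width, edt[j])
            if cand > best[j]:
                best[j] = cand
                prev[j] = k
                heapq.heappush(heap, (-cand, int(j)))
    if end is None:  # disconnected mouths: fall back to the widest voxel
        k = int(np.argmax(best))
        return best[k], k, [k]
    path = [end]
    while prev[path[-1]] >= 0:
        path.append(int(prev[path[-1]]))
    k_min = path[int(np.argmin(edt[path]))]
    return best[end], k_min, path


def measure_pore(pore: Pore, grid: OccupancyGrid) -> tuple[float, float]:
    """Constriction diameters (d_min, d_max) of a channel.

    d_min is twice the maximin inscribed-sphere radius over all
    interior-to-exterior routes through the channel (the widest path's
    narrowest point); d_max adds one voxel spacing to the longest
    center-to-center chord of the constriction cross-section to account
    for the half-voxel extent at either end.
    """
    if len(pore.voxels) == 0:
        raise ValueError("empty pore")
    s = grid.spacing
    centers = grid.origin + (pore.voxels + 0.5) * s
    _zax, rho = grid.axial_coords()
    rr = rho[tuple(pore.voxels.T)]
    inner_m = rr <= rr.min() + 1.5 * s
    outer_m = rr >= rr.max() - 1.5 * s
    direction = centers[outer_m].mean(axis=0) - centers[inner_m].mean(axis=0)
    nrm = np.linalg.norm(direction)
    if nrm < 1e-9:
        direction = grid.structure.barrel_axis.astype(float)
        nrm = np.linalg.norm(direction)
    direction = direction / nrm
    pore.channel_direction = direction

    edt = grid.surface_distance(centers)
    _r_raw, k_center, path = _widest_path_bottleneck(
        pore.voxels, edt, inner_m, outer_m
    )
    # refine each path voxel's clearance continuously within its in-plane
    # voxel cell: the discrete maximin underestimates (by up to half a voxel
    # diagonal) when the channel is oblique to the grid; the bead geometry
    # itself is exact, so the refined widest-path bottleneck is too
    u = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, direction)) > 0.9:
        u = np.array([0.0, 1.0, 0.0])
    e1 = u - np.dot(u, direction) * direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    g1, g2 = np.meshgrid(np.linspace(-s, s, 9), np.linspace(-s, s, 9))
    probes = np.outer(g1.ravel(), e1) + np.outer(g2.ravel(), e2)
    focus = [k for k in path if edt[k] <= edt[k_center] + 2 * s]
    pts = (centers[focus][:, None, :] + probes[None, :, :]).reshape(-1, 3)
    refined = grid.surface_distance(pts).reshape(len(focus), -1).max(axis=1)
    r_min = float(refined.min())
    k_center = focus[int(np.argmin(refined))]
    pore.constriction_center = centers[k_center]
    t = centers @ direction
    d_min = 2.0 * float(r_min)
    if d_min < grid.spacing:
        warnings.warn(
            "channel thinner than one voxel; d_min reported as 0 "
            "(insufficient grid resolution)",
            RuntimeWarning,
        )
        pore.d_min, pore.d_max = 0.0, 0.0
        return 0.0, 0.0

    m = np.abs(t - t[k_center]) <= 0.75 * s
    slab_pts = centers[m]
    perp = slab_pts - np.outer(slab_pts @ direction, direction)
    if len(perp) == 1:
        d_max = d_min
    else:
        # longest chord of the constriction cross-section
        hull_d2 = 0.0
        for p in perp:
            hull_d2 = max(hull_d2, float(((perp - p) ** 2).sum(axis=1).max()))
        d_max = np.sqrt(hull_d2) + s
    pore.d_min = d_min
    pore.d_max = float(max(d_max, d_min))
    return pore.d_min, pore.d_max


def measure_gate(grid: OccupancyGrid) -> float:
    """Diameter of the axial gate opening through the distal-ring cap.

    Largest inscribed circle centered on the barrel axis, minimized over
    the cap planes (the gate corridor's constriction): for every cap
    bead the radial clearance to its probe-inflated surface is
    rho_bead - sqrt(r_eff^2 - dz^2) at axial offset dz; the gate is twice
    the smallest clearance, and 0 when the axis itself is blocked.
    """
    structure = grid.structure
    meta = structure.meta
    axis = structure.barrel_axis / np.linalg.norm(structure.barrel_axis)
    rel = structure.positions - structure.axis_origin
    z = rel @ axis
    rho = np.linalg.norm(rel - np.outer(z, axis), axis=1)
    z_cap = meta["cap_centers_z"][1]
    half = meta["cap_thickness"] / 2.0
    reach = structure.radii + grid.probe_radius
    gate = np.inf
    # scan the cap plane range: the constriction is the tightest plane
    for z_plane in np.linspace(z_cap - half, z_cap + half, 21):
        dz = np.abs(z - z_plane)
        cut = dz < reach  # beads whose inflated sphere crosses this plane
        if not np.any(cut):
            continue
        eff = np.sqrt(reach[cut] ** 2 - dz[cut] ** 2)
        clearance = (rho[cut] - eff).min()
        gate = min(gate, clearance)
    if not np.isfinite(gate):
        return 0.0
    return float(max(0.0, 2.0 * gate))


def characterize_pore(
    pore: Pore, structure: BeadModel, grid: OccupancyGrid
) -> tuple[int, float, str]:
    """Chemistry of the channel lining (beads within 4 A of channel voxels).

    Net formal charge counts D/E as -1 and K/R as +1 at neutral pH
    (H = 0); mean hydropathy is the Kyte-Doolittle average; the class is
    hydrophobic for positive mean hydropathy, hydrophilic otherwise.
    """
    centers = grid.origin + (pore.voxels + 0.5) * grid.spacing
    tree = cKDTree(structure.positions)
    idx = sorted({i for hits in tree.query_ball_point(centers, LINING_DISTANCE_A) for i in hits})
    residues = [str(structure.pseudo_residues[i]) for i in idx]
    pore.lining_residues = residues
    if not residues:
        warnings.warn("pore has no lining residues; chemistry undefined", RuntimeWarning)
        pore.net_formal_charge = 0
        pore.mean_hydropathy = np.nan
        pore.hydropathy_class = "unknown"
        return 0, np.nan, "unknown"
    pore.net_formal_charge = int(sum(FORMAL_CHARGE.get(r, 0) for r in residues))
    pore.mean_hydropathy = float(np.mean([KYTE_DOOLITTLE[r] for r in residues]))
    pore.hydropathy_class = "hydrophobic" if pore.mean_hydropathy > 0 else "hydrophilic"
    return pore.net_formal_charge, pore.mean_hydropathy, pore.hydropathy_class


def filter_releasing(pores: list[Pore]) -> tuple[list[Pore], int]:
    """Pores wide enough for bulky residues: d_min strictly above 7 A."""
    subset = [p for p in pores if p.releasing]
    return subset, len(subset)


def analyze_pores(
    structure: BeadModel, spacing: float = 0.5, probe_radius: float = 1.4
) -> tuple[list[Pore], float, OccupancyGrid]:
    """Full census: rasterize, detect + measure + characterize, measure gate."""
    grid = rasterize(structure, spacing=spacing, probe_radius=probe_radius)
    pores = detect_pores(grid)
    for p in pores:
        characterize_pore(p, structure, grid)
    gate = measure_gate(grid)
    return pores, gate, grid
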