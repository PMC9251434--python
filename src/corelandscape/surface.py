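"""Model free-energy surfaces over two mode coordinates and Boltzmann sampling.

The canonical landscape axes are q1 = lid rotation (degrees, 0-35) and
q2 = core-particle compression (Angstrom, 0-12).  The default surface has
three wells — resting (58%), rotated (35%) and fully compressed (7%; the
42% non-resting mass is split between the latter two) — joined by
one-bin-wide "pass" channels whose apex sits a configurable barrier
(default 5.6 k_BT) above the resting minimum.

Basin masses are imposed by per-basin probability rescaling over
explicitly declared basin regions rather than by tuning well depths, so
the generator's state fractions are exact ground truth for recovery
tests.  Pass bins up to and including the apex belong to the resting
basin; rescaling therefore shifts the whole resting region (apex
included) by one common factor and the barrier measured from the resting
minimum is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FreeEnergySurface",
    "ParticleSet",
    "Well",
    "default_surface",
    "build_surface",
    "sample_particles",
]

DEFAULT_SEED = 20220311


@dataclass(frozen=True)
class Well:
    """A Gaussian well: center/sigma in physical (q1, q2) units."""

    label: str
    center: tuple[float, float]
    sigma: tuple[float, float]
    fraction: float


@dataclass
class FreeEnergySurface:
    """Energies (k_BT) over a (q1, q2) grid with declared basin regions.

    ``energies`` already include any per-basin rescaling: bin
    probabilities are exp(-E) * bin_area, normalized.  The minimum over
    the grid is 0 at the global probability maximum.
    """

    energies: np.ndarray  # (n1, n2)
    bin_edges_q1: np.ndarray
    bin_edges_q2: np.ndarray
    basin_labels: np.ndarray  # (n1, n2) int, index into basin_names
    basin_names: tuple[str, ...]
    target_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (
            len(self.bin_edges_q1) - 1,
            len(self.bin_edges_q2) - 1,
        ):
            raise ValueError("energy grid does not match bin edges")

    @property
    def bin_area(self) -> float:
        return float(
            np.diff(self.bin_edges_q1)[0] * np.diff(self.bin_edges_q2)[0]
        )

    @property
    def probabilities(self) -> np.ndarray:
        w = np.exp(-self.energies) * self.bin_area
        w[~np.isfinite(w)] = 0.0
        total = w.sum()
        if total <= 0:
            raise ValueError("surface has no finite-probability bins")
        return w / total

    def basin_masses(self) -> dict[str, float]:
        p = self.probabilities
        return {
            name: float(p[self.basin_labels == k].sum())
            for k, name in enumerate(self.basin_names)
        }

    @classmethod
    def from_energies(cls, energies, bin_edges_q1, bin_edges_q2) -> "FreeEnergySurface":
        """Single-basin surface directly from an energy grid (no rescaling)."""
        e = np.asarray(energies, dtype=float)
        e = e - np.nanmin(e[np.isfinite(e)])
        return cls(
            e,
            np.asarray(bin_edges_q1, dtype=float),
            np.asarray(bin_edges_q2, dtype=float),
            np.zeros(e.shape, dtype=int),
            ("basin_0",),
        )


@dataclass
class ParticleSet:
    """Sampled particle population over the two mode coordinates."""

    mode_coords: np.ndarray  # (n, 2)
    truth_basin: np.ndarray | None = None  # (n,) str
    seed: int | None = None

    def __post_init__(self):
        self.mode_coords = np.asarray(self.mode_coords, dtype=float)
        if self.mode_coords.ndim != 2 or self.mode_coords.shape[1] != 2:
            raise ValueError("mode_coords must be (n, 2)")
        if not np.all(np.isfinite(self.mode_coords)):
            raise ValueError("mode_coords must be finite")

    @property
    def n(self) -> int:
        return len(self.mode_coords)


def _line_bins(a, b):
    """8-connected raster of the segment from bin a to bin b (inclusive)."""
    n = max(abs(b[0] - a[0]), abs(b[1] - a[1])) + 1
    ii = np.round(np.linspace(a[0], b[0], n)).astype(int)
    jj = np.round(np.linspace(a[1], b[1], n)).astype(int)
    return list(zip(ii.tolist(), jj.tolist()))


def build_surface(
    wells: list[Well],
    passes: list[tuple[str, str]],
    n_bins: tuple[int, int] = (30, 30),
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 35.0), (0.0, 12.0)),
    barrier: float = 5.6,
    background: float = 12.0,
    anchor_energy: float | None = 6.0,
) -> FreeEnergySurface:
    """Assemble a multi-well surface with tent-profile passes between wells.

    Each pass is a one-bin-wide channel whose single apex bin lies exactly
    ``barrier`` k_BT above the (deepest) first well's minimum, so the
    minimax barrier out of that well is ``barrier`` by construction.
    ``anchor_energy`` bins at the four grid corners keep the sampled
    coordinate range pinned to the full domain (so a data-driven re-binning
    reproduces this grid); set to None to disable.
    """
    (q1_lo, q1_hi), (q2_lo, q2_hi) = domain
    e1 = np.linspace(q1_lo, q1_hi, n_bins[0] + 1)
    e2 = np.linspace(q2_lo, q2_hi, n_bins[1] + 1)
    c1 = 0.5 * (e1[:-1] + e1[1:])
    c2 = 0.5 * (e2[:-1] + e2[1:])
    Q1, Q2 = np.meshgrid(c1, c2, indexing="ij")

    E = np.full(n_bins, float(background))
    owner = np.full(n_bins, -1, dtype=int)  # declared basin regions
    names = tuple(w.label for w in wells)
    centers_bin = {}
    for k, w in enumerate(wells):
        d2 = ((Q1 - w.center[0]) / w.sigma[0]) ** 2 + (
            (Q2 - w.center[1]) / w.sigma[1]
        ) ** 2
        ew = d2 / 2.0
        take = ew < E
        E[take] = ew[take]
        owner[take] = k
        i = int(np.argmin(np.abs(c1 - w.center[0])))
        j = int(np.argmin(np.abs(c2 - w.center[1])))
        centers_bin[w.label] = (i, j)

    if anchor_energy is not None:
        for i, j in [(0, 0), (0, -1), (-1, 0), (-1, -1)]:
            if E[i, j] > anchor_energy:
                E[i, j] = anchor_energy

    # background/anchor bins join the nearest well's declared region
    bg = owner < 0
    if np.any(bg):
        dist = np.full(E.shape + (len(wells),), np.inf)
        for k, w in enumerate(wells):
            dist[..., k] = ((Q1 - w.center[0]) / (q1_hi - q1_lo)) ** 2 + (
                (Q2 - w.center[1]) / (q2_hi - q2_lo)
            ) ** 2
        owner[bg] = np.argmin(dist[bg], axis=-1)

    # declare pass-bin ownership up front: the climb and the apex belong to
    # the first (deeper) basin, the descent to the second
    pass_bins = []
    for a_label, b_label in passes:
        ka = names.index(a_label)
        kb = names.index(b_label)
        path = _line_bins(centers_bin[a_label], centers_bin[b_label])
        apex = len(path) // 2
        pass_bins.append((ka, kb, path, apex))
        for s, (i, j) in enumerate(path):
            owner[i, j] = ka if s <= apex else kb

    fractions = {w.label: w.fraction for w in wells}
    total_frac = sum(fractions.values())

    def rescale(e):
        p = np.exp(-e)
        for k, w in enumerate(wells):
            mask = owner == k
            p[mask] *= (w.fraction / total_frac) / p[mask].sum()
        p /= p.sum()
        return -np.log(p / p.max())

    def impose_passes(e):
        e = e.copy()
        mins = [e[owner == k].min() for k in range(len(wells))]
        for ka, kb, path, apex in pass_bins:
            ea, eb = mins[ka], mins[kb]
            top = ea + barrier
            for s, (i, j) in enumerate(path):
                # concave climb to a single apex bin: steep out of the wells
                # so the pass carries little probability mass; the descent
                # starts from the second well's own minimum so rescaling
                # never lifts a descent bin above the apex
                if s <= apex:
                    ep = ea + barrier * np.sqrt(s / apex) if apex else top
                else:
                    frac = (len(path) - 1 - s) / (len(path) - 1 - apex)
                    ep = eb + (top - eb) * np.sqrt(frac)
                e[i, j] = min(e[i, j], ep)
        return e

    # fixed point: impose passes in post-rescale energy space, then restore
    # exact basin masses (a uniform per-basin shift that leaves all
    # within-basin energy differences — the barrier included — intact)
    energies = rescale(E)
    for _ in range(3):
        energies = rescale(impose_passes(energies))

    return FreeEnergySurface(
        energies, e1, e2, owner, names, target_fractions=fractions
    )


def default_surface(barrier: float = 5.6) -> FreeEnergySurface:
    """The reference three-well landscape (58/35/7, saddle ``barrier`` k_BT)."""
    bw1 = 35.0 / 30.0
    bw2 = 12.0 / 30.0
    wells = [
        Well("resting", (4.5 * bw1, 4.5 * bw2), (0.9 * bw1, 0.9 * bw2), 0.58),
        Well("rotated", (25.5 * bw1, 4.5 * bw2), (0.9 * bw1, 0.9 * bw2), 0.35),
        Well("compressed", (4.5 * bw1, 25.5 * bw2), (0.9 * bw1, 0.9 * bw2), 0.07),
    ]
    passes = [("resting", "rotated"), ("resting", "compressed")]
    return build_surface(wells, passes, barrier=barrier)


def sample_particles(
    surface: FreeEnergySurface, n: int, seed: int = DEFAULT_SEED
) -> ParticleSet:
    """Draw ``n`` particles from ``surface``.

    Bins are drawn with probability proportional to exp(-E) * bin_area
    (already rescaled to the surface's target fractions); positions are
    uniform within the chosen bin.  The per-particle ground-truth basin
    label is recorded.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = surface.probabilities.ravel()  # raises on all-infinite surfaces
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p).reshape(surface.energies.shape)

    n1, n2 = surface.energies.shape
    ii, jj = np.nonzero(counts)
    reps = counts[ii, jj]
    bi = np.repeat(ii, reps)
    bj = np.repeat(jj, reps)
    w1 = np.diff(surface.bin_edges_q1)
    w2 = np.diff(surface.bin_edges_q2)
    q1 = surface.bin_edges_q1[bi] + rng.random(n) * w1[bi]
    q2 = surface.bin_edges_q2[bj] + rng.random(n) * w2[bj]
    labels = np.asarray(surface.basin_names, dtype=object)[
        surface.basin_labels[bi, bj]
    ]
    order = rng.permutation(n)
    return ParticleSet(
        mode_coords=np.column_stack([q1, q2])[order],
        truth_basin=labels[order],
        seed=seed,
    )
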