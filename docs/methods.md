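# Methods

## The surrogate assembly

The package analyses a coarse-grained bead model of a 26S-proteasome-like
machine rather than experimental maps: every analysis operator is then
testable against exact construction ground truth.  The 20S-style core is a
closed barrel of four stacked ring segments (outer radius 55 Å, wall
thickness 10 Å, ring spacing 15 Å, total height 60 Å) built from 2.5 Å
beads on a lattice with strict sevenfold symmetry per ring (bead counts
are multiples of 7 with aligned angular offsets).  Both ends are capped;
the distal alpha-ring cap carries an annular gate of configurable inner
diameter (0 = closed, default open at 14 Å).  The 19S-style regulatory
particle — lid, ATPase base, an off-axis RPN1 cluster and a small RPN11
marker at the lid/base interface — sits below the proximal face (z < 0;
the barrel axis is +z).  These dimensions are a design choice at a
proteasome-like scale: they place gates and drilled pores in the 4–17 Å
regime where constriction measurements are meaningful.

Wall pores are radial elliptical channels.  Drilling removes lattice
beads inside the channel footprint inflated by a clearance
(bead radius + 1.4 Å probe) and adds a *rim* — rings of beads placed
exactly on the inflated ellipse.  Without the rim, the solvent channel
size would be quantized by the wall lattice (≈2.6 Å); with it, the
nearest bead surface sits exactly at the requested solvent semi-axes, so
"measured within one grid spacing of construction" is a meaningful
contract.  Drilling is restricted to the near wall so a channel never
emerges through the diametrically opposite side.  The default census
drills 30 channels in three staggered rows (diameters 4–17 Å, including
one 11.3 × 7.9 Å elliptical channel); the staggering is forced by
packing: thirty non-overlapping drill footprints only fit on the
60-Å-tall wall if the large pores sit in the middle row between offset
rows of small ones.  Diameters were fixed once, with no value placed
within ±0.4 Å of the 7 Å release threshold, because the grid measurement
carries an uncertainty of roughly ±0.2 Å and a construction value
straddling the threshold would make the releasing count ill-defined.

Pseudo-residues (one-letter codes) are assigned per bead by a seeded
draw from a fixed composition — 10% each D/E/K/R, 30% hydrophobic
(A/V/L/I/F/M), 30% polar-neutral (S/T/N/Q/G) — so that pore-lining
chemistry exercises both the formal-charge and the hydropathy
classifiers.

## Conformational modes

The default catalogue holds four rigid-body modes: lid rotation about
the barrel axis through the RPN11 marker (0–35°), lid tilt about a
perpendicular axis through the lid/base gap centroid (4–10°), core
compression — translation of the two distal core rings toward the
proximal face (0–12 Å) — and the RPN1 swing (translation, 1–25 Å).  The
tilt pivot location is not constrained by any observation; the gap
centroid is a surrogate convention.  Amplitude 0 is accepted for every
mode (the resting reference), even where the observed range starts above
zero.  Transforms apply in catalogue order; unaffected beads are
bit-identical to the reference.

Recovery is by Kabsch superposition (scipy's `Rotation.align_vectors`)
of the moving group, the angle from the rotation magnitude, and the
screw axis from rotation plus residual translation; the pivot reported
is the point of the screw axis nearest the group centroid (the unique
stable representative of the line).  Classification thresholds — 2°
minimum angle, 0.5 Å minimum displacement, 15°/75° axis cones, and
"anti-parallel to the barrel axis on a core group" for compression —
are package conventions; the motions are named in the field but no
numeric cutoffs exist.  PCA uses exact SVD of the mean-centred
coordinate matrix (ensembles here are tens to hundreds of conformers; no
randomized solver is warranted).  Note that a pure rotation traces a
curved path in coordinate space, so a rotation-only ensemble legitimately
spreads over two principal components (~99.2%/0.8% at 35°); only strictly
linear (translational) modes concentrate >99.9% of variance in one
component.

## The model free-energy surface

The landscape axes are q1 = lid rotation (degrees, 0–35) and q2 = core
compression (Å, 0–12) on a 30×30 grid; other modes are nuisance
coordinates sampled independently.  The default surface has Gaussian
wells (σ = 0.9 bins) at resting (58%), rotated (35%) and fully
compressed (7%) positions, joined by one-bin-wide pass channels with a
concave (square-root) energy profile and a single apex bin; a 12 k_BT
background and 6 k_BT anchor bins at the grid corners complete the
surface.  The anchors guarantee that the sampled coordinate range spans
the full domain, so the analysis side's data-driven binning reproduces
the generator's bins to a fraction of a bin width; their probability
mass (~4×10⁻⁴) is negligible against the binomial confidence intervals
used in recovery tests.

State fractions are imposed by per-basin probability rescaling over
explicitly declared basin regions, not by tuning well depths: ground
truth is then exact by construction.  Because rescaling is a uniform
energy shift within each region, it preserves within-region energy
differences; the pass bins up to and including each apex are declared
part of the resting region, so the barrier measured from the resting
minimum survives rescaling exactly.  The builder iterates
(impose passes in post-rescale energy space → rescale) to a fixed point,
after which basin masses match their targets to 10⁻⁹ and the minimax
barrier out of the resting basin equals the configured 5.6 k_BT to
better than 0.002 k_BT on the generator grid.  The single-bin apex is a
statistical design decision: at n = 10⁵ the apex bin expects ~35 counts,
putting the sampling standard deviation of the recovered barrier near
0.17 k_BT — inside the ±0.3 k_BT recovery contract — whereas a flat
multi-bin saddle would bias the minimax estimate low through
extreme-value selection.

Sampling draws bins multinomially with probability ∝ exp(−E)·(bin area)
and positions uniformly within the bin; per-particle truth labels are
retained.  All randomness is `numpy.random.default_rng` under a single
integer seed (package default 20220311); pipeline stages derive
independent substreams via `SeedSequence.spawn`.

## Landscape analysis

Binning spans the observed coordinate range exactly (right-open bins,
last bin closed).  Boltzmann inversion is `E_i = −ln(N_i/N_max)` in
k_BT with no pseudocounts; the temperature is absorbed into the unit.
Empty bins are masked and impassable rather than set to a large finite
energy: a barrier computed across unsampled territory is reported with
an explicit lower-bound flag ("at least this high"), never silently
interpolated.  Basins are 8-connected watershed catchments of local
minima, processed in increasing energy with deterministic index
tie-breaks (plateau bins join their earliest assigned equal-energy
neighbour).  Barriers use a widest-path variant of Dijkstra: the saddle
is the minimum over 8-connected non-empty paths of the path's maximum
energy, validated in the tests against exhaustive path enumeration on
all grids up to 4×4.  A basin whose minimum lies at |q2| ≥ 6 Å (half the
full compression range) is reported as a compressed state.

## Pore and gate measurement

Rasterization marks a voxel occupied when its center lies within
(bead radius + probe) of any bead center (probe 1.4 Å, spacing 0.5 Å by
default; the grid is padded with ≥2 solvent voxels).  Wall pores are
6-connected solvent components, inside the radial wall zone between the
cap planes, that span the wall from the interior boundary to the
exterior; the axial gate corridor lies outside this zone and is reported
separately.  This detection procedure is a definition made by this
package — no published workflow is being reproduced.

The constriction is found by a maximin ("widest path") search from the
inner to the outer mouth, where each voxel's clearance is the *exact*
Euclidean distance from its center to the nearest probe-inflated bead
surface (KD-tree), not a grid distance transform: obstacle quantization
would otherwise bias d_min low by up to half a voxel diagonal and break
rotation invariance.  Clearances along the widest path are then refined
continuously within each voxel's in-plane cell, and d_min is twice the
refined bottleneck radius.  d_max is the longest center-to-center chord
of the constriction cross-section (a one-voxel slab perpendicular to the
channel direction) plus one spacing for the half-voxel extent at either
end, floored at d_min.  On the default census these measurements land
within 0.15 Å of the drilled construction at 0.5 Å spacing.  The gate
diameter is computed analytically as twice the smallest axis-centred
radial clearance to any cap bead's inflated surface over the distal cap
planes (the corridor's constriction), which is exact for the annular
construction and zero when the axis is blocked.

Lining chemistry takes all beads within 4 Å of channel voxels: net
formal charge counts D/E as −1 and K/R as +1 (neutral pH, H = 0), mean
hydropathy is the Kyte–Doolittle average (scale from biopython), and the
binary class is hydrophobic for positive mean.  The release filter is
strict: d_min > 7 Å, the transverse size needed by bulky side chains
(R/W/Y); a pore of exactly 7 Å is excluded.

## Release kinetics

Transit of a peptide of L residues across a pore of thickness x with
diffusivity D is modelled as the one-dimensional free diffusion time
x²/(2D) hindered by a factor L²: τ_pore = L²·x²/(2D).  This is the only
reading consistent with the model's four printed anchors (4× at L = 2,
100× at L = 10, ~160 ns free transit and ~16 µs hindered transit at
x = 1 nm, D = 3 µm²/s); the package reports the exact 166.7 ns / 16.7 µs
rather than rounding.  The translocation comparison is per product:
generation time L/v (0.25 s for a decapeptide at 40 residues/s) divided
by τ_pore gives 1.5×10⁴, i.e. floor(log₁₀) = 4 orders of magnitude; a
per-residue reading (1/v) would give three orders and is not used.
Pores are treated as inert; a strongly hydrophobic lining (mean
Kyte–Doolittle above a configurable 2.0) only raises a boolean
attraction flag — no quantitative adsorption model is attempted.  Units
are explicit (nm, µm²/s → ns) with converters for nm²/ns and Å²/ns.

## Pipeline, determinism and problem sizes

`run_pipeline` executes simulate → modes → landscape → pores → kinetics
from a single serializable `RunConfig`; outputs are plain TSV tables, a
multi-model PDB of conformers (CA-only records, one chain per group,
occupancy 1.00, B-factor 0.00; per-chain residue numbering — bead
identity is record order, and radii are re-supplied on reading since PDB
has no radius field), a PNG heatmap, a flat key=value summary and a
timestamped log.  Reruns of the same config and seed are byte-identical
(the log is the only timestamped file).  Validation reports *all*
invariant violations, not just the first; a stage failure aborts with
the stage name, leaves upstream outputs, and writes a FAILED marker.

Reference problem sizes: 10⁵ sampled particles, 30×30 bins, 0.5 Å pore
grid (~9×10⁶ voxels), 40-conformer PCA ensembles; the test suite and
examples use reduced sizes (2×10⁴ particles, 1 Å grids, compact
25-Å barrels) chosen so the whole suite exercises every code path in
well under a minute of landscape work and a few seconds per
rasterization.

## What the synthetic data does and does not show

The generator emulates the *statistical structure* of a heterogeneous
single-particle ensemble: Boltzmann-populated states with controlled
fractions and barrier, rigid-body modes with exact amplitudes, and a
solvent-accessible geometry with known channels.  It does not emulate
image formation, alignment error, continuous intra-group flexibility,
atomic side-chain packing, or electrostatics beyond formal charges.
Passing recovery tests therefore demonstrates the correctness of the
analysis operators under their stated models — not that real cryo-EM
data would yield these numbers.  Known limitations: the minimax barrier
on sampled data inherits Poisson noise at the saddle (~0.17 k_BT s.d.
at the reference size); constriction measurements assume roughly
prismatic channels (strongly winding pores would need a centerline
search); and `infer_barrel_meta` (used when structures are re-read from
PDB without construction metadata) assumes a two-layer wall lattice.
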