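# corelandscape

Quantitative analysis of conformational heterogeneity and peptide-release
geometry for barrel-shaped macromolecular machines, modelled on the 26S
proteasome: a gated four-ring 20S core barrel carrying wall pores, with a
flexible 19S regulatory particle (lid, AAA-ATPase base, RPN1) on one face.

Single-particle ensembles of such machines are not single structures but
populations spread over conformational modes — lid rotation (up to 35°),
lid tilt (4–10°), an RPN1 swing (up to 25 Å) and an axial compression of
the core (12 Å) that partially opens the unoccupied gate.  This package
provides both sides of that analysis as a tested, reusable library:

* **Synthetic ensemble generation** — a coarse-grained bead surrogate of the
  assembly with exact, configurable ground truth: rigid-body mode catalogue,
  drilled wall pores and annular gate, and particle populations
  Boltzmann-distributed on a model free-energy surface
  (58% resting / 42% non-resting, of which 7% fully compressed, separated by
  a 5.6 k_BT saddle).
* **Mode recovery** — anchor-group superposition, PCA of conformer
  ensembles, and screw-axis decomposition of group motions
  (angle, axis, pivot, translation, maximum displacement) with a
  rotation/tilt/compression/translation/mixed classifier.
* **Free-energy landscapes** — population binning over two mode
  coordinates, Boltzmann inversion `E_i = −ln(N_i / N_max)` (k_BT),
  watershed basin detection, state fractions, and minimax (lowest-ridge)
  barriers between basins, with honest lower-bound semantics across
  unsampled ridges.
* **Pore & gate geometry** — occupancy-grid rasterization with a solvent
  probe, flood-fill detection of wall channels, inscribed-sphere
  constriction diameters (d_min, d_max), Kyte–Doolittle/formal-charge
  lining chemistry, the strict >7 Å release filter, and the axial gate
  diameter.
* **Release kinetics** — hindered diffusion through narrow pores:
  transit time `τ_pore = L²·x²/(2D)` for a peptide of L residues across a
  pore of thickness x, compared per product with the translocation time
  L/v of the protease.

## Worked example

```python
import corelandscape as cl

surface = cl.default_surface()                       # 58/35/7%, 5.6 k_BT saddle
particles = cl.sample_particles(surface, 100_000, seed=20220311)
grid = cl.boltzmann_invert(cl.bin_particles(particles, (30, 30)))
basins = cl.find_basins(grid)
labels, summary = cl.assign_states(particles, grid, basins)
print(summary[summary.fraction >= 0.01][["basin", "fraction", "is_compressed"]])
major = max(basins, key=lambda b: b.fraction)
comp = next(b for b in basins if b.minimum_bin[1] > 15)
print(cl.find_barrier(grid, major, comp).barrier_from_a)
```

prints (seed 20220311):

```
   basin  fraction  is_compressed
0      0   0.58138          False
1      1   0.34753          False
2      2   0.06976           True
5.8488443571655795
```

i.e. the recovered state fractions land within sampling noise of the
generator's 58/35/7% ground truth, and the minimax barrier out of the
resting basin recovers the constructed 5.6 k_BT saddle to ~0.25 k_BT.
The kinetics chain prints `τ_free = 166.7 ns`, `τ_pore = 16.7 µs`
(L = 10, x = 1 nm, D = 3 µm²/s) and an `orders_of_magnitude = 4` margin
of pore release over translocation at 40 residues/s.

The `examples/` directory holds one short narrative script per
capability (assembly construction, mode recovery, landscape, pore
census, kinetics, full pipeline).  A thin CLI mirrors the pipeline:

```bash
corelandscape init-config --out config.yaml
corelandscape run --config config.yaml --out results_dir
corelandscape kinetics -L 10 -D 3 -x 1 -v 40
```

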