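"""Run the complete pipeline from one configuration.

simulate -> modes -> landscape -> pores -> kinetics, writing TSV tables,
a conformer PDB, a landscape heatmap and a flat key=value summary into
the output directory.  A reduced particle count keeps this example fast;
the reference run uses n_particles = 100000 and 0.5 A pore spacing.
"""

import corelandscape as cl

config = cl.RunConfig.default()
config.n_particles = 20_000
config.n_conformers = 12
config.pore_spacing = 1.0
config.out_dir = "scratch/example_run"

summary = cl.run_pipeline(config)

for key in (
    "resting_fraction",
    "compressed_fraction",
    "barrier_resting_to_compressed_kBT",
    "lid_rotation_rotation_angle_deg",
    "cp_compression_max_displacement_A",
    "rpn1_swing_max_displacement_A",
    "gate_diameter_A",
    "n_pores",
    "n_releasing_pores",
    "kinetics_tau_pore_us",
    "kinetics_orders_of_magnitude",
):
    print(f"{key} = {summary[key]}")
print(f"\nfull outputs in {config.out_dir}/ (see summary.txt, run.log)")
# The consolidated summary shows the recovered state fractions (~0.58 /
# ~0.07), the ~5.6 k_BT barrier, the constructed mode amplitudes, the
# 14 A gate, the 30-pore census and the kinetics chain in one place.
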