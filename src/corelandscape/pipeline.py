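"""End-to-end orchestration: simulate -> modes -> landscape -> pores -> kinetics.

A run is fully described by a :class:`RunConfig` (serializable to YAML)
and a seed; all stage randomness flows from that single seed through
named substreams, so rerunning a config reproduces every output file
byte for byte.  Each stage writes plain TSV tables into the output
directory, a consolidated flat key=value summary is written at the end,
and a timestamped log records versions, seed and config echo.  A stage
failure leaves a FAILED marker naming the stage, with upstream outputs
retained.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import (
    CP_GROUPS,
    AssemblyConfig,
    PoreSpec,
    build_reference_assembly,
    default_pore_set,
)
from .decompose import align_ensemble, classify_mode, decompose_rigid_motion, principal_modes
from .ensemble_io import write_ensemble
from .kinetics import ReleaseParams, attraction_flag, release_report
from .landscape import assign_states, bin_particles, boltzmann_invert, find_barrier, find_basins
from .modes import apply_modes, define_modes
from .pores import analyze_pores
from .surface import default_surface, sample_particles

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]

#: default endpoint amplitudes (the full observed amplitude of each mode)
DEFAULT_MODE_AMPLITUDES = {
    "lid_rotation": 35.0,
    "lid_tilt": 10.0,
    "cp_compression": 12.0,
    "rpn1_swing": 25.0,
}
_MODE_RANGES = {
    "lid_rotation": (0.0, 35.0),
    "lid_tilt": (4.0, 10.0),
    "cp_compression": (0.0, 12.0),
    "rpn1_swing": (1.0, 25.0),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Serializable description of a full analysis run."""

    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    mode_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_MODE_AMPLITUDES))
    surface_barrier: float = 5.6
    n_particles: int = 100_000
    n_conformers: int = 40
    seed: int = 20220311
    n_bins: tuple[int, int] = (30, 30)
    pore_spacing: float = 0.5
    probe_radius: float = 1.4
    kinetics: ReleaseParams = field(default_factory=ReleaseParams)
    out_dir: str = "corelandscape_run"

    @classmethod
    def default(cls) -> "RunConfig":
        """The reference parameterization (open gate, 30-pore census)."""
        return cls(
            assembly=AssemblyConfig(gate_diameter=14.0, pores=default_pore_set())
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assembly"]["pores"] = [dataclasses.asdict(p) for p in self.assembly.pores]
        d["n_bins"] = list(self.n_bins)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        asm = dict(d.get("assembly", {}))
        asm["pores"] = tuple(PoreSpec(**p) for p in asm.get("pores", ()))
        d["assembly"] = AssemblyConfig(**asm)
        d["kinetics"] = ReleaseParams(**d.get("kinetics", {}))
        if "n_bins" in d:
            d["n_bins"] = tuple(d["n_bins"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(config: RunConfig) -> list[str]:
    """Check every field invariant; return all violations, not just the first."""
    errors = []
    errors += config.assembly.validate()
    errors += config.kinetics.validate()
    for name, amp in config.mode_amplitudes.items():
        if name not in _MODE_RANGES:
            errors.append(f"mode_amplitudes: unknown mode {name!r}")
            continue
        lo, hi = _MODE_RANGES[name]
        if amp != 0 and not (lo <= amp <= hi):
            errors.append(
                f"mode_amplitudes[{name!r}] = {amp} outside range [{lo}, {hi}]"
            )
    if config.n_particles < 1:
        errors.append("n_particles must be >= 1")
    if config.n_conformers < 2:
        errors.append("n_conformers must be >= 2")
    if len(config.n_bins) != 2 or min(config.n_bins) < 2:
        errors.append("n_bins must be two integers >= 2")
    if config.pore_spacing <= 0:
        errors.append("pore_spacing must be positive")
    if config.probe_radius < 0:
        errors.append("probe_radius must be >= 0")
    if not (0 < config.surface_barrier < 50):
        errors.append("surface_barrier must be a positive energy in k_BT")
    return errors


def _substream_seeds(seed: int, n: int) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the consolidated summary dictionary."""
    errors = validate_config(config)
    if errors:
        raise PipelineError("invalid configuration: " + "; ".join(errors))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("corelandscape.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.propagate = False

    summary: dict = {"version": __version__, "seed": config.seed}
    stage = "setup"
    t0 = time.time()
    try:
        log.info("corelandscape %s, seed %d", __version__, config.seed)
        config.save(out / "config_echo.yaml")
        seed_sample, seed_nuisance = _substream_seeds(config.seed, 2)

        stage = "simulate"
        reference = build_reference_assembly(config.assembly)
        modes = define_modes(reference)
        surface = default_surface(barrier=config.surface_barrier)
        particles = sample_particles(surface, config.n_particles, seed=seed_sample)
        rng = np.random.default_rng(seed_nuisance)
        conformers = []
        for q1, q2 in particles.mode_coords[: config.n_conformers]:
            amps = {
                "lid_rotation": float(np.clip(q1, 0.0, 35.0)),
                "cp_compression": float(np.clip(q2, 0.0, 12.0)),
                "lid_tilt": float(rng.uniform(4.0, 10.0)),
                "rpn1_swing": float(rng.uniform(1.0, 25.0)),
            }
            conformers.append(apply_modes(reference, modes, amps))
        write_ensemble(
            particles, reference, modes, out, conformers=conformers
        )
        log.info("simulated %d particles, %d conformers", particles.n, len(conformers))

        stage = "modes"
        rows = []
        for mode in modes:
            amp = float(config.mode_amplitudes.get(mode.name, mode.amplitude_range[1]))
            endpoint = apply_modes(reference, modes, {mode.name: amp})
            desc = decompose_rigid_motion(reference, endpoint, mode.affected_groups)
            kind = classify_mode(desc, reference.barrel_axis)
            rows.append(
                {
                    "mode": mode.name,
                    "construction_kind": mode.kind,
                    "recovered_kind": kind,
                    "amplitude_input": amp,
                    "rotation_angle_deg": desc.rotation_angle,
                    "translation_along_axis_A": desc.translation_along_axis,
                    "max_displacement_A": desc.max_displacement,
                    "pivot_x": desc.pivot[0],
                    "pivot_y": desc.pivot[1],
                    "pivot_z": desc.pivot[2],
                }
            )
            key = mode.name
            summary[f"{key}_recovered_kind"] = kind
            summary[f"{key}_rotation_angle_deg"] = round(desc.rotation_angle, 6)
            summary[f"{key}_max_displacement_A"] = round(desc.max_displacement, 6)
        pd.DataFrame(rows).to_csv(out / "mode_descriptors.tsv", sep="\t", index=False)

        aligned = align_ensemble(conformers, reference)
        k = min(4, len(conformers) - 1)
        _components, variances, projections = principal_modes(aligned, k)
        proj = pd.DataFrame(
            projections, columns=[f"pc{i + 1}" for i in range(k)]
        )
        proj.insert(0, "conformer", np.arange(len(conformers)))
        proj.to_csv(out / "pca_projections.tsv", sep="\t", index=False)
        summary["pca_variance_fraction_pc1"] = round(
            float(variances[0] / variances.sum()), 6
        )
        log.info("mode table and PCA projections written")

        stage = "landscape"
        grid = boltzmann_invert(bin_particles(particles, config.n_bins))
        basins = find_basins(grid)
        labels, basin_summary = assign_states(particles, grid, basins)
        basin_summary.to_csv(out / "basin_summary.tsv", sep="\t", index=False)
        np.savetxt(out / "counts.tsv", grid.counts, fmt="%d", delimiter="\t")
        with np.printoptions():
            energies = pd.DataFrame(grid.energies)
            energies.to_csv(
                out / "energies.tsv", sep="\t", index=False, header=False,
                na_rep="NA", float_format="%.6f",
            )
        major = basins[int(np.argmax([b.fraction for b in basins]))]
        barrier_rows = []
        for b in basins:
            if b.label == major.label:
                continue
            res = find_barrier(grid, major, b)
            barrier_rows.append(
                {
                    "from_basin": major.label,
                    "to_basin": b.label,
                    "saddle_energy_kBT": res.saddle_energy,
                    "barrier_forward_kBT": res.barrier_from_a,
                    "barrier_reverse_kBT": res.barrier_from_b,
                    "lower_bound": res.lower_bound,
                }
            )
        pd.DataFrame(barrier_rows).to_csv(
            out / "barrier_report.tsv", sep="\t", index=False
        )
        summary["resting_fraction"] = round(float(major.fraction), 6)
        compressed = basin_summary[basin_summary["is_compressed"]]
        summary["compressed_fraction"] = round(float(compressed["fraction"].sum()), 6)
        significant = [
            r for r in barrier_rows
            if basins[r["to_basin"]].fraction >= 0.01
        ]
        if significant:
            summary["min_barrier_from_resting_kBT"] = round(
                min(r["barrier_forward_kBT"] for r in significant), 6
            )
        compressed_ids = set(compressed["basin"])
        for r in barrier_rows:
            if r["to_basin"] in compressed_ids and basins[r["to_basin"]].fraction >= 0.01:
                summary["barrier_resting_to_compressed_kBT"] = round(
                    r["barrier_forward_kBT"], 6
                )
                break
        _plot_landscape(grid, out / "landscape.png")
        log.info("landscape: %d basins", len(basins))

        stage = "pores"
        core = reference.select(CP_GROUPS)
        pores, gate, _grid = analyze_pores(
            core, spacing=config.pore_spacing, probe_radius=config.probe_radius
        )
        pore_rows = [
            {
                "pore_id": p.pore_id,
                "x": p.constriction_center[0],
                "y": p.constriction_center[1],
                "z": p.constriction_center[2],
                "d_min_A": p.d_min,
                "d_max_A": p.d_max,
                "net_charge": p.net_formal_charge,
                "mean_hydropathy": p.mean_hydropathy,
                "class": p.hydropathy_class,
                "releasing": p.releasing,
                "attraction_flag": attraction_flag(p.mean_hydropathy),
            }
            for p in pores
        ]
        pd.DataFrame(pore_rows).to_csv(
            out / "pore_table.tsv", sep="\t", index=False, float_format="%.3f"
        )
        summary["n_pores"] = len(pores)
        summary["n_releasing_pores"] = sum(1 for p in pores if p.releasing)
        summary["gate_diameter_A"] = round(gate, 3)
        log.info("pores: %d found, gate %.2f A", len(pores), gate)

        stage = "kinetics"
        report = release_report(config.kinetics)
        pd.DataFrame([report]).to_csv(
            out / "kinetics_report.tsv", sep="\t", index=False
        )
        for k_, v in report.items():
            summary[f"kinetics_{k_}"] = v

        stage = "summary"
        with open(out / "summary.txt", "w") as fh:
            for k_, v in summary.items():
                fh.write(f"{k_}={v}\n")
        log.info("finished in %.1f s", time.time() - t0)
        return summary
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _plot_landscape(grid, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    masked = np.ma.masked_invalid(grid.energies.T)
    mesh = ax.pcolormesh(
        grid.bin_edges_q1, grid.bin_edges_q2, masked, shading="flat", cmap="viridis"
    )
    fig.colorbar(mesh, ax=ax, label=r"free energy ($k_B T$)")
    ax.set_xlabel("lid rotation q1 (deg)")
    ax.set_ylabel("CP compression q2 ($\\AA$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
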