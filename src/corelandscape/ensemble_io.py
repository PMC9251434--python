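"""Ensemble I/O: multi-model PDB conformers and ground-truth TSV tables.

Conformers are written as a multi-MODEL PDB with one chain per bead
group and CA-only records (occupancy 1.00, B-factor 0.00); this
round-trips losslessly at the format's 3-decimal coordinate precision.
Bead radii are not representable in PDB and are re-supplied on reading.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from biotite.sequence import ProteinSequence
from biotite.structure import AtomArray, stack
from biotite.structure.io.pdb import PDBFile

from .assembly import BeadModel, infer_barrel_meta
from .surface import ParticleSet

__all__ = [
    "write_ensemble",
    "write_conformers_pdb",
    "read_conformers_pdb",
    "write_particles_tsv",
    "read_particles_tsv",
]

_GROUP_TO_CHAIN = {
    "cp_alpha_proximal": "A",
    "cp_beta_1": "B",
    "cp_beta_2": "C",
    "cp_alpha_distal": "D",
    "lid": "L",
    "base_atpase": "E",
    "rpn1": "R",
    "rpn11_marker": "M",
}
_CHAIN_TO_GROUP = {v: k for k, v in _GROUP_TO_CHAIN.items()}


def _to_atom_array(model: BeadModel) -> AtomArray:
    n = len(model)
    arr = AtomArray(n)
    arr.coord = model.positions.astype(np.float32)
    arr.chain_id = np.array([_GROUP_TO_CHAIN[g] for g in model.groups])
    # per-chain 1-based numbering keeps res_id within the PDB field width;
    # bead identity is the (preserved) record order
    counters: dict[str, int] = {}
    res_id = np.empty(n, dtype=int)
    for k, g in enumerate(model.groups):
        counters[g] = counters.get(g, 0) + 1
        res_id[k] = counters[g]
    arr.res_id = res_id
    arr.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(r).upper() for r in model.pseudo_residues]
    )
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    return arr


def write_conformers_pdb(conformers: list[BeadModel], path) -> None:
    """Write conformers as a multi-MODEL PDB (one MODEL per conformer)."""
    if not conformers:
        raise ValueError("no conformers to write")
    arrays = [_to_atom_array(m) for m in conformers]
    structure = arrays[0] if len(arrays) == 1 else stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(structure)
    try:
        pdb.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write conformer PDB to {path}: {exc}") from exc


def read_conformers_pdb(path, bead_radius: float = 2.5) -> list[BeadModel]:
    """Read a multi-model PDB back into bead models.

    ``bead_radius`` restores the radius annotation the PDB format drops;
    barrel metadata is re-inferred from the geometry.
    """
    pdb = PDBFile.read(str(path))
    structure = pdb.get_structure(model=None)
    if structure.stack_depth() == 0:
        raise ValueError(f"no models in {path}")
    models = []
    template = structure[0]
    groups = np.array(
        [_CHAIN_TO_GROUP[c] for c in template.chain_id], dtype=object
    )
    residues = np.array(
        [ProteinSequence.convert_letter_3to1(r) for r in template.res_name],
        dtype=object,
    )
    bead_ids = np.arange(len(template))
    for k in range(structure.stack_depth()):
        model = BeadModel(
            bead_ids=bead_ids.astype(int),
            groups=groups.copy(),
            positions=structure.coord[k].astype(float),
            radii=np.full(len(template), bead_radius),
            pseudo_residues=residues.copy(),
        )
        try:
            model.meta = infer_barrel_meta(model)
        except Exception:
            model.meta = {}
        models.append(model)
    return models


def write_particles_tsv(particles: ParticleSet, path) -> None:
    """Ground-truth table: one row per particle (particle_id, q1, q2, basin)."""
    basin = (
        particles.truth_basin
        if particles.truth_basin is not None
        else np.full(particles.n, "NA", dtype=object)
    )
    df = pd.DataFrame(
        {
            "particle_id": np.arange(particles.n),
            "q1": particles.mode_coords[:, 0],
            "q2": particles.mode_coords[:, 1],
            "basin": basin,
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_particles_tsv(path) -> ParticleSet:
    df = pd.read_csv(path, sep="\t")
    return ParticleSet(
        mode_coords=df[["q1", "q2"]].to_numpy(float),
        truth_basin=df["basin"].to_numpy(object) if "basin" in df else None,
    )


def write_ensemble(
    particles: ParticleSet,
    reference: BeadModel,
    modes,
    out_dir,
    conformers: list[BeadModel] | None = None,
    config_echo: dict | None = None,
) -> dict[str, Path]:
    """Write the synthetic ensemble to ``out_dir``.

    Emits the ground-truth particle TSV, a multi-model conformer PDB
    (the supplied conformers, or the reference alone), and a YAML echo of
    the generating configuration.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    paths = {
        "particles": out / "particles.tsv",
        "conformers": out / "conformers.pdb",
        "config": out / "config_echo.yaml",
    }
    write_particles_tsv(particles, paths["particles"])
    write_conformers_pdb(conformers or [reference], paths["conformers"])
    echo = dict(config_echo or {})
    echo.setdefault("n_particles", particles.n)
    echo.setdefault("seed", particles.seed)
    echo.setdefault(
        "modes",
        [
            {
                "name": m.name,
                "kind": m.kind,
                "affected_groups": list(m.affected_groups),
                "pivot": [float(x) for x in m.pivot],
                "axis": [float(x) for x in m.axis],
                "amplitude_range": [float(x) for x in m.amplitude_range],
            }
            for m in modes
        ],
    )
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
    return paths
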