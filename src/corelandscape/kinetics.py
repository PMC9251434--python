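"""Hindered diffusion of peptide products through narrow wall pores.

A peptide of L residues threading a pore of thickness x diffuses the
pore thickness in a time L^2 * x^2 / (2 D): the one-dimensional free
diffusion time x^2/(2D) slowed by an L^2 hindrance factor.  Dimers
(L = 2) cross four times slower than free diffusion, decapeptides
(L = 10) a hundred times slower.  Setting x = 1 nm and D = 3 um^2/s
gives a free-diffusion time of 166.7 ns and a pore transit of 16.7 us
for L = 10, to be compared per product with the time the protease needs
to translocate one product length of substrate (L / v, 0.25 s at
v = 40 residues/s) — four orders of magnitude slower than the possible
release, so inert pores do not limit degradation.

The model treats pores as inert; an attractive pore lining would slow
release further, which is surfaced only as a warning flag on strongly
hydrophobic pores (no quantitative adsorption model is attempted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ReleaseParams",
    "slowdown_factor",
    "free_diffusion_time",
    "pore_release_time",
    "translocation_comparison",
    "attraction_flag",
    "release_report",
]

_LENGTH_TO_NM = {"A": 0.1, "angstrom": 0.1, "nm": 1.0, "um": 1.0e3}
# diffusivity units -> nm^2/ns
_DIFFUSIVITY_TO_NM2_PER_NS = {
    "um2/s": 1.0e6 / 1.0e9,
    "nm2/ns": 1.0,
    "A2/ns": 1.0e-2,
    "nm2/s": 1.0 / 1.0e9,
}


@dataclass(frozen=True)
class ReleaseParams:
    """Kinetic parameters of the release model.

    D: product diffusivity (um^2/s); x: pore thickness (nm); L: peptide
    length in residues; v: substrate translocation speed (residues/s).
    """

    D: float = 3.0
    x: float = 1.0
    L: int = 10
    v: float = 40.0

    def validate(self) -> list[str]:
        errors = []
        if self.D <= 0:
            errors.append("diffusivity D must be positive")
        if self.x <= 0:
            errors.append("pore thickness x must be positive")
        if self.L < 1 or int(self.L) != self.L:
            errors.append("peptide length L must be an integer >= 1")
        if self.v <= 0:
            errors.append("translocation speed v must be positive")
        return errors


def slowdown_factor(L: int) -> float:
    """Pore transit time relative to free diffusion over the same distance: L^2."""
    if L < 1:
        raise ValueError("peptide length L must be >= 1")
    return float(L) ** 2


def free_diffusion_time(
    x: float, D: float, x_unit: str = "nm", D_unit: str = "um2/s"
) -> float:
    """One-dimensional free diffusion time tau = x^2 / (2 D), in ns."""
    if x <= 0 or D <= 0:
        raise ValueError("x and D must be positive")
    x_nm = x * _LENGTH_TO_NM[x_unit]
    d_nm2_ns = D * _DIFFUSIVITY_TO_NM2_PER_NS[D_unit]
    return x_nm**2 / (2.0 * d_nm2_ns)


def pore_release_time(
    L: int, x: float, D: float, x_unit: str = "nm", D_unit: str = "um2/s"
) -> float:
    """Hindered transit time tau_pore = L^2 * x^2 / (2 D), in ns."""
    return slowdown_factor(L) * free_diffusion_time(x, D, x_unit=x_unit, D_unit=D_unit)


def translocation_comparison(L: int, v: float, tau_pore_ns: float):
    """Compare product generation with pore release, per product.

    Returns (product_generation_time_s, ratio, orders_of_magnitude) where
    the generation time is L / v — the time to translocate one
    product-length of substrate — and the ratio divides it by the pore
    transit time.  orders_of_magnitude = floor(log10(ratio)).
    """
    if L < 1 or v <= 0 or tau_pore_ns <= 0:
        raise ValueError("L >= 1, v > 0 and tau_pore > 0 required")
    generation_s = L / v
    ratio = generation_s / (tau_pore_ns * 1e-9)
    return generation_s, ratio, math.floor(math.log10(ratio))


def attraction_flag(mean_hydropathy: float, threshold: float = 2.0) -> bool:
    """Warn when a pore lining is hydrophobic enough to bind peptides.

    The inert-pore assumption breaks down for attractive pores; a mean
    Kyte-Doolittle hydropathy above ``threshold`` raises the flag.  The
    resulting slowdown is not modelled quantitatively.
    """
    return bool(mean_hydropathy > threshold)


def release_report(params: ReleaseParams | None = None) -> dict:
    """Full kinetics chain for one parameter set, in reporting units."""
    p = params or ReleaseParams()
    errors = p.validate()
    if errors:
        raise ValueError("; ".join(errors))
    tau_free_ns = free_diffusion_time(p.x, p.D)
    factor = slowdown_factor(p.L)
    tau_pore_ns = factor * tau_free_ns
    generation_s, ratio, orders = translocation_comparison(p.L, p.v, tau_pore_ns)
    return {
        "D_um2_per_s": p.D,
        "x_nm": p.x,
        "L_residues": p.L,
        "v_res_per_s": p.v,
        "tau_free_ns": tau_free_ns,
        "slowdown_factor": factor,
        "tau_pore_us": tau_pore_ns * 1e-3,
        "product_generation_s": generation_s,
        "generation_to_release_ratio": ratio,
        "orders_of_magnitude": orders,
    }
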