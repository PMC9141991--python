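"""Electron-transfer kinetics: Marcus barriers, Eyring rates, diffusion.

The SET barrier comes from Marcus theory,

    dG_act = (lambda / 4) * (1 + dG / lambda)**2,

a parabola in dG with a barrierless point at dG = -lambda and a re-rising
("inverted") branch beyond it.  The activation-controlled bimolecular rate
follows Eyring transition-state theory,

    k_act = (kB * T / h) * exp(-dG_act / (R * T)),

(prefactor ~6.212e12 s^-1 at 298.15 K, no tunneling, path degeneracy
sigma = 1).  Physically the rate cannot exceed the diffusion-limited
encounter rate; the Collins-Kimball interpolation

    k_app = k_diff * k_act / (k_diff + k_act)

caps it.  k_diff can be estimated de novo from Smoluchowski encounter
theory with Stokes-Einstein diffusion coefficients; for the packaged DPPH
tables the empirical 7.5e9 M^-1 s^-1 limit is used instead since the
underlying radii are unknown.

Species-resolved apparent rates are aggregated into an observable overall
rate coefficient by weighting with equilibrium molar fractions at the
working pH (QM-ORSA-style aggregation).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhysicalConstants:
    """SI constants plus the working temperature and solvent viscosity."""

    boltzmann: float = 1.380649e-23  # J/K
    planck: float = 6.62607015e-34  # J s
    gas_constant_kcal: float = 1.987204e-3  # kcal/(mol K)
    avogadro: float = 6.02214076e23  # 1/mol
    temperature: float = 298.15  # K
    viscosity: float = 8.91e-4  # Pa s (water, 25 C)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValidationError("viscosity must be positive")

    @property
    def eyring_prefactor(self) -> float:
        """kB*T/h in s^-1 (~6.212e12 at 298.15 K)."""
        return self.boltzmann * self.temperature / self.planck


DEFAULT_CONSTANTS = PhysicalConstants()

#: Empirical diffusion limit used for the DPPH reproduction (M^-1 s^-1).
KDIFF_DPPH = 7.5e9


@dataclass(frozen=True)
class RateResult:
    """Barrier and rate decomposition for one species/channel."""

    barrier: float  # kcal/mol
    k_act: float  # M^-1 s^-1
    k_diff: float  # M^-1 s^-1
    k_app: float  # M^-1 s^-1
    dg_set: float | None = None
    lambda_reorg: float | None = None


def marcus_barrier(dg_set: float, lambda_reorg: float) -> float:
    """Marcus activation energy (lambda/4)(1 + dG/lambda)^2, kcal/mol.

    ``lambda_reorg`` may come from a vertical/adiabatic gap difference
    (lambda = dE_vertical - dG_SET) when available.
    """
    if not lambda_reorg > 0:
        raise ValidationError(
            f"reorganization energy must be positive, got {lambda_reorg}"
        )
    return (lambda_reorg / 4.0) * (1.0 + dg_set / lambda_reorg) ** 2


def lambda_from_vertical_gap(de_vertical: float, dg_set: float) -> float:
    """Reorganization energy as the vertical-minus-adiabatic difference."""
    lam = de_vertical - dg_set
    if not lam > 0:
        raise ValidationError(
            f"derived reorganization energy is non-positive ({lam})"
        )
    return lam


def eyring_rate(
    barrier: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Activation-controlled rate from a free-energy barrier (kcal/mol).

    Negative barriers cannot arise from the Marcus formula; a negative
    user-supplied value is clamped to zero with a warning, matching the
    semantics of a printed "0.0" barrier (diffusion control takes over).
    """
    if barrier < 0:
        warnings.warn(
            f"negative barrier {barrier} clamped to 0 (diffusion-controlled)",
            stacklevel=2,
        )
        barrier = 0.0
    rt = constants.gas_constant_kcal * constants.temperature
    return constants.eyring_prefactor * math.exp(-barrier / rt)


def smoluchowski_kd(
    radius_a: float,
    radius_b: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Diffusion-limited rate from Smoluchowski encounter theory.

    Radii in Angstrom; Stokes-Einstein diffusion coefficients
    D_i = kB*T / (6 pi eta r_i); result in M^-1 s^-1 via the factor
    1000 * N_A (m^3 -> L per mole).
    """
    if radius_a <= 0 or radius_b <= 0:
        raise ValidationError("radii must be positive")
    ra = radius_a * 1e-10
    rb = radius_b * 1e-10
    kbt = constants.boltzmann * constants.temperature
    d_a = kbt / (6.0 * math.pi * constants.viscosity * ra)
    d_b = kbt / (6.0 * math.pi * constants.viscosity * rb)
    k_m3 = 4.0 * math.pi * (ra + rb) * (d_a + d_b)  # m^3/s per pair
    return k_m3 * constants.avogadro * 1000.0


def collins_kimball(k_act: float, k_diff: float) -> float:
    """Apparent rate interpolating activation and diffusion control.

    k_app = k_diff * k_act / (k_diff + k_act); bounded above by both
    inputs.  Both-zero input is the defined limit 0.
    """
    if k_act < 0 or k_diff < 0:
        raise ValidationError("rates must be non-negative")
    if k_act == 0.0 or k_diff == 0.0:
        return 0.0
    return k_diff * k_act / (k_diff + k_act)


def apparent_rate(
    barrier: float,
    k_diff: float = KDIFF_DPPH,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    dg_set: float | None = None,
    lambda_reorg: float | None = None,
) -> RateResult:
    """Barrier -> Eyring -> Collins-Kimball pipeline for one species."""
    k_act = eyring_rate(barrier, constants)
    return RateResult(
        barrier=max(barrier, 0.0),
        k_act=k_act,
        k_diff=k_diff,
        k_app=collins_kimball(k_act, k_diff),
        dg_set=dg_set,
        lambda_reorg=lambda_reorg,
    )


def overall_rate(
    fractions: Mapping[str, float], k_apps: Mapping[str, float]
) -> float:
    """Molar-fraction-weighted overall rate coefficient, sum_j f_j k_j.

    ``fractions`` must sum to 1 over the ladder; species present in the
    speciation but missing a rate contribute zero with a warning (e.g.
    trace species never submitted to kinetics).  Rates for tags absent
    from the speciation are a misalignment and raise.
    """
    total_f = math.fsum(fractions.values())
    if abs(total_f - 1.0) > 1e-6:
        raise ValidationError(f"fractions sum to {total_f}, expected 1")
    stray = set(k_apps) - set(fractions)
    if stray:
        raise ValidationError(
            f"rate tags {sorted(stray)} not present in the speciation"
        )
    total = 0.0
    for tag, frac in fractions.items():
        k = k_apps.get(tag)
        if k is None:
            if frac > 0:
                logger.warning(
                    "overall_rate: species %s (f=%.4g) has no rate; counts as 0",
                    tag,
                    frac,
                )
            continue
        total += frac * k
    return total
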