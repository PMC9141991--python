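"""Reduction of antioxidant assay readouts to reported quantities.

Two assay geometries are covered:

* Lipid-peroxidation inhibition in liposomes, read out as relative
  fluorescence of a membrane probe bleached by peroxyl radicals:

      % inhibition = 100 * (F_s - F_c) / (F_b - F_c)

  with F_s the sample (radical + antioxidant), F_c the oxidized control
  (radical, no antioxidant) and F_b the blank (no radical).  The quotient
  is the only reading that is 0% at no protection and 100% at full
  protection, and it is invariant to rescaling all three fluorescences.

* DPPH radical scavenging, read out as the 517-nm absorbance change:

      % reduction = 100 * (dA_0 - dA_1) / dA_0.

Half-maximal concentrations (IC50 for inhibition, EC50 for DPPH) are
estimated with the linear model the assays were designed around: ordinary
least squares of response on concentration, inverted at 50%.  A 4PL
sigmoid is deliberately not offered.  Responses are not clipped to
[0, 100]; noisy points outside the bounds are legitimate fit inputs.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import BracketingError, ValidationError


@dataclass(frozen=True)
class OxidationReadout:
    """One fluorescence triple (sample, oxidized control, blank)."""

    f_sample: float
    f_control: float
    f_blank: float
    time_min: float | None = None
    concentration: float | None = None  # µM

    def __post_init__(self) -> None:
        for name in ("f_sample", "f_control", "f_blank"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not self.f_blank > self.f_control:
            raise ValidationError(
                "blank fluorescence must exceed the oxidized control "
                f"(got blank={self.f_blank}, control={self.f_control})"
            )


@dataclass(frozen=True)
class DoseResponse:
    """A fitted linear dose-response with its half-maximal concentration."""

    concentrations: tuple[float, ...]  # µM
    responses: tuple[float, ...]  # %
    half_max: float  # µM
    fit_slope: float  # %/µM
    fit_intercept: float  # %
    r_squared: float


def percent_inhibition(readout: OxidationReadout) -> float:
    """Percent inhibition of lipid peroxidation from one readout."""
    denom = readout.f_blank - readout.f_control
    return 100.0 * (readout.f_sample - readout.f_control) / denom


def percent_dpph_reduction(delta_a0: float, delta_a1: float) -> float:
    """Percent DPPH reduction from absorbance changes at 517 nm."""
    if not delta_a0 > 0:
        raise ValidationError(
            f"control absorbance change must be positive, got {delta_a0}"
        )
    return 100.0 * (delta_a0 - delta_a1) / delta_a0


def half_max_linear(
    concentrations: Sequence[float],
    responses: Sequence[float],
    extrapolate: bool = False,
) -> DoseResponse:
    """IC50/EC50 from a linear response-vs-concentration fit.

    OLS line response = m*conc + b, inverted at 50%: half_max = (50-b)/m.
    Requires m > 0 (a responsive assay) and, unless ``extrapolate``,
    responses that bracket 50%.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    resp = np.asarray(list(responses), dtype=float)
    if conc.size != resp.size:
        raise ValidationError("concentrations and responses differ in length")
    if conc.size < 2:
        raise ValidationError("need at least two dose-response points")
    if np.any(np.diff(conc) <= 0):
        raise ValidationError("concentrations must be strictly increasing")
    if not extrapolate and not (resp.min() <= 50.0 <= resp.max()):
        raise BracketingError(
            f"responses [{resp.min():.3g}, {resp.max():.3g}] do not bracket "
            "50% (pass extrapolate=True to override)"
        )
    fit = stats.linregress(conc, resp)
    if not fit.slope > 0:
        raise ValidationError(
            f"non-responsive assay: fitted slope {fit.slope:.3g} <= 0"
        )
    half = (50.0 - fit.intercept) / fit.slope
    return DoseResponse(
        concentrations=tuple(conc),
        responses=tuple(resp),
        half_max=float(half),
        fit_slope=float(fit.slope),
        fit_intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def fold_vs_reference(half_max_compound: float, half_max_reference: float) -> float:
    """How many times more potent than a reference antioxidant.

    Ratio of half-maximal concentrations, reference over compound: a
    compound needing 50-fold less material scores 50.
    """
    if half_max_compound <= 0 or half_max_reference <= 0:
        raise ValidationError("half-max concentrations must be positive")
    return half_max_reference / half_max_compound
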