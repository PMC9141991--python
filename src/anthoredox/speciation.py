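"""Polyprotic acid-base speciation.

For an n-protic acid with stepwise dissociation constants pKa_1 < ... <
pKa_n, the equilibrium molar fraction of the species that has lost j
protons at a given pH is

    f_j = 10**(sum_{i<=j} (pH - pKa_i)) / sum_k 10**(sum_{i<=k} (pH - pKa_i))

i.e. a partition function over cumulative Henderson-Hasselbalch terms.
The exponents are shifted by their maximum before exponentiation so that
ladders spanning tens of log units neither overflow nor underflow.

Temperature does not appear: the pKa values already encapsulate it.
No activity/ionic-strength corrections are applied (macroscopic
speciation only, one macro-state per deprotonation step).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import PHYSIOLOGICAL_PH
from .exceptions import ValidationError


def default_state_labels(n_steps: int) -> list[str]:
    """Charge-state tags for a flavylium-type ladder: +, 0, 1-, 2-, ..."""
    labels = ["+", "0"]
    labels += [f"{i}-" for i in range(1, n_steps)]
    return labels[: n_steps + 1]


@dataclass(frozen=True)
class AcidBaseLadder:
    """Ordered stepwise pKa list defining a compound's macro-speciation."""

    compound_id: str
    pka: tuple[float, ...]
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pka = tuple(float(p) for p in self.pka)
        object.__setattr__(self, "pka", pka)
        if len(pka) == 0:
            raise ValidationError(f"{self.compound_id}: empty pKa ladder")
        if any(not np.isfinite(p) for p in pka):
            raise ValidationError(f"{self.compound_id}: non-finite pKa value")
        if any(b <= a for a, b in zip(pka, pka[1:])):
            raise ValidationError(
                f"{self.compound_id}: pKa list must be strictly increasing, "
                f"got {pka}"
            )
        labels = tuple(self.labels) or tuple(default_state_labels(len(pka)))
        if len(labels) != len(pka) + 1:
            raise ValidationError(
                f"{self.compound_id}: need {len(pka) + 1} labels, got "
                f"{len(labels)}"
            )
        object.__setattr__(self, "labels", labels)

    @property
    def n_species(self) -> int:
        return len(self.pka) + 1


@dataclass(frozen=True)
class SpeciationProfile:
    """Molar fractions of every macro-state of one ladder at one pH."""

    ladder: AcidBaseLadder
    ph: float
    fractions: tuple[float, ...]

    def as_percent(self) -> tuple[float, ...]:
        return tuple(100.0 * f for f in self.fractions)

    def as_dict(self, percent: bool = False) -> dict[str, float]:
        vals = self.as_percent() if percent else self.fractions
        return dict(zip(self.ladder.labels, vals))


def molar_fractions(ladder: AcidBaseLadder, ph: float) -> SpeciationProfile:
    """Equilibrium molar fractions of all macro-states at a given pH.

    Numerically stable closed form: cumulative (pH - pKa_i) exponents are
    shifted by their maximum before exponentiation, so ladders with pKa
    spreads of 40+ log units evaluate without overflow or underflow of the
    normalisation.
    """
    if not np.isfinite(ph):
        raise ValidationError(f"pH must be finite, got {ph}")
    exponents = np.concatenate(
        [[0.0], np.cumsum(ph - np.asarray(ladder.pka, dtype=float))]
    )
    exponents -= exponents.max()
    weights = np.power(10.0, exponents)
    fractions = weights / weights.sum()
    return SpeciationProfile(ladder=ladder, ph=float(ph), fractions=tuple(fractions))


def at_physiological_ph(ladder: AcidBaseLadder) -> SpeciationProfile:
    """Convenience wrapper at pH 7.40."""
    return molar_fractions(ladder, PHYSIOLOGICAL_PH)


def distribution_diagram(
    ladder: AcidBaseLadder, ph_grid: Sequence[float]
) -> np.ndarray:
    """Fractions over a pH grid; row g is ``molar_fractions`` at grid[g].

    Adjacent species' curves cross exactly at pH = pKa_i (where the two
    cumulative terms are equal), the textbook distribution-diagram shape.
    """
    grid = np.asarray(list(ph_grid), dtype=float)
    if grid.size == 0:
        raise ValidationError("ph_grid is empty")
    if np.any(np.diff(grid) < 0):
        raise ValidationError("ph_grid must be sorted ascending")
    return np.vstack([molar_fractions(ladder, ph).fractions for ph in grid])


def prune_species(
    profile: SpeciationProfile, threshold: float = 0.001
) -> list[str]:
    """Tags of species with fraction strictly above ``threshold``.

    The default 0.001 (0.1%) is the population cut below which species are
    treated as negligible for reactivity aggregation.  Ladder order is
    preserved.
    """
    if not (0.0 <= threshold < 1.0):
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    return [
        tag
        for tag, frac in zip(profile.ladder.labels, profile.fractions)
        if frac > threshold
    ]


def pka_fitted_params(
    delta_g_deprot: float, slope: float, intercept: float
) -> float:
    """pKa from a deprotonation free energy via a fitted linear model.

    ``pKa = slope * dG_deprot + intercept``, with slope/intercept fitted
    per level of theory and solvent (supplied by the caller; the raw
    thermodynamic slope would be 1/(RT ln 10) but fitted parameterisations
    absorb systematic solvation-model error).
    """
    if not slope > 0:
        raise ValidationError(f"slope must be positive, got {slope}")
    return slope * float(delta_g_deprot) + float(intercept)
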