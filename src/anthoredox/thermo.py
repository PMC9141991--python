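"""Per-site reaction thermochemistry for radical-scavenging mechanisms.

Three channels against a named radical partner R·:

f-HAT  (formal H-atom transfer):   ArOH + R·  -> ArO· + RH
SET    (single electron transfer): ArOH + R·  -> ArOH·+ + R−
SPLET proton-loss first step:      ArOH       -> ArO− + H+(solv)

Each is a plain Hess sum over supplied Gibbs energies; no vibrational or
entropy corrections are applied internally — whatever G values the caller
supplies define the frame.  The ETPT second step (proton transfer after
electron transfer) is not modelled: when the first step is downhill it
drives the reaction.

Site ranking uses the Bell-Evans-Polanyi assumption: among O-H sites of
one species, the lowest reaction free energy marks the kinetically
preferred site, so no transition states are needed for f-HAT.

``dpph_partner_from_offset`` builds an effective DPPH/DPPH-H partner whose
(G_adduct - G_radical) difference is calibrated so that per-site f-HAT
free energies equal BDE - offset; the 72.2 kcal/mol default offset is
empirical from the packaged reference tables (the partner's absolute
thermochemistry is never printed).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping

from .exceptions import ConfigurationError, ValidationError
from .species_store import canonical_site_sort_key

logger = logging.getLogger(__name__)

#: Empirical (G_RH - G_R.) calibration for the packaged DPPH tables:
#: dG_fHAT(site) = BDE(site) - 72.2 kcal/mol on the printed water data.
DPPH_FHAT_OFFSET_KCAL = 72.2


class Mechanism(str, Enum):
    FHAT = "fhat"
    SET = "set"
    PROTON_LOSS = "proton_loss"


@dataclass(frozen=True)
class RadicalPartner:
    """Thermochemistry of the scavenged radical, as far as it is known.

    Only the fields needed by the requested mechanism must be present:
    f-HAT needs ``gibbs_radical`` and ``gibbs_h_adduct``; SET needs
    ``gibbs_radical`` and ``gibbs_reduced``.
    """

    name: str
    gibbs_radical: float | None = None
    gibbs_h_adduct: float | None = None
    gibbs_reduced: float | None = None


@dataclass(frozen=True)
class MechanismThermo:
    """Reaction free energies of one mechanism for one species."""

    species_label: str
    partner: RadicalPartner
    mechanism: Mechanism
    dg_by_site: dict[str, float]

    @property
    def dg(self) -> float:
        """Scalar dG for site-independent mechanisms (SET)."""
        if len(self.dg_by_site) != 1:
            raise ValidationError(
                f"{self.species_label}: mechanism {self.mechanism} is site-resolved"
            )
        return next(iter(self.dg_by_site.values()))


def dpph_partner_from_offset(
    offset: float = DPPH_FHAT_OFFSET_KCAL,
) -> RadicalPartner:
    """Effective DPPH partner with (G_adduct - G_radical) = -offset."""
    return RadicalPartner(name="DPPH", gibbs_radical=0.0, gibbs_h_adduct=-offset)


def fhat_gibbs(
    antiox_g: float,
    antiox_radical_g_by_site: Mapping[str, float | None],
    partner: RadicalPartner,
) -> dict[str, float]:
    """Per-site f-HAT reaction free energies.

    dG(site) = G(ArO·, site) + G(RH) - G(ArOH) - G(R·).  Sites without a
    radical free energy are omitted with a warning.
    """
    if partner.gibbs_radical is None or partner.gibbs_h_adduct is None:
        raise ValidationError(
            f"partner {partner.name!r} lacks gibbs_radical/gibbs_h_adduct"
        )
    out: dict[str, float] = {}
    for site, g_rad in antiox_radical_g_by_site.items():
        if g_rad is None or not math.isfinite(g_rad):
            logger.warning("f-HAT: site %s has no radical energy; omitted", site)
            continue
        out[site] = (
            g_rad + partner.gibbs_h_adduct - antiox_g - partner.gibbs_radical
        )
    return out


def set_gibbs(
    antiox_g: float,
    antiox_oxidized_g: float | None,
    partner: RadicalPartner,
    species_label: str = "species",
) -> float:
    """SET reaction free energy:
    dG = G(ArOH·+) + G(R−) - G(ArOH) - G(R·)."""
    if partner.gibbs_radical is None or partner.gibbs_reduced is None:
        raise ValidationError(
            f"partner {partner.name!r} lacks gibbs_radical/gibbs_reduced"
        )
    if antiox_oxidized_g is None:
        raise ValidationError(
            f"missing oxidized-species record for {species_label}"
        )
    return (
        antiox_oxidized_g
        + partner.gibbs_reduced
        - antiox_g
        - partner.gibbs_radical
    )


def proton_loss_gibbs(
    antiox_g: float,
    antiox_deprotonated_g: float,
    proton_solvation_g: float | None,
) -> float:
    """Proton-affinity step of SPLET:
    dG = G(ArO−) + G(H+, solv) - G(ArOH)."""
    if proton_solvation_g is None:
        raise ConfigurationError(
            "proton_solvation_g must be supplied (configuration constant)"
        )
    return antiox_deprotonated_g + proton_solvation_g - antiox_g


def bep_preferred_site(dg_by_site: Mapping[str, float]) -> str:
    """Bell-Evans-Polanyi pick: argmin dG, canonical-order tie-break."""
    if not dg_by_site:
        raise ValidationError("empty dG map")
    return min(
        dg_by_site,
        key=lambda s: (dg_by_site[s], canonical_site_sort_key(s)),
    )
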