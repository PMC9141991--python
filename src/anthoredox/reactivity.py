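"""Intrinsic reactivity indices and the eH-DAMA.

BDE (O-H bond dissociation enthalpy) proxies f-HAT feasibility; adiabatic
IP proxies electron donation.  The conceptual-DFT indices are computed
from *vertical* gaps:

    mu    = -(vIP + vEA) / 2        (chemical potential)
    eta   =  (vIP - vEA) / 2        (chemical hardness)
    omega =  mu**2 / (2 * eta)      (electrophilicity index)

omega depends on IP nonlinearly, with a Marcus-parabola-like shape, which
makes it a better single-number descriptor of electron-transfer proclivity
than raw IP for strongly reducing polyanions that sit in the inverted
region.  All indices are unit-homogeneous with their inputs (kcal/mol
throughout this package); mixing eV and kcal/mol inputs is the caller's
bug and is guarded only by the eta > 0 precondition.

The eH-DAMA (electron and Hydrogen Donating Ability Map of Antioxidants)
places each species at (min-site BDE, omega): low on both axes — the
bottom-left corner — marks a species that donates both H atoms and
electrons readily.  Axis assignment is configurable.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ConsistencyError, GeometryError, ValidationError
from .species_store import SpeciesRecord, canonical_site_sort_key

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-site BDE map plus global indices for one species."""

    species: SpeciesRecord | None
    label: str
    bde_by_site: dict[str, float] = field(default_factory=dict)
    adiabatic_ip: float | None = None
    vertical_ip: float | None = None
    vertical_ea: float | None = None
    chemical_potential: float | None = None
    hardness: float | None = None
    electrophilicity: float | None = None

    @property
    def min_bde(self) -> float | None:
        if not self.bde_by_site:
            return None
        return min(self.bde_by_site.values())


@dataclass(frozen=True)
class EhDamaPoint:
    """One point of the donating-ability map."""

    label: str
    min_bde: float
    electrophilicity: float
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.min_bde) and math.isfinite(self.electrophilicity)):
            raise ValidationError(f"{self.label}: non-finite eH-DAMA coordinates")


def bde(
    parent_enthalpy: float,
    radical_enthalpy: float,
    h_atom_enthalpy: float,
    *,
    parent_solvent: str | None = None,
    radical_solvent: str | None = None,
) -> float:
    """O-H bond dissociation enthalpy: H(radical) + H(H·) - H(parent)."""
    if parent_solvent is not None and radical_solvent is not None:
        if parent_solvent != radical_solvent:
            raise ConsistencyError(
                f"parent ({parent_solvent}) and radical ({radical_solvent}) "
                "enthalpies are from different solvents"
            )
    for name, v in (
        ("parent_enthalpy", parent_enthalpy),
        ("radical_enthalpy", radical_enthalpy),
        ("h_atom_enthalpy", h_atom_enthalpy),
    ):
        if not math.isfinite(v):
            raise ValidationError(f"{name} is not finite: {v}")
    return radical_enthalpy + h_atom_enthalpy - parent_enthalpy


def adiabatic_ip(neutral_energy: float, oxidized_energy: float) -> float:
    """Adiabatic ionization potential from two relaxed-geometry energies."""
    if not (math.isfinite(neutral_energy) and math.isfinite(oxidized_energy)):
        raise ValidationError("adiabatic_ip requires finite energies")
    return oxidized_energy - neutral_energy


def conceptual_dft_indices(
    vertical_ip: float, vertical_ea: float
) -> tuple[float, float, float]:
    """(mu, eta, omega) from vertical IP/EA, in the input unit.

    Raises when vIP <= vEA: hardness would be non-positive and omega
    undefined (this is also the symptom of mixed-unit inputs).
    """
    if not vertical_ip > vertical_ea:
        raise ValidationError(
            f"vertical_ip ({vertical_ip}) must exceed vertical_ea "
            f"({vertical_ea}); hardness would be <= 0"
        )
    mu = -(vertical_ip + vertical_ea) / 2.0
    eta = (vertical_ip - vertical_ea) / 2.0
    omega = mu * mu / (2.0 * eta)
    return mu, eta, omega


def ring_dihedral(p1, p2, p3, p4) -> float:
    """Unsigned torsion angle of four points, degrees in [0, 180].

    Used for the B-C inter-ring dihedral Phi that controls pi
    delocalization between rings; reported unsigned to match convention.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2))
    return abs(math.degrees(math.atan2(y, x)))


def signed_ring_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion in (-180, 180]; antisymmetric under point reversal."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("three consecutive points are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2 / np.linalg.norm(b2)), n2))
    return math.degrees(math.atan2(y, x))


def preferred_homolysis_site(bde_by_site: dict[str, float]) -> str:
    """Site with the lowest BDE; ties broken by canonical site order."""
    if not bde_by_site:
        raise ValidationError("empty BDE map")
    return min(
        bde_by_site,
        key=lambda s: (bde_by_site[s], canonical_site_sort_key(s)),
    )


def profile_from_energies(
    species: SpeciesRecord,
    label: str,
    bde_by_site: dict[str, float] | None = None,
    adiabatic_ip_value: float | None = None,
) -> ReactivityProfile:
    """Assemble a ReactivityProfile, deriving mu/eta/omega when the species
    record carries vertical energies."""
    mu = eta = omega = None
    if species.vertical_ip is not None and species.vertical_ea is not None:
        mu, eta, omega = conceptual_dft_indices(
            species.vertical_ip, species.vertical_ea
        )
    return ReactivityProfile(
        species=species,
        label=label,
        bde_by_site=dict(bde_by_site or {}),
        adiabatic_ip=adiabatic_ip_value,
        vertical_ip=species.vertical_ip,
        vertical_ea=species.vertical_ea,
        chemical_potential=mu,
        hardness=eta,
        electrophilicity=omega,
    )


def build_eh_dama(
    profiles: Iterable[ReactivityProfile],
    references: Sequence[EhDamaPoint] = (),
) -> tuple[list[EhDamaPoint], list[str]]:
    """eH-DAMA points plus a ranking (best antioxidant candidates first).

    One point per species at (min over unblocked sites of BDE, omega).
    Profiles lacking either coordinate (all sites blocked, or no vertical
    energies) are skipped with a warning.  Ranking sums the fractional
    rank (quantile) of each coordinate over all points — low on both axes
    ranks first — with lexicographic (omega, min_bde) tie-breaking.
    Reference antioxidants (Trolox, BHT, ascorbic acid, ...) enter as
    user-supplied data flagged ``is_reference``.
    """
    points: list[EhDamaPoint] = []
    for prof in profiles:
        if not prof.bde_by_site:
            logger.warning("eH-DAMA: %s has no unblocked sites; skipped", prof.label)
            continue
        if prof.electrophilicity is None:
            logger.warning(
                "eH-DAMA: %s lacks vertical energies (omega undefined); skipped",
                prof.label,
            )
            continue
        points.append(
            EhDamaPoint(
                label=prof.label,
                min_bde=prof.min_bde,
                electrophilicity=prof.electrophilicity,
            )
        )
    all_points = points + list(references)
    if not all_points:
        return [], []

    omegas = np.array([p.electrophilicity for p in all_points])
    bdes = np.array([p.min_bde for p in all_points])

    def quantile(values: np.ndarray) -> np.ndarray:
        order = values.argsort(kind="stable")
        ranks = np.empty(len(values))
        ranks[order] = np.arange(len(values))
        return ranks / max(len(values) - 1, 1)

    score = quantile(omegas) + quantile(bdes)
    ranked = sorted(
        range(len(all_points)),
        key=lambda i: (
            score[i],
            all_points[i].electrophilicity,
            all_points[i].min_bde,
        ),
    )
    ranking = [all_points[i].label for i in ranked]
    return all_points, ranking
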