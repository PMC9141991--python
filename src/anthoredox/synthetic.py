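"""Synthetic data generators for end-to-end testing without any download.

The generators emit inputs with the *structural* properties the analysis
assumes rather than attempting chemical realism:

* compounds have strictly increasing pKa ladders (3-6 acidic sites);
* per-site O-H BDEs carry a distinguished minimum and drop strictly with
  each deprotonation, as do vertical ionization potentials — the trend
  the real tables show;
* emitted energies are internally consistent: applying the BDE operation
  to the emitted parent/radical enthalpies reproduces the emitted BDE map
  to round-off;
* dose-response curves cross 50% exactly at a known true IC50 before
  noise, so estimator recovery can be scored against truth.

All randomness flows through ``numpy.random.default_rng(seed)`` (the
PCG64 generator, whose stream is stable across platforms for a fixed
seed), so every generated dataset is reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .kinetics import marcus_barrier
from .speciation import AcidBaseLadder
from .species_store import CANONICAL_SITE_ORDER, SiteThermo, SpeciesRecord


@dataclass(frozen=True)
class SyntheticCompoundParams:
    """Hyperparameters of the species-set generator.

    Distribution bounds are chosen to *cover* the value ranges of real
    anthocyanin tables (pKa 3-14, BDE 60-90 kcal/mol, IP 70-160
    kcal/mol), not to fit them.
    """

    n_acidic_sites: int = 5
    pka_start: tuple[float, float] = (3.0, 5.5)  # Uniform bounds
    pka_gap: tuple[float, float] = (0.5, 3.0)  # Uniform bounds, per step
    bde_base: tuple[float, float] = (78.0, 4.0)  # Normal(mean, sd)
    bde_site_spread: tuple[float, float] = (2.0, 10.0)
    bde_drop_per_deprotonation: tuple[float, float] = (2.0, 8.0)
    ip_base: tuple[float, float] = (150.0, 5.0)  # Normal(mean, sd)
    ip_drop_per_deprotonation: tuple[float, float] = (8.0, 25.0)
    h_atom_enthalpy: float = -313.9  # kcal/mol reference for the cycle
    glycosylated: bool = False  # block the C3 site when True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 3 <= self.n_acidic_sites <= 6:
            raise ValidationError(
                f"n_acidic_sites must be 3-6, got {self.n_acidic_sites}"
            )


@dataclass(frozen=True)
class SyntheticSpeciesSet:
    """Everything one generated compound produces."""

    compound_id: str
    ladder: AcidBaseLadder
    records: tuple[SpeciesRecord, ...]
    site_thermo: tuple[SiteThermo, ...]
    bde_maps: dict[str, dict[str, float]]  # state tag -> site -> BDE
    h_atom_enthalpy: float


def gen_species_set(params: SyntheticCompoundParams) -> SyntheticSpeciesSet:
    """Generate one compound: ladder, species records, site radicals.

    Deterministic for a given seed.  The parent enthalpy of each
    deprotonation state and the radical enthalpy of each open site are
    chosen so that radical + H-atom - parent reproduces the generated
    per-site BDE exactly, and both BDE and vertical IP decrease strictly
    with the deprotonation index.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_acidic_sites
    sites = list(CANONICAL_SITE_ORDER[:n])
    blocked = ["C3"] if params.glycosylated else []

    pka0 = rng.uniform(*params.pka_start)
    gaps = rng.uniform(*params.pka_gap, size=n - 1)
    pka = pka0 + np.concatenate([[0.0], np.cumsum(gaps)])
    compound_id = f"synthetic-{params.seed}"
    ladder = AcidBaseLadder(compound_id=compound_id, pka=tuple(pka))

    bde_base = rng.normal(*params.bde_base)
    spread = rng.uniform(*params.bde_site_spread)
    site_offsets = rng.uniform(0.0, spread, size=n)
    site_offsets[rng.integers(n)] = 0.0  # distinguished minimum site
    drops = rng.uniform(*params.bde_drop_per_deprotonation, size=n)
    ip_base = rng.normal(*params.ip_base)
    ip_drops = rng.uniform(*params.ip_drop_per_deprotonation, size=n)
    hardness = rng.uniform(40.0, 70.0)

    records: list[SpeciesRecord] = []
    thermo: list[SiteThermo] = []
    bde_maps: dict[str, dict[str, float]] = {}
    parent_h = -1000.0 * (1.0 + rng.uniform())  # arbitrary absolute scale
    for state_idx, tag in enumerate(ladder.labels):
        vip = ip_base - float(np.sum(ip_drops[:state_idx]))
        record = SpeciesRecord(
            compound_id=compound_id,
            deprotonation_index=state_idx,
            charge=1 - state_idx,
            solvent="water",
            enthalpy=parent_h - 5.0 * state_idx,
            gibbs_energy=parent_h - 5.0 * state_idx - rng.uniform(5, 15),
            vertical_ip=vip,
            vertical_ea=vip - 2.0 * hardness,
            site_labels=list(sites),
            glycosylated_sites=list(blocked),
        )
        records.append(record)
        bde_map: dict[str, float] = {}
        for j, site in enumerate(sites):
            if site in blocked:
                thermo.append(SiteThermo(species=record, site=site, blocked=True))
                continue
            if j < state_idx:
                continue  # already deprotonated in this macro-state
            bde_value = (
                bde_base + float(site_offsets[j]) - float(np.sum(drops[:state_idx]))
            )
            bde_map[site] = bde_value
            thermo.append(
                SiteThermo(
                    species=record,
                    site=site,
                    radical_enthalpy=bde_value
                    - params.h_atom_enthalpy
                    + record.enthalpy,
                )
            )
        if bde_map:
            bde_maps[tag] = bde_map

    return SyntheticSpeciesSet(
        compound_id=compound_id,
        ladder=ladder,
        records=tuple(records),
        site_thermo=tuple(thermo),
        bde_maps=bde_maps,
        h_atom_enthalpy=params.h_atom_enthalpy,
    )


@dataclass(frozen=True)
class SyntheticAssayParams:
    """Hyperparameters of the dose-response generator."""

    true_ic50: float = 3.0  # µM
    hill_slope_linear: float = 12.0  # %/µM
    noise_sd: float = 2.0  # % (Gaussian, independent per point)
    n_concentrations: int = 6
    concentration_range: tuple[float, float] = (0.5, 6.0)  # µM
    extrapolate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if self.n_concentrations < 2:
            raise ValidationError("need at least two concentrations")
        lo, hi = self.concentration_range
        if not lo < hi:
            raise ValidationError("empty concentration range")
        if not self.extrapolate and not lo <= self.true_ic50 <= hi:
            raise ValidationError(
                f"concentration range {self.concentration_range} does not "
                f"span true_ic50={self.true_ic50} "
                "(set extrapolate=True to allow)"
            )


def gen_assay_curves(params: SyntheticAssayParams) -> pd.DataFrame:
    """Synthetic inhibition-vs-concentration table with known truth.

    Noise-free responses are linear, crossing 50% exactly at
    ``true_ic50``; Gaussian noise of ``noise_sd`` percent is then added.
    The table also carries the fluorescence triple that reproduces each
    response through the inhibition formula (blank 1.0, control 0.2), so
    the full readout -> response -> IC50 chain can be exercised.
    """
    rng = np.random.default_rng(params.seed)
    conc = np.linspace(*params.concentration_range, params.n_concentrations)
    clean = 50.0 + params.hill_slope_linear * (conc - params.true_ic50)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=conc.size)
    f_blank, f_control = 1.0, 0.2
    f_sample = f_control + noisy / 100.0 * (f_blank - f_control)
    return pd.DataFrame(
        {
            "concentration_um": conc,
            "response_percent": noisy,
            "response_percent_clean": clean,
            "f_sample": f_sample,
            "f_control": f_control,
            "f_blank": f_blank,
        }
    )


def gen_kinetics_grid(
    lambda_range: tuple[float, float] = (10.0, 60.0),
    n_lambda: int = 5,
    n_dg: int = 81,
) -> pd.DataFrame:
    """Marcus test grid covering both parabola branches.

    For each reorganization energy lambda in the range, dG spans
    [-2*lambda, +lambda] so the normal region, the barrierless apex and
    the inverted region are all exercised; the barrier column is the
    closed-form Marcus value.
    """
    lo, hi = lambda_range
    if not (lo > 0 and lo < hi):
        raise ValidationError(f"invalid lambda range {lambda_range}")
    if n_lambda < 1 or n_dg < 3:
        raise ValidationError("grid too small")
    rows = []
    for lam in np.linspace(lo, hi, n_lambda):
        for dg in np.linspace(-2.0 * lam, lam, n_dg):
            rows.append(
                {
                    "lambda_reorg": lam,
                    "dg_set": dg,
                    "barrier": marcus_barrier(dg, lam),
                }
            )
    return pd.DataFrame(rows)
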