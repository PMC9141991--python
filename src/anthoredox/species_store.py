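"""Species interchange model and packaged reference tables.

A *species* is one protonation/charge macro-state of one compound in one
solvent, together with whatever thermochemical scalars a quantum-chemistry
post-processing run produced for it.  Internal energy unit is kcal/mol
everywhere; hartree and eV are accepted on input via an explicit ``unit``
tag.  Deprotonation is tracked as a macro-state index only (0 = fully
protonated flavylium cation); site-resolved microstates are out of scope.

The module also ships, as versioned package data, the printed reference
tables for the six anthocyan(id)ins studied here (pKa ladders and molar
fractions, per-site O-H bond dissociation enthalpies and adiabatic
ionization potentials, f-HAT reaction free energies against DPPH, SET
activation energies and rate constants, and the experimental IC50 set).
Cells whose provenance is typographically ambiguous carry a ``confidence``
flag; cells that are demonstrably inconsistent with the rest of their table
are flagged anomalous rather than silently corrected.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .exceptions import (
    DuplicateKeyError,
    SchemaError,
    ValidationError,
)

#: CODATA conversion used for hartree-tagged inputs.
HARTREE_TO_KCAL = 627.5095
EV_TO_KCAL = 23.060548

SOLVENTS = ("water", "pentyl_ethanoate")

#: Canonical O-H site order used for tie-breaking throughout the package.
CANONICAL_SITE_ORDER = ("C3", "C3p", "C4p", "C5", "C5p", "C7")

#: ASCII-safe site labels -> display form with primes.
SITE_DISPLAY = {"C3p": "C3′", "C4p": "C4′", "C5p": "C5′"}

_ENERGY_FIELDS = (
    "gibbs_energy",
    "enthalpy",
    "electronic_energy",
    "vertical_ip",
    "vertical_ea",
)

_REQUIRED_COLUMNS = ("compound_id", "deprotonation_index", "charge", "solvent")

_UNIT_FACTORS = {"kcal/mol": 1.0, "kcal": 1.0, "hartree": HARTREE_TO_KCAL, "ev": EV_TO_KCAL}


@dataclass
class SpeciesRecord:
    """One protonation/charge state of one compound in one solvent.

    Energies are stored in kcal/mol.  ``deprotonation_index`` 0 is the
    fully protonated flavylium cation; for these compounds the charge is
    ``+1 - deprotonation_index`` but is stored explicitly.
    """

    compound_id: str
    deprotonation_index: int
    charge: int
    solvent: str
    gibbs_energy: float | None = None
    enthalpy: float | None = None
    electronic_energy: float | None = None
    vertical_ip: float | None = None
    vertical_ea: float | None = None
    site_labels: list[str] = field(default_factory=list)
    glycosylated_sites: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.deprotonation_index < 0:
            raise ValidationError(
                f"{self.compound_id}: deprotonation_index must be >= 0"
            )
        if self.solvent not in SOLVENTS:
            raise ValidationError(
                f"{self.compound_id}: unknown solvent {self.solvent!r}; "
                f"expected one of {SOLVENTS}"
            )
        if all(
            getattr(self, f) is None
            for f in ("gibbs_energy", "enthalpy", "electronic_energy")
        ):
            raise ValidationError(
                f"{self.compound_id} (n={self.deprotonation_index}): at least one "
                "of gibbs_energy/enthalpy/electronic_energy is required"
            )
        if len(set(self.site_labels)) != len(self.site_labels):
            raise ValidationError(
                f"{self.compound_id}: duplicate site labels {self.site_labels}"
            )
        if self.site_labels and self.deprotonation_index > len(self.site_labels):
            raise ValidationError(
                f"{self.compound_id}: deprotonation_index "
                f"{self.deprotonation_index} exceeds the {len(self.site_labels)} "
                "acidic sites"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.compound_id, self.deprotonation_index, self.solvent)


@dataclass
class SiteThermo:
    """Radical (O-H homolysis product) thermochemistry for one site."""

    species: SpeciesRecord
    site: str
    radical_enthalpy: float | None = None
    radical_gibbs: float | None = None
    blocked: bool = False

    def __post_init__(self) -> None:
        if self.species.site_labels and self.site not in self.species.site_labels:
            raise ValidationError(
                f"site {self.site!r} not among {self.species.compound_id} "
                f"labels {self.species.site_labels}"
            )
        if self.blocked and (
            self.radical_enthalpy is not None or self.radical_gibbs is not None
        ):
            raise ValidationError(
                f"{self.species.compound_id}/{self.site}: blocked (glycosylated) "
                "sites carry no radical thermochemistry"
            )


def display_site(site: str) -> str:
    """Render an ASCII site label with its prime, e.g. ``C4p`` -> ``C4′``."""
    return SITE_DISPLAY.get(site, site)


def canonical_site_sort_key(site: str):
    """Sort key placing known sites in canonical order, unknowns after."""
    try:
        return (0, CANONICAL_SITE_ORDER.index(site))
    except ValueError:
        return (1, site)


# ---------------------------------------------------------------------------
# interchange I/O

def _coerce_record(row: dict, origin: str) -> SpeciesRecord:
    missing = [c for c in _REQUIRED_COLUMNS if row.get(c) in (None, "")]
    if missing:
        raise SchemaError(f"{origin}: missing required column(s) {missing}")
    unit = str(row.get("unit", "kcal/mol") or "kcal/mol").lower()
    if unit not in _UNIT_FACTORS:
        raise ValidationError(
            f"{origin}: unknown unit {unit!r}; expected one of "
            f"{sorted(_UNIT_FACTORS)}"
        )
    factor = _UNIT_FACTORS[unit]

    def energy(name: str) -> float | None:
        raw = row.get(name)
        if raw is None or raw == "":
            return None
        return float(raw) * factor

    def listed(name: str) -> list[str]:
        raw = row.get(name)
        if raw is None or raw == "":
            return []
        if isinstance(raw, list):
            return [str(x) for x in raw]
        return [tok for tok in str(raw).split(";") if tok]

    known = set(_REQUIRED_COLUMNS) | set(_ENERGY_FIELDS) | {
        "unit", "site_labels", "glycosylated_sites"
    }
    metadata = {k: v for k, v in row.items() if k not in known}
    return SpeciesRecord(
        compound_id=str(row["compound_id"]),
        deprotonation_index=int(row["deprotonation_index"]),
        charge=int(row["charge"]),
        solvent=str(row["solvent"]),
        gibbs_energy=energy("gibbs_energy"),
        enthalpy=energy("enthalpy"),
        electronic_energy=energy("electronic_energy"),
        vertical_ip=energy("vertical_ip"),
        vertical_ea=energy("vertical_ea"),
        site_labels=listed("site_labels"),
        glycosylated_sites=listed("glycosylated_sites"),
        metadata=metadata,
    )


def load_species(path: str | Path, format: str | None = None) -> list[SpeciesRecord]:
    """Read species records from a CSV or JSON interchange file.

    The CSV header carries the documented columns plus an optional ``unit``
    column (``kcal/mol`` default, ``hartree`` and ``ev`` converted on load);
    unknown columns are preserved in ``record.metadata``.  JSON is a list of
    objects with the same fields.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format not in ("csv", "json"):
        raise ValidationError(f"unknown interchange format {format!r}")

    if format == "json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list):
            raise SchemaError(f"{path}: expected a JSON array of records")
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise SchemaError(f"{path}: empty CSV")
            missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise SchemaError(f"{path}: missing required column(s) {missing}")
            rows = list(reader)

    records: list[SpeciesRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(rows):
        rec = _coerce_record(dict(row), origin=f"{path}:{i}")
        if rec.key in seen:
            raise DuplicateKeyError(
                f"{path}: duplicate species key {rec.key}"
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def write_species(
    records: Iterable[SpeciesRecord], path: str | Path, format: str | None = None
) -> Path:
    """Write species records to CSV or JSON (kcal/mol, round-trip safe)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    records = list(records)
    if format == "json":
        rows = []
        for rec in records:
            row = asdict(rec)
            meta = row.pop("metadata")
            row.update(meta)
            row["unit"] = "kcal/mol"
            rows.append(row)
        path.write_text(json.dumps(rows, indent=1))
        return path

    meta_cols = sorted({k for rec in records for k in rec.metadata})
    cols = list(_REQUIRED_COLUMNS) + ["unit"] + list(_ENERGY_FIELDS) + [
        "site_labels", "glycosylated_sites",
    ] + meta_cols
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for rec in records:
            row = {
                "compound_id": rec.compound_id,
                "deprotonation_index": rec.deprotonation_index,
                "charge": rec.charge,
                "solvent": rec.solvent,
                "unit": "kcal/mol",
                "site_labels": ";".join(rec.site_labels),
                "glycosylated_sites": ";".join(rec.glycosylated_sites),
            }
            for f in _ENERGY_FIELDS:
                v = getattr(rec, f)
                row[f] = "" if v is None else repr(v)
            row.update(rec.metadata)
            writer.writerow(row)
    return path


# ---------------------------------------------------------------------------
# packaged reference tables


@dataclass(frozen=True)
class TableCell:
    """One fixture cell with provenance and a confidence flag."""

    compound: str
    state: str
    site: str | None
    value: float
    table: str
    confidence: str = "high"
    anomalous: bool = False


@dataclass(frozen=True)
class KineticsCell:
    """One SET activation energy / rate constant pair."""

    compound: str
    state: str
    barrier: float
    k: float
    table: str = "table5"
    anomalous: bool = False


@dataclass(frozen=True)
class FixtureSet:
    """All packaged reference tables, normalised on load.

    Energies in kcal/mol, fractions in percent, concentrations in µM,
    rates in M⁻¹s⁻¹.  ``anomalies`` records the printed cells that
    disagree with their own table's internal logic (kept verbatim,
    flagged, never corrected).
    """

    pka_table: dict[str, list[float]]
    fractions_table: dict[tuple[str, str], float]
    bde_ip_table: tuple[TableCell, ...]
    fhat_gibbs_table: tuple[TableCell, ...]
    set_kinetics_table: dict[tuple[str, str], KineticsCell]
    ic50_table: dict[str, float]
    ec50_reference: float
    blocked_sites: dict[str, list[str]]
    dihedral_pentyl_deg: dict[str, float]
    anomalies: tuple[dict, ...]
    version: str

    def bde_map(
        self,
        compound: str,
        state: str,
        solvent: str = "water",
        min_confidence: str = "low",
    ) -> dict[str, float]:
        """Per-site BDE map for one species; filter by confidence level."""
        levels = {"low": 0, "medium": 1, "high": 2}
        floor = levels[min_confidence]
        return {
            c.site: c.value
            for c in self.bde_ip_table
            if c.compound == compound
            and c.state == state
            and c.table == f"table3:{solvent}:bde"
            and levels[c.confidence] >= floor
        }

    def adiabatic_ip_of(
        self, compound: str, state: str, solvent: str = "water"
    ) -> float | None:
        for c in self.bde_ip_table:
            if (
                c.compound == compound
                and c.state == state
                and c.table == f"table3:{solvent}:ip"
            ):
                return c.value
        return None

    def fhat_map(
        self, compound: str, state: str, min_confidence: str = "low"
    ) -> dict[str, float]:
        levels = {"low": 0, "medium": 1, "high": 2}
        floor = levels[min_confidence]
        return {
            c.site: c.value
            for c in self.fhat_gibbs_table
            if c.compound == compound
            and c.state == state
            and levels[c.confidence] >= floor
        }


def load_fixtures() -> FixtureSet:
    """Load the packaged reference tables (versioned JSON)."""
    text = resources.files("anthoredox").joinpath("data/fixtures.json").read_text()
    raw = json.loads(text)

    fractions = {
        (compound, state): value
        for compound, states in raw["fractions_percent"].items()
        for state, value in states.items()
    }

    bde_ip = []
    for cell in raw["bde"]:
        bde_ip.append(
            TableCell(
                compound=cell["compound"],
                state=cell["state"],
                site=cell["site"],
                value=float(cell["value"]),
                table=f"table3:{cell['solvent']}:bde",
                confidence=cell["confidence"],
            )
        )
    for cell in raw["adiabatic_ip"]:
        bde_ip.append(
            TableCell(
                compound=cell["compound"],
                state=cell["state"],
                site=None,
                value=float(cell["value"]),
                table=f"table3:{cell['solvent']}:ip",
            )
        )

    fhat = tuple(
        TableCell(
            compound=cell["compound"],
            state=cell["state"],
            site=cell["site"],
            value=float(cell["value"]),
            table="table4",
            confidence=cell["confidence"],
        )
        for cell in raw["fhat_gibbs"]
    )

    kinetics = {
        (cell["compound"], cell["state"]): KineticsCell(
            compound=cell["compound"],
            state=cell["state"],
            barrier=float(cell["barrier"]),
            k=float(cell["k"]),
            anomalous=bool(cell["anomalous"]),
        )
        for cell in raw["set_kinetics"]
    }

    return FixtureSet(
        pka_table={k: list(map(float, v)) for k, v in raw["pka"].items()},
        fractions_table=fractions,
        bde_ip_table=tuple(bde_ip),
        fhat_gibbs_table=fhat,
        set_kinetics_table=kinetics,
        ic50_table={k: float(v) for k, v in raw["ic50_um"].items()},
        ec50_reference=float(raw["ec50_reference_um"]),
        blocked_sites={k: list(v) for k, v in raw["blocked_sites"].items()},
        dihedral_pentyl_deg={
            k: float(v) for k, v in raw["dihedral_pentyl_deg"].items()
        },
        anomalies=tuple(raw["anomalies"]),
        version=raw["version"],
    )
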