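"""CSV readers/writers, schema validation and run configuration.

All tables are plain UTF-8 CSV with a header row and "." decimal. Lines
starting with ``#`` are provenance comments and are skipped on read.
Energies may be declared per row as kcal/mol or kJ/mol; kJ values are
converted to the internal kcal/mol on ingest.

Schemas::

    species.csv:  species_id,name,identifier,ionization_class,ion_charge,trusted,notes
    solvation.csv: form_id,species_id,form_role,solvent,dg_solv,unit,source
    pka.csv:      species_id,solvent,pka,temperature,source,anchor_note,trusted
    literature_transfer.csv: solvent,method,value,unit,citation
"""

from __future__ import annotations

import csv
import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, Field

from .curation import PKaMeasurement
from .metrics import LiteratureTransferEnergy
from .thermocycle import SolvationTable, SpeciesRecord

__all__ = [
    "SchemaError",
    "RunConfig",
    "normalize_solvent",
    "read_species",
    "read_solvation",
    "read_pka",
    "read_literature",
    "read_deltas",
    "write_species",
    "write_solvation",
    "write_pka",
    "write_deltas",
]

KJ_PER_KCAL = 4.184

# common shorthand for solvent names; unrecognized names pass through verbatim
SOLVENT_ALIASES = {
    "mecn": "acetonitrile",
    "acn": "acetonitrile",
    "ch3cn": "acetonitrile",
    "meoh": "methanol",
    "etoh": "ethanol",
    "dmso": "dmso",
    "dmf": "dmf",
    "dce": "dce",
    "1,2-dichloroethane": "dce",
    "h2o": "water",
    "meno2": "nitromethane",
}

_KNOWN_SOLVENTS = {
    "water", "acetonitrile", "methanol", "ethanol", "dmso", "dmf", "dce",
    "nitromethane", "acetone", "pyridine", "formamide",
}


def normalize_solvent(name: str, warn_unknown: bool = False) -> str:
    """Lower-case, strip and resolve aliases; unknown names pass through."""
    key = name.strip().lower()
    if key in SOLVENT_ALIASES:
        return SOLVENT_ALIASES[key]
    if warn_unknown and key not in _KNOWN_SOLVENTS:
        warnings.warn(f"unrecognized solvent name {name!r}; passing through verbatim")
    return key


class SchemaError(ValueError):
    """Raised when a CSV fails validation; carries all offending lines."""

    def __init__(self, path: str | Path, problems: list[str]):
        self.path = str(path)
        self.problems = problems
        super().__init__(f"{path}: {len(problems)} schema problem(s):\n  " + "\n  ".join(problems))


class RunConfig(BaseModel):
    """Flat run configuration; unknown keys are rejected."""

    model_config = {"extra": "forbid"}

    temperature: float = Field(default=298.0, gt=0)
    energy_unit: str = Field(default="kcal_per_mol", pattern="^(kcal_per_mol|kJ_per_mol)$")
    ref_solvent: str = "water"
    r2_mode: str = Field(default="pearson_sq", pattern="^(pearson_sq|coefficient_of_determination)$")
    duplicate_tolerance: float = Field(default=0.4, ge=0)
    min_points: int = Field(default=10, ge=1)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _rows(path: str | Path, required: Sequence[str]) -> tuple[list[dict], list[str]]:
    path = Path(path)
    if not path.exists():
        raise SchemaError(path, ["file does not exist"])
    with open(path, newline="", encoding="utf-8") as fh:
        filtered = (line for line in fh if not line.lstrip().startswith("#"))
        reader = csv.DictReader(filtered)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise SchemaError(path, [f"missing column(s): {', '.join(missing)}"])
        rows = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):
            row["_line"] = lineno
            rows.append(row)
    return rows, problems


def _parse_float(row: dict, col: str, problems: list[str], required: bool = True) -> Optional[float]:
    raw = (row.get(col) or "").strip()
    if raw == "":
        if required:
            problems.append(f"line {row['_line']}: empty {col}")
        return None
    try:
        return float(raw)
    except ValueError:
        problems.append(f"line {row['_line']}: unparseable {col} value {raw!r}")
        return None


def _parse_bool(raw: str) -> bool:
    return (raw or "").strip().lower() not in {"false", "0", "no"}


def _energy_to_kcal(value: float, unit: str, row: dict, problems: list[str]) -> float:
    unit = (unit or "kcal/mol").strip().lower()
    if unit in {"kcal/mol", "kcal_per_mol", "kcal"}:
        return value
    if unit in {"kj/mol", "kj_per_mol", "kj"}:
        return value / KJ_PER_KCAL
    problems.append(f"line {row['_line']}: unknown energy unit {unit!r}")
    return value


def read_species(path: str | Path) -> tuple[list[SpeciesRecord], list[tuple[str, str]]]:
    """Read species records.

    Returns (records, rejected) where ``rejected`` lists (species_id,
    reason) for rows excluded at ingest — currently multiply-charged ion
    forms, which fall outside the single-proton transfer model.
    """
    rows, problems = _rows(path, ["species_id", "ionization_class"])
    records: list[SpeciesRecord] = []
    rejected: list[tuple[str, str]] = []
    seen: set[str] = set()
    for row in rows:
        sid = (row.get("species_id") or "").strip()
        if not sid:
            problems.append(f"line {row['_line']}: empty species_id")
            continue
        if sid in seen:
            problems.append(f"line {row['_line']}: duplicate species_id {sid!r}")
            continue
        seen.add(sid)
        charge_raw = (row.get("ion_charge") or "").strip()
        charge = 0
        if charge_raw:
            try:
                charge = int(charge_raw)
            except ValueError:
                problems.append(f"line {row['_line']}: unparseable ion_charge {charge_raw!r}")
                continue
        if abs(charge) >= 2:
            rejected.append((sid, f"multiply-charged ion form (charge {charge:+d})"))
            continue
        try:
            records.append(
                SpeciesRecord(
                    species_id=sid,
                    name=(row.get("name") or "").strip(),
                    identifier=(row.get("identifier") or "").strip() or None,
                    ionization_class=(row.get("ionization_class") or "").strip().lower(),
                    ion_charge=charge,
                    trusted=_parse_bool(row.get("trusted", "true")),
                    notes=(row.get("notes") or "").strip(),
                )
            )
        except ValueError as exc:
            problems.append(f"line {row['_line']}: {exc}")
    if problems:
        raise SchemaError(path, problems)
    return records, rejected


def read_solvation(path: str | Path) -> SolvationTable:
    rows, problems = _rows(path, ["form_id", "solvent", "dg_solv"])
    table = SolvationTable()
    seen: set[tuple[str, str]] = set()
    for row in rows:
        form = (row.get("form_id") or "").strip()
        solvent = normalize_solvent(row.get("solvent") or "")
        if not form or not solvent:
            problems.append(f"line {row['_line']}: empty form_id or solvent")
            continue
        value = _parse_float(row, "dg_solv", problems)
        if value is None:
            continue
        value = _energy_to_kcal(value, row.get("unit", ""), row, problems)
        key = (form, solvent)
        if key in seen:
            problems.append(f"line {row['_line']}: duplicate entry for form {form!r} in {solvent!r}")
            continue
        seen.add(key)
        table.add(form, solvent, value, source=(row.get("source") or "").strip())
    if problems:
        raise SchemaError(path, problems)
    return table


def read_pka(path: str | Path) -> list[PKaMeasurement]:
    rows, problems = _rows(path, ["species_id", "solvent", "pka"])
    out: list[PKaMeasurement] = []
    for row in rows:
        sid = (row.get("species_id") or "").strip()
        solvent = normalize_solvent(row.get("solvent") or "")
        if not sid or not solvent:
            problems.append(f"line {row['_line']}: empty species_id or solvent")
            continue
        pka = _parse_float(row, "pka", problems)
        if pka is None:
            continue
        temp = _parse_float(row, "temperature", problems, required=False)
        out.append(
            PKaMeasurement(
                species_id=sid,
                solvent=solvent,
                pka=pka,
                temperature=temp if temp is not None else 298.0,
                source=(row.get("source") or "").strip(),
                anchor_note=(row.get("anchor_note") or "").strip(),
                trusted=_parse_bool(row.get("trusted", "true")),
            )
        )
    if problems:
        raise SchemaError(path, problems)
    return out


def read_literature(path: str | Path) -> list[LiteratureTransferEnergy]:
    rows, problems = _rows(path, ["solvent", "method", "value"])
    out: list[LiteratureTransferEnergy] = []
    for row in rows:
        value = _parse_float(row, "value", problems, required=False)
        if value is not None:
            value = _energy_to_kcal(value, row.get("unit", ""), row, problems)
        out.append(
            LiteratureTransferEnergy(
                solvent=normalize_solvent(row.get("solvent") or ""),
                method=(row.get("method") or "").strip(),
                value=value,
                citation=(row.get("citation") or "").strip(),
            )
        )
    if problems:
        raise SchemaError(path, problems)
    return out


def read_deltas(path: str | Path) -> dict[str, float]:
    """Read a solvent -> fitted shift map from a fit-summary CSV."""
    rows, problems = _rows(path, ["solvent", "delta_kcal_mol"])
    deltas: dict[str, float] = {}
    for row in rows:
        value = _parse_float(row, "delta_kcal_mol", problems)
        if value is not None:
            deltas[normalize_solvent(row.get("solvent") or "")] = value
    if problems:
        raise SchemaError(path, problems)
    return deltas


# --- writers ---------------------------------------------------------------

def _provenance_header(config_hash: str = "") -> str:
    from . import __version__

    tail = f" config={config_hash}" if config_hash else ""
    return f"# pkashift v{__version__}{tail}\n"


def _write_csv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence], config_hash: str = "") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(_provenance_header(config_hash))
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def write_species(records: Sequence[SpeciesRecord], path: str | Path, config_hash: str = "") -> None:
    _write_csv(
        path,
        ["species_id", "name", "identifier", "ionization_class", "ion_charge", "trusted", "notes"],
        (
            [r.species_id, r.name, r.identifier or "", r.ionization_class.value,
             r.ion_charge, str(r.trusted).lower(), r.notes]
            for r in records
        ),
        config_hash,
    )


def write_solvation(
    table: SolvationTable,
    path: str | Path,
    species: Optional[Sequence[SpeciesRecord]] = None,
    config_hash: str = "",
) -> None:
    role_of: dict[str, tuple[str, str]] = {}
    for sp in species or []:
        role_of[sp.neutral_form_id] = (sp.species_id, "neutral")
        role_of[sp.ion_form_id] = (sp.species_id, "ion")
    rows = []
    for form_id, solvent, dg, source in table:
        sid, role = role_of.get(form_id, ("", ""))
        rows.append([form_id, sid, role, solvent, repr(dg), "kcal/mol", source])
    rows.sort(key=lambda r: (r[0], r[3]))
    _write_csv(path, ["form_id", "species_id", "form_role", "solvent", "dg_solv", "unit", "source"],
               rows, config_hash)


def write_pka(measurements: Sequence[PKaMeasurement], path: str | Path, config_hash: str = "") -> None:
    _write_csv(
        path,
        ["species_id", "solvent", "pka", "temperature", "source", "anchor_note", "trusted"],
        (
            [m.species_id, m.solvent, repr(m.pka), repr(m.temperature), m.source,
             m.anchor_note, str(m.trusted).lower()]
            for m in measurements
        ),
        config_hash,
    )


def write_deltas(deltas: dict[str, float], path: str | Path, config_hash: str = "") -> None:
    _write_csv(
        path,
        ["solvent", "delta_kcal_mol"],
        ([solvent, repr(value)] for solvent, value in sorted(deltas.items())),
        config_hash,
    )
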