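"""Dataset assembly and curation filters.

Turns raw measurement/species/solvation tables into fit-ready transfer
datapoints for one target solvent, applying the filters a careful
benchmark requires: multiply-charged ions are excluded (single-proton
equilibria only), species must have a measured pKa in both the reference
and the target solvent, every required solvation entry must be present,
and rows flagged untrusted by the caller are dropped. Duplicate
measurements of the same (species, solvent) are averaged when they agree
within a tolerance and discarded as conflicting otherwise — conflicts
beyond the tolerance usually signal measurements anchored to different
acidity scales, which no average can repair.

Small datasets and missing ionization classes produce warnings, not
failures: some solvents simply lack measured bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .thermocycle import (
    IonizationClass,
    SolvationTable,
    SpeciesRecord,
    TransferDatapoint,
    ddg_transfer,
)

__all__ = ["PKaMeasurement", "CurationReport", "MergeResult", "merge_duplicates", "curate"]

DEFAULT_DUPLICATE_TOLERANCE = 0.4  # pKa units


@dataclass(frozen=True)
class PKaMeasurement:
    """One experimental pKa value for a species in a solvent."""

    species_id: str
    solvent: str
    pka: float
    temperature: float = 298.0
    source: str = ""
    anchor_note: str = ""
    trusted: bool = True


@dataclass
class CurationReport:
    solvent: str
    n_in: int = 0
    n_out: int = 0
    removed: list[tuple[str, str]] = field(default_factory=list)  # (species_id, reason)
    n_acids: int = 0
    n_bases: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "solvent": self.solvent,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "removed": [list(t) for t in self.removed],
            "n_acids": self.n_acids,
            "n_bases": self.n_bases,
            "warnings": list(self.warnings),
        }


@dataclass
class MergeResult:
    """Outcome of duplicate merging; every input row is accounted for."""

    measurements: list[PKaMeasurement]
    merged: list[tuple[str, str, list[float]]] = field(default_factory=list)
    conflicts: list[tuple[str, str, list[float]]] = field(default_factory=list)

    @property
    def n_accounted(self) -> int:
        kept_singletons = len(self.measurements) - len(self.merged)
        return (
            kept_singletons
            + sum(len(v) for _, _, v in self.merged)
            + sum(len(v) for _, _, v in self.conflicts)
        )


def merge_duplicates(
    measurements: Sequence[PKaMeasurement],
    tolerance: float = DEFAULT_DUPLICATE_TOLERANCE,
) -> MergeResult:
    """Collapse duplicate (species, solvent) measurements.

    Duplicates whose full range (max - min) is within ``tolerance`` are
    replaced by their arithmetic mean with concatenated provenance; beyond
    the tolerance all copies are dropped and the conflict is logged in the
    result. Idempotent.
    """
    if tolerance < 0:
        raise ValueError(f"tolerance must be non-negative, got {tolerance}")
    groups: dict[tuple[str, str], list[PKaMeasurement]] = {}
    order: list[tuple[str, str]] = []
    for m in measurements:
        key = (m.species_id, m.solvent)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(m)

    out = MergeResult(measurements=[])
    for key in order:
        group = groups[key]
        if len(group) == 1:
            out.measurements.append(group[0])
            continue
        values = [m.pka for m in group]
        if max(values) - min(values) <= tolerance:
            mean = float(np.mean(values))
            sources = "; ".join(sorted({m.source for m in group if m.source}))
            out.measurements.append(
                PKaMeasurement(
                    species_id=key[0],
                    solvent=key[1],
                    pka=mean,
                    temperature=group[0].temperature,
                    source=sources,
                    anchor_note=group[0].anchor_note,
                    trusted=all(m.trusted for m in group),
                )
            )
            out.merged.append((key[0], key[1], values))
        else:
            out.conflicts.append((key[0], key[1], values))
    return out


def curate(
    measurements: Sequence[PKaMeasurement],
    species: Sequence[SpeciesRecord],
    solvation: SolvationTable,
    target_solvent: str,
    ref_solvent: str = "water",
    min_points: int = 10,
    require_both_classes: bool = False,
    duplicate_tolerance: float = DEFAULT_DUPLICATE_TOLERANCE,
) -> tuple[list[TransferDatapoint], CurationReport]:
    """Build fit-ready datapoints for one target solvent.

    Filters, in order: duplicate merging; untrusted species or measurements;
    multiply-charged ion forms; missing reference-solvent pKa; missing
    solvation entries for either form in either solvent. Every removal is
    recorded with a reason. Small surviving sets (< ``min_points``) and a
    missing ionization class yield warnings only.
    """
    report = CurationReport(solvent=target_solvent)
    species_by_id = {s.species_id: s for s in species}

    merge = merge_duplicates(measurements, tolerance=duplicate_tolerance)
    for sid, solv, values in merge.conflicts:
        report.warnings.append(
            f"conflicting duplicates for {sid} in {solv}: {values} (span exceeds "
            f"{duplicate_tolerance} pKa units); all dropped"
        )
    by_key = {(m.species_id, m.solvent): m for m in merge.measurements}

    candidates = [m for m in merge.measurements if m.solvent == target_solvent]
    report.n_in = len(candidates)

    datapoints: list[TransferDatapoint] = []
    for m in candidates:
        sp = species_by_id.get(m.species_id)
        if sp is None:
            report.removed.append((m.species_id, "unknown-species"))
            continue
        if not (sp.trusted and m.trusted):
            report.removed.append((m.species_id, "untrusted"))
            continue
        if abs(sp.ion_charge) >= 2:
            report.removed.append((m.species_id, "multiply-charged"))
            continue
        ref = by_key.get((m.species_id, ref_solvent))
        if ref is None:
            report.removed.append((m.species_id, f"missing-reference-pka:{ref_solvent}"))
            continue
        missing = [
            f"{form}@{solv}"
            for form in (sp.neutral_form_id, sp.ion_form_id)
            for solv in (target_solvent, ref_solvent)
            if not solvation.has(form, solv)
        ]
        if missing:
            report.removed.append((m.species_id, "missing-solvation:" + ",".join(missing)))
            continue
        datapoints.append(
            TransferDatapoint(
                species_id=m.species_id,
                ref_solvent=ref_solvent,
                target_solvent=target_solvent,
                pka_ref=ref.pka,
                pka_target_exp=m.pka,
                ddg_neutral=ddg_transfer(sp.neutral_form_id, target_solvent, ref_solvent, solvation),
                ddg_ion=ddg_transfer(sp.ion_form_id, target_solvent, ref_solvent, solvation),
                ionization_class=sp.ionization_class,
            )
        )

    report.n_out = len(datapoints)
    report.n_acids = sum(
        dp.ionization_class is IonizationClass.ACID for dp in datapoints
    )
    report.n_bases = report.n_out - report.n_acids
    if report.n_out < min_points:
        report.warnings.append(
            f"only {report.n_out} datapoints in {target_solvent} (min_points={min_points}); "
            "fit may be unreliable"
        )
    if report.n_out > 0 and (report.n_acids == 0 or report.n_bases == 0):
        missing_class = "bases" if report.n_bases == 0 else "acids"
        prefix = "required class missing" if require_both_classes else "class missing"
        report.warnings.append(
            f"{prefix}: no {missing_class} among the {report.n_out} datapoints in {target_solvent}"
        )
    return datapoints, report
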