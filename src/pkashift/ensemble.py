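"""Multi-reference pKa prediction.

A species measured in several solvents admits one prediction per reference
measurement: from a reference solvent a to target b the shift uses the
difference of fitted per-solvent proton shifts (delta_b - delta_a, the
anchor solvent's shift being zero by definition) together with the solute
transfer energies between a and b. Combining the per-reference predictions
(unweighted mean by default, median optionally) damps noise in any single
reference measurement; the spread across references is a diagnostic for
inconsistent acidity scales or systematic solvation-model error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .thermocycle import (
    SolvationTable,
    SpeciesRecord,
    TempContext,
    TransferDatapoint,
    ddg_transfer,
    predict_pka,
)

__all__ = ["EnsemblePrediction", "predict_from_reference", "predict_ensemble"]


@dataclass
class EnsemblePrediction:
    species_id: str
    target_solvent: str
    per_reference: list[tuple[str, float]]
    combined_pka: float
    spread: float  # population SD across references, pKa units


def predict_from_reference(
    species: SpeciesRecord,
    ref_solvent: str,
    target_solvent: str,
    pka_ref: float,
    solvation: SolvationTable,
    deltas: Mapping[str, float],
    ctx: TempContext,
) -> float:
    """Predict the pKa in ``target_solvent`` from one measurement in ``ref_solvent``.

    ``deltas`` maps solvent -> fitted proton shift relative to the anchor
    (the anchor itself, water by default, has shift 0 and need not appear).
    A target equal to the reference returns the measurement unchanged.
    """
    if ref_solvent == target_solvent:
        return pka_ref
    missing = [s for s in (ref_solvent, target_solvent) if s not in deltas]
    if missing:
        raise KeyError(f"no fitted proton shift for solvent(s) {missing}")
    effective_delta = deltas[target_solvent] - deltas[ref_solvent]
    dp = TransferDatapoint(
        species_id=species.species_id,
        ref_solvent=ref_solvent,
        target_solvent=target_solvent,
        pka_ref=pka_ref,
        ddg_neutral=ddg_transfer(species.neutral_form_id, target_solvent, ref_solvent, solvation),
        ddg_ion=ddg_transfer(species.ion_form_id, target_solvent, ref_solvent, solvation),
        ionization_class=species.ionization_class,
    )
    return predict_pka(dp, effective_delta, ctx)


def predict_ensemble(
    species: SpeciesRecord,
    target_solvent: str,
    reference_measurements: Sequence[tuple[str, float]],
    solvation: SolvationTable,
    deltas: Mapping[str, float],
    ctx: TempContext,
    combine: str = "mean",
) -> EnsemblePrediction:
    """Predict from every usable reference measurement and combine.

    ``reference_measurements`` is a sequence of (solvent, measured pKa)
    pairs; a measurement in the target solvent itself is skipped (it is the
    quantity being predicted). The combined value is the unweighted mean
    (or median) of the per-reference predictions; the spread is their
    population standard deviation, zero for a single reference.
    """
    per_ref: list[tuple[str, float]] = []
    for solvent, pka in reference_measurements:
        if solvent == target_solvent:
            continue
        per_ref.append(
            (solvent, predict_from_reference(species, solvent, target_solvent, pka, solvation, deltas, ctx))
        )
    if not per_ref:
        raise ValueError(
            f"species {species.species_id!r}: no usable reference measurement for "
            f"prediction in {target_solvent!r}"
        )
    values = np.array([p for _, p in per_ref])
    if combine == "mean":
        combined = float(values.mean())
    elif combine == "median":
        combined = float(np.median(values))
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    return EnsemblePrediction(
        species_id=species.species_id,
        target_solvent=target_solvent,
        per_reference=per_ref,
        combined_pka=combined,
        spread=float(values.std()),
    )
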