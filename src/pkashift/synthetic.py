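"""Synthetic species/solvation/pKa tables with known ground truth.

The generator emulates the structure of a curated multi-solvent pKa
compilation paired with continuum-solvation free energies: a set of small
acids (neutral AH / anion A-) and bases (cation BH+ / neutral B), one
solvation free energy per form per solvent, an aqueous pKa per species,
and non-aqueous pKa values that follow the transfer relation exactly for a
known per-solvent proton shift, corrupted by configurable error terms:

- ``noise_sd``: iid Gaussian noise on the non-reference measurements,
  in pKa units (experimental scatter is reported in pKa units, so this is
  the default noise channel; an energy-noise mode perturbs the solvation
  table instead).
- ``anchor_offset``: a constant pKa offset per solvent, emulating an
  acidity scale anchored to an inconsistent reference value. In the
  noiseless limit it biases the fitted shift by exactly c * offset.
- ``ion_bias``: a systematic solvation-model error on ionic transfer free
  energies, in kcal/mol. The reported (model) ion solvation energies in
  non-reference solvents are shifted by +ion_bias while the measurements
  follow the unbiased truth. Because the anion term enters the transfer
  relation with + and the cation term with -, the induced prediction error
  is oppositely signed for acids and bases: their residual clouds separate
  by 2*ion_bias/c pKa units while a balanced fit splits the difference.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .curation import PKaMeasurement
from .thermocycle import (
    IonizationClass,
    SolvationTable,
    SpeciesRecord,
    TempContext,
    TransferDatapoint,
    ddg_transfer,
    make_temp_context,
    pka_shift,
)

__all__ = ["SimulationSpec", "SimulationResult", "simulate", "write_fixture"]

REFERENCE_SOLVENT = "water"


class SimulationSpec(BaseModel):
    """Parameters of one synthetic benchmark world.

    ``solvents`` maps solvent name to its true proton shift (kcal/mol)
    relative to water; water itself is implicit with shift 0 (an explicit
    entry must be 0). Solvation free energies are drawn per form per
    solvent from Gaussians whose (mean, sd) reflect typical magnitudes for
    small organics: about -5 kcal/mol for neutrals and -60 kcal/mol for
    singly charged ions. The exact values are irrelevant to the model
    identities being tested — only differences between solvents enter.
    """

    model_config = {"extra": "forbid"}

    n_species: int = Field(default=50, ge=1)
    acid_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    solvents: dict[str, float] = Field(
        default_factory=lambda: {"acetonitrile": 10.0, "dmso": -6.0, "methanol": -0.5}
    )
    dg_neutral_distribution: tuple[float, float] = (-5.0, 2.0)
    dg_ion_distribution: tuple[float, float] = (-60.0, 5.0)
    aqueous_pka_range: tuple[float, float] = (2.0, 12.0)
    noise_sd: float = Field(default=0.5, ge=0.0)
    noise_on: Literal["pka", "energy"] = "pka"
    anchor_offset: dict[str, float] = Field(default_factory=dict)
    ion_bias: float = 0.0
    temperature: float = Field(default=298.0, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationSpec":
        if self.solvents.get(REFERENCE_SOLVENT, 0.0) != 0.0:
            raise ValueError("solvents: water must have true shift 0 (it is the reference)")
        for name, (_, sd) in {
            "dg_neutral_distribution": self.dg_neutral_distribution,
            "dg_ion_distribution": self.dg_ion_distribution,
        }.items():
            if sd < 0:
                raise ValueError(f"{name}: sd must be non-negative")
        lo, hi = self.aqueous_pka_range
        if not lo < hi:
            raise ValueError("aqueous_pka_range: need lo < hi")
        return self


@dataclass
class SimulationResult:
    species: list[SpeciesRecord]
    solvation: SolvationTable  # the model's (possibly biased) energies
    measurements: list[PKaMeasurement]
    ground_truth: dict = field(default_factory=dict)
    ctx: TempContext = field(default_factory=make_temp_context)


def simulate(spec: SimulationSpec) -> SimulationResult:
    """Draw one synthetic world from the spec; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    ctx = make_temp_context(spec.temperature)
    solvents = [s for s in spec.solvents if s != REFERENCE_SOLVENT]
    all_solvents = [REFERENCE_SOLVENT] + solvents

    n_acids = int(round(spec.acid_fraction * spec.n_species))
    classes = [IonizationClass.ACID] * n_acids + [IonizationClass.BASE] * (spec.n_species - n_acids)

    species: list[SpeciesRecord] = []
    truth_table: SolvationTable = SolvationTable()  # unbiased energies
    model_table: SolvationTable = SolvationTable()  # what the modeler sees
    measurements: list[PKaMeasurement] = []
    true_pkas: dict[str, dict[str, float]] = {}

    mu_n, sd_n = spec.dg_neutral_distribution
    mu_i, sd_i = spec.dg_ion_distribution
    lo, hi = spec.aqueous_pka_range

    for k, cls in enumerate(classes):
        sid = f"s{k:04d}"
        sp = SpeciesRecord(
            species_id=sid,
            name=f"synthetic {cls.value} {k}",
            ionization_class=cls,
            neutral_form_id=f"{sid}.neutral",
            ion_form_id=f"{sid}.ion",
            ion_charge=-1 if cls is IonizationClass.ACID else +1,
        )
        species.append(sp)

        pka_water = float(rng.uniform(lo, hi))
        true_pkas[sid] = {REFERENCE_SOLVENT: pka_water}
        measurements.append(
            PKaMeasurement(species_id=sid, solvent=REFERENCE_SOLVENT, pka=pka_water, source="synthetic")
        )

        for solvent in all_solvents:
            dg_n = float(rng.normal(mu_n, sd_n))
            dg_i = float(rng.normal(mu_i, sd_i))
            truth_table.add(sp.neutral_form_id, solvent, dg_n, source="synthetic-truth")
            truth_table.add(sp.ion_form_id, solvent, dg_i, source="synthetic-truth")
            # model error channels: shared ion bias off-reference, optional energy noise
            dg_n_model, dg_i_model = dg_n, dg_i
            if solvent != REFERENCE_SOLVENT:
                dg_i_model += spec.ion_bias
                if spec.noise_on == "energy" and spec.noise_sd > 0:
                    dg_n_model += float(rng.normal(0.0, spec.noise_sd))
                    dg_i_model += float(rng.normal(0.0, spec.noise_sd))
            model_table.add(sp.neutral_form_id, solvent, dg_n_model, source="synthetic-model")
            model_table.add(sp.ion_form_id, solvent, dg_i_model, source="synthetic-model")

        for solvent in solvents:
            dp = TransferDatapoint(
                species_id=sid,
                ref_solvent=REFERENCE_SOLVENT,
                target_solvent=solvent,
                pka_ref=pka_water,
                ddg_neutral=ddg_transfer(sp.neutral_form_id, solvent, REFERENCE_SOLVENT, truth_table),
                ddg_ion=ddg_transfer(sp.ion_form_id, solvent, REFERENCE_SOLVENT, truth_table),
                ionization_class=cls,
            )
            pka_exact = pka_water + pka_shift(dp, spec.solvents[solvent], ctx)
            true_pkas[sid][solvent] = pka_exact
            observed = pka_exact + spec.anchor_offset.get(solvent, 0.0)
            if spec.noise_on == "pka" and spec.noise_sd > 0:
                observed += float(rng.normal(0.0, spec.noise_sd))
            measurements.append(
                PKaMeasurement(species_id=sid, solvent=solvent, pka=observed, source="synthetic")
            )

    ground_truth = {
        "spec": spec.model_dump(),
        "true_deltas": {s: spec.solvents[s] for s in solvents},
        "true_pkas": true_pkas,
        "c_kcal_mol": ctx.c,
    }
    return SimulationResult(
        species=species,
        solvation=model_table,
        measurements=measurements,
        ground_truth=ground_truth,
        ctx=ctx,
    )


def write_fixture(result: SimulationResult, directory: str | Path) -> dict[str, Path]:
    """Write the three CSV tables plus ground_truth.json; byte-stable per seed."""
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": directory / "species.csv",
        "solvation": directory / "solvation.csv",
        "pka": directory / "pka.csv",
        "ground_truth": directory / "ground_truth.json",
    }
    _io.write_species(result.species, paths["species"])
    _io.write_solvation(result.solvation, paths["pka"].with_name("solvation.csv"), species=result.species)
    _io.write_pka(result.measurements, paths["pka"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(result.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
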