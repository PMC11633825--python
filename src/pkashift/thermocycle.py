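"""Thermodynamic-cycle arithmetic for transferring pKa values between solvents.

The dissociation constant of an acid HA (or cationic acid BH+) in a target
solvent is related to its value in a reference solvent (water by default)
through the transfer free energies of every species in the equilibrium:

    acids:  pKa(S) = pKa(ref) + [dGt(H+) + dGt(A-) - dGt(AH)] / (ln10 * R * T)
    bases:  pKa(S) = pKa(ref) + [dGt(H+) - dGt(BH+) + dGt(B)] / (ln10 * R * T)

where dGt(Z) = dG_solv(Z, S) - dG_solv(Z, ref) is the transfer (solvation
free-energy difference) of species Z from the reference solvent into S.
The proton term dGt(H+) is not directly computable from a continuum
solvation model and is carried as the per-solvent shift parameter ``delta``
(see :mod:`pkashift.fitting`). Note the sign convention: the anion transfer
energy is *added* while the cation transfer energy is *subtracted*.

All energies are kcal/mol internally; temperatures are kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "GAS_CONSTANT_KCAL",
    "IonizationClass",
    "TempContext",
    "make_temp_context",
    "SpeciesRecord",
    "SolvationTable",
    "TransferDatapoint",
    "ddg_transfer",
    "pka_shift",
    "predict_pka",
]

#: Molar gas constant in kcal mol^-1 K^-1 (CODATA).
GAS_CONSTANT_KCAL = 1.98720425864083e-3


class IonizationClass(str, Enum):
    """Class of the ionization equilibrium.

    ``ACID``: neutral acid AH dissociating to anion A- (ion charge -1).
    ``BASE``: cationic acid BH+ dissociating to neutral base B (ion charge +1).
    """

    ACID = "acid"
    BASE = "base"


@dataclass(frozen=True)
class TempContext:
    """Temperature context bundling T, R and the prefactor denominator.

    Attributes
    ----------
    temperature : float
        Absolute temperature in kelvin.
    gas_constant : float
        Molar gas constant in energy-unit mol^-1 K^-1.
    c : float
        ``ln(10) * R * T`` — the denominator converting an energy into pKa
        units. At 298 K in kcal/mol, c is about 1.3636.
    """

    temperature: float
    gas_constant: float = GAS_CONSTANT_KCAL
    c: float = field(init=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature) or self.temperature <= 0:
            raise ValueError(
                f"temperature must be a positive finite value in kelvin, got {self.temperature!r}"
            )
        if not math.isfinite(self.gas_constant) or self.gas_constant <= 0:
            raise ValueError(
                f"gas_constant must be a positive finite value, got {self.gas_constant!r}"
            )
        object.__setattr__(self, "c", math.log(10.0) * self.gas_constant * self.temperature)


def make_temp_context(temperature: float = 298.0, gas_constant: float = GAS_CONSTANT_KCAL) -> TempContext:
    """Build a :class:`TempContext` for the given temperature (default 298 K)."""
    return TempContext(temperature=temperature, gas_constant=gas_constant)


@dataclass(frozen=True)
class SpeciesRecord:
    """One ionizable compound and the identities of its two protonation forms."""

    species_id: str
    name: str = ""
    identifier: Optional[str] = None  # SMILES/InChI, opaque — never interpreted
    ionization_class: IonizationClass = IonizationClass.ACID
    neutral_form_id: str = ""
    ion_form_id: str = ""
    ion_charge: int = 0
    trusted: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        cls = IonizationClass(self.ionization_class)
        object.__setattr__(self, "ionization_class", cls)
        neutral = self.neutral_form_id or f"{self.species_id}.neutral"
        ion = self.ion_form_id or f"{self.species_id}.ion"
        object.__setattr__(self, "neutral_form_id", neutral)
        object.__setattr__(self, "ion_form_id", ion)
        expected_sign = -1 if cls is IonizationClass.ACID else +1
        charge = self.ion_charge if self.ion_charge != 0 else expected_sign
        if charge * expected_sign <= 0:
            raise ValueError(
                f"species {self.species_id!r}: ionization_class {cls.value!r} requires a "
                f"{'negative' if expected_sign < 0 else 'positive'} ion_charge, got {charge}"
            )
        # |charge| >= 2 is representable but outside the single-proton model;
        # ingest and curation remove such records with an explicit reason.
        object.__setattr__(self, "ion_charge", charge)
        if self.neutral_form_id == self.ion_form_id:
            raise ValueError(
                f"species {self.species_id!r}: neutral_form_id and ion_form_id must differ"
            )


class SolvationTable:
    """Map from (species form, solvent) to a solvation free energy in kcal/mol.

    At most one entry per (form, solvent) pair; energies must be finite.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], float] = {}
        self._sources: dict[tuple[str, str], str] = {}

    def add(self, form_id: str, solvent: str, dg_solv: float, source: str = "") -> None:
        if not math.isfinite(dg_solv):
            raise ValueError(
                f"non-finite solvation energy for form {form_id!r} in {solvent!r}: {dg_solv!r}"
            )
        key = (form_id, solvent)
        if key in self._entries and self._entries[key] != dg_solv:
            raise ValueError(
                f"conflicting duplicate solvation entry for form {form_id!r} in {solvent!r}"
            )
        self._entries[key] = dg_solv
        self._sources[key] = source

    def get(self, form_id: str, solvent: str) -> float:
        try:
            return self._entries[(form_id, solvent)]
        except KeyError:
            raise KeyError(
                f"no solvation energy for form {form_id!r} in solvent {solvent!r}"
            ) from None

    def has(self, form_id: str, solvent: str) -> bool:
        return (form_id, solvent) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        for (form_id, solvent), dg in self._entries.items():
            yield form_id, solvent, dg, self._sources[(form_id, solvent)]


@dataclass
class TransferDatapoint:
    """A joined row ready for the transfer relation.

    ``ddg_neutral`` / ``ddg_ion`` are transfer free energies
    dG_solv(target) - dG_solv(ref) for the neutral and ionic forms;
    ``pka_target_exp`` is absent when the point is used for prediction
    rather than fitting.
    """

    species_id: str
    ref_solvent: str
    target_solvent: str
    pka_ref: float
    ddg_neutral: float
    ddg_ion: float
    ionization_class: IonizationClass
    pka_target_exp: Optional[float] = None

    def __post_init__(self) -> None:
        self.ionization_class = IonizationClass(self.ionization_class)
        if self.ref_solvent == self.target_solvent:
            raise ValueError(
                f"species {self.species_id!r}: ref_solvent and target_solvent are both "
                f"{self.ref_solvent!r}"
            )


def ddg_transfer(form_id: str, target_solvent: str, ref_solvent: str, table: SolvationTable) -> float:
    """Transfer free energy dG_solv(target) - dG_solv(ref) for one form, kcal/mol.

    The arbitrary reference state of the solvation energies cancels provided
    both solvents use the same convention.
    """
    return table.get(form_id, target_solvent) - table.get(form_id, ref_solvent)


def ion_energy_combination(dp: TransferDatapoint) -> float:
    """The non-proton energy combination g of the transfer relation, kcal/mol.

    Acids: g = ddg_ion - ddg_neutral (anion added, neutral acid subtracted).
    Bases: g = -ddg_ion + ddg_neutral (cation subtracted, neutral base added).
    """
    if dp.ionization_class is IonizationClass.ACID:
        return dp.ddg_ion - dp.ddg_neutral
    if dp.ionization_class is IonizationClass.BASE:
        return -dp.ddg_ion + dp.ddg_neutral
    raise ValueError(f"unknown ionization_class {dp.ionization_class!r}")


def pka_shift(dp: TransferDatapoint, delta: float, ctx: TempContext) -> float:
    """pKa shift from reference to target solvent, in pKa units.

    ``delta`` is the proton transfer free energy estimate (kcal/mol) for the
    ref -> target pair. The shift is (delta + g) / (ln10 * R * T) with g the
    class-dependent combination of solute transfer energies.
    """
    return (delta + ion_energy_combination(dp)) / ctx.c


def predict_pka(dp: TransferDatapoint, delta: float, ctx: TempContext) -> float:
    """Predicted pKa in the target solvent: pka_ref + pka_shift."""
    if dp.pka_ref is None or not math.isfinite(dp.pka_ref):
        raise ValueError(f"species {dp.species_id!r}: missing or non-finite pka_ref")
    return dp.pka_ref + pka_shift(dp, delta, ctx)
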