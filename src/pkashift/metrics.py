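"""Error statistics and reporting tables for fits and predictions."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "rmse",
    "mae",
    "r_squared",
    "LiteratureTransferEnergy",
    "summarize_fits",
    "compare_transfer_energies",
]


def rmse(residuals: Sequence[float]) -> float:
    """Root-mean-square of a residual vector."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("rmse of an empty residual vector is undefined")
    return float(np.sqrt(np.mean(r**2)))


def mae(residuals: Sequence[float]) -> float:
    """Mean absolute value of a residual vector."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("mae of an empty residual vector is undefined")
    return float(np.mean(np.abs(r)))


def r_squared(predicted: Sequence[float], experimental: Sequence[float], mode: str = "pearson_sq") -> float:
    """R-squared between predictions and experiment.

    Two common definitions are supported because parity-plot reports rarely
    state which one they use:

    - ``pearson_sq``: squared Pearson correlation coefficient. Invariant
      under any positive affine rescaling of either series; blind to a
      constant offset.
    - ``coefficient_of_determination``: 1 - SS_res / SS_tot measured about
      the parity line y = x, which penalizes systematic offsets.
    """
    p = np.asarray(predicted, dtype=float)
    e = np.asarray(experimental, dtype=float)
    if p.shape != e.shape or p.size < 2:
        raise ValueError("need two equal-length series of at least 2 points")
    if np.var(e) == 0:
        raise ValueError("experimental series has zero variance; R^2 undefined")
    if mode == "pearson_sq":
        if np.var(p) == 0:
            return 0.0
        return float(np.corrcoef(p, e)[0, 1] ** 2)
    if mode == "coefficient_of_determination":
        ss_res = float(np.sum((e - p) ** 2))
        ss_tot = float(np.sum((e - np.mean(e)) ** 2))
        return 1.0 - ss_res / ss_tot
    raise ValueError(f"unknown R^2 mode {mode!r}")


@dataclass(frozen=True)
class LiteratureTransferEnergy:
    """A published proton transfer free energy for one solvent.

    ``method`` names the extrathermodynamic assumption behind the value
    (TATB, CPA, Rossini-style regression, ...). ``value`` may be None —
    published compilations have gaps.
    """

    solvent: str
    method: str
    value: Optional[float]
    citation: str = ""

    def __post_init__(self) -> None:
        if self.value is not None and not np.isfinite(self.value):
            raise ValueError(f"non-finite literature value for {self.solvent!r}/{self.method!r}")


def summarize_fits(fits: Sequence["DeltaFit"], r2_mode: str = "pearson_sq") -> pd.DataFrame:
    """One row per solvent: delta (kcal/mol), N, RMSE, MAE, R^2 (pKa units)."""
    if len(fits) == 0:
        raise ValueError("no fits to summarize")
    rows = []
    for f in fits:
        r2 = f.r2_pearson if r2_mode == "pearson_sq" else f.r2_determination
        rows.append(
            {
                "solvent": f.target_solvent,
                "delta_kcal_mol": f.delta_hat,
                "n": f.n_points,
                "n_acids": f.n_acids,
                "n_bases": f.n_bases,
                "rmse": f.rmse,
                "mae": f.mae,
                "r2": r2,
            }
        )
    return pd.DataFrame(rows)


def compare_transfer_energies(
    fits: Sequence["DeltaFit"],
    literature: Sequence[LiteratureTransferEnergy],
) -> pd.DataFrame:
    """Fitted shifts side by side with literature proton transfer energies.

    One row per (solvent, method) with the fitted delta, the literature
    value and their difference (fitted - literature); solvents lacking a
    literature entry keep a row with empty cells so every fit is visible.
    """
    delta_by_solvent = {f.target_solvent: f.delta_hat for f in fits}
    lit_by_solvent: dict[str, list[LiteratureTransferEnergy]] = {}
    for lt in literature:
        lit_by_solvent.setdefault(lt.solvent, []).append(lt)

    rows = []
    for solvent, delta in delta_by_solvent.items():
        entries = lit_by_solvent.get(solvent)
        if not entries:
            rows.append({"solvent": solvent, "method": None, "delta_fit": delta,
                         "literature": None, "difference": None})
            continue
        for lt in entries:
            diff = None if lt.value is None else delta - lt.value
            rows.append({"solvent": solvent, "method": lt.method, "delta_fit": delta,
                         "literature": lt.value, "difference": diff})
    return pd.DataFrame(rows)
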