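"""Regression of the per-solvent proton shift delta.

For each target solvent the transfer relation leaves a single unknown: the
proton transfer free energy from the reference solvent. Treating it as a
regression parameter delta, the residual of datapoint i is

    f_i(delta) = pKa_ref,i - pKa_exp,i + (delta + g_i) / c

which is affine in delta with slope 1/c, so the least-squares optimum has
the closed form

    delta_hat = mean_i r_i,    r_i = c * (pKa_exp,i - pKa_ref,i) - g_i

i.e. the mean of the per-point delta estimates. ``fit_delta`` implements
the closed form; ``fit_delta_grid_oracle`` is an independent brute-force
check of the same objective. ``fit_joint`` generalizes to datapoints
spanning many solvent pairs by solving for all per-solvent shifts at once
with the anchor solvent's shift fixed to zero.

A robust least-absolute-deviation mode (median of r_i) is available but
non-default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .thermocycle import TempContext, TransferDatapoint, IonizationClass, ion_energy_combination, predict_pka

__all__ = [
    "ResidualTerm",
    "DeltaFit",
    "residual",
    "per_point_delta",
    "fit_delta",
    "fit_delta_grid_oracle",
    "fit_joint",
]


@dataclass(frozen=True)
class ResidualTerm:
    """Per-datapoint pieces of the delta regression.

    ``g`` is the non-delta energy combination (kcal/mol); ``r`` is the
    per-point delta estimate c*(pKa_exp - pKa_ref) - g (kcal/mol).
    """

    species_id: str
    g: float
    r: float


@dataclass
class DeltaFit:
    """Fitted shift for one (ref, target) solvent pair with residual statistics.

    ``residuals_pka`` are predicted - experimental in pKa units, evaluated at
    ``delta_hat``; their mean is zero at the least-squares optimum.
    """

    target_solvent: str
    ref_solvent: str
    delta_hat: float
    n_points: int
    n_acids: int
    n_bases: int
    residuals_pka: list[float] = field(default_factory=list)
    rmse: float = float("nan")
    mae: float = float("nan")
    r2_pearson: float = float("nan")
    r2_determination: float = float("nan")


def residual(dp: TransferDatapoint, delta: float, ctx: TempContext) -> float:
    """Fit residual predicted - experimental, pKa units; positive = overprediction."""
    if dp.pka_target_exp is None:
        raise ValueError(f"species {dp.species_id!r}: no experimental pKa in "
                         f"{dp.target_solvent!r}; cannot form a fit residual")
    return predict_pka(dp, delta, ctx) - dp.pka_target_exp


def per_point_delta(dp: TransferDatapoint, ctx: TempContext) -> ResidualTerm:
    """The single-point delta estimate r = c*(pKa_exp - pKa_ref) - g."""
    if dp.pka_target_exp is None:
        raise ValueError(f"species {dp.species_id!r}: no experimental pKa in "
                         f"{dp.target_solvent!r}")
    g = ion_energy_combination(dp)
    r = ctx.c * (dp.pka_target_exp - dp.pka_ref) - g
    return ResidualTerm(species_id=dp.species_id, g=g, r=r)


def _check_single_pair(datapoints: Sequence[TransferDatapoint]) -> tuple[str, str]:
    pairs = {(dp.ref_solvent, dp.target_solvent) for dp in datapoints}
    if len(pairs) > 1:
        raise ValueError(f"datapoints span multiple solvent pairs: {sorted(pairs)}")
    return next(iter(pairs))


def fit_delta(
    datapoints: Sequence[TransferDatapoint],
    ctx: TempContext,
    weights: Optional[Sequence[float]] = None,
    robust: bool = False,
) -> DeltaFit:
    """Least-squares fit of the proton shift for one solvent pair.

    Parameters
    ----------
    datapoints
        One or more datapoints sharing the same (ref, target) solvent pair,
        all with experimental target pKa values.
    ctx
        Temperature context.
    weights
        Optional per-point weights (default uniform).
    robust
        If true, minimize the sum of absolute residuals instead of squares
        (delta_hat becomes the weighted median of the per-point estimates).
    """
    if len(datapoints) == 0:
        raise ValueError("fit_delta requires at least one datapoint")
    ref, target = _check_single_pair(datapoints)

    terms = [per_point_delta(dp, ctx) for dp in datapoints]
    r = np.array([t.r for t in terms], dtype=float)
    if weights is None:
        w = np.ones_like(r)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != r.shape or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative, same length as datapoints, not all zero")

    if robust:
        order = np.argsort(r)
        cum = np.cumsum(w[order])
        delta_hat = float(r[order][np.searchsorted(cum, 0.5 * cum[-1])])
    else:
        delta_hat = float(np.average(r, weights=w))

    return _finalize_fit(datapoints, delta_hat, ctx, ref, target)


def _finalize_fit(
    datapoints: Sequence[TransferDatapoint],
    delta_hat: float,
    ctx: TempContext,
    ref: str,
    target: str,
) -> DeltaFit:
    from .metrics import rmse as _rmse, mae as _mae, r_squared

    res = [residual(dp, delta_hat, ctx) for dp in datapoints]
    pred = np.array([predict_pka(dp, delta_hat, ctx) for dp in datapoints])
    exp = np.array([dp.pka_target_exp for dp in datapoints], dtype=float)
    n_acids = sum(dp.ionization_class is IonizationClass.ACID for dp in datapoints)
    n_bases = len(datapoints) - n_acids
    fit = DeltaFit(
        target_solvent=target,
        ref_solvent=ref,
        delta_hat=delta_hat,
        n_points=len(datapoints),
        n_acids=n_acids,
        n_bases=n_bases,
        residuals_pka=res,
        rmse=_rmse(res),
        mae=_mae(res),
    )
    if len(datapoints) >= 2 and np.var(exp) > 0:
        fit.r2_pearson = r_squared(pred, exp, mode="pearson_sq")
        fit.r2_determination = r_squared(pred, exp, mode="coefficient_of_determination")
    return fit


def fit_delta_grid_oracle(
    datapoints: Sequence[TransferDatapoint],
    ctx: TempContext,
    lo: float,
    hi: float,
    step: float,
) -> float:
    """Brute-force grid minimizer of the squared-residual objective.

    Exists purely as an independent check on the closed-form solution; ties
    break toward the smaller delta. Raises if the optimum sits on the grid
    boundary (the bracket is then suspect).
    """
    if not lo < hi:
        raise ValueError(f"need lo < hi, got lo={lo}, hi={hi}")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    if len(datapoints) == 0:
        raise ValueError("grid oracle requires at least one datapoint")
    _check_single_pair(datapoints)

    grid = np.arange(lo, hi + 0.5 * step, step)
    # objective evaluated pointwise, no reuse of the closed form
    obj = np.empty_like(grid)
    for k, d in enumerate(grid):
        obj[k] = sum(residual(dp, float(d), ctx) ** 2 for dp in datapoints)
    best = int(np.argmin(obj))  # argmin takes the first (smallest delta) on ties
    if best == 0 or best == len(grid) - 1:
        raise ValueError(
            f"grid optimum at boundary delta={grid[best]:.6g}; widen [lo, hi]"
        )
    return float(grid[best])


def fit_joint(
    datapoints: Sequence[TransferDatapoint],
    ctx: TempContext,
    anchor_solvent: str = "water",
) -> dict[str, DeltaFit]:
    """Simultaneous fit of per-solvent shifts from datapoints spanning many pairs.

    Each solvent S carries an unknown shift delta_S relative to the anchor
    (delta_anchor = 0 by definition of the reference). A datapoint measured
    between solvents a and b contributes the residual

        f = pKa_ref - pKa_exp + ((delta_b - delta_a) + g) / c

    which is linear in the deltas with coefficients +-1/c, so the joint
    optimum solves an ordinary linear least-squares system. Solvents with no
    path to the anchor in the datapoint graph are not identifiable and raise.

    Returns a map solvent -> DeltaFit for every non-anchor solvent, with
    per-solvent statistics computed against the joint solution (pooled over
    every datapoint touching that solvent as the target).
    """
    if len(datapoints) == 0:
        raise ValueError("fit_joint requires at least one datapoint")
    for dp in datapoints:
        if dp.pka_target_exp is None:
            raise ValueError(f"species {dp.species_id!r}: no experimental pKa in "
                             f"{dp.target_solvent!r}")

    solvents = sorted({dp.ref_solvent for dp in datapoints} | {dp.target_solvent for dp in datapoints})
    if anchor_solvent not in solvents:
        raise ValueError(f"anchor solvent {anchor_solvent!r} appears in no datapoint")

    # connectivity to the anchor (undirected BFS over solvent pairs)
    adj: dict[str, set[str]] = {s: set() for s in solvents}
    for dp in datapoints:
        adj[dp.ref_solvent].add(dp.target_solvent)
        adj[dp.target_solvent].add(dp.ref_solvent)
    seen = {anchor_solvent}
    frontier = [anchor_solvent]
    while frontier:
        nxt = []
        for s in frontier:
            for t in adj[s]:
                if t not in seen:
                    seen.add(t)
                    nxt.append(t)
        frontier = nxt
    disconnected = [s for s in solvents if s not in seen]
    if disconnected:
        raise ValueError(
            f"solvents {disconnected} have no datapoint path to anchor {anchor_solvent!r}; "
            "their shifts are not identifiable"
        )

    free = [s for s in solvents if s != anchor_solvent]
    col = {s: j for j, s in enumerate(free)}
    A = np.zeros((len(datapoints), len(free)))
    b = np.empty(len(datapoints))
    for i, dp in enumerate(datapoints):
        g = ion_energy_combination(dp)
        # residual zero when delta_target - delta_ref = c*(pKa_exp - pKa_ref) - g
        if dp.target_solvent != anchor_solvent:
            A[i, col[dp.target_solvent]] = 1.0
        if dp.ref_solvent != anchor_solvent:
            A[i, col[dp.ref_solvent]] = -1.0
        b[i] = ctx.c * (dp.pka_target_exp - dp.pka_ref) - g
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    deltas = {anchor_solvent: 0.0, **{s: float(sol[col[s]]) for s in free}}

    fits: dict[str, DeltaFit] = {}
    for s in free:
        pts = [dp for dp in datapoints if dp.target_solvent == s]
        if not pts:
            continue
        # per-point effective shift delta_target - delta_ref under the joint solution
        res, preds, exps = [], [], []
        n_acids = 0
        for dp in pts:
            eff = deltas[dp.target_solvent] - deltas[dp.ref_solvent]
            res.append(residual(dp, eff, ctx))
            preds.append(predict_pka(dp, eff, ctx))
            exps.append(dp.pka_target_exp)
            n_acids += dp.ionization_class is IonizationClass.ACID
        from .metrics import rmse as _rmse, mae as _mae, r_squared
        fit = DeltaFit(
            target_solvent=s,
            ref_solvent=anchor_solvent,
            delta_hat=deltas[s],
            n_points=len(pts),
            n_acids=n_acids,
            n_bases=len(pts) - n_acids,
            residuals_pka=res,
            rmse=_rmse(res),
            mae=_mae(res),
        )
        exp_arr = np.asarray(exps, dtype=float)
        if len(pts) >= 2 and np.var(exp_arr) > 0:
            fit.r2_pearson = r_squared(np.asarray(preds), exp_arr, mode="pearson_sq")
            fit.r2_determination = r_squared(np.asarray(preds), exp_arr, mode="coefficient_of_determination")
        fits[s] = fit
    return fits
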