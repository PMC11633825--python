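"""Proton-shift regression: closed form vs grid oracle, joint fit, properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pkashift import (
    TransferDatapoint,
    fit_delta,
    fit_delta_grid_oracle,
    fit_joint,
    make_temp_context,
    residual,
)
from pkashift.fitting import per_point_delta


def _dp(cls, ddg_n, ddg_i, pka_ref, pka_exp, sid="x", ref="water", target="s"):
    return TransferDatapoint(
        species_id=sid, ref_solvent=ref, target_solvent=target,
        pka_ref=pka_ref, pka_target_exp=pka_exp,
        ddg_neutral=ddg_n, ddg_ion=ddg_i, ionization_class=cls,
    )


def random_dataset(rng, n, target="s"):
    points = []
    for k in range(n):
        cls = "acid" if rng.random() < 0.5 else "base"
        points.append(
            _dp(cls,
                float(rng.normal(0, 3)), float(rng.normal(0, 5)),
                float(rng.uniform(2, 12)), float(rng.uniform(0, 25)),
                sid=f"s{k}", target=target)
        )
    return points


class TestResidual:
    def test_exact_interpolation_of_one_point(self, ctx):
        dp = _dp("acid", 1.0, -2.0, 4.0, 9.0)
        delta = ctx.c * (dp.pka_target_exp - dp.pka_ref) - (dp.ddg_ion - dp.ddg_neutral)
        assert residual(dp, delta, ctx) == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_inputs(self, ctx):
        assert residual(_dp("acid", 0, 0, 5.0, 5.0), 0.0, ctx) == 0.0

    def test_overprediction_is_positive(self, ctx):
        # prediction 10.00 against experiment 9.00 -> +1.00
        dp = _dp("acid", 1.363, 5.454, 5.0, 9.0)
        assert residual(dp, 2.727, ctx) == pytest.approx(1.00, abs=1e-3)

    def test_missing_experiment_raises(self, ctx):
        with pytest.raises(ValueError, match="experimental"):
            residual(_dp("acid", 0, 0, 5.0, None), 0.0, ctx)


class TestFitDelta:
    def test_single_point_is_exact(self, ctx):
        dp = _dp("base", 0.5, -1.5, 6.0, 3.0)
        fit = fit_delta([dp], ctx)
        assert fit.delta_hat == pytest.approx(per_point_delta(dp, ctx).r, rel=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_two_point_mean(self, ctx):
        # per-point delta estimates 0 and 2 kcal/mol -> mean 1, residuals +-1/c
        p1 = _dp("acid", 0.0, 0.0, 5.0, 5.0, sid="a")  # r = 0
        p2 = _dp("acid", 0.0, 0.0, 5.0, 5.0 + 2.0 / ctx.c, sid="b")  # r = 2
        fit = fit_delta([p1, p2], ctx)
        assert fit.delta_hat == pytest.approx(1.0, rel=1e-10)
        assert sorted(fit.residuals_pka) == pytest.approx([-1 / ctx.c, 1 / ctx.c], rel=1e-9)
        oracle = fit_delta_grid_oracle([p1, p2], ctx, -5, 5, 1e-3)
        assert oracle == pytest.approx(1.0, abs=5e-4)

    def test_empty_input_raises(self, ctx):
        with pytest.raises(ValueError, match="at least one"):
            fit_delta([], ctx)

    def test_mixed_solvent_pairs_raise(self, ctx):
        pts = [_dp("acid", 0, 0, 5, 6, target="s1"), _dp("acid", 0, 0, 5, 6, target="s2")]
        with pytest.raises(ValueError, match="multiple solvent pairs"):
            fit_delta(pts, ctx)

    def test_residual_mean_zero_at_optimum(self, ctx):
        rng = np.random.default_rng(3)
        fit = fit_delta(random_dataset(rng, 25), ctx)
        assert np.mean(fit.residuals_pka) == pytest.approx(0.0, abs=1e-8)

    def test_robust_mode_is_median(self, ctx):
        pts = [
            _dp("acid", 0, 0, 5.0, 5.0 + r / ctx.c, sid=f"s{i}")
            for i, r in enumerate([0.0, 1.0, 50.0])
        ]
        fit = fit_delta(pts, ctx, robust=True)
        assert fit.delta_hat == pytest.approx(1.0, rel=1e-9)


class TestGridOracle:
    def test_constant_estimates_recovered(self, ctx):
        pts = [_dp("acid", 0, 0, 5.0, 5.0 + 3.0 / ctx.c, sid=f"s{i}") for i in range(4)]
        assert fit_delta_grid_oracle(pts, ctx, -1, 7, 0.01) == pytest.approx(3.0, abs=0.005)

    def test_boundary_optimum_raises(self, ctx):
        pts = [_dp("acid", 0, 0, 5.0, 5.0 + 3.0 / ctx.c)]
        with pytest.raises(ValueError, match="boundary"):
            fit_delta_grid_oracle(pts, ctx, -1, 2, 0.1)

    def test_bad_bracket_rejected(self, ctx):
        pts = [_dp("acid", 0, 0, 5.0, 5.0)]
        with pytest.raises(ValueError):
            fit_delta_grid_oracle(pts, ctx, 2, -2, 0.1)
        with pytest.raises(ValueError):
            fit_delta_grid_oracle(pts, ctx, -2, 2, -0.1)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 30))
    def test_closed_form_matches_brute_force(self, seed, n):
        """Convex 1-D objective: grid minimum within step/2 of the closed form."""
        ctx = make_temp_context(298.0)
        rng = np.random.default_rng(seed)
        pts = random_dataset(rng, n)
        fit = fit_delta(pts, ctx)
        step = 0.01
        oracle = fit_delta_grid_oracle(pts, ctx, fit.delta_hat - 3 + step / 3,
                                       fit.delta_hat + 3 + step / 3, step)
        assert abs(oracle - fit.delta_hat) <= step / 2 + 1e-12


class TestObjectiveProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.floats(-20, 20, allow_nan=False))
    def test_translation_equivariance(self, seed, k):
        """Adding k to every energy combination shifts delta_hat by -k, residuals unchanged."""
        ctx = make_temp_context(298.0)
        rng = np.random.default_rng(seed)
        pts = random_dataset(rng, 12)
        shifted = [
            _dp(p.ionization_class.value,
                p.ddg_neutral,
                # add k to g: acids g = ddg_ion - ddg_neutral, bases g = -ddg_ion + ddg_neutral
                p.ddg_ion + (k if p.ionization_class.value == "acid" else -k),
                p.pka_ref, p.pka_target_exp, sid=p.species_id)
            for p in pts
        ]
        f0, f1 = fit_delta(pts, ctx), fit_delta(shifted, ctx)
        assert f1.delta_hat == pytest.approx(f0.delta_hat - k, rel=1e-9, abs=1e-9)
        assert np.allclose(f1.residuals_pka, f0.residuals_pka, atol=1e-9)

    def test_convexity_around_optimum(self, ctx):
        rng = np.random.default_rng(5)
        pts = random_dataset(rng, 15)
        fit = fit_delta(pts, ctx)

        def objective(d):
            return sum(residual(p, d, ctx) ** 2 for p in pts)

        at_opt = objective(fit.delta_hat)
        for eps in (1e-3, 0.1, 1.0, -1e-3, -0.1, -1.0):
            assert objective(fit.delta_hat + eps) > at_opt


class TestJointFit:
    def test_star_topology_equals_per_solvent_fits(self, ctx):
        rng = np.random.default_rng(9)
        pts_a = random_dataset(rng, 10, target="a")
        pts_b = random_dataset(rng, 8, target="b")
        joint = fit_joint(pts_a + pts_b, ctx, anchor_solvent="water")
        assert joint["a"].delta_hat == pytest.approx(fit_delta(pts_a, ctx).delta_hat, rel=1e-9)
        assert joint["b"].delta_hat == pytest.approx(fit_delta(pts_b, ctx).delta_hat, rel=1e-9)

    def test_chain_recovers_known_shifts(self, ctx):
        """Noiseless chain water->A, A->B identifies both shifts exactly."""
        delta_a, delta_b = 4.0, -3.0
        pts = []
        rng = np.random.default_rng(2)
        for k in range(6):
            g = float(rng.normal(0, 3))
            pka_w = float(rng.uniform(2, 12))
            pka_a = pka_w + (delta_a + g) / ctx.c
            pts.append(_dp("acid", 0.0, g, pka_w, pka_a, sid=f"wa{k}", ref="water", target="a"))
        for k in range(6):
            g = float(rng.normal(0, 3))
            pka_a = float(rng.uniform(2, 12))
            pka_b = pka_a + ((delta_b - delta_a) + g) / ctx.c
            pts.append(_dp("acid", 0.0, g, pka_a, pka_b, sid=f"ab{k}", ref="a", target="b"))
        joint = fit_joint(pts, ctx, anchor_solvent="water")
        assert joint["a"].delta_hat == pytest.approx(delta_a, abs=1e-8)
        assert joint["b"].delta_hat == pytest.approx(delta_b, abs=1e-8)
        assert joint["b"].rmse == pytest.approx(0.0, abs=1e-8)

    def test_disconnected_solvent_raises(self, ctx):
        pts = [
            _dp("acid", 0, 0, 5, 6, ref="water", target="a"),
            _dp("acid", 0, 0, 5, 6, sid="y", ref="b", target="c"),
        ]
        with pytest.raises(ValueError, match=r"\['b', 'c'\]"):
            fit_joint(pts, ctx, anchor_solvent="water")
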