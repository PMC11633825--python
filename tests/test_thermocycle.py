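"""Transfer-relation arithmetic: prefactor, sign conventions, invariances."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from pkashift import (
    GAS_CONSTANT_KCAL,
    SolvationTable,
    SpeciesRecord,
    TempContext,
    TransferDatapoint,
    ddg_transfer,
    make_temp_context,
    pka_shift,
    predict_pka,
)

KJ_PER_KCAL = 4.184


def _dp(cls, ddg_neutral, ddg_ion, pka_ref=0.0, pka_exp=None):
    return TransferDatapoint(
        species_id="x", ref_solvent="water", target_solvent="s",
        pka_ref=pka_ref, pka_target_exp=pka_exp,
        ddg_neutral=ddg_neutral, ddg_ion=ddg_ion, ionization_class=cls,
    )


class TestTempContext:
    def test_prefactor_at_298K(self):
        ctx = make_temp_context(298.0)
        assert ctx.c == pytest.approx(1.36355, abs=2e-5)
        assert ctx.c == pytest.approx(math.log(10) * GAS_CONSTANT_KCAL * 298.0, rel=1e-12)

    def test_linear_in_temperature(self):
        assert make_temp_context(596.0).c == pytest.approx(2 * make_temp_context(298.0).c, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -10.0, float("nan"), float("inf")])
    def test_rejects_degenerate_temperature(self, bad):
        with pytest.raises(ValueError, match="temperature"):
            make_temp_context(bad)


class TestDdgTransfer:
    def setup_method(self):
        self.table = SolvationTable()
        self.table.add("f", "acetonitrile", -5.0)
        self.table.add("f", "water", -8.0)

    def test_direct_subtraction(self):
        assert ddg_transfer("f", "acetonitrile", "water", self.table) == pytest.approx(3.0)

    def test_same_solvent_is_zero(self):
        assert ddg_transfer("f", "water", "water", self.table) == 0.0

    def test_missing_entry_names_pair(self):
        with pytest.raises(KeyError, match="dmso"):
            ddg_transfer("f", "dmso", "water", self.table)


class TestPkaShift:
    def test_null_cycle(self, ctx):
        assert pka_shift(_dp("acid", 0.0, 0.0), 0.0, ctx) == 0.0

    def test_acid_sign_pattern(self, ctx):
        # (2.727 + 5.454 - 1.363) / 1.36355 — anion added, neutral subtracted
        shift = pka_shift(_dp("acid", 1.363, 5.454), 2.727, ctx)
        assert shift == pytest.approx(5.00, abs=1e-3)

    def test_base_sign_pattern(self, ctx):
        # (2.727 - 5.454 + 1.363) / 1.36355 — cation subtracted, neutral added
        shift = pka_shift(_dp("base", 1.363, 5.454), 2.727, ctx)
        assert shift == pytest.approx(-1.00, abs=1e-3)

    def test_predict_identity(self, ctx):
        assert predict_pka(_dp("acid", 0.0, 0.0, pka_ref=4.20), 0.0, ctx) == pytest.approx(4.20)

    def test_predict_acid_and_base(self, ctx):
        assert predict_pka(_dp("acid", 1.363, 5.454, pka_ref=5.0), 2.727, ctx) == pytest.approx(10.00, abs=1e-3)
        assert predict_pka(_dp("base", 1.363, 5.454, pka_ref=5.0), 2.727, ctx) == pytest.approx(4.00, abs=1e-3)

    def test_unknown_class_rejected(self, ctx):
        with pytest.raises(ValueError):
            _dp("zwitterion", 0.0, 0.0)


energies = st.floats(min_value=-80, max_value=80, allow_nan=False)


class TestInvariances:
    @settings(max_examples=100, derandomize=True)
    @given(delta=energies, ddg_n=energies, ddg_i=energies)
    def test_acid_base_antisymmetry(self, delta, ddg_n, ddg_i):
        """Swapping class while negating both transfer terms leaves the shift unchanged."""
        ctx = make_temp_context(298.0)
        acid = pka_shift(_dp("acid", ddg_n, ddg_i), delta, ctx)
        base = pka_shift(_dp("base", -ddg_n, -ddg_i), delta, ctx)
        assert acid == pytest.approx(base, abs=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(delta=energies, ddg_n=energies, ddg_i=energies,
           scale=st.floats(min_value=0.1, max_value=10))
    def test_homogeneity(self, delta, ddg_n, ddg_i, scale):
        """Degree 1 in the energies jointly, degree -1 in temperature."""
        ctx = make_temp_context(298.0)
        base_shift = pka_shift(_dp("acid", ddg_n, ddg_i), delta, ctx)
        scaled = pka_shift(_dp("acid", scale * ddg_n, scale * ddg_i), scale * delta, ctx)
        assert scaled == pytest.approx(scale * base_shift, rel=1e-9, abs=1e-9)
        hot = pka_shift(_dp("acid", ddg_n, ddg_i), delta, make_temp_context(298.0 * scale))
        assert hot == pytest.approx(base_shift / scale, rel=1e-9, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(delta=energies, ddg_n=energies, ddg_i=energies,
           pka=st.floats(min_value=-5, max_value=25, allow_nan=False),
           cls=st.sampled_from(["acid", "base"]))
    def test_round_trip(self, delta, ddg_n, ddg_i, pka, cls):
        """Forward prediction then backward with negated terms recovers the input."""
        ctx = make_temp_context(298.0)
        forward = predict_pka(_dp(cls, ddg_n, ddg_i, pka_ref=pka), delta, ctx)
        back = predict_pka(
            TransferDatapoint("x", "s", "water", forward, -ddg_n, -ddg_i, cls),
            -delta, ctx,
        )
        assert back == pytest.approx(pka, abs=1e-10)

    @settings(max_examples=100, derandomize=True)
    @given(delta=energies, ddg_n=energies, ddg_i=energies)
    def test_unit_invariance(self, delta, ddg_n, ddg_i):
        """kJ inputs with a kJ-configured gas constant give the identical shift."""
        kcal_ctx = make_temp_context(298.0)
        kj_ctx = TempContext(temperature=298.0, gas_constant=GAS_CONSTANT_KCAL * KJ_PER_KCAL)
        shift_kcal = pka_shift(_dp("acid", ddg_n, ddg_i), delta, kcal_ctx)
        shift_kj = pka_shift(
            _dp("acid", ddg_n * KJ_PER_KCAL, ddg_i * KJ_PER_KCAL), delta * KJ_PER_KCAL, kj_ctx
        )
        assert shift_kj == pytest.approx(shift_kcal, abs=1e-10)


class TestSpeciesRecord:
    def test_charge_must_match_class(self):
        with pytest.raises(ValueError, match="ion_charge"):
            SpeciesRecord(species_id="a", ionization_class="acid", ion_charge=+1)

    def test_defaults_fill_forms_and_charge(self):
        sp = SpeciesRecord(species_id="a", ionization_class="base")
        assert sp.ion_charge == +1
        assert sp.neutral_form_id != sp.ion_form_id

    def test_same_solvent_datapoint_rejected(self):
        with pytest.raises(ValueError, match="ref_solvent"):
            TransferDatapoint("x", "water", "water", 1.0, 0.0, 0.0, "acid")
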