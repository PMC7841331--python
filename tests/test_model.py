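"""Effect functions, right-hand sides, parameter bundles and schedules."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemocontrol.model import (
    DoseSchedule,
    ModelParams,
    PDParams,
    PKParams,
    TumorParams,
    effect,
    effect_derivative,
    get_param,
    pk_rhs,
    set_param,
    tumor_rhs,
)

PD = PDParams(e0=0.0, emax=100.0, ec50=15.0, hill_k=1)


class TestEffect:
    @pytest.mark.parametrize(
        "c,model,hill_k,expected",
        [
            (0.0, "emax", 1, 0.0),           # zero-concentration baseline
            (15.0, "emax", 1, 50.0),         # c = EC50 gives half-max
            (15.0, "sigmoid", 3, 50.0),      # ... for any Hill exponent
            (30.0, "emax", 1, 100.0 * 30 / 45),
        ],
    )
    def test_known_values(self, c, model, hill_k, expected):
        pd = PDParams(e0=0.0, emax=100.0, ec50=15.0, hill_k=hill_k)
        assert effect(c, pd, model) == pytest.approx(expected, rel=1e-14)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            effect(-0.1, PD)

    def test_sigmoid_with_unit_hill_equals_emax_exactly(self):
        pd = PDParams(e0=2.0, emax=50.0, ec50=7.5, hill_k=1)
        c = np.linspace(0, 100, 1000)
        assert np.array_equal(effect(c, pd, "emax"), effect(c, pd, "sigmoid"))

    @settings(max_examples=100, derandomize=True)
    @given(
        c1=st.floats(0, 1e6),
        dc=st.floats(0, 1e6),
        hill_k=st.integers(1, 6),
        model=st.sampled_from(["emax", "sigmoid"]),
    )
    def test_monotone_and_bounded(self, c1, dc, hill_k, model):
        pd = PDParams(e0=1.0, emax=100.0, ec50=15.0, hill_k=hill_k)
        lo, hi = effect(c1, pd, model), effect(c1 + dc, pd, model)
        assert hi >= lo - 1e-9
        # the open upper bound e0+emax is attained only by fp rounding at large c
        assert pd.e0 <= lo <= pd.e0 + pd.emax

    def test_derivative_matches_finite_difference(self):
        pd = PDParams(e0=0.0, emax=100.0, ec50=15.0, hill_k=3)
        for c in (0.5, 5.0, 15.0, 80.0):
            fd = (effect(c + 1e-6, pd, "sigmoid") - effect(c - 1e-6, pd, "sigmoid")) / 2e-6
            assert effect_derivative(c, pd, "sigmoid") == pytest.approx(fd, rel=1e-5)


class TestPKRhs:
    def test_quiescent(self):
        assert pk_rhs(0.0, 0.0, PKParams()) == 0.0

    def test_fixed_point(self):
        pk = PKParams(k1=0.005, k2=0.0004, h=0.001)
        c_ss = pk.h * 10 / (pk.k1 + pk.k2 * 10)  # 0.01/0.009
        assert pk_rhs(c_ss, 10.0, pk) == pytest.approx(0.0, abs=1e-18)

    def test_negative_k2(self):
        pk = PKParams(k1=0.005, k2=-0.0004, h=0.001)
        assert pk_rhs(1.0, 10.0, pk) == pytest.approx(0.009)

    @settings(max_examples=50, derandomize=True)
    @given(c=st.floats(0, 1e3), u1=st.floats(0, 100), u2=st.floats(0, 100),
           lam=st.floats(0, 1))
    def test_affine_in_dose(self, c, u1, u2, lam):
        pk = PKParams(k1=0.01, k2=0.002, h=0.03)
        mix = pk_rhs(c, lam * u1 + (1 - lam) * u2, pk)
        sep = lam * pk_rhs(c, u1, pk) + (1 - lam) * pk_rhs(c, u2, pk)
        assert mix == pytest.approx(sep, rel=1e-10, abs=1e-12)

    def test_affine_in_concentration(self):
        pk = PKParams(k1=0.01, k2=0.002, h=0.03)
        u = 7.0
        slope = pk_rhs(2.0, u, pk) - pk_rhs(1.0, u, pk)
        assert pk_rhs(5.0, u, pk) == pytest.approx(pk_rhs(0.0, u, pk) + 5 * slope)


class TestTumorRhs:
    def test_scalar_cases(self):
        tp = TumorParams(a_matrix=[[0.001]], b_matrix=[[0.001]])
        assert tumor_rhs([1.0], 0.0, tp) == pytest.approx([0.001])
        assert tumor_rhs([1.0], 50.0, tp) == pytest.approx([0.051])

    def test_zero_drift(self, rng):
        tp = TumorParams(a_matrix=np.zeros((3, 3)), b_matrix=np.zeros((3, 3)))
        n = rng.uniform(0.1, 5, 3)
        assert np.all(tumor_rhs(n, 0.0, tp) == 0)

    def test_dimension_mismatch(self):
        tp = TumorParams(a_matrix=np.eye(2), b_matrix=np.eye(2))
        with pytest.raises(ValueError, match="length"):
            tumor_rhs([1.0, 1.0, 1.0], 0.0, tp)

    def test_linearity_in_state(self, rng):
        tp = TumorParams(a_matrix=rng.normal(size=(3, 3)),
                         b_matrix=rng.normal(size=(3, 3)))
        x, y = rng.normal(size=3), rng.normal(size=3)
        np.testing.assert_allclose(
            tumor_rhs(2 * x + y, 1.5, tp),
            2 * tumor_rhs(x, 1.5, tp) + tumor_rhs(y, 1.5, tp),
            rtol=1e-12,
        )


class TestValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(ec50=0.0), dict(ec50=-1.0), dict(emax=-5.0), dict(e0=-1.0),
         dict(hill_k=0), dict(hill_k=1.5)],
    )
    def test_bad_pd(self, kwargs):
        with pytest.raises(ValueError):
            PDParams(**kwargs)

    @pytest.mark.parametrize("kwargs", [dict(k1=0.0), dict(k1=-0.1), dict(h=0.0)])
    def test_bad_pk(self, kwargs):
        with pytest.raises(ValueError):
            PKParams(**kwargs)

    def test_k2_sign_unrestricted(self):
        assert PKParams(k2=-0.01).k2 == -0.01

    def test_matrix_shape_mismatch(self):
        with pytest.raises(ValueError):
            TumorParams(a_matrix=np.eye(2), b_matrix=np.eye(3))

    def test_n0_must_match_and_be_positive(self):
        tp = TumorParams(a_matrix=np.eye(2), b_matrix=np.eye(2))
        with pytest.raises(ValueError):
            ModelParams(tumor=tp, n0=[1.0])
        with pytest.raises(ValueError):
            ModelParams(tumor=tp, n0=[1.0, 0.0])

    def test_default_n0_is_unit_per_compartment(self):
        tp = TumorParams(a_matrix=np.eye(3), b_matrix=np.zeros((3, 3)))
        np.testing.assert_array_equal(ModelParams(tumor=tp).n0, np.ones(3))


class TestDoseSchedule:
    def test_cosine_values(self):
        u = DoseSchedule(form="cosine", amplitude=10, frequency=0.1, offset=10)
        assert u(0.0) == pytest.approx(20.0)
        assert u(np.pi / 0.1) == pytest.approx(0.0, abs=1e-12)

    def test_piecewise(self):
        u = DoseSchedule(form="piecewise_constant", breakpoints=(0.0, 10.0, 20.0),
                         levels=(5.0, 0.0, 2.0))
        np.testing.assert_array_equal(u([0, 9.9, 10, 15, 25]), [5, 5, 0, 0, 2])

    def test_negative_schedule_rejected_not_clipped(self):
        u = DoseSchedule(form="cosine", amplitude=10, frequency=0.1, offset=5)
        with pytest.raises(ValueError, match="negative"):
            u.validate_nonnegative(np.linspace(0, 100, 500))

    def test_bad_forms(self):
        with pytest.raises(ValueError):
            DoseSchedule(form="bolus")
        with pytest.raises(ValueError):
            DoseSchedule(form="cosine", frequency=0.0)
        with pytest.raises(ValueError):
            DoseSchedule(form="piecewise_constant", breakpoints=(1.0, 1.0),
                         levels=(1.0, 2.0))


class TestSerialization:
    def test_model_params_json_roundtrip_exact(self, ref_params):
        text = ref_params.to_json()
        back = ModelParams.from_json(text)
        assert back.to_dict() == ref_params.to_dict()
        assert back.pk == ref_params.pk and back.pd == ref_params.pd
        np.testing.assert_array_equal(back.n0, ref_params.n0)

    def test_schedule_roundtrip_exact(self, ref_schedule):
        d = json.loads(json.dumps(ref_schedule.to_dict()))
        assert DoseSchedule.from_dict(d) == ref_schedule


class TestParamPaths:
    def test_short_names_and_dotted_paths(self, ref_params):
        p = set_param(ref_params, "k2", 0.01)
        assert p.pk.k2 == 0.01
        p = set_param(ref_params, "pk.k2", 0.02)
        assert p.pk.k2 == 0.02
        p = set_param(ref_params, "A", 0.005)
        assert p.tumor.a_matrix[0, 0] == 0.005
        assert get_param(ref_params, "B") == 0.001

    def test_hill_exponent_rounded_to_integer(self, ref_params):
        assert set_param(ref_params, "hill_k", 3.4).pd.hill_k == 3
        assert set_param(ref_params, "k", 4.6).pd.hill_k == 5

    def test_unknown_name_lists_valid_ones(self, ref_params):
        with pytest.raises(KeyError, match="k1"):
            set_param(ref_params, "clearance", 1.0)

    def test_original_bundle_untouched(self, ref_params):
        set_param(ref_params, "k1", 0.009)
        assert ref_params.pk.k1 == 0.005
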