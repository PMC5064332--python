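import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from twinlia.biometric import (
    CorrelationPair,
    ModelSpec,
    TwinVarianceModel,
    VarianceComponents,
    chi2_pvalue,
    compare_nested,
    expected_correlations,
    falconer_heritability,
    fit_model,
    solve_saturated,
    variance_from_paths,
)

CORR = CorrelationPair(r_mz=0.40, r_dz=0.14, se_mz=0.035, se_dz=0.05,
                       n_mz=726, n_dz=726)


def grid_search_fit(spec, corr, step=1e-3):
    """Independent oracle: exhaustive search over the free simplex."""
    free = ModelSpec(spec).free
    coef = {"a2": (1.0, 0.5), "c2": (1.0, 1.0), "d2": (1.0, 0.25)}
    grid = np.arange(0.0, 1.0 + step / 2, step)
    if len(free) == 0:
        axes = [()]
    elif len(free) == 1:
        axes = ((x,) for x in grid)
    else:
        axes = ((x, y) for x in grid for y in grid if x + y <= 1.0)
    best = np.inf
    for point in axes:
        r_mz = sum(x * coef[f][0] for f, x in zip(free, point))
        r_dz = sum(x * coef[f][1] for f, x in zip(free, point))
        chi2 = ((corr.r_mz - r_mz) / corr.se_mz) ** 2 + (
            (corr.r_dz - r_dz) / corr.se_dz
        ) ** 2
        best = min(best, chi2)
    return best


components_strategy = st.tuples(
    st.floats(0, 0.9), st.floats(0, 0.9), st.floats(0, 0.9)
).filter(lambda x: sum(x) < 0.95).map(
    lambda x: VarianceComponents(a2=x[0], c2=x[1], d2=x[2], e2=1 - sum(x))
)


class TestExpectedCorrelations:
    @pytest.mark.parametrize(
        "v, expected",
        [
            (VarianceComponents(a2=1 - 1e-9, e2=1e-9), (1.0, 0.5)),
            (VarianceComponents(d2=1 - 1e-9, e2=1e-9), (1.0, 0.25)),
            (VarianceComponents(a2=0.27, d2=0.25, e2=0.48), (0.52, 0.1975)),
        ],
    )
    def test_known_values(self, v, expected):
        r_mz, r_dz = expected_correlations(v)
        assert r_mz == pytest.approx(expected[0], abs=1e-6)
        assert r_dz == pytest.approx(expected[1], abs=1e-6)


class TestVarianceFromPaths:
    def test_with_severe_printed_row(self):
        v = variance_from_paths(0.52, 0, 0.50, 0.69)
        assert round(v.a2, 2) == 0.27
        assert round(v.d2, 2) == 0.25
        assert round(v.e2, 2) == 0.48
        assert v.a2 + v.d2 == pytest.approx(0.52, abs=5e-3)

    def test_nonsevere_printed_row(self):
        v = variance_from_paths(0, 0, 0.58, 0.82)
        assert round(v.d2, 2) == 0.33
        assert round(v.e2, 2) == 0.67
        assert v.a2 == 0

    def test_pure_additive(self):
        assert variance_from_paths(1, 0, 0, 1e-6).a2 == pytest.approx(1, abs=1e-6)

    def test_far_from_unit_variance_errors(self):
        with pytest.raises(ValueError):
            variance_from_paths(1, 0, 0, 1)


class TestSolveSaturated:
    def test_ade_study_correlations(self):
        v, flags = solve_saturated("ADE", 0.40, 0.14)
        assert (v.a2, v.d2, v.e2) == pytest.approx((0.16, 0.24, 0.60), abs=1e-10)
        assert not flags
        assert expected_correlations(v) == pytest.approx((0.40, 0.14))

    def test_ace_interior(self):
        v, flags = solve_saturated("ACE", 0.40, 0.30)
        assert (v.a2, v.c2, v.e2) == pytest.approx((0.20, 0.20, 0.60), abs=1e-10)
        assert not flags

    def test_ace_boundary_collapses_to_ae(self):
        # 2*r_dz - r_mz < 0 forces the shared-environment estimate to zero
        v, flags = solve_saturated("ACE", 0.40, 0.14)
        assert "c2" in flags
        assert v.c2 == 0
        assert v.a2 > 0

    def test_non_saturated_spec_rejected(self):
        with pytest.raises(ValueError):
            solve_saturated("AE", 0.4, 0.2)

    @given(st.floats(0.01, 0.6), st.floats(0.01, 0.6))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity_off_boundary(self, a2, d2):
        if a2 + d2 > 0.9:
            return
        truth = VarianceComponents(a2=a2, d2=d2, e2=1 - a2 - d2)
        r = expected_correlations(truth)
        v, flags = solve_saturated("ADE", *r)
        if not flags:
            assert expected_correlations(v) == pytest.approx(r, abs=1e-9)
            assert v.a2 == pytest.approx(a2, abs=1e-9)


class TestFitModel:
    def test_saturated_ade_fits_exactly(self):
        res = fit_model("ADE", CORR)
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.df == 0
        assert res.p == 1.0
        assert not res.boundary_flags

    def test_ace_equals_ae_at_boundary(self):
        # the shared-environment non-negativity constraint binds, so ACE
        # collapses onto AE: identical chi-square, as in the printed table
        ace = fit_model("ACE", CORR)
        ae = fit_model("AE", CORR)
        assert "c2" in ace.boundary_flags
        assert ace.chi2 == pytest.approx(ae.chi2, abs=1e-6)
        assert ace.df == ae.df

    def test_e_model_on_independent_twins(self):
        corr = CorrelationPair(r_mz=0.001, r_dz=-0.002, se_mz=0.04, se_dz=0.04)
        res = fit_model("E", corr)
        assert res.chi2 < 0.01
        assert res.df == 2

    def test_matches_grid_oracle(self, rng):
        for _ in range(15):
            corr = CorrelationPair(
                r_mz=rng.uniform(-0.2, 0.8),
                r_dz=rng.uniform(-0.2, 0.6),
                se_mz=rng.uniform(0.02, 0.1),
                se_dz=rng.uniform(0.02, 0.1),
            )
            for spec in ("ADE", "ACE", "AE", "CE", "DE", "E"):
                res = fit_model(spec, corr)
                oracle = grid_search_fit(spec, corr)
                assert res.chi2 <= oracle + 1e-4, (spec, corr)

    def test_chi2_non_increasing_along_nested_chains(self, rng):
        for _ in range(10):
            corr = CorrelationPair(
                r_mz=rng.uniform(0, 0.8),
                r_dz=rng.uniform(0, 0.5),
                se_mz=0.04,
                se_dz=0.04,
            )
            chains = [("ADE", "AE", "E"), ("ADE", "DE", "E"), ("ACE", "CE", "E")]
            for chain in chains:
                chis = [fit_model(m, corr).chi2 for m in chain]
                assert chis[0] <= chis[1] + 1e-8 <= chis[2] + 2e-8

    def test_saturated_chi2_invariant_to_common_se_rescale(self):
        res1 = fit_model("ADE", CORR)
        corr2 = CorrelationPair(CORR.r_mz, CORR.r_dz, CORR.se_mz * 3, CORR.se_dz * 3)
        res2 = fit_model("ADE", corr2)
        assert res1.chi2 == pytest.approx(res2.chi2, abs=1e-9)


class TestFalconer:
    def test_printed_heritabilities(self):
        assert falconer_heritability(0.40, 0.14) == pytest.approx(0.52)
        assert falconer_heritability(0.18, 0.06) == pytest.approx(0.24)

    def test_equal_correlations_give_zero(self):
        assert falconer_heritability(0.3, 0.3) == 0

    @given(components_strategy)
    @settings(max_examples=100, deadline=None)
    def test_equals_a2_plus_1p5_d2_under_model(self, v):
        r_mz, r_dz = expected_correlations(v)
        assert falconer_heritability(r_mz, r_dz) == pytest.approx(
            v.a2 + 1.5 * v.d2, abs=1e-9
        )


class TestChi2Pvalue:
    def test_printed_nested_test(self):
        assert round(chi2_pvalue(2.6, 1), 2) == 0.11

    def test_critical_value(self):
        assert round(chi2_pvalue(3.84, 1), 2) == 0.05

    @pytest.mark.parametrize("df", [1, 2, 5])
    def test_zero_statistic(self, df):
        assert chi2_pvalue(0.0, df) == 1.0

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            chi2_pvalue(-0.1, 1)


class TestCompareNested:
    def test_printed_difference_test(self):
        full = fit_model("ADE", CorrelationPair(0.18, 0.06, 0.04, 0.04))
        reduced = fit_model("DE", CorrelationPair(0.18, 0.06, 0.04, 0.04))
        test = compare_nested(full, reduced)
        assert test.df == 1
        # the structural property: delta equals the reduced-model chi2
        assert test.delta_chi2 == pytest.approx(reduced.chi2 - full.chi2)

    def test_printed_delta_value(self):
        # delta chi2 = 2.6 on 1 df gives p = .11
        assert round(chi2_pvalue(2.6, 1), 2) == 0.11

    def test_identical_fits_give_unit_pvalue(self):
        # nesting AE inside ADE when the data already satisfy r_dz = r_mz/2
        corr = CorrelationPair(0.40, 0.20, 0.04, 0.04)
        test = compare_nested(fit_model("ADE", corr), fit_model("AE", corr))
        assert test.delta_chi2 == pytest.approx(0.0, abs=1e-8)
        assert test.p == pytest.approx(1.0)

    def test_non_nested_pair_rejected(self):
        ade = fit_model("ADE", CORR)
        ce = fit_model("CE", CORR)
        with pytest.raises(ValueError, match="not nested"):
            compare_nested(ade, ce)


class TestTwinVarianceModelEstimator:
    def test_sklearn_protocol(self):
        model = TwinVarianceModel(model="ADE")
        clone(model)
        model.fit(CORR)
        assert model.chi2_ == pytest.approx(0.0, abs=1e-10)
        assert model.components_.a2 == pytest.approx(0.16, abs=1e-6)
        assert model.expected_correlations() == pytest.approx((0.40, 0.14), abs=1e-8)

    def test_rejects_wrong_input(self):
        with pytest.raises(TypeError):
            TwinVarianceModel().fit([0.4, 0.14])
        with pytest.raises(ValueError):
            TwinVarianceModel(model="ACDE").fit(CORR)
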