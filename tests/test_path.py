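"""Non-recursive path analysis: implied covariance, ML fit, effects, indices."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mrue.path import (
    DivergentLoopError,
    EffectTable,
    ModelError,
    PathCoefficients,
    PathModelSpec,
    aggregate_effects,
    decompose_effects,
    fit_indices,
    fit_ml,
    implied_covariance,
    mardia_test,
    normality_diagnostics,
    stability_index,
)
from mrue.reference import (
    LOOP_EPS_TO_MRUE,
    LOOP_MRUE_TO_EPS,
    reference_effect_table,
    reference_model_spec,
    reference_path_coefficients,
)


def two_var_spec():
    return PathModelSpec(variables=("x", "y"), exogenous=("x",), directed_edges=(("x", "y"),))


class TestSpecValidation:
    def test_rejects_self_edge_and_edge_into_exogenous(self):
        with pytest.raises(ModelError):
            PathModelSpec(("a", "b"), ("a",), (("b", "b"),))
        with pytest.raises(ModelError):
            PathModelSpec(("a", "b"), ("a",), (("b", "a"),))

    def test_cycles_among_endogenous_allowed(self):
        spec = PathModelSpec(("x", "y", "z"), ("x",), (("x", "y"), ("y", "z"), ("z", "y")))
        assert spec.endogenous == ("y", "z")


class TestImpliedCovariance:
    def test_null_model_is_block_diagonal(self):
        spec = PathModelSpec(("x", "y"), ("x",), ())
        c = PathCoefficients(spec, B=np.zeros((1, 1)), G=np.zeros((1, 1)),
                             Phi=np.array([[2.0]]), Psi=np.array([[3.0]]))
        np.testing.assert_allclose(implied_covariance(c), np.diag([2.0, 3.0]))

    def test_single_edge_closed_form(self):
        b, psi = 0.7, 0.3
        c = PathCoefficients.from_edges(
            two_var_spec(), {("x", "y"): b}, Phi=np.array([[1.0]]), Psi=np.array([[psi]])
        )
        sigma = implied_covariance(c)
        assert sigma[0, 1] == pytest.approx(b)
        assert sigma[1, 1] == pytest.approx(b * b + psi)

    def test_singular_feedback_loop_raises_naming_loop(self):
        spec = PathModelSpec(("u", "v"), (), (("u", "v"), ("v", "u")))
        c = PathCoefficients.from_edges(spec, {("u", "v"): 2.0, ("v", "u"): 0.5})
        with pytest.raises(DivergentLoopError, match="u"):
            implied_covariance(c)


class TestFitML:
    def test_saturated_model_zero_discrepancy(self):
        S = np.array([[1.0, 0.4], [0.4, 2.0]])
        res = fit_ml(S, n=50, spec=two_var_spec(), standardized=False)
        assert res.df == 0
        assert res.discrepancy == pytest.approx(0.0, abs=1e-8)
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        assert math.isnan(res.rmsea) and math.isnan(res.agfi)

    def test_recovers_single_edge_coefficient(self):
        rng = np.random.default_rng(7)
        b = 0.6
        n = 10_000
        x = rng.standard_normal(n)
        y = b * x + math.sqrt(1 - b * b) * rng.standard_normal(n)
        S = np.cov(np.c_[x, y], rowvar=False)
        res = fit_ml(S, n=n, spec=two_var_spec(), standardized=True)
        assert res.converged
        assert res.coefficients.coefficient("x", "y") == pytest.approx(b, abs=0.02)
        assert res.r2["y"] == pytest.approx(b * b, abs=0.03)

    def test_nonrecursive_reference_topology_sign_recovery(self):
        # simulate from the reported coefficient pattern, refit, compare signs
        truth = reference_path_coefficients(include_ns=True)
        spec = truth.spec
        truth.Phi = np.array([[1.0, 0.5], [0.5, 1.0]])
        truth.Psi = np.diag([0.5, 0.8, 0.2, 0.4])
        sigma = implied_covariance(truth)
        rng = np.random.default_rng(21)
        X = rng.multivariate_normal(np.zeros(6), sigma, size=10_000)
        S = np.cov(X, rowvar=False)
        res = fit_ml(S, n=10_000, spec=spec, seed=3)
        assert res.converged
        for s, t in spec.directed_edges:
            fitted = res.coefficients.coefficient(s, t)
            assert np.sign(fitted) == np.sign(truth.coefficient(s, t)), (s, t, fitted)

    def test_unidentified_model_raises(self):
        # 2 observed moments... saturated spec plus an error covariance
        spec = PathModelSpec(
            ("x", "y", "z"), ("x",),
            (("x", "y"), ("x", "z"), ("y", "z"), ("z", "y")),
            error_covariances=(("y", "z"),),
        )
        S = np.eye(3) + 0.1
        with pytest.raises(ModelError):
            fit_ml(S, n=100, spec=spec)


def random_acyclic_coefficients(rng, ny=4, nx=2, density=0.5):
    names = tuple(f"v{i}" for i in range(nx + ny))
    exo = names[:nx]
    edges = []
    for j in range(nx + ny):
        for i in range(max(j + 1, nx), nx + ny):
            if i != j and rng.random() < density:
                edges.append((names[j], names[i]))
    if not edges:
        edges = [(names[0], names[nx])]
    spec = PathModelSpec(names, exo, tuple(edges))
    values = {e: rng.uniform(-0.6, 0.6) for e in edges}
    return PathCoefficients.from_edges(spec, values)


class TestDecomposeEffects:
    def test_reported_two_step_water_nitrogen_path(self):
        coeffs = reference_path_coefficients(include_ns=False)
        table = decompose_effects(coeffs, mode="path-sum")
        # transpiration -> nitrogen uptake -> efficiency composite
        assert table.effect("Tr", "mRUE", "indirect") == pytest.approx(0.32 * 0.66)

    def test_no_endogenous_coupling_means_no_indirect(self):
        spec = PathModelSpec(("a", "b", "y"), ("a", "b"), (("a", "y"), ("b", "y")))
        coeffs = PathCoefficients.from_edges(spec, {("a", "y"): 0.3, ("b", "y"): -0.2})
        for mode in ("path-sum", "series-limit"):
            t = decompose_effects(coeffs, mode=mode)
            assert t.effect("a", "y", "indirect") == pytest.approx(0.0, abs=1e-15)
            assert t.effect("a", "y", "total") == pytest.approx(0.3)

    @pytest.mark.parametrize("trial", range(10))
    def test_path_sum_equals_series_limit_on_acyclic_models(self, trial):
        rng = np.random.default_rng(100 + trial)
        coeffs = random_acyclic_coefficients(rng)
        t1 = decompose_effects(coeffs, mode="path-sum")
        t2 = decompose_effects(coeffs, mode="series-limit")
        keys = set(t1.effects) | set(t2.effects)
        for key in keys:
            for comp in ("direct", "indirect", "total"):
                assert t1.effect(*key, comp) == pytest.approx(
                    t2.effect(*key, comp), abs=1e-12
                ), (key, comp)

    def test_series_limit_matches_truncated_power_series(self):
        coeffs = reference_path_coefficients(include_ns=True)
        B = coeffs.B
        assert max(abs(np.linalg.eigvals(B))) < 1
        total = decompose_effects(coeffs, mode="series-limit")
        acc = np.zeros_like(B)
        Bk = np.eye(B.shape[0])
        for _ in range(50):
            Bk = Bk @ B
            acc += Bk
        endo = coeffs.spec.endogenous
        for i, t in enumerate(endo):
            for j, s in enumerate(endo):
                if i != j:
                    assert total.effect(s, t, "total") == pytest.approx(acc[i, j], abs=1e-10)

    def test_divergent_loop_rejected_in_series_limit(self):
        spec = PathModelSpec(("u", "v"), (), (("u", "v"), ("v", "u")))
        coeffs = PathCoefficients.from_edges(spec, {("u", "v"): 1.5, ("v", "u"): 0.9})
        with pytest.raises(DivergentLoopError):
            decompose_effects(coeffs, mode="series-limit")

    def test_mediator_restriction_limits_paths(self):
        coeffs = reference_path_coefficients(include_ns=False)
        t = decompose_effects(coeffs, mode="path-sum", mediators={"aPAR", "N_uptake"})
        # only the resource-mediated channels contribute
        assert t.effect("Ms", "eps", "indirect") == pytest.approx(0.58 * 0.30)
        assert t.effect("Tr", "eps", "indirect") == pytest.approx(
            0.32 * 0.67 + 0.32 * 0.35 * 0.30
        )


class TestAggregateEffects:
    def test_reported_water_sums(self):
        table = reference_effect_table()
        assert aggregate_effects(table, ("Ms", "Tr"), "eps", components=("direct",)) == pytest.approx(0.28)
        assert aggregate_effects(table, ("Ms", "Tr"), "eps") == pytest.approx(0.73)
        assert aggregate_effects(table, ("Ms", "Tr"), "mRUE") == pytest.approx(-0.28)

    def test_empty_sources_and_unknown_names(self):
        table = reference_effect_table()
        assert aggregate_effects(table, (), "eps") == 0.0
        with pytest.raises(KeyError):
            aggregate_effects(table, ("Nope",), "eps")
        with pytest.raises(KeyError):
            aggregate_effects(table, ("Ms",), "nope")

    def test_component_selector_mapping(self):
        table = reference_effect_table()
        mixed = aggregate_effects(
            table, {"Ms": "direct", "Tr": "indirect"}, "mRUE"
        )
        assert mixed == pytest.approx(-0.49 + 0.21)


class TestStabilityIndex:
    def test_acyclic_is_zero(self):
        B = np.array([[0.0, 0.0], [0.5, 0.0]])
        assert stability_index(B) == 0.0

    def test_reported_feedback_loop(self):
        B = np.array([[0.0, LOOP_MRUE_TO_EPS], [LOOP_EPS_TO_MRUE, 0.0]])
        idx = stability_index(B)
        assert idx == pytest.approx(abs(0.23 * -0.11), rel=1e-12)
        assert float(f"{idx:.2g}") == 0.025

    def test_three_cycle_product(self):
        B = np.zeros((3, 3))
        B[1, 0], B[2, 1], B[0, 2] = 0.5, 0.4, -0.5
        assert stability_index(B) == pytest.approx(0.1, rel=1e-12)

    def test_invariant_under_variable_reordering(self, rng):
        n = 4
        B = rng.uniform(-0.5, 0.5, (n, n)) * (rng.random((n, n)) < 0.4)
        np.fill_diagonal(B, 0.0)
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        assert stability_index(P @ B @ P.T) == pytest.approx(stability_index(B), rel=1e-12)

    def test_eigenvalue_variant(self):
        B = np.array([[0.0, LOOP_MRUE_TO_EPS], [LOOP_EPS_TO_MRUE, 0.0]])
        assert stability_index(B, method="eigenvalue") == pytest.approx(
            math.sqrt(0.23 * 0.11), rel=1e-9
        )


class TestFitIndices:
    def test_exact_fit_boundary(self):
        S = np.eye(3)
        gfi, agfi, nfi, rmsea, p = fit_indices(2.0, 2, 100, S, S, baseline_chi2=50.0)
        assert rmsea == 0.0
        assert gfi == pytest.approx(1.0)

    def test_reported_chi_square_p_value(self):
        S = np.eye(3)
        *_, p = fit_indices(2.412, 2, 126, S, S, baseline_chi2=50.0)
        assert round(p, 3) == 0.299
        # chi-square with 2 df: upper tail is exp(-x/2) analytically
        assert p == pytest.approx(math.exp(-2.412 / 2), rel=1e-12)

    def test_df_zero_markers(self):
        S = np.eye(2)
        gfi, agfi, nfi, rmsea, p = fit_indices(0.0, 0, 100, S, S, baseline_chi2=10.0)
        assert math.isnan(agfi) and math.isnan(rmsea)
        assert p == 1.0


class TestNormalityDiagnostics:
    def test_standard_normal_moments(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"z": rng.standard_normal(50_000)})
        out = normality_diagnostics(df)
        assert abs(out["univariate"]["z"]["skewness"]) < 0.05
        assert abs(out["univariate"]["z"]["kurtosis"] - 3.0) < 0.05

    def test_symmetric_two_point_sample_has_zero_skewness(self):
        df = pd.DataFrame({"s": [-1.0, 1.0] * 50})
        out = normality_diagnostics(df)
        assert out["univariate"]["s"]["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_diagnostics(pd.DataFrame({"c": np.ones(10), "z": np.arange(10.0)}))

    def test_mardia_null_calibration(self):
        rng = np.random.default_rng(11)
        skew_p, kurt_p = [], []
        for _ in range(200):
            m = mardia_test(rng.standard_normal((500, 3)))
            skew_p.append(m["skew_p"])
            kurt_p.append(m["kurtosis_p"])
        assert stats.kstest(skew_p, "uniform").pvalue > 0.01
        assert stats.kstest(kurt_p, "uniform").pvalue > 0.01

    def test_mardia_detects_heavy_tails(self):
        rng = np.random.default_rng(3)
        X = rng.standard_t(df=3, size=(2000, 3))
        m = mardia_test(X)
        assert m["kurtosis_p"] < 1e-6


def test_fit_indices_admissible_on_reference_spec_fit(default_records):
    """Full reference topology fits generated data with sensible indices."""
    eff_log = pd.DataFrame(
        {
            "Ms": np.log(default_records["ms"]),
            "Tr": np.log(default_records["tr"]),
            "aPAR": np.log(default_records["apar"]),
            "N_uptake": np.log(default_records["n_uptake"]),
        }
    )
    from mrue.core import efficiency_table

    eff = efficiency_table(default_records)
    eff_log["eps"] = np.log(eff["eps"])
    eff_log["mRUE"] = np.log(eff["mrue"])
    spec = reference_model_spec()
    frame = eff_log[list(spec.variables)]
    S = np.cov(frame.to_numpy(), rowvar=False)
    res = fit_ml(S, n=len(frame), spec=spec, seed=0)
    assert res.converged
    assert 0.0 <= res.rmsea < 1.0
    assert 0.5 < res.gfi <= 1.0
    assert all(0.0 <= v <= 1.0 for v in res.r2.values())
    assert res.stability < 1.0
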