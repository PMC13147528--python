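"""Regression layer: fitting, offsets, AIC comparison, Bonferroni."""

import numpy as np
import pandas as pd
import pytest

from strpurity.glm import (
    GLMResult,
    ModelSpec,
    bonferroni,
    compare_aic,
    fit_glm,
    joint_consequence_model,
)
from strpurity.simulate import generate_design_table


def newton_raphson_poisson(X: np.ndarray, y: np.ndarray, offset: np.ndarray,
                           iters: int = 50) -> np.ndarray:
    """Direct likelihood maximization, independent of statsmodels IRLS."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        mu = np.exp(X @ beta + offset)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * mu[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


@pytest.fixture
def count_table(rng):
    n = 200
    gc = rng.uniform(0, 1, n)
    motif_len = rng.integers(2, 7, n).astype(float)
    length = motif_len * rng.integers(8, 20, n)
    eta = np.log(0.05) - 0.4 * gc + np.log(length)
    return pd.DataFrame({
        "gc_fraction": gc, "motif_len": motif_len,
        "log_allele_len": np.log(length),
        "count": rng.poisson(np.exp(eta)),
    })


class TestFitGLM:
    def test_intercept_only_closed_form(self, rng):
        counts = rng.poisson(3.0, 500)
        table = pd.DataFrame({"count": counts,
                              "log_e": np.full(500, np.log(2.0))})
        spec = ModelSpec(response="count", covariates=(), offset="log_e")
        res = fit_glm(table, spec)
        assert res.coefficients["const"] == pytest.approx(
            np.log(counts.mean() / 2.0), abs=1e-8)

    def test_doubling_exposure_shifts_intercept_only(self, count_table):
        spec = ModelSpec(response="count", offset="log_allele_len")
        res1 = fit_glm(count_table, spec)
        doubled = count_table.assign(
            log_allele_len=count_table["log_allele_len"] + np.log(2))
        res2 = fit_glm(doubled, spec)
        assert res2.coefficients["const"] == pytest.approx(
            res1.coefficients["const"] - np.log(2), abs=1e-6)
        for term in ("gc_fraction", "motif_len"):
            assert res2.coefficients[term] == pytest.approx(
                res1.coefficients[term], abs=1e-6)

    def test_matches_newton_raphson_oracle_on_small_fixture(self, rng):
        n = 50
        gc = rng.uniform(0, 1, n)
        x = rng.normal(0, 1, n)
        off = np.log(rng.integers(10, 60, n).astype(float))
        y = rng.poisson(np.exp(-2 + 0.3 * gc - 0.2 * x + off))
        table = pd.DataFrame({"y": y, "gc_fraction": gc, "x": x, "off": off})
        spec = ModelSpec(response="y", covariates=("gc_fraction", "x"), offset="off")
        res = fit_glm(table, spec)
        X = np.column_stack([np.ones(n), gc, x])
        beta = newton_raphson_poisson(X, y.astype(float), off)
        for est, oracle in zip(res.coefficients, beta):
            assert est == pytest.approx(oracle, rel=1e-6)

    def test_parameter_recovery_within_two_se(self, rng):
        hits = 0
        for r in range(30):
            table, spec, truth = generate_design_table("sistr_snv", 2500, seed=300 + r)
            res = fit_glm(table, ModelSpec(**spec))
            b, se = res.coefficients["constrained"], res.std_errors["constrained"]
            hits += abs(b - truth["constrained"]) <= 2 * se
        assert hits >= 27

    def test_non_integer_response_rejected(self, count_table):
        bad = count_table.assign(count=count_table["count"] + 0.5)
        with pytest.raises(ValueError):
            fit_glm(bad, ModelSpec(response="count", offset="log_allele_len"))

    def test_poisson_requires_offset(self):
        with pytest.raises(ValueError):
            ModelSpec(response="count", offset=None)

    def test_missing_rows_dropped_not_propagated(self, count_table):
        table = count_table.copy()
        table.loc[:9, "gc_fraction"] = np.nan
        res = fit_glm(table, ModelSpec(response="count", offset="log_allele_len"))
        assert res.n_obs == len(table) - 10
        assert res.converged

    def test_likelihood_ratio_pvalues_available(self, count_table):
        res = fit_glm(count_table,
                      ModelSpec(response="count", offset="log_allele_len"),
                      likelihood_ratio=True)
        assert res.lrt_p_values is not None
        # Wald and LRT agree to the order of magnitude on healthy fits
        for term in ("gc_fraction",):
            assert abs(np.log10(res.lrt_p_values[term] + 1e-300)
                       - np.log10(res.p_values[term] + 1e-300)) < 2


class TestJointModel:
    def test_single_class_table_rejected(self):
        table = pd.DataFrame({
            "consequence": ["silent"] * 4,
            "n_interruptions": [1, 0, 2, 1],
            "exposure": [10.0] * 4,
            "gc_fraction": [0.5] * 4,
            "motif_len": [3.0] * 4,
            "loeuf": [0.5] * 4,
        })
        with pytest.raises(ValueError):
            joint_consequence_model(table)

    def test_interaction_sign_recovered(self, rng):
        recovered = 0
        for r in range(20):
            table, _, truth = generate_design_table("joint_interaction", 2000,
                                                    seed=700 + r)
            res = joint_consequence_model(table)
            recovered += res.coefficients["is_missense:loeuf"] < 0
        assert recovered >= 19


class TestCompareAic:
    def test_identical_models_give_zero(self, count_table):
        spec = ModelSpec(response="count", offset="log_allele_len")
        res = fit_glm(count_table, spec)
        assert compare_aic(res, res) == 0.0

    def test_planted_effect_favors_richer_model(self, rng):
        table, spec, _ = generate_design_table("sistr_snv", 10000, seed=42)
        full = fit_glm(table, ModelSpec(**spec))
        reduced_spec = dict(spec, covariates=("gc_fraction", "motif_len"))
        reduced = fit_glm(table, ModelSpec(**reduced_spec))
        assert compare_aic(full, reduced) < 0

    def test_null_extra_term_costs_about_two(self, rng):
        deltas = []
        for r in range(40):
            table, spec, _ = generate_design_table("enhancer_purity", 4000,
                                                   seed=900 + r, null=True)
            full = fit_glm(table, ModelSpec(**spec))
            reduced = fit_glm(table, ModelSpec(**dict(
                spec, covariates=("gc_fraction", "motif_len"))))
            deltas.append(compare_aic(full, reduced))
        assert np.mean(deltas) == pytest.approx(1.0, abs=1.0)  # E[dAIC] = 2 - E[chi2_1]

    def test_mismatched_rows_rejected(self, count_table):
        spec = ModelSpec(response="count", offset="log_allele_len")
        res1 = fit_glm(count_table, spec)
        res2 = fit_glm(count_table.iloc[:100], spec)
        with pytest.raises(ValueError):
            compare_aic(res1, res2)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni([0.01], 10) == [pytest.approx(0.1)]
        assert bonferroni([0.2], 10) == [1.0]

    def test_ordering_preserved(self):
        ps = [0.04, 0.001, 0.2]
        out = bonferroni(ps, 10)
        assert np.argsort(out).tolist() == np.argsort(ps).tolist()

    def test_family_smaller_than_list_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)
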