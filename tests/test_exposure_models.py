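import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from peptidome_dx.exposure_models import (
    ModelSpec,
    adj_r2_table,
    aicc_table,
    composite_values,
    correlation_filter,
    default_model_space,
    design_matrix,
    enumerate_models,
    fit_aicc,
    make_composite,
    vote_models,
)
from peptidome_dx.cohort import generate_cohort, cohort_to_frame


class TestComposite:
    def test_log10_arithmetic(self, cohort):
        from dataclasses import replace

        r = replace(cohort[0], inh_ec=10.0, res_ec=1.0, struct_count=0.1)
        assert make_composite(r) == pytest.approx(0.0)
        r = replace(r, inh_ec=1.0, res_ec=1.0, struct_count=1.0)
        assert make_composite(r) == pytest.approx(0.0)

    def test_strictly_increasing_in_each_metric(self, cohort):
        from dataclasses import replace

        r = cohort[1]
        assert make_composite(replace(r, inh_ec=r.inh_ec * 1.5)) > make_composite(r)

    def test_weighted_variant(self, workers):
        unweighted = composite_values(workers)
        weighted = composite_values(workers, weights=(1.0, 1.0, 1.0))
        pd.testing.assert_series_equal(unweighted, weighted)
        half = composite_values(workers, metrics=("inh_ec",), weights=(0.5,))
        np.testing.assert_allclose(half, 0.5 * np.log10(workers["inh_ec"]))

    def test_rejects_nonpositive_metric(self, workers):
        bad = workers.copy()
        bad.iloc[0, bad.columns.get_loc("inh_ec")] = 0.0
        with pytest.raises(ValueError):
            composite_values(bad)


class TestEnumeration:
    def test_combinatorial_count(self):
        space = {
            "bases": ["logInhEC", "logResEC", "logSC", "logInhResEC", "logSumExp"],
            "covariates": ["logIL6", "logCCL2", "age_bin", "sex"],
            "max_covariates": 1,
        }
        assert len(enumerate_models(space)) == 5 * 5

    def test_default_space_size_and_validity(self, workers):
        models = enumerate_models(default_model_space())
        assert len(models) == 230
        assert len({m.model_id for m in models}) == 230
        X = design_matrix(workers, models[-1].predictors)
        assert X.shape == (24, len(models[-1].predictors) + 1)

    def test_duplicate_predictors_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", ("logIL6", "logIL6"))

    def test_empty_space_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models({"bases": [], "covariates": [], "max_covariates": 0})


class TestAICc:
    def test_closed_form_substitution(self):
        # n = 10, RSS/n = 1, two coefficients (intercept + slope) plus the
        # variance parameter -> k = 3: AIC = 6, AICc = 10.
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        X = np.column_stack([np.ones(10), x])
        beta = np.linalg.lstsq(X, rng.normal(size=10), rcond=None)[0]
        # craft y with residuals of exactly RSS = 10 around the fit
        resid = rng.normal(size=10)
        resid -= X @ np.linalg.lstsq(X, resid, rcond=None)[0]  # orthogonal to X
        resid *= math.sqrt(10.0 / (resid @ resid))
        y = X @ beta + resid
        res = fit_aicc(y, X)
        assert res.k == 3
        assert res.rss == pytest.approx(10.0)
        assert res.aicc == pytest.approx(10.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_gaussian_likelihood(self, seed):
        # Independent oracle: -2 max log-likelihood + 2k from the normal
        # density at the MLE variance, minus the model-independent
        # constant n(ln 2pi + 1), to 1e-9.
        rng = np.random.default_rng(seed)
        n, p = 18, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        res = fit_aicc(y, X)
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        sigma2 = ((y - X @ beta) ** 2).sum() / n
        loglik = sps.norm.logpdf(y, X @ beta, math.sqrt(sigma2)).sum()
        k = p + 1
        aic_full = -2 * loglik + 2 * k
        aicc_full = aic_full + 2 * k * (k + 1) / (n - k - 1)
        assert res.aicc == pytest.approx(aicc_full - n * (math.log(2 * math.pi) + 1), abs=1e-9)

    def test_constant_response_adj_r2_zero(self):
        X = np.ones((8, 1))
        res = fit_aicc(np.full(8, 3.3), X)
        assert res.adj_r2 == 0.0
        assert res.degenerate and res.aicc == -math.inf

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError):
            fit_aicc(np.arange(6.0), X)

    @pytest.mark.parametrize("seed", range(3))
    def test_extra_predictor_never_decreases_raw_r2(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        X1 = np.column_stack([np.ones(n), rng.normal(size=n)])
        X2 = np.column_stack([X1, rng.normal(size=n)])
        y = rng.normal(size=n)
        assert fit_aicc(y, X2).rss <= fit_aicc(y, X1).rss + 1e-12

    def test_batch_table_matches_single_fits(self, workers):
        rng = np.random.default_rng(9)
        Y = pd.DataFrame(
            rng.normal(size=(6, 24)), index=[f"p{i}" for i in range(6)], columns=workers.index
        )
        models = [ModelSpec("logSumExp", ("logSumExp",)), ModelSpec("logResEC+age_bin", ("logResEC", "age_bin"))]
        table = aicc_table(Y, workers, models)
        for spec in models:
            X = design_matrix(workers, spec.predictors)
            for pid in Y.index:
                single = fit_aicc(Y.loc[pid].to_numpy(), X)
                assert table.loc[pid, spec.model_id] == pytest.approx(single.aicc, abs=1e-9)


class TestVoting:
    def _table(self, counts, n_models=5):
        # build an AICc table realizing the given winner counts
        rows = []
        for model, c in enumerate(counts):
            for _ in range(c):
                row = np.arange(n_models, dtype=float) + 10
                row[model] = 0.0
                rows.append(row)
        return pd.DataFrame(rows, columns=[f"m{i}" for i in range(n_models)])

    def test_counts_and_z_from_worked_example(self):
        votes = vote_models(self._table([10, 2, 2, 3, 3]))
        counts = [v.count for v in votes]
        assert counts == [10, 2, 2, 3, 3]
        assert votes[0].z == pytest.approx(1.77, abs=0.01)
        assert votes[0].p == pytest.approx(sps.norm.sf(votes[0].z))

    def test_exclusive_counts_sum_to_peptides(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(rng.normal(size=(40, 6)), columns=[f"m{i}" for i in range(6)])
        votes = vote_models(table)
        assert sum(v.count for v in votes) == pytest.approx(40)

    def test_identical_scores_split_uniformly(self):
        table = pd.DataFrame(np.ones((12, 4)), columns=list("abcd"))
        votes = vote_models(table)
        assert [v.count for v in votes] == pytest.approx([3.0] * 4)
        assert all(v.z == 0.0 for v in votes)

    def test_invariance_to_peptide_order_and_monotone_rescale(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(30, 5)), columns=[f"m{i}" for i in range(5)])
        base = [v.count for v in vote_models(table)]
        shuffled = table.sample(frac=1.0, random_state=1)
        assert [v.count for v in vote_models(shuffled)] == pytest.approx(base)
        warped = table.apply(lambda row: np.exp(0.3 * row) + 5.0, axis=1)
        assert [v.count for v in vote_models(warped)] == pytest.approx(base)

    def test_requires_three_models(self):
        with pytest.raises(ValueError):
            vote_models(pd.DataFrame(np.zeros((4, 2)), columns=["a", "b"]))


class TestCorrelationFilter:
    def test_planted_strong_peptide_detected(self, workers):
        # True R^2 = 0.9 at n = 24 should classify strong essentially always.
        rng = np.random.default_rng(5)
        x = composite_values(workers).to_numpy()
        beta = 1.0
        noise_sd = math.sqrt(np.var(beta * x, ddof=1) * (1 - 0.9) / 0.9)
        hits = 0
        trials = 200
        for _ in range(trials):
            y = beta * x + rng.normal(0, noise_sd, size=x.size)
            Y = pd.DataFrame([y], index=["p0"], columns=workers.index)
            tiers = correlation_filter(Y, workers, [ModelSpec("logSumExp", ("logSumExp",))])
            hits += "p0" in tiers.strong["logSumExp"]
        assert hits / trials > 0.95

    def test_pure_noise_rarely_strong(self, workers):
        rng = np.random.default_rng(6)
        Y = pd.DataFrame(
            rng.normal(size=(2000, 24)), index=[f"p{i}" for i in range(2000)], columns=workers.index
        )
        tiers = correlation_filter(Y, workers, [ModelSpec("logSumExp", ("logSumExp",))])
        assert len(tiers.strong["logSumExp"]) / 2000 < 0.01

    def test_intersection_of_identical_sets(self, workers):
        rng = np.random.default_rng(7)
        x = composite_values(workers).to_numpy()
        Y = pd.DataFrame(
            np.outer(np.ones(3), x) + rng.normal(0, 0.05, size=(3, 24)),
            index=list("abc"),
            columns=workers.index,
        )
        specs = [ModelSpec("logSumExp", ("logSumExp",)), ModelSpec("dup", ("logSumExp",))]
        tiers = correlation_filter(Y, workers, specs)
        assert tiers.common_strong == list("abc")
        assert tiers.strong["logSumExp"] == tiers.strong["dup"]

    def test_moderate_contains_strong(self, workers):
        rng = np.random.default_rng(8)
        Y = pd.DataFrame(
            rng.normal(size=(100, 24)), index=[f"p{i}" for i in range(100)], columns=workers.index
        )
        tiers = correlation_filter(Y, workers, [ModelSpec("logSumExp", ("logSumExp",))])
        assert set(tiers.strong["logSumExp"]) <= set(tiers.moderate["logSumExp"])
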