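"""Mismatched-cancer F1 background and the negative-binomial test."""

import numpy as np
import pytest
from scipy.stats import nbinom

from sigspec.ml import EvalMetrics, FeatureTable, ModelSpec, evaluate, train_model
from sigspec.significance import (
    BackgroundDistribution,
    background_f1,
    fit_negative_binomial,
    nb_pvalue,
    significance_table,
)


def make_tables(seed=0, n_types=3, n=40, informative=True):
    """Per-cancer one-vs-rest train/test tables over a shared sample pool."""
    rng = np.random.default_rng(seed)
    types = [f"T{i}" for i in range(n_types)]
    owner = rng.integers(0, n_types, size=n * n_types)
    X = rng.normal(size=(owner.size, 4))
    if informative:
        for t in range(n_types):
            X[owner == t, t % 4] += 3.0
    ids = [f"s{i}" for i in range(owner.size)]
    feats = [f"f{i}" for i in range(4)]
    tables = {
        t: FeatureTable(X, (owner == i).astype(int), ids, feats)
        for i, t in enumerate(types)
    }
    return types, tables


@pytest.fixture
def trained(separable_table):
    types, tables = make_tables()
    models = {
        t: train_model(ModelSpec("RF", seed=i), tables[t]) for i, t in enumerate(types)
    }
    return types, models, tables


class TestBackgroundF1:
    def test_two_types_give_two_values(self):
        types, tables = make_tables(n_types=2)
        models = {t: train_model(ModelSpec("RF", seed=0), tables[t]) for t in types}
        with pytest.warns(UserWarning, match="background"):
            bg = background_f1(models, tables)
        assert bg.n == 2

    def test_all_negative_model_gives_zero_background(self):
        types, tables = make_tables(n_types=3)

        class Stub:
            method = "RF"

            def predict_score(self, X):
                return np.zeros(len(X))

        models = {t: Stub() for t in types}
        with pytest.warns(UserWarning):
            bg = background_f1(models, tables)
        assert (bg.scores == 0).all()

    def test_matches_hand_pair_loop(self, trained):
        types, models, tables = trained
        bg = background_f1(models, tables)
        oracle = []
        for a in types:
            for b in types:
                if a != b:
                    oracle.append(evaluate(models[a], tables[b]).f1)
        assert bg.n == len(types) * (len(types) - 1)
        np.testing.assert_allclose(np.sort(bg.scores), np.sort(oracle))

    def test_single_type_errors(self, trained):
        types, models, tables = trained
        with pytest.raises(ValueError):
            background_f1({types[0]: models[types[0]]}, tables)


class TestNegativeBinomialFit:
    def test_moment_equations_mean4_var8(self):
        # counts 0..8 engineered to have mean 4 and population variance 8
        counts = np.array([0, 4, 4, 8]) / 100.0  # mean 4, var 8 on the count scale
        params = fit_negative_binomial(counts)
        assert params.kind == "nb"
        assert params.r == pytest.approx(4.0)
        assert params.p == pytest.approx(0.5)

    def test_all_identical_point_mass(self):
        with pytest.warns(UserWarning, match="point-mass"):
            params = fit_negative_binomial(np.full(10, 0.3))
        assert params.kind == "point"

    def test_underdispersed_poisson_fallback(self):
        with pytest.warns(UserWarning, match="Poisson"):
            params = fit_negative_binomial(np.array([0.03, 0.04, 0.05, 0.04]))
        assert params.kind == "poisson"

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            fit_negative_binomial([])

    def test_parameter_recovery_from_nb_draws(self):
        rng = np.random.default_rng(12)
        r_true, p_true = 3.0, 0.4
        counts = rng.negative_binomial(r_true, p_true, size=1000)
        params = fit_negative_binomial(counts / 100.0)
        assert params.kind == "nb"
        assert abs(params.r - r_true) / r_true < 0.2
        assert abs(params.p - p_true) / p_true < 0.1


def nb_background(r=3.0, p=0.4, seed=0, n=200):
    rng = np.random.default_rng(seed)
    scores = rng.negative_binomial(r, p, size=n) / 100.0
    return BackgroundDistribution(scores, np.round(100 * scores), fit_negative_binomial(scores))


class TestPValue:
    def test_zero_observed_is_one(self):
        bg = nb_background()
        assert nb_pvalue(0.0, bg).parametric == pytest.approx(1.0)

    def test_far_above_background(self):
        rng = np.random.default_rng(1)
        scores = np.clip(rng.normal(0.1, 0.05, size=100), 0, 0.2)
        bg = BackgroundDistribution(scores, np.round(100 * scores), fit_negative_binomial(scores))
        pv = nb_pvalue(0.9, bg)
        assert pv.parametric < 1e-6
        assert pv.empirical == pytest.approx(1 / 101)

    def test_parametric_matches_pmf_summation_oracle(self):
        params_bg = nb_background(seed=3)
        r, p = params_bg.nb_params.r, params_bg.nb_params.p
        obs = 0.20  # count 20
        expected = 0.0
        k = 20
        while True:
            term = nbinom.pmf(k, r, p)
            expected += term
            if term < 1e-16 and k > 20:
                break
            k += 1
        assert nb_pvalue(obs, params_bg).parametric == pytest.approx(expected, rel=1e-9)

    def test_monotone_nonincreasing_in_observed(self):
        bg = nb_background(seed=4)
        ps = [nb_pvalue(f, bg).parametric for f in np.linspace(0, 1, 51)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        es = [nb_pvalue(f, bg).empirical for f in np.linspace(0, 1, 51)]
        assert all(a >= b for a, b in zip(es, es[1:]))


def metrics_with_f1(f1):
    return EvalMetrics(precision=f1, recall=f1, f1=f1, accuracy=0.9, auc=0.8, n_positive=10)


class TestSignificanceTable:
    def test_single_model_with_p_one_unflagged(self):
        bg = nb_background()
        table = significance_table([("A", "US", "RF", metrics_with_f1(0.0))], {"RF": bg})
        assert not table.significant.iloc[0]
        assert table.p_value.iloc[0] == pytest.approx(1.0)

    def test_rows_sorted_ascending_by_p(self):
        bg = nb_background()
        rows = [
            ("A", "US", "RF", metrics_with_f1(0.1)),
            ("B", "US", "RF", metrics_with_f1(0.9)),
            ("C", "US", "RF", metrics_with_f1(0.4)),
        ]
        table = significance_table(rows, {"RF": bg})
        assert (table.p_value.diff().dropna() >= 0).all()
        assert table.cancer_type.iloc[0] == "B"

    def test_high_f1_flagged(self):
        bg = nb_background()
        table = significance_table([("A", "US", "RF", metrics_with_f1(0.95))], {"RF": bg})
        assert bool(table.significant.iloc[0])
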