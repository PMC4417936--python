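"""Decoder correctness: fitted moments, posterior oracles, CV behaviour."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from hypothesis import given, settings, strategies as st

import foodcode as fc
from foodcode import decoder
from conftest import make_expression_table, make_lifespan_table


def _table_from_points(points_by_food: dict[str, list[tuple]], genotype="wildtype"):
    rows = []
    for fi, (label, points) in enumerate(points_by_food.items()):
        for i, p in enumerate(points):
            p = np.atleast_1d(p)
            vals = {"NSM": p[0],
                    "ADF": p[1] if len(p) > 1 else np.nan,
                    "ASI": p[2] if len(p) > 2 else np.nan}
            rows.append({"animal_id": f"{label}-{i}", "genotype": genotype,
                         "food_label": label, "food_cells_per_ml": float(fi), **vals})
    return pd.DataFrame(rows)


class TestFitGaussian:
    def test_hand_computed_moments(self):
        """Four points at the corners of a square: mean (1,1), variance 4/3 per axis."""
        table = _table_from_points({
            "A": [(0, 0), (2, 2), (0, 2), (2, 0)],
            "B": [(5, 5), (6, 6), (5, 6), (6, 5)],
        })
        model = fc.fit_gaussian(table, ("NSM", "ADF"))
        mean, cov = model.params["A"]
        np.testing.assert_allclose(mean, [1.0, 1.0])
        np.testing.assert_allclose(np.diag(cov), [4 / 3, 4 / 3], rtol=1e-5)
        assert abs(cov[0, 1]) < 1e-9

    def test_univariate_density_integrates_to_one(self):
        """Quadrature oracle on the d=1 fitted density."""
        rng = np.random.default_rng(2)
        table = _table_from_points({
            "A": rng.normal(10, 2, 40).tolist(),
            "B": rng.normal(30, 3, 40).tolist(),
        })
        model = fc.fit_gaussian(table, ("NSM",))
        mean, cov = model.params["A"]
        total, _ = integrate.quad(
            lambda x: math.exp(-0.5 * (x - mean[0]) ** 2 / cov[0, 0])
            / math.sqrt(2 * math.pi * cov[0, 0]), -200, 200)
        assert abs(total - 1.0) < 1e-3

    def test_insufficient_rows_names_the_level(self):
        table = _table_from_points({"A": [(1, 1), (2, 2)], "B": [(1, 1)] * 8})
        with pytest.raises(ValueError, match="'A'"):
            fc.fit_gaussian(table, ("NSM", "ADF"))


class TestFitWeibull:
    def test_parameter_recovery(self):
        table = make_lifespan_table({"A": (1.0, 10.0), "B": (1.0, 10.0)}, n=2000, seed=4)
        model = fc.fit_weibull(table)
        shape, scale = model.params["A"]
        assert shape == pytest.approx(1.0, rel=0.05)
        # moment identity: scale * Gamma(1 + 1/shape) tracks the sample mean
        sample_mean = table[table.food_label == "A"].age_days.mean()
        assert scale * math.gamma(1 + 1 / shape) == pytest.approx(sample_mean, rel=0.02)

    def test_degenerate_sample_caps_shape(self):
        rows = _table_from_points({"A": [7.0] * 6, "B": [1, 2, 3, 4, 5, 6]})
        table = rows.rename(columns={"NSM": "age_days"}).assign(event=1)
        with pytest.warns(UserWarning, match="capping"):
            model = fc.fit_weibull(table)
        shape, scale = model.params["A"]
        assert shape == decoder.MAX_WEIBULL_SHAPE and scale == 7.0


class TestConditionalProbs:
    def test_closed_form_gaussian_ratio(self):
        """Two unit-variance classes 10 apart, obs at one mean.

        Independent oracle: posterior_2 = e^{-50} / (1 + e^{-50}).
        """
        model = decoder.ClassConditionalModel(
            kind="gaussian", foods=["A", "B"],
            params={"A": (np.array([0.0]), np.array([[1.0]])),
                    "B": (np.array([10.0]), np.array([[1.0]]))},
            neuron_subset=("NSM",))
        post = fc.conditional_probs(model, [0.0])
        expected_b = math.exp(-50) / (1 + math.exp(-50))
        assert post[1] == pytest.approx(expected_b, rel=1e-9)
        assert post[0] == pytest.approx(1.0 - expected_b, rel=1e-12)

    def test_symmetry_cases(self):
        model = decoder.ClassConditionalModel(
            kind="gaussian", foods=["A", "B"],
            params={"A": (np.array([0.0]), np.array([[4.0]])),
                    "B": (np.array([6.0]), np.array([[4.0]]))},
            neuron_subset=("NSM",))
        np.testing.assert_allclose(fc.conditional_probs(model, [3.0]), [0.5, 0.5])
        identical = decoder.ClassConditionalModel(
            kind="gaussian", foods=["A", "B", "C"],
            params={f: (np.array([1.0]), np.array([[1.0]])) for f in "ABC"},
            neuron_subset=("NSM",))
        np.testing.assert_allclose(fc.conditional_probs(identical, [0.3]), [1 / 3] * 3)

    def test_underflow_returns_uniform(self):
        model = decoder.ClassConditionalModel(
            kind="weibull", foods=["A", "B"],
            params={"A": (2.0, 10.0), "B": (2.0, 12.0)})
        with pytest.warns(UserWarning, match="underflow"):
            post = fc.conditional_probs(model, [np.inf])
        np.testing.assert_allclose(post, [0.5, 0.5])


class TestMlAssign:
    @pytest.mark.parametrize("posterior,expected", [
        ([0.1, 0.7, 0.2], 1),
        ([0.5, 0.5], 0),
        ([1 / 6] * 6, 0),
    ])
    def test_argmax_with_low_index_tie_break(self, posterior, expected):
        assert fc.ml_assign(np.array(posterior)) == expected


class TestCrossvalDecode:
    def test_separated_classes_are_perfectly_decoded(self):
        means = {f"f{i}": [500 * i, 500 * i, 500 * i] for i in range(6)}
        table = make_expression_table(means, sd=5.0, n=100, seed=0)
        res = fc.crossval_decode(table, k=5, seed=0)
        assert res.overall_accuracy > 0.99
        assert np.all(np.diag(res.ml_matrix) > 0.95)

    def test_identical_classes_decode_at_chance(self):
        means = {f"f{i}": [100, 100, 100] for i in range(6)}
        table = make_expression_table(means, sd=20.0, n=100, seed=1)
        res = fc.crossval_decode(table, k=5, seed=1)
        n = 600
        se = math.sqrt((1 / 6) * (5 / 6) / n)
        assert abs(res.overall_accuracy - 1 / 6) < 3 * se

    def test_leave_one_out_matches_brute_force(self):
        """12 printed 1-D values, k = n per food: hand-run fit+posterior+argmax."""
        values = {"A": [1.0, 1.2, 0.8, 1.1, 0.9, 1.6],
                  "B": [2.0, 2.3, 1.8, 2.1, 1.4, 2.2]}
        table = _table_from_points({k: [(v,) for v in vs] for k, vs in values.items()})
        res, details = fc.crossval_decode(table, neuron_subset=("NSM",), k=6, seed=3,
                                          return_details=True)
        tab, folds, posteriors = details["table"], details["folds"], details["posteriors"]
        for r in range(len(tab)):
            train = tab[folds != folds[r]]
            logps = []
            for label in ("A", "B"):
                x = train.loc[train.food_label == label, "NSM"].to_numpy()
                mu, var = x.mean(), x.var(ddof=1)
                var = var + decoder.COV_EPSILON * var  # the documented ridge, d=1
                logps.append(-0.5 * math.log(2 * math.pi * var)
                             - 0.5 * (tab.NSM[r] - mu) ** 2 / var)
            expected = np.exp(logps - np.max(logps))
            expected /= expected.sum()
            np.testing.assert_allclose(posteriors[r], expected, atol=1e-10)
        # confusion matrix equals the frequency of brute-force argmax decisions
        assert res.ml_matrix.shape == (2, 2)
        np.testing.assert_allclose(res.ml_matrix.sum(axis=1), 1.0)

    def test_fold_assignment_invariant_to_row_order(self, wildtype_expression):
        shuffled = wildtype_expression.sample(frac=1.0, random_state=9).reset_index(drop=True)
        a = fc.crossval_decode(wildtype_expression, k=5, seed=2)
        b = fc.crossval_decode(shuffled, k=5, seed=2)
        np.testing.assert_array_equal(a.prob_matrix, b.prob_matrix)
        np.testing.assert_array_equal(a.ml_matrix, b.ml_matrix)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=10, deadline=None)
    def test_matrices_are_row_stochastic(self, seed):
        means = {f"f{i}": [50 * i + 20, 100, 30 * i] for i in range(3)}
        table = make_expression_table(means, sd=40.0, n=15, seed=seed)
        res = fc.crossval_decode(table, k=3, seed=seed)
        np.testing.assert_allclose(res.prob_matrix.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(res.ml_matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.prob_matrix >= 0) and np.all(res.prob_matrix <= 1)

    def test_lifespan_readout_decodes_weibull_classes(self):
        table = make_lifespan_table({"A": (6.0, 10.0), "B": (6.0, 40.0)}, n=100, seed=6)
        res = fc.crossval_decode(table, readout="lifespan", k=5, seed=6)
        assert res.overall_accuracy > 0.9


class TestFunctionalSubsets:
    @pytest.mark.parametrize("genotype,expected", [
        ("wildtype", ("NSM", "ADF", "ASI")),
        ("tph1_null", ("ASI",)),
        ("daf7_null", ("NSM", "ADF")),
        ("double_null", ()),
    ])
    def test_known_genotypes(self, genotype, expected):
        assert fc.functional_subset(genotype) == expected

    def test_unknown_genotype_raises(self):
        with pytest.raises(KeyError, match="known"):
            fc.functional_subset("mystery")

    def test_empty_subset_reports_chance(self):
        res = decoder.chance_result(["A", "B", "C", "D"], np.array([10] * 4), k=5, seed=0)
        assert res.overall_accuracy == pytest.approx(0.25)
        np.testing.assert_allclose(res.ml_matrix, 0.25)


class TestSubsetSweep:
    def test_seven_results_with_shared_folds(self, wildtype_expression):
        results = fc.subset_sweep(wildtype_expression, k=5, seed=1)
        assert len(results) == 7
        assert set(map(len, results)) == {1, 2, 3}

    def test_combining_neurons_improves_accuracy(self, wildtype_expression):
        results = fc.subset_sweep(wildtype_expression, k=5, seed=1)
        combined = results[("NSM", "ADF", "ASI")].overall_accuracy
        singles = [results[(n,)].overall_accuracy for n in ("NSM", "ADF", "ASI")]
        assert all(combined >= s - 0.02 for s in singles)
        # single readouts sit strictly between chance and perfect
        assert all(1 / 6 + 0.05 < s < 0.95 for s in singles)

    def test_pure_noise_neuron_does_not_change_true_density_accuracy(self):
        """Decoding with known densities: an independent noise axis is inert.

        Monte-Carlo oracle with the true generating densities rather than
        fitted ones; accuracy with (signal,) equals accuracy with
        (signal, noise) because the noise likelihood factorizes out.
        """
        rng = np.random.default_rng(12)
        mus = np.array([0.0, 30.0, 60.0])
        sd, noise_sd = 10.0, 500.0
        n = 30_000
        truth = rng.integers(0, 3, size=n)
        signal = rng.normal(mus[truth], sd)
        logp_sig = np.stack([stats.norm.logpdf(signal, m, sd) for m in mus], axis=1)
        noise = rng.normal(0.0, noise_sd, size=n)
        logp_noise = stats.norm.logpdf(noise, 0.0, noise_sd)[:, None]  # same per class
        acc_signal = np.mean(np.argmax(logp_sig, axis=1) == truth)
        acc_both = np.mean(np.argmax(logp_sig + logp_noise, axis=1) == truth)
        assert acc_both == acc_signal
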