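"""Compound covariate predictor: hand-calculated parameters, closed-form
posterior identity, LOOCV against a from-scratch fold loop, and cross-cohort
transfer on platform-shifted synthetic data."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fatsig import SimulationConfig, simulate_multi_cohort
from fatsig.bccp import (BCCPModel, fit_bccp, loocv_error, predict_bccp,
                         standardize, _posterior_hr)
from fatsig.errors import DegenerateDataError, SchemaError

from conftest import null_config, random_expression


class FakeSignature:
    def __init__(self, gene_ids):
        self.gene_ids = list(gene_ids)


def _labels(ids, hr_ids):
    return pd.Series(["HR" if s in hr_ids else "LR" for s in ids],
                     index=pd.Index(ids, name="sample_id"), name="label")


def toy_training():
    """2-gene, 6-sample fixture with closed-form parameters."""
    expr = pd.DataFrame(
        [[0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
         [1.0, 0.0, 1.0, 1.0, 2.0, 0.0]],
        index=pd.Index(["g1", "g2"], name="gene_id"),
        columns=[f"s{i}" for i in range(1, 7)])
    labels = _labels(expr.columns, {"s4", "s5", "s6"})
    return expr, labels


class TestStandardize:
    def test_zero_mean_unit_sd(self, training_cohort):
        std, params = standardize(training_cohort.expression)
        assert np.allclose(std.mean(axis=1), 0.0, atol=1e-10)
        assert np.allclose(std.std(axis=1, ddof=1), 1.0, atol=1e-10)
        assert not params.dropped_genes

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        expr = random_expression(rng, 15, 10)
        once, _ = standardize(expr)
        twice, _ = standardize(once)
        pd.testing.assert_frame_equal(once, twice, atol=1e-10, rtol=0)

    def test_constant_gene_dropped(self):
        rng = np.random.default_rng(1)
        expr = random_expression(rng, 4, 6)
        expr.loc["G2"] = 5.0
        std, params = standardize(expr)
        assert params.dropped_genes == ["G2"]
        assert "G2" not in std.index

    def test_platform_shift_absorbed(self):
        """Two cohorts differing only by per-gene location/scale become
        indistinguishable after standardization (KS, alpha=0.01)."""
        cfg = null_config(seed=12, n_samples=200, n_genes=60, n_signature=5,
                          n_cohorts=2, platform_shift_sd=0.8,
                          platform_scale_sd=0.4)
        c0, c1 = simulate_multi_cohort(cfg)
        s0, _ = standardize(c0.expression)
        s1, _ = standardize(c1.expression)
        _, p = stats.ks_2samp(s0.to_numpy().ravel(), s1.to_numpy().ravel())
        assert p > 0.01


class TestFit:
    def test_toy_parameters_match_hand_computation(self):
        expr, labels = toy_training()
        model = fit_bccp(expr, labels, FakeSignature(["g1", "g2"]))
        # oracle: plain-arithmetic pooled t and compound covariate moments
        def pooled_t(hr_vals, lr_vals):
            n1, n2 = len(hr_vals), len(lr_vals)
            v1 = np.var(hr_vals, ddof=1)
            v2 = np.var(lr_vals, ddof=1)
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            return (np.mean(hr_vals) - np.mean(lr_vals)) / math.sqrt(
                sp2 * (1 / n1 + 1 / n2))
        t1 = pooled_t([3.0, 4.0, 5.0], [0.0, 1.0, 2.0])
        t2 = pooled_t([1.0, 2.0, 0.0], [1.0, 0.0, 1.0])
        assert model.weights["g1"] == pytest.approx(t1, abs=1e-12)
        assert model.weights["g2"] == pytest.approx(t2, abs=1e-12)
        c = t1 * expr.loc["g1"].to_numpy() + t2 * expr.loc["g2"].to_numpy()
        c_lr, c_hr = c[:3], c[3:]
        assert model.mu_lr == pytest.approx(c_lr.mean(), abs=1e-12)
        assert model.mu_hr == pytest.approx(c_hr.mean(), abs=1e-12)
        pooled = (2 * np.var(c_lr, ddof=1) + 2 * np.var(c_hr, ddof=1)) / 4
        assert model.sigma == pytest.approx(math.sqrt(pooled), abs=1e-12)

    def test_separable_labels_give_zero_training_error(self):
        rng = np.random.default_rng(2)
        expr = random_expression(rng, 5, 20)
        expr.loc["G0", expr.columns[:10]] += 6.0
        labels = _labels(expr.columns, set(expr.columns[:10]))
        std, _ = standardize(expr)
        model = fit_bccp(std, labels, FakeSignature(expr.index))
        pred = predict_bccp(model, std)
        assert (pred["label"] == labels).all()

    def test_permuted_labels_give_similar_class_means(self):
        rng = np.random.default_rng(3)
        gaps, spreads = [], []
        for rep in range(20):
            expr = random_expression(np.random.default_rng(rep), 10, 60)
            ids = list(expr.columns)
            labels = _labels(ids, set(rng.permutation(ids)[:30]))
            std, _ = standardize(expr)
            model = fit_bccp(std, labels, FakeSignature(expr.index))
            gaps.append(model.mu_hr - model.mu_lr)
            spreads.append(model.sigma)
        # no systematic separation relative to the covariate's spread
        assert abs(np.mean(gaps)) < np.mean(spreads)

    def test_single_class_rejected(self):
        expr, labels = toy_training()
        labels[:] = "LR"
        with pytest.raises(DegenerateDataError):
            fit_bccp(expr, labels, FakeSignature(["g1", "g2"]))

    def test_missing_genes_recorded_all_missing_rejected(self):
        expr, labels = toy_training()
        model = fit_bccp(expr, labels, FakeSignature(["g1", "g2", "g3"]))
        assert model.missing_genes == ["g3"]
        with pytest.raises(DegenerateDataError):
            fit_bccp(expr, labels, FakeSignature(["nope"]))

    def test_model_json_round_trip(self, tmp_path):
        from fatsig import io as fio

        expr, labels = toy_training()
        model = fit_bccp(expr, labels, FakeSignature(["g1", "g2"]))
        path = tmp_path / "model.json"
        fio.write_model(model, path)
        back = fio.read_model(path)
        assert back.mu_lr == model.mu_lr and back.sigma == model.sigma
        pd.testing.assert_series_equal(back.weights,
                                       model.weights.rename(None))
        payload = model.to_dict()
        del payload["sigma"]
        path.write_text(pd.io.json.ujson_dumps(payload)
                        if hasattr(pd.io.json, "ujson_dumps")
                        else __import__("json").dumps(payload))
        with pytest.raises(SchemaError):
            fio.read_model(path)


def _model(mu_lr=-1.0, mu_hr=1.0, sigma=1.0, p_hr=0.5, genes=("g1",)):
    return BCCPModel(gene_ids=list(genes),
                     weights=pd.Series(1.0, index=list(genes)),
                     mu_lr=mu_lr, mu_hr=mu_hr, sigma=sigma,
                     prior_lr=1.0 - p_hr, prior_hr=p_hr)


class TestPosterior:
    def test_midpoint_with_equal_priors_is_half(self):
        model = _model()
        assert _posterior_hr(np.array([0.0]), model)[0] == pytest.approx(0.5)

    def test_closed_form_logistic_identity(self):
        """Equal-variance Gaussians: posterior = logistic of
        (mu_hr-mu_lr)(c-(mu_hr+mu_lr)/2)/sigma^2 (+ prior log-odds)."""
        model = _model(mu_lr=-1.0, mu_hr=1.0, sigma=1.3, p_hr=0.35)
        c = np.linspace(-4, 4, 31)
        expected = 1.0 / (1.0 + np.exp(
            -((model.mu_hr - model.mu_lr) * (c - (model.mu_hr + model.mu_lr) / 2)
              / model.sigma ** 2 + math.log(model.prior_hr / model.prior_lr))))
        np.testing.assert_allclose(_posterior_hr(c, model), expected,
                                   atol=1e-10)

    def test_matches_numerically_normalized_bayes(self):
        model = _model(mu_lr=-0.5, mu_hr=2.0, sigma=0.8, p_hr=0.6)
        c = np.array([0.5])
        num = model.prior_hr * stats.norm.pdf(c, model.mu_hr, model.sigma)
        den = num + model.prior_lr * stats.norm.pdf(c, model.mu_lr, model.sigma)
        assert _posterior_hr(c, model)[0] == pytest.approx(
            float((num / den)[0]), abs=1e-10)

    def test_posteriors_sum_to_one_exactly(self):
        rng = np.random.default_rng(4)
        expr = random_expression(rng, 3, 25)
        model = _model(genes=expr.index)
        pred = predict_bccp(model, expr)
        assert (pred["posterior_hr"] + pred["posterior_lr"] == 1.0).all()

    def test_zero_weights_return_prior(self):
        rng = np.random.default_rng(5)
        expr = random_expression(rng, 2, 8)
        model = BCCPModel(gene_ids=list(expr.index),
                          weights=pd.Series(0.0, index=list(expr.index)),
                          mu_lr=0.0, mu_hr=1e-300, sigma=1.0,
                          prior_lr=0.3, prior_hr=0.7)
        pred = predict_bccp(model, expr)
        np.testing.assert_allclose(pred["posterior_hr"], 0.7, atol=1e-12)

    def test_posterior_monotone_in_c(self):
        model = _model()
        c = np.linspace(-5, 5, 101)
        post = _posterior_hr(c, model)
        assert (np.diff(post) > 0).all()

    def test_threshold_half_equals_nearest_class_mean(self):
        """Equal priors: posterior > 0.5 iff c is nearer mu_hr than mu_lr."""
        model = _model(mu_lr=-0.7, mu_hr=1.9, sigma=1.1)
        c = np.linspace(-5, 5, 200)
        by_posterior = _posterior_hr(c, model) > 0.5
        by_distance = np.abs(c - model.mu_hr) < np.abs(c - model.mu_lr)
        np.testing.assert_array_equal(by_posterior, by_distance)

    def test_no_shared_genes_rejected(self):
        rng = np.random.default_rng(6)
        expr = random_expression(rng, 2, 5)
        with pytest.raises(DegenerateDataError):
            predict_bccp(_model(genes=["absent"]), expr)


class TestLoocv:
    def test_matches_from_scratch_fold_loop(self):
        """n=6 toy: the reported rate equals an explicit leave-one-out loop
        written directly from the definition."""
        expr, labels = toy_training()
        sig = FakeSignature(["g1", "g2"])
        rate = loocv_error(expr, labels, sig)

        errors = 0
        for held in expr.columns:
            rest = [s for s in expr.columns if s != held]
            model = fit_bccp(expr[rest], labels[rest], sig)
            pred = predict_bccp(model, expr[[held]])
            if pred.loc[held, "label"] != labels[held]:
                errors += 1
        assert rate == errors / 6

    def test_separable_data_zero_error(self):
        rng = np.random.default_rng(7)
        expr = random_expression(rng, 5, 30)
        expr.loc["G0", expr.columns[:15]] += 8.0
        labels = _labels(expr.columns, set(expr.columns[:15]))
        std, _ = standardize(expr)
        assert loocv_error(std, labels, FakeSignature(expr.index)) == 0.0

    def test_null_error_near_minority_baseline(self):
        """Labels independent of expression, empirical priors: the classifier
        defaults to the majority class, so error ~ minority fraction."""
        rates = []
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            expr = random_expression(rng, 8, 50)
            hr_ids = set(rng.permutation(list(expr.columns))[:30])
            labels = _labels(expr.columns, hr_ids)
            std, _ = standardize(expr)
            rates.append(loocv_error(std, labels, FakeSignature(expr.index),
                                     priors="empirical"))
        assert abs(np.mean(rates) - 0.4) < 0.12

    def test_too_few_samples_rejected(self):
        expr, labels = toy_training()
        with pytest.raises(DegenerateDataError):
            loocv_error(expr.iloc[:, :3], labels.iloc[:3],
                        FakeSignature(["g1", "g2"]))


class TestCrossCohort:
    def test_platform_shifted_cohort_recovered(self, cohort_pair):
        """Train on cohort 0 labels, predict the platform-shifted cohort 1:
        balanced accuracy vs the latent truth >= 0.9 at generator defaults."""
        from sklearn.metrics import balanced_accuracy_score

        train, test = cohort_pair
        std0, _ = standardize(train.expression)
        model = fit_bccp(std0, train.truth_labels.rename("label"),
                         FakeSignature(train.truth_genes))
        std1, _ = standardize(test.expression)
        pred = predict_bccp(model, std1)
        acc = balanced_accuracy_score(test.truth_labels,
                                      pred["label"].loc[test.truth_labels.index])
        assert acc >= 0.9
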