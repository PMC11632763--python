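"""Bernoulli naive Bayes and the per-clique marginal P(BBB+ | clique)."""

import numpy as np
import pytest
from sklearn.naive_bayes import BernoulliNB

from bbbcliques.bayes import (
    clique_report,
    fit_bernoulli_nb,
    marginal_probabilities,
    marginal_probability,
    nb_posterior,
)
from bbbcliques.cliques import binarize, build_vocabulary, decompose, featurize_many


def random_binary_problem(rng, n=None, v=None):
    n = n or int(rng.integers(10, 60))
    v = v or int(rng.integers(1, 8))
    X = rng.integers(0, 2, size=(n, v))
    y = rng.integers(0, 2, size=n)
    if len(np.unique(y)) < 2:
        y[0], y[1] = 0, 1
    return X, y


class TestFit:
    def test_empirical_frequency_alpha0(self):
        X = np.array([[1]] * 4 + [[0]] * 2 + [[0]] * 3)
        y = np.array([1] * 6 + [0] * 3)
        model = fit_bernoulli_nb(X, y, alpha=0.0)
        assert model.cond[1, 0] == pytest.approx(4 / 6)

    def test_laplace_smoothing(self):
        X = np.zeros((3, 1), dtype=int)
        y = np.array([1, 1, 1])
        X = np.vstack([X, np.zeros((1, 1), dtype=int)])
        y = np.append(y, 0)
        model = fit_bernoulli_nb(X, y, alpha=1.0)
        assert model.cond[1, 0] == pytest.approx((0 + 1) / (3 + 2))

    def test_complementary_events_sum_to_one(self):
        rng = np.random.default_rng(1)
        X, y = random_binary_problem(rng)
        model = fit_bernoulli_nb(X, y, alpha=1.0)
        # P(x=1|y) + P(x=0|y) = 1 by construction of a Bernoulli model
        assert np.allclose(model.cond + (1 - model.cond), 1.0)
        assert np.all((model.cond > 0) & (model.cond < 1))  # alpha>0 forbids 0/1

    def test_matches_sklearn_bernoulli_nb(self):
        rng = np.random.default_rng(7)
        X, y = random_binary_problem(rng, n=80, v=5)
        ours = fit_bernoulli_nb(X, y, alpha=1.0)
        ref = BernoulliNB(alpha=1.0).fit(X, y)
        assert np.allclose(np.exp(ref.feature_log_prob_), ours.cond)
        post = nb_posterior(ours, X)
        assert np.allclose(post, ref.predict_proba(X)[:, 1], atol=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_bernoulli_nb(np.zeros((3, 2)), np.ones(3, dtype=int))
        with pytest.raises(ValueError):
            fit_bernoulli_nb(np.zeros((3, 2)), np.array([0, 1, 1]), alpha=-1)


class TestPosterior:
    def test_uninformative_evidence_returns_prior(self):
        X = np.array([[1], [1], [1], [1]])
        y = np.array([1, 1, 1, 0])
        model = fit_bernoulli_nb(X, y, alpha=0.0)
        # the feature is present in every molecule of both classes
        assert nb_posterior(model, np.array([1])) == pytest.approx(model.prior)

    def test_log_space_matches_direct_product_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            X, y = random_binary_problem(rng, v=int(rng.integers(1, 10)))
            model = fit_bernoulli_nb(X, y, alpha=1.0)
            x = rng.integers(0, 2, size=X.shape[1])
            direct = {}
            for cls in (0, 1):
                p = model.prior if cls == 1 else 1 - model.prior
                for i, xi in enumerate(x):
                    p *= model.cond[cls, i] if xi else 1 - model.cond[cls, i]
                direct[cls] = p
            expected = direct[1] / (direct[0] + direct[1])
            assert nb_posterior(model, x) == pytest.approx(expected, abs=1e-9)

    def test_width_mismatch_rejected(self):
        model = fit_bernoulli_nb(np.array([[0, 1], [1, 0]]), np.array([0, 1]))
        with pytest.raises(ValueError):
            nb_posterior(model, np.array([1]))


class TestMarginal:
    def test_worked_example(self):
        # 10 molecules, 6 positive; clique in 4 positives + 1 negative
        X = np.array([[1]] * 4 + [[0]] * 2 + [[1]] + [[0]] * 3)
        y = np.array([1] * 6 + [0] * 4)
        model = fit_bernoulli_nb(X, y, alpha=0.0)
        assert marginal_probability(model, 0) == pytest.approx(0.8)

    def test_present_everywhere_returns_prior(self):
        X = np.ones((10, 1), dtype=int)
        y = np.array([1] * 7 + [0] * 3)
        model = fit_bernoulli_nb(X, y, alpha=0.0)
        assert marginal_probability(model, 0) == pytest.approx(0.7)

    def test_only_in_positives_gives_one(self):
        X = np.array([[1], [1], [0], [0]])
        y = np.array([1, 1, 0, 0])
        model = fit_bernoulli_nb(X, y, alpha=0.0)
        assert marginal_probability(model, 0) == pytest.approx(1.0)

    def test_absent_everywhere_alpha0_undefined(self):
        X = np.zeros((4, 1), dtype=int)
        y = np.array([1, 1, 0, 0])
        model = fit_bernoulli_nb(X, y, alpha=0.0)
        with pytest.raises(ValueError):
            marginal_probability(model, 0)

    def test_alpha0_equals_empirical_fraction_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            X, y = random_binary_problem(rng)
            model = fit_bernoulli_nb(X, y, alpha=0.0)
            marg = marginal_probabilities(model)
            for i in range(X.shape[1]):
                present = X[:, i] == 1
                if present.sum() == 0:
                    assert np.isnan(marg[i])
                else:
                    assert marg[i] == pytest.approx(
                        np.sum(present & (y == 1)) / present.sum(), abs=1e-12
                    )

    def test_invariant_under_dataset_duplication(self):
        rng = np.random.default_rng(29)
        X, y = random_binary_problem(rng, n=40, v=4)
        m1 = marginal_probabilities(fit_bernoulli_nb(X, y, alpha=0.0))
        m2 = marginal_probabilities(
            fit_bernoulli_nb(np.vstack([X, X]), np.concatenate([y, y]), alpha=0.0)
        )
        np.testing.assert_allclose(m1, m2, equal_nan=True)

    def test_monotone_in_added_positive(self):
        rng = np.random.default_rng(31)
        for alpha in (0.0, 1.0):
            X, y = random_binary_problem(rng, n=30, v=3)
            X[:, 0][:3] = 1  # ensure presence
            before = marginal_probabilities(fit_bernoulli_nb(X, y, alpha=alpha))[0]
            X2 = np.vstack([X, np.array([[1] + [0] * (X.shape[1] - 1)])])
            y2 = np.append(y, 1)
            after = marginal_probabilities(fit_bernoulli_nb(X2, y2, alpha=alpha))[0]
            assert after >= before - 1e-12


class TestCliqueReport:
    def _fit(self, smiles, labels, alpha=0.0):
        decs = [decompose(s) for s in smiles]
        vocab = build_vocabulary(decs)
        X, _ = featurize_many(decs, vocab)
        model = fit_bernoulli_nb(binarize(X), np.array(labels), alpha=alpha)
        return model, vocab

    def test_threshold_split_and_completeness(self):
        smiles = ["CF"] * 5 + ["CCO"] * 5
        labels = [1] * 5 + [0] * 5
        model, vocab = self._fit(smiles, labels)
        full, enh, sup = clique_report(model, vocab, min_document_frequency=1)
        assert len(full) == len(vocab)
        assert "CF" in set(enh.fragment_smiles)
        assert set(sup.fragment_smiles) == {"CC", "CO"}
        assert {"fragment_smiles", "document_frequency", "p_bbb_pos", "fragment_clogp"} <= set(
            full.columns
        )

    def test_midrange_clique_in_neither_table(self):
        smiles = ["CF", "CF", "CCO", "CCO"]
        labels = [1, 0, 1, 0]
        model, vocab = self._fit(smiles, labels)
        _, enh, sup = clique_report(model, vocab, min_document_frequency=1)
        assert enh.empty and sup.empty

    def test_low_df_excluded_from_labelled_tables(self):
        smiles = ["CF"] * 5 + ["CCO"] * 5
        labels = [1] * 5 + [0] * 5
        model, vocab = self._fit(smiles, labels)
        full, enh, sup = clique_report(model, vocab, min_document_frequency=6)
        assert enh.empty and sup.empty
        assert len(full) == len(vocab)

    def test_bad_thresholds_rejected(self):
        smiles = ["CF", "CCO"]
        model, vocab = self._fit(smiles, [1, 0])
        with pytest.raises(ValueError):
            clique_report(model, vocab, hi=0.2, lo=0.8)
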