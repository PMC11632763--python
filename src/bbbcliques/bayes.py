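"""Bernoulli naive Bayes as an analytical tool for clique-level insight.

Beyond being a (weaker) classifier, the Bernoulli naive-Bayes fit gives
direct access to the per-clique marginal probability

    P(y=1 | x_i=1) = P(x_i=1 | y=1) P(y=1) / sum_y P(x_i=1 | y) P(y),

the probability that a molecule permeates the blood-brain barrier given
that clique i is present.  Because every variable is binary, the
evidence term P(x_i=1) is tractable exactly, so no normalizer is
dropped.  With smoothing alpha = 0 the marginal reduces to the
empirical fraction count(x_i=1, y=1) / count(x_i=1).

The marginal analysis is fitted on the full labelled dataset: it is an
interpretation device, not a predictor, so cross-validation is not
involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cliques import CliqueVocabulary
from .data import clogp

__all__ = [
    "BernoulliNBModel",
    "CliqueStat",
    "fit_bernoulli_nb",
    "nb_posterior",
    "marginal_probability",
    "marginal_probabilities",
    "clique_report",
]


@dataclass
class BernoulliNBModel:
    """Fitted Bernoulli naive Bayes with its sufficient counts retained."""

    prior: float  # P(y=1), empirical class frequency
    cond: np.ndarray  # shape (2, V): cond[y, i] = P(x_i=1 | y)
    alpha: float
    class_counts: np.ndarray  # shape (2,): number of molecules per class
    presence_counts: np.ndarray  # shape (2, V): count(x_i=1, y)

    @property
    def n_features(self) -> int:
        return self.cond.shape[1]


def fit_bernoulli_nb(X_binary: np.ndarray, y: np.ndarray, alpha: float = 1.0) -> BernoulliNBModel:
    """Fit class prior and per-feature Bernoulli conditionals.

    ``P(x_i=1 | y) = (count(x_i=1, y) + alpha) / (count(y) + 2 alpha)``;
    alpha = 1 is Laplace smoothing, alpha = 0 the raw empirical
    frequency.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X = np.asarray(X_binary)
    y = np.asarray(y)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("both classes must be present")
    class_counts = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=float)
    presence = np.stack([X[y == 0].sum(axis=0), X[y == 1].sum(axis=0)]).astype(float)
    cond = (presence + alpha) / (class_counts[:, None] + 2.0 * alpha)
    prior = class_counts[1] / class_counts.sum()
    return BernoulliNBModel(
        prior=float(prior),
        cond=cond,
        alpha=float(alpha),
        class_counts=class_counts.astype(int),
        presence_counts=presence.astype(int),
    )


def nb_posterior(model: BernoulliNBModel, x_binary: np.ndarray) -> np.ndarray:
    """Posterior P(y=1 | x) for one vector or a matrix of rows.

    Computed in log space with the normalizer over y restored, so a
    genuine probability is returned; the hard label is posterior >= 0.5.
    """
    X = np.atleast_2d(np.asarray(x_binary))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature width {X.shape[1]} does not match model width {model.n_features}"
        )
    priors = np.array([1.0 - model.prior, model.prior])
    # clip so an alpha=0 conditional of exactly 0 or 1 cannot produce
    # 0 * -inf = nan for features whose factor is not even selected
    tiny = 1e-300
    log_p = np.log(np.clip(model.cond, tiny, 1.0))  # P(x=1|y)
    log_q = np.log(np.clip(1.0 - model.cond, tiny, 1.0))  # P(x=0|y)
    # log-likelihood per class: X @ log_p + (1-X) @ log_q
    ll = X @ log_p.T + (1 - X) @ log_q.T + np.log(priors)
    ll -= ll.max(axis=1, keepdims=True)
    probs = np.exp(ll)
    post = probs[:, 1] / probs.sum(axis=1)
    return post if np.asarray(x_binary).ndim == 2 else float(post[0])


def marginal_probabilities(model: BernoulliNBModel) -> np.ndarray:
    """Vector of P(y=1 | x_i=1) over all features."""
    num = model.cond[1] * model.prior
    den = model.cond[1] * model.prior + model.cond[0] * (1.0 - model.prior)
    out = np.full(model.n_features, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def marginal_probability(model: BernoulliNBModel, clique_index: int) -> float:
    """P(y=1 | x_i=1) for one clique; the central interpretive statistic."""
    if not 0 <= clique_index < model.n_features:
        raise IndexError(f"clique index {clique_index} out of range")
    m = marginal_probabilities(model)[clique_index]
    if np.isnan(m):
        raise ValueError(
            "marginal undefined: clique present nowhere and alpha = 0 gives P(x_i=1) = 0"
        )
    return float(m)


@dataclass
class CliqueStat:
    fragment_smiles: str
    document_frequency: int
    p_bbb_pos: float
    fragment_clogp: float


def clique_report(
    model: BernoulliNBModel,
    vocab: CliqueVocabulary,
    min_document_frequency: int = 50,
    hi: float = 0.8,
    lo: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank cliques by their marginal P(BBB+ | clique present).

    Returns ``(full, enhancers, suppressors)``.  ``full`` has one row
    per vocabulary entry with the marginal, document frequency and the
    fragment's Wildman-Crippen clogP (a qualitative lipophilicity
    indicator only for an isolated fragment).  ``enhancers`` are the
    reported cliques with marginal >= ``hi``, ``suppressors`` those with
    marginal <= ``lo``; cliques occurring in fewer than
    ``min_document_frequency`` molecules stay in ``full`` (flagged) but
    are excluded from the two labelled tables.
    """
    if hi <= lo:
        raise ValueError(f"hi ({hi}) must exceed lo ({lo})")
    if len(vocab) != model.n_features:
        raise ValueError("model and vocabulary disagree on the number of cliques")
    frags = vocab.fragments
    marg = marginal_probabilities(model)
    full = pd.DataFrame(
        {
            "fragment_smiles": frags,
            "document_frequency": [vocab.document_frequency[f] for f in frags],
            "p_bbb_pos": marg,
            "fragment_clogp": [clogp(f) for f in frags],
        }
    )
    full["reported"] = full["document_frequency"] >= min_document_frequency
    full = full.sort_values(["p_bbb_pos", "fragment_smiles"], ascending=[False, True]).reset_index(
        drop=True
    )
    reported = full[full["reported"]]
    enhancers = reported[reported["p_bbb_pos"] >= hi].reset_index(drop=True)
    suppressors = reported[reported["p_bbb_pos"] <= lo].reset_index(drop=True)
    return full, enhancers, suppressors
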