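"""Random-forest classification, MDI importances, metrics and repeated k-fold CV.

The classifier is a 64-tree random forest grown by Gini-impurity
minimization with library-default hyperparameters (no tuning).  A
molecule's score is the fraction of trees voting for the permeable
class.  Evaluation is repeated k-fold cross-validation — by default
5 folds and 10 repeats with fresh shuffled splits per repeat — with
sensitivity, specificity, Matthews correlation coefficient and ROC AUC
aggregated over all folds of all repeats.  Class balancing, when
enabled, is applied to each training fold only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .balance import BalanceConfig, balance_training_set
from .cliques import CliqueVocabulary, build_vocabulary, featurize_many

__all__ = [
    "ForestConfig",
    "CVPlan",
    "ConfusionCounts",
    "MetricsReport",
    "gini",
    "train_forest",
    "predict_scores",
    "mdi_importances",
    "compute_metrics",
    "confusion_counts",
    "repeated_kfold",
]


@dataclass
class ForestConfig:
    """Random-forest hyperparameters: 64 Gini trees, library defaults otherwise."""

    n_trees: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class CVPlan:
    """Repeated k-fold plan: k folds, fresh shuffled split per repeat.

    Repeat ``r`` uses split seed ``base_seed + r`` so repeats are
    statistically independent yet fully reproducible.
    """

    k: int = 5
    repeats: int = 10
    base_seed: int = 0
    stratified: bool = False


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """SN/SP/MCC/AUC, per fold and aggregated over folds x repeats."""

    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame)

    @classmethod
    def from_single(cls, sn: float, sp: float, mcc: float, auc: float) -> "MetricsReport":
        return cls(per_fold=pd.DataFrame([{"sn": sn, "sp": sp, "mcc": mcc, "auc": auc}]))

    @property
    def mean(self) -> pd.Series:
        return self.per_fold[["sn", "sp", "mcc", "auc"]].mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold[["sn", "sp", "mcc", "auc"]].std(ddof=0)

    def to_dict(self) -> dict:
        return {
            "mean": {k: float(v) for k, v in self.mean.items()},
            "std": {k: float(v) for k, v in self.std.items()},
            "per_fold": self.per_fold.to_dict(orient="records"),
        }

    def summary(self) -> str:
        m, s = self.mean, self.std
        lines = [f"folds evaluated: {len(self.per_fold)}"]
        for k, label in (("sn", "sensitivity"), ("sp", "specificity"), ("mcc", "MCC"), ("auc", "AUC")):
            lines.append(f"{label:>12s}: {m[k]:.3f} +/- {s[k]:.3f}")
        return "\n".join(lines)


def gini(p) -> float:
    """Gini impurity 1 - sum(p_i^2) of a vector of class proportions."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("proportions must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    return float(1.0 - np.sum(p**2))


def train_forest(X: np.ndarray, y: np.ndarray, config: ForestConfig | None = None) -> RandomForestClassifier:
    """Fit a Gini random forest; reproducible for a given config seed."""
    config = config or ForestConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        random_state=config.seed,
    )
    model.fit(np.asarray(X), y)
    return model


def predict_scores(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the positive class, per row.

    The hard label is score >= 0.5 (ties at exactly 0.5 classify as
    positive).
    """
    X = np.asarray(X)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature width {X.shape[1]} does not match training width {model.n_features_in_}"
        )
    pos_col = int(np.where(model.classes_ == 1)[0][0])
    votes = np.zeros(X.shape[0])
    for tree in model.estimators_:
        votes += (tree.predict(X) == model.classes_[pos_col]).astype(float)
    return votes / len(model.estimators_)


def mdi_importances(
    model: RandomForestClassifier,
    vocab: CliqueVocabulary,
    min_document_frequency: int = 50,
) -> pd.DataFrame:
    """Mean-decrease-in-impurity ranking of the clique features.

    The MDI vector is averaged over trees and normalized so the full
    (unfiltered) vector sums to one.  Cliques occurring in fewer than
    ``min_document_frequency`` molecules are flagged and dropped from
    the ranked report, but they still take part in the normalization.
    The per-tree standard deviation quantifies how stable each
    importance is across the ensemble.
    """
    per_tree = np.array([t.feature_importances_ for t in model.estimators_])
    mdi = per_tree.mean(axis=0)
    total = mdi.sum()
    if total > 0:
        mdi = mdi / total
    std = per_tree.std(axis=0, ddof=0)
    if total > 0:
        std = std / total
    frags = vocab.fragments
    df = pd.DataFrame(
        {
            "fragment_smiles": frags,
            "document_frequency": [vocab.document_frequency[f] for f in frags],
            "mdi_mean": mdi,
            "mdi_std": std,
        }
    )
    df["reported"] = df["document_frequency"] >= min_document_frequency
    return (
        df.sort_values(["mdi_mean", "fragment_smiles"], ascending=[False, True])
        .reset_index(drop=True)
    )


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """SN, SP, MCC at a score threshold plus trapezoidal ROC AUC.

    SN = tp/(tp+fn), SP = tn/(tn+fp),
    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)) with the
    convention MCC = 0 when the denominator vanishes.  Scores exactly at
    the threshold classify as positive.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to compute metrics")
    cc = confusion_counts(y_true, (scores >= threshold).astype(int))
    sn = cc.tp / (cc.tp + cc.fn)
    sp = cc.tn / (cc.tn + cc.fp)
    denom = float(cc.tp + cc.fp) * (cc.tp + cc.fn) * (cc.tn + cc.fp) * (cc.tn + cc.fn)
    mcc = (cc.tp * cc.tn - cc.fp * cc.fn) / np.sqrt(denom) if denom > 0 else 0.0
    auc = float(roc_auc_score(y_true, scores))
    return MetricsReport.from_single(float(sn), float(sp), float(mcc), auc)


def _validation_hash(indices: np.ndarray, X_val: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(indices).tobytes())
    h.update(np.ascontiguousarray(X_val).tobytes())
    return h.hexdigest()


def repeated_kfold(
    dataset,
    plan: CVPlan | None = None,
    forest: ForestConfig | None = None,
    use_smote: bool = True,
    vocab_scope: str = "fold",
    decompositions=None,
    classifier: str = "rf",
    nb_alpha: float = 1.0,
) -> tuple[MetricsReport, dict]:
    """Evaluate the clique classifier by repeated shuffled k-fold CV.

    Per fold: a vocabulary is built from the training fold only (scope
    ``"fold"``) or once from the whole dataset (scope ``"full"``), both
    folds are featurized against it, the training fold is optionally
    balanced with discretized SMOTE, the model is trained, and the
    untouched validation fold is scored.  No synthetic row can reach a
    validation fold by construction; the returned diagnostics carry a
    hash of each validation fold's indices and features so an identical
    run without SMOTE can prove the validation data are byte-identical.

    ``classifier`` is "rf" (random forest) or "nb" (Bernoulli naive
    Bayes on the binarized descriptor, mainly for reference — it is the
    weaker classifier).  Returns ``(MetricsReport, diagnostics)``.
    """
    from .bayes import fit_bernoulli_nb, nb_posterior
    from .cliques import binarize

    plan = plan or CVPlan()
    forest = forest or ForestConfig()
    if vocab_scope not in ("fold", "full"):
        raise ValueError(f"vocab_scope must be 'fold' or 'full', got {vocab_scope!r}")

    records = [r for r in dataset.records if r.label is not None]
    y_all = np.array([r.label for r in records], dtype=int)
    if len(np.unique(y_all)) < 2:
        raise ValueError("dataset must contain both classes")
    if len(records) < plan.k:
        raise ValueError("fewer records than folds")

    if decompositions is None:
        from .cliques import decompose_dataset

        decompositions = decompose_dataset(r.canonical_smiles for r in records)

    full_vocab = build_vocabulary(decompositions) if vocab_scope == "full" else None

    rows = []
    val_hashes = []
    for rep in range(plan.repeats):
        split_seed = plan.base_seed + rep
        splitter_cls = StratifiedKFold if plan.stratified else KFold
        splitter = splitter_cls(n_splits=plan.k, shuffle=True, random_state=split_seed)
        split_args = (np.zeros(len(records)), y_all) if plan.stratified else (np.zeros(len(records)),)
        for fold, (tr, va) in enumerate(splitter.split(*split_args)):
            vocab = full_vocab if full_vocab is not None else build_vocabulary(
                [decompositions[i] for i in tr]
            )
            X_tr, _ = featurize_many([decompositions[i] for i in tr], vocab, row_ids=tr)
            X_va, _ = featurize_many([decompositions[i] for i in va], vocab, row_ids=va)
            Xt, yt = X_tr.counts, y_all[tr]
            Xv, yv = X_va.counts, y_all[va]
            val_hashes.append(_validation_hash(va, Xv))
            if use_smote:
                rng = np.random.default_rng(1_000_003 * split_seed + fold)
                Xt, yt, _ = balance_training_set(Xt, yt, rng=rng)
            if classifier == "rf":
                model = train_forest(Xt, yt, ForestConfig(n_trees=forest.n_trees, seed=forest.seed + rep))
                scores = predict_scores(model, Xv)
            elif classifier == "nb":
                nb = fit_bernoulli_nb(binarize(Xt), yt, alpha=nb_alpha)
                scores = nb_posterior(nb, binarize(Xv))
            else:
                raise ValueError(f"unknown classifier {classifier!r}")
            fold_metrics = compute_metrics(yv, scores)
            row = fold_metrics.per_fold.iloc[0].to_dict()
            row.update({"repeat": rep, "fold": fold})
            rows.append(row)
    report = MetricsReport(per_fold=pd.DataFrame(rows))
    diagnostics = {"validation_hashes": val_hashes, "n_records": len(records)}
    return report, diagnostics
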