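"""High-level modelling interface: fit once, get everything.

:class:`CliquePermeabilityModel` wraps a molecule dataset and, on
``fit()``, runs the whole transparent-modelling workflow: clique
featurization, repeated k-fold evaluation of the random forest (with
training-fold-only SMOTE when requested), a final forest fitted on all
labelled data for the MDI importance ranking, and the Bernoulli
naive-Bayes marginal analysis.  The returned
:class:`CliquePermeabilityResults` carries the cross-validated metrics
with their spread, the importance table, the per-clique marginal
P(BBB+ | clique) table, and a ``summary()`` in the spirit of the
classic statistical-modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bayes, cliques, forest
from .data import Dataset
from .forest import CVPlan, ForestConfig, MetricsReport

__all__ = ["CliquePermeabilityModel", "CliquePermeabilityResults"]


class CliquePermeabilityModel:
    """Transparent clique-descriptor model of blood-brain-barrier permeability.

    Parameters
    ----------
    dataset
        A :class:`bbbcliques.data.Dataset`; unlabelled records are
        ignored during fitting.
    use_smote
        Balance each training fold with discretized SMOTE.
    vocab_scope
        ``"fold"`` builds the clique vocabulary from each training fold
        only (no leakage); ``"full"`` builds it once from all molecules.
    nb_alpha
        Laplace smoothing for the naive-Bayes marginal analysis
        (``0`` gives the exact empirical per-clique marginal).
    """

    def __init__(
        self,
        dataset: Dataset,
        plan: CVPlan | None = None,
        forest_config: ForestConfig | None = None,
        use_smote: bool = True,
        vocab_scope: str = "fold",
        nb_alpha: float = 1.0,
        min_document_frequency: int = 50,
        hi: float = 0.8,
        lo: float = 0.2,
    ) -> None:
        self.dataset = dataset.labelled()
        self.plan = plan or CVPlan()
        self.forest_config = forest_config or ForestConfig()
        self.use_smote = use_smote
        self.vocab_scope = vocab_scope
        self.nb_alpha = nb_alpha
        self.min_document_frequency = min_document_frequency
        self.hi = hi
        self.lo = lo
        self.decompositions = cliques.decompose_dataset(
            r.canonical_smiles for r in self.dataset.records
        )
        self.vocab = cliques.build_vocabulary(self.decompositions)

    @classmethod
    def from_table(cls, path: str, column_map=None, **kwargs) -> "CliquePermeabilityModel":
        from .data import read_table

        return cls(read_table(path, column_map=column_map), **kwargs)

    def fit(self, evaluate: bool = True) -> "CliquePermeabilityResults":
        X, _ = cliques.featurize_many(self.decompositions, self.vocab)
        y = np.array([r.label for r in self.dataset.records], dtype=int)

        cv_report = None
        diagnostics: dict = {}
        if evaluate:
            cv_report, diagnostics = forest.repeated_kfold(
                self.dataset,
                plan=self.plan,
                forest=self.forest_config,
                use_smote=self.use_smote,
                vocab_scope=self.vocab_scope,
                decompositions=self.decompositions,
            )

        final_forest = forest.train_forest(X.counts, y, self.forest_config)
        mdi = forest.mdi_importances(final_forest, self.vocab, self.min_document_frequency)

        nb = bayes.fit_bernoulli_nb(cliques.binarize(X), y, alpha=self.nb_alpha)
        full, enhancers, suppressors = bayes.clique_report(
            nb,
            self.vocab,
            min_document_frequency=self.min_document_frequency,
            hi=self.hi,
            lo=self.lo,
        )
        return CliquePermeabilityResults(
            model=self,
            cv_metrics=cv_report,
            diagnostics=diagnostics,
            forest=final_forest,
            mdi=mdi,
            nb=nb,
            clique_stats=full,
            enhancers=enhancers,
            suppressors=suppressors,
        )


@dataclass
class CliquePermeabilityResults:
    """Everything the fitted workflow produced."""

    model: CliquePermeabilityModel
    cv_metrics: MetricsReport | None
    diagnostics: dict
    forest: object
    mdi: pd.DataFrame
    nb: object
    clique_stats: pd.DataFrame
    enhancers: pd.DataFrame
    suppressors: pd.DataFrame

    def predict_scores(self, smiles_list) -> np.ndarray:
        """Score new molecules (fraction of trees voting permeable)."""
        decs = cliques.decompose_dataset(smiles_list)
        X, _ = cliques.featurize_many(decs, self.model.vocab)
        return forest.predict_scores(self.forest, X.counts)

    def summary(self) -> str:
        n = len(self.model.dataset)
        y = self.model.dataset.labels
        lines = [
            "Clique permeability model",
            "=" * 60,
            f"molecules: {n}  (BBB+ {int(y.sum())}, BBB- {int((1 - y).sum())})",
            f"vocabulary: {len(self.model.vocab)} cliques",
            f"forest: {self.model.forest_config.n_trees} trees; "
            f"SMOTE={'on' if self.model.use_smote else 'off'}; "
            f"vocab scope={self.model.vocab_scope}",
        ]
        if self.cv_metrics is not None:
            lines += [
                "-" * 60,
                f"repeated {self.model.plan.k}-fold CV x {self.model.plan.repeats} repeats",
                self.cv_metrics.summary(),
            ]
        lines += ["-" * 60, "top cliques by MDI (document frequency >= "
                  f"{self.model.min_document_frequency}):"]
        top = self.mdi[self.mdi["reported"]].head(5)
        for _, r in top.iterrows():
            lines.append(
                f"  {r.fragment_smiles:<12s} mdi={r.mdi_mean:.3f} +/- {r.mdi_std:.3f}"
                f"  (in {int(r.document_frequency)} molecules)"
            )
        lines += ["-" * 60, f"naive-Bayes marginals (alpha={self.model.nb_alpha:g}):",
                  f"  enhancers  (P(BBB+|clique) >= {self.model.hi}): {len(self.enhancers)}",
                  f"  suppressors (P(BBB+|clique) <= {self.model.lo}): {len(self.suppressors)}"]
        for _, r in self.enhancers.head(5).iterrows():
            lines.append(
                f"    + {r.fragment_smiles:<12s} P(BBB+)={r.p_bbb_pos:.3f}"
                f" clogp={r.fragment_clogp:+.2f} df={int(r.document_frequency)}"
            )
        for _, r in self.suppressors.head(5).iterrows():
            lines.append(
                f"    - {r.fragment_smiles:<12s} P(BBB+)={r.p_bbb_pos:.3f}"
                f" clogp={r.fragment_clogp:+.2f} df={int(r.document_frequency)}"
            )
        return "\n".join(lines)
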