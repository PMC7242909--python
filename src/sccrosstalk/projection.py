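"""Cross-dataset cluster projection by L2-regularized multinomial logistic
regression.

A classifier is trained on a reference dataset's clusters using the
log-transformed normalized expression; query cells (e.g. cells from another
tissue or species, already mapped into the reference gene namespace) are then
scored by their predicted probability of belonging to each reference cluster.
Group-averaged probability tables indicate which reference cluster each query
population is most similar to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .cluster import ClusterAssignment
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["ClusterProjection", "ProjectionResults", "fit_projection",
           "project_cells", "summarize_projection"]


class ClusterProjection:
    """Multinomial logistic projection model over a reference dataset.

    Parameters
    ----------
    reference
        log-normalized genes x cells reference matrix.
    assignment
        Reference cluster labels (>= 2 clusters, each with >= 3 cells).
    penalty
        Inverse L2 regularization strength (sklearn's ``C``); larger means
        weaker shrinkage.
    genes
        Optional feature restriction, e.g. the intersection with a known
        query gene list or a highly-variable subset; defaults to all
        reference genes.
    scale
        Standardize each gene on the training data (mean 0, unit variance)
        before fitting, applying the same transform at prediction time.  On
        by default: the L2 penalty is not scale-invariant, and without
        standardization a handful of very highly expressed genes dominate
        the fit.  ``scale=False`` fits on the log-normalized values as-is.
    """

    def __init__(self, reference: ExpressionMatrix,
                 assignment: ClusterAssignment, penalty: float = 1.0,
                 genes: list[str] | None = None, scale: bool = True,
                 tol: float = 1e-6, max_iter: int = 2000):
        if assignment.n_clusters < 2:
            raise ValueError("reference must contain at least 2 clusters")
        sizes = assignment.labels.value_counts()
        if (sizes < 3).any():
            raise ValueError("every reference cluster needs >= 3 cells")
        if genes is not None:
            genes = [g for g in genes if g in set(reference.genes)]
            if not genes:
                raise ValueError("no requested genes present in reference")
            reference = reference.subset_genes(genes)
        self.reference = reference
        self.assignment = assignment
        self.penalty = float(penalty)
        self.scale = scale
        self.tol = tol
        self.max_iter = max_iter

    def fit(self) -> "ProjectionResults":
        X = self.reference.values.T.copy()  # cells x genes
        y = self.assignment.labels.loc[self.reference.cells].to_numpy()
        if self.scale:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        # L2 penalty is sklearn's default; strength is 1/C
        clf = LogisticRegression(C=self.penalty, solver="lbfgs",
                                 tol=self.tol, max_iter=self.max_iter)
        clf.fit((X - mu) / sd, y)
        return ProjectionResults(self, clf, mu, sd)


@dataclass
class ProjectionResults:
    """Fitted projection: weights plus prediction helpers."""

    model: ClusterProjection
    classifier: LogisticRegression
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    @property
    def genes(self) -> list[str]:
        return list(self.model.reference.genes)

    @property
    def classes(self) -> np.ndarray:
        return self.classifier.classes_

    @property
    def coef_(self) -> np.ndarray:
        return self.classifier.coef_

    def predict_proba(self, query: ExpressionMatrix) -> pd.DataFrame:
        """Per-cell probability of membership in each reference cluster.

        Query genes are aligned to the training gene list by name; genes
        missing from the query are imputed as 0 (a count of such genes is
        logged).  Rows sum to 1.
        """
        shared = [g for g in self.genes if g in set(query.genes)]
        if not shared:
            raise ValueError("query shares no genes with the reference model")
        n_missing = len(self.genes) - len(shared)
        if n_missing:
            logger.warning("%d model genes absent from query; imputed as 0",
                           n_missing)
        X = query.data.reindex(self.genes).fillna(0.0).to_numpy().T
        proba = self.classifier.predict_proba(
            (X - self.feature_mean) / self.feature_sd)
        return pd.DataFrame(proba, index=query.cells,
                            columns=[f"cluster_{c}" for c in self.classes])

    def summary_by_group(self, query: ExpressionMatrix,
                         groups) -> pd.DataFrame:
        probs = self.predict_proba(query)
        return summarize_projection(probs, groups)

    def training_accuracy(self) -> float:
        ref = self.model.reference
        X = (ref.values.T - self.feature_mean) / self.feature_sd
        y = self.model.assignment.labels.loc[ref.cells].to_numpy()
        return float((self.classifier.predict(X) == y).mean())

    def summary(self) -> str:
        ref = self.model.reference
        lines = [
            "Multinomial logistic cluster projection (L2)",
            "=" * 44,
            f"reference:        {ref.n_genes} genes x {ref.n_cells} cells",
            f"clusters:         {len(self.classes)}",
            f"inverse penalty:  {self.model.penalty}",
            f"converged:        {self.classifier.n_iter_.max()} iterations",
            f"training accuracy: {self.training_accuracy():.3f}",
        ]
        return "\n".join(lines)


def fit_projection(reference: ExpressionMatrix, assignment: ClusterAssignment,
                   penalty: float = 1.0, genes: list[str] | None = None
                   ) -> ProjectionResults:
    """Convenience wrapper: build and fit a :class:`ClusterProjection`."""
    return ClusterProjection(reference, assignment, penalty, genes).fit()


def project_cells(results: ProjectionResults,
                  query: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell reference-cluster probabilities for a query matrix."""
    return results.predict_proba(query)


def summarize_projection(probabilities: pd.DataFrame, groups) -> pd.DataFrame:
    """Mean cluster probability per query group (rows sum to 1).

    ``groups`` maps each query cell to a group label (Series or dict); every
    cell must be covered.
    """
    g = pd.Series(groups)
    missing = set(probabilities.index) - set(g.index)
    if missing:
        raise ValueError(f"groups missing for {len(missing)} query cells")
    g = g.loc[probabilities.index]
    return probabilities.groupby(g).mean()
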