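"""Permutation-based inference of cluster-pair-specific ligand-receptor
interactions, with heteromeric-complex handling.

For an interaction between partner A (in cluster i) and partner B (in cluster
j), the statistic is the arithmetic mean of A's average expression in cluster
i and B's average expression in cluster j, computed on log(TPM+1) by
convention.  An interaction is *tested* for a cluster pair only if each
partner is expressed in more than 10% of its cluster's cells; for a
heteromeric complex every subunit must clear the filter, and the complex is
represented by the subunit with the minimum cluster-average expression (its
"effective gene").

The null distribution comes from globally shuffling the cluster labels of all
cells (one shuffle per permutation, shared by every cluster pair and
interaction) and recomputing the statistic with the effective genes held
fixed at their observed choice.  The p-value is the plain proportion of null
means as high or higher than the observed mean, so it can be exactly 0 at
finite permutations; the ``add_one`` option gives the (1+k)/(1+N) estimator.
No multiple-testing correction is applied for filtering; Benjamini-Hochberg
q-values are reported as an extra column for reference only.

An exhaustive enumerator over all distinct label arrangements provides an
exact oracle for small instances (<= 12 cells).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .matrix import ExpressionMatrix
from .simulate import partner_genes

__all__ = [
    "InteractionRecord",
    "PermutationConfig",
    "load_interaction_db",
    "expressed_fraction",
    "partner_mean",
    "observed_interaction_mean",
    "permutation_pvalues",
    "exhaustive_pvalues",
    "summarize_significant",
    "CellCommunication",
    "CommunicationResults",
]

# numerical slack for the "as or higher" comparison: keeps exactly-tied null
# means (e.g. fully degenerate data) counted as ties despite float roundoff
_TIE_ATOL = 1e-9


@dataclass(frozen=True)
class InteractionRecord:
    """One directed ligand->receptor interaction.

    Each partner is an ordered tuple of subunit genes; a single-gene partner
    is a 1-tuple.  ``partner_a`` is the ligand side by convention, recorded
    in ``direction``.
    """

    id: str
    partner_a: tuple[str, ...]
    partner_b: tuple[str, ...]
    direction: str = "a_is_ligand"
    annotation: str = ""

    def __post_init__(self):
        for name, partner in (("partner_a", self.partner_a),
                              ("partner_b", self.partner_b)):
            if not partner:
                raise ValueError(f"{name} of {self.id!r} is empty")
            if len(set(partner)) != len(partner):
                raise ValueError(f"{name} of {self.id!r} repeats a subunit")

    @classmethod
    def make(cls, id: str, partner_a, partner_b, **kw) -> "InteractionRecord":
        return cls(id, tuple(partner_genes(partner_a)),
                   tuple(partner_genes(partner_b)), **kw)


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-test settings (defaults follow the published protocol)."""

    n_permutations: int = 1000
    expression_fraction_threshold: float = 0.10
    seed: int = 0
    add_one: bool = False

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 <= self.expression_fraction_threshold < 1.0:
            raise ValueError("expression_fraction_threshold must be in [0, 1)")


def load_interaction_db(path) -> list[InteractionRecord]:
    """Parse an interaction CSV: ``id,partner_a,partner_b[,annotation]``.

    Complexes are written ``GENE1+GENE2+...``.  Duplicate ids and malformed
    rows raise, with the offending line number.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["id", "partner_a", "partner_b"]
    if not set(required).issubset(df.columns):
        raise ValueError(f"interaction DB must have columns {required}")
    records = []
    seen = set()
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            if row[required].isna().any():
                raise ValueError("missing field")
            rec = InteractionRecord.make(
                row["id"], row["partner_a"], row["partner_b"],
                annotation=str(row.get("annotation", "") or ""))
        except ValueError as e:
            raise ValueError(f"malformed interaction row at line {line}: {e}")
        if rec.id in seen:
            raise ValueError(f"duplicate interaction id {rec.id!r} at line {line}")
        seen.add(rec.id)
        records.append(rec)
    return records


def _labels_array(matrix: ExpressionMatrix,
                  assignment: ClusterAssignment) -> np.ndarray:
    return assignment.labels.loc[matrix.cells].to_numpy()


def expressed_fraction(matrix: ExpressionMatrix, assignment: ClusterAssignment,
                       cluster: int, gene: str) -> float:
    """Fraction of the cluster's cells with expression > 0 for ``gene``."""
    if gene not in matrix.genes:
        raise KeyError(f"unknown gene {gene!r}")
    mask = _labels_array(matrix, assignment) == cluster
    if not mask.any():
        raise ValueError(f"cluster {cluster} is empty")
    row = matrix.data.loc[gene].to_numpy()
    return float((row[mask] > 0).mean())


def partner_mean(matrix: ExpressionMatrix, assignment: ClusterAssignment,
                 cluster: int, partner, threshold: float = 0.10
                 ) -> tuple[float, bool, str]:
    """Cluster-average expression of a partner and its detection status.

    Simple partner: the gene's mean over the cluster; qualifies iff its
    expressed fraction strictly exceeds ``threshold``.  Complex: qualifies
    only if *every* subunit clears the filter; the effective gene is the
    subunit with the minimum cluster-average expression (first-listed wins
    ties) and the mean is that subunit's average.
    """
    genes = partner_genes(partner)
    mask = _labels_array(matrix, assignment) == cluster
    if not mask.any():
        raise ValueError(f"cluster {cluster} is empty")
    sub = matrix.data.loc[genes].to_numpy()[:, mask]
    fracs = (sub > 0).mean(axis=1)
    means = sub.mean(axis=1)
    qualifies = bool((fracs > threshold).all())
    eff_idx = int(np.argmin(means))
    return float(means[eff_idx]), qualifies, genes[eff_idx]


def observed_interaction_mean(matrix: ExpressionMatrix,
                              assignment: ClusterAssignment,
                              cluster_a: int, cluster_b: int,
                              record: InteractionRecord,
                              threshold: float = 0.10) -> dict:
    """Observed statistic for one (cluster pair, interaction), without p-value.

    ``tested`` is True only when both partners qualify in their respective
    clusters; the observed mean is the arithmetic mean of the two partner
    cluster averages (so swapping partners together with clusters leaves it
    unchanged).
    """
    mean_a, ok_a, eff_a = partner_mean(matrix, assignment, cluster_a,
                                       record.partner_a, threshold)
    mean_b, ok_b, eff_b = partner_mean(matrix, assignment, cluster_b,
                                       record.partner_b, threshold)
    return {
        "cluster_a": int(cluster_a), "cluster_b": int(cluster_b),
        "interaction": record.id,
        "effective_a": eff_a, "effective_b": eff_b,
        "mean": 0.5 * (mean_a + mean_b),
        "tested": bool(ok_a and ok_b),
        "autocrine": cluster_a == cluster_b,
    }


def _cluster_means(E: np.ndarray, labels: np.ndarray,
                   n_clusters: int) -> np.ndarray:
    """Mean of each row of E within each label group: (genes x clusters)."""
    out = np.empty((E.shape[0], n_clusters))
    for k in range(n_clusters):
        out[:, k] = E[:, labels == k].mean(axis=1)
    return out


def _observed_table(matrix, assignment, records, threshold):
    """All ordered cluster pairs x records, with fixed effective genes."""
    clusters = range(assignment.n_clusters)
    rows = []
    for rec in records:
        for ca, cb in itertools.product(clusters, repeat=2):
            rows.append(observed_interaction_mean(
                matrix, assignment, ca, cb, rec, threshold))
    return pd.DataFrame(rows)


def permutation_pvalues(matrix: ExpressionMatrix,
                        assignment: ClusterAssignment,
                        records: list[InteractionRecord],
                        config: PermutationConfig = PermutationConfig()
                        ) -> pd.DataFrame:
    """Permutation p-values for every ordered cluster pair and interaction.

    One global shuffle of all cluster labels per permutation serves every
    cluster pair; the expression-fraction filter and each complex's effective
    gene are decided once on the observed labels and held fixed across
    permutations.  Returns a long-format table with columns ``cluster_a,
    cluster_b, interaction, effective_a, effective_b, mean, p, q, tested,
    autocrine, n_permutations`` (p and q are NaN for untested rows).
    """
    if assignment.n_clusters < 2:
        raise ValueError("need at least 2 clusters")
    thr = config.expression_fraction_threshold
    table = _observed_table(matrix, assignment, records, thr)

    tested = table.index[table["tested"]].to_numpy()
    table["p"] = np.nan
    table["q"] = np.nan
    table["n_permutations"] = config.n_permutations
    if len(tested):
        genes_needed = sorted(set(table.loc[tested, "effective_a"])
                              | set(table.loc[tested, "effective_b"]))
        gidx = {g: i for i, g in enumerate(genes_needed)}
        E = matrix.data.loc[genes_needed].to_numpy()
        ga = table.loc[tested, "effective_a"].map(gidx).to_numpy()
        gb = table.loc[tested, "effective_b"].map(gidx).to_numpy()
        ca = table.loc[tested, "cluster_a"].to_numpy()
        cb = table.loc[tested, "cluster_b"].to_numpy()
        obs = table.loc[tested, "mean"].to_numpy()

        labels = _labels_array(matrix, assignment)
        K = assignment.n_clusters
        rng = np.random.default_rng(config.seed)
        counts = np.zeros(len(tested), dtype=np.int64)
        for _ in range(config.n_permutations):
            perm = rng.permutation(labels)
            means = _cluster_means(E, perm, K)
            stat = 0.5 * (means[ga, ca] + means[gb, cb])
            counts += stat >= obs - _TIE_ATOL
        if config.add_one:
            p = (1.0 + counts) / (1.0 + config.n_permutations)
        else:
            p = counts / config.n_permutations
        table.loc[tested, "p"] = p
        table.loc[tested, "q"] = _bh_adjust(p)
    return table


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _distinct_label_arrangements(labels: np.ndarray):
    """Yield every distinct arrangement of the label multiset, each once."""
    values, counts = np.unique(labels, return_counts=True)
    n = len(labels)

    def rec(positions: tuple[int, ...], vi: int, current: np.ndarray):
        if vi == len(values):
            yield current.copy()
            return
        for combo in itertools.combinations(positions, counts[vi]):
            nxt = tuple(p for p in positions if p not in combo)
            current[list(combo)] = values[vi]
            yield from rec(nxt, vi + 1, current)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=labels.dtype))


def exhaustive_pvalues(matrix: ExpressionMatrix, assignment: ClusterAssignment,
                       record: InteractionRecord, cluster_a: int,
                       cluster_b: int, threshold: float = 0.10) -> dict:
    """Exact permutation p-value by enumerating all label arrangements.

    Feasible only for tiny instances (<= 12 cells).  The observed arrangement
    is one of the enumerated ones, so the exact p is always >= 1/#arrangements.
    Effective genes are fixed from the observed labels, as in the sampled test.
    """
    labels = _labels_array(matrix, assignment)
    n = len(labels)
    if n > 12:
        raise ValueError(f"{n} cells: exhaustive enumeration limited to 12")
    obs_row = observed_interaction_mean(matrix, assignment, cluster_a,
                                        cluster_b, record, threshold)
    if not obs_row["tested"]:
        return {**obs_row, "p": math.nan, "n_arrangements": 0}

    E = matrix.data.loc[[obs_row["effective_a"],
                         obs_row["effective_b"]]].to_numpy()
    K = assignment.n_clusters
    obs = obs_row["mean"]
    count = total = 0
    for arr in _distinct_label_arrangements(labels):
        means = _cluster_means(E, arr, K)
        stat = 0.5 * (means[0, cluster_a] + means[1, cluster_b])
        count += stat >= obs - _TIE_ATOL
        total += 1
    return {**obs_row, "p": count / total, "n_arrangements": total}


def summarize_significant(results: pd.DataFrame, alpha: float = 0.05
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a results table into (significant-at-alpha, full) views.

    The significant view keeps tested rows with p <= alpha, sorted by cluster
    pair then p; the full table is returned unfiltered (sorted the same way)
    for downstream plotting.
    """
    full = results.sort_values(["cluster_a", "cluster_b", "p"],
                               na_position="last").reset_index(drop=True)
    sig = full[full["tested"] & (full["p"] <= alpha)].reset_index(drop=True)
    return sig, full


class CellCommunication:
    """Cluster-to-cluster communication model over a log-expression matrix.

    Parameters
    ----------
    matrix
        log(TPM+1) expression (genes x cells), QC'd and normalized.
    assignment
        Cluster labels for every cell of ``matrix``.
    records
        The ligand-receptor interaction database.
    config
        Permutation-test settings.
    """

    def __init__(self, matrix: ExpressionMatrix, assignment: ClusterAssignment,
                 records: list[InteractionRecord],
                 config: PermutationConfig = PermutationConfig()):
        if assignment.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        missing = {g for r in records for g in r.partner_a + r.partner_b
                   if g not in matrix.genes}
        if missing:
            raise KeyError(f"interaction genes absent from matrix: "
                           f"{sorted(missing)[:5]}")
        self.matrix = matrix
        self.assignment = assignment
        self.records = list(records)
        self.config = config

    def fit(self, n_permutations: int | None = None,
            seed: int | None = None) -> "CommunicationResults":
        cfg = self.config
        if n_permutations is not None:
            cfg = replace(cfg, n_permutations=n_permutations)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        table = permutation_pvalues(self.matrix, self.assignment,
                                    self.records, cfg)
        return CommunicationResults(self, table, cfg)


@dataclass
class CommunicationResults:
    """Fitted communication test: long-format results plus summaries."""

    model: CellCommunication
    table: pd.DataFrame
    config: PermutationConfig

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return summarize_significant(self.table, alpha)[0]

    def summary(self, alpha: float = 0.05) -> str:
        sig, full = summarize_significant(self.table, alpha)
        n_pairs = self.model.assignment.n_clusters ** 2
        lines = [
            "Cell-cell communication permutation test",
            "=" * 42,
            f"clusters:            {self.model.assignment.n_clusters}",
            f"interactions tested: {len(self.model.records)}",
            f"ordered pairs:       {n_pairs}",
            f"permutations:        {self.config.n_permutations}",
            f"fraction threshold:  {self.config.expression_fraction_threshold}",
            f"rows tested:         {int(full['tested'].sum())} / {len(full)}",
            f"significant (p<={alpha}): {len(sig)}",
            "",
            "Top interactions:",
        ]
        top = sig.head(10)
        for _, r in top.iterrows():
            lines.append(
                f"  {r['interaction']:<20s} {r['cluster_a']}->{r['cluster_b']}"
                f"  mean={r['mean']:.3f}  p={r['p']:.4f}")
        if not len(top):
            lines.append("  (none)")
        return "\n".join(lines)
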