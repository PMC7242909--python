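"""Synthetic Smart-seq2-style TPM data with known ground truth.

The generator emulates the structure downstream stages assume: a multi-cluster
tumor/lymph-node-like population with cluster-specific marker genes,
mitochondrial genes, ERCC spike-in rows, Bernoulli dropout, and (optionally)
planted cluster-pair-specific ligand-receptor co-expression.  Baseline
expression is log-normal on the TPM scale and every emitted column is rescaled
to sum to one million, so the matrix behaves like real TPM output.

Everything is deterministic given ``SimConfig.seed``; the accompanying
:class:`SimTruth` records the true cluster of every cell, which cells were
deliberately corrupted to fail quality control, and which ligand-receptor
signals were planted where.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import ExpressionMatrix, TPM_TOTAL

__all__ = [
    "SimConfig",
    "SimTruth",
    "PlantedSignal",
    "simulate_matrix",
    "inject_qc_failures",
    "plant_interaction",
    "partner_genes",
]


def partner_genes(partner) -> list[str]:
    """Expand a ligand/receptor partner into its subunit gene list.

    A partner is either a single gene name, a ``+``-joined complex string
    (``"R1+R2"``) or a sequence of subunit names.
    """
    if isinstance(partner, str):
        genes = [g.strip() for g in partner.split("+") if g.strip()]
    else:
        genes = [str(g) for g in partner]
    if not genes:
        raise ValueError("empty partner")
    if len(set(genes)) != len(genes):
        raise ValueError(f"duplicated subunits in partner {genes}")
    return genes


@dataclass(frozen=True)
class PlantedSignal:
    """One planted ligand->receptor signal between a source and target cluster."""

    ligand: str
    receptor: str
    source_cluster: int
    target_cluster: int
    fold: float

    @property
    def interaction_id(self) -> str:
        return f"{self.ligand}|{self.receptor}"


@dataclass
class SimConfig:
    """Parameters of the synthetic expression matrix.

    Defaults describe a small but realistic Smart-seq2 plate experiment:
    four transcriptionally distinct populations of 50 cells, strong
    (eight-fold) markers and 30% dropout — conditions under which clustering,
    marker ranking and the communication test are expected to succeed.
    """

    n_clusters: int = 4
    cells_per_cluster: int = 50
    n_genes: int = 1000
    n_marker_genes_per_cluster: int = 50
    n_mito_genes: int = 10
    n_ercc: int = 20
    dropout_rate: float = 0.3
    marker_fold: float = 8.0
    lr_signals: Sequence[tuple] = field(default_factory=tuple)
    seed: int = 0
    # baseline log-normal: per-gene log-mean ~ N(log_mean_loc, log_mean_scale),
    # per-cell log-expression ~ N(gene log-mean, cell_scale).  The wide
    # per-gene scale reproduces the heavy tail of real transcriptomes: a few
    # genes carry most of the TPM mass, the typical gene sits at a few TPM.
    log_mean_loc: float = np.log(5.0)
    log_mean_scale: float = 2.0
    cell_scale: float = 0.4
    # marker genes get their own low, narrow baseline: real cell-type markers
    # behave as on/off genes (near-silent outside their type), which is also
    # where a fold-change carries the most information under dropout; and a
    # balanced, small marker mass per cluster keeps the TPM renormalization
    # from imprinting cluster signatures on baseline genes
    marker_log_mean_loc: float = np.log(0.08)
    marker_log_mean_scale: float = 0.5
    mito_prefix: str = "mt-"
    ercc_prefix: str = "ERCC-"

    def validate(self) -> None:
        for name in ("n_clusters", "cells_per_cluster", "n_genes",
                     "n_marker_genes_per_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_mito_genes < 0 or self.n_ercc < 0:
            raise ValueError("n_mito_genes and n_ercc must be >= 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.marker_fold <= 1.0:
            raise ValueError("marker_fold must be > 1")
        if self.n_clusters * self.n_marker_genes_per_cluster > self.n_genes:
            raise ValueError("marker genes exceed endogenous gene count")
        for sig in self.lr_signals:
            if len(sig) != 5:
                raise ValueError(
                    "lr_signals entries are (ligand, receptor, source, target, fold)")
            _, _, src, tgt, _ = sig
            if not (0 <= src < self.n_clusters and 0 <= tgt < self.n_clusters):
                raise ValueError("lr_signal cluster out of range")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated matrix."""

    cell_cluster: dict[str, int]
    planted: list[PlantedSignal] = field(default_factory=list)
    low_quality_cells: set[str] = field(default_factory=set)
    marker_genes: dict[int, list[str]] = field(default_factory=dict)

    def labels(self, cells: Sequence[str]) -> np.ndarray:
        """Cluster labels aligned to ``cells`` order."""
        return np.array([self.cell_cluster[c] for c in cells], dtype=int)

    def to_dict(self) -> dict:
        return {
            "cell_cluster": self.cell_cluster,
            "planted": [dataclasses.asdict(p) for p in self.planted],
            "low_quality_cells": sorted(self.low_quality_cells),
            "marker_genes": {str(k): v for k, v in self.marker_genes.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            cell_cluster={k: int(v) for k, v in d["cell_cluster"].items()},
            planted=[PlantedSignal(**p) for p in d.get("planted", [])],
            low_quality_cells=set(d.get("low_quality_cells", [])),
            marker_genes={int(k): list(v)
                          for k, v in d.get("marker_genes", {}).items()},
        )


def _rescale_columns(values: np.ndarray) -> None:
    """In-place rescale of each column to sum to 1e6; zero columns untouched."""
    sums = values.sum(axis=0)
    nz = sums > 0
    values[:, nz] *= TPM_TOTAL / sums[nz]


def simulate_matrix(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw a TPM matrix with planted cluster structure.

    Rows are ``n_genes`` endogenous genes (named ``G0001``...), then
    ``n_mito_genes`` mitochondrial genes (``mt-1``...), then ``n_ercc``
    spike-in rows (``ERCC-0001``...).  Marker genes of cluster ``c`` are the
    ``c``-th block of endogenous genes, up-shifted ``marker_fold``-fold in
    that cluster before dropout and the final rescale to 1e6 per column.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_cells = config.n_clusters * config.cells_per_cluster
    gene_names = (
        [f"G{i + 1:04d}" for i in range(config.n_genes)]
        + [f"{config.mito_prefix}{i + 1}" for i in range(config.n_mito_genes)]
        + [f"{config.ercc_prefix}{i + 1:04d}" for i in range(config.n_ercc)]
    )
    cell_names = [f"C{i + 1:04d}" for i in range(n_cells)]
    labels = np.repeat(np.arange(config.n_clusters), config.cells_per_cluster)

    n_rows = len(gene_names)
    gene_log_mean = rng.normal(config.log_mean_loc, config.log_mean_scale, n_rows)
    n_marker_rows = config.n_clusters * config.n_marker_genes_per_cluster
    gene_log_mean[:n_marker_rows] = rng.normal(
        config.marker_log_mean_loc, config.marker_log_mean_scale, n_marker_rows)
    values = np.exp(gene_log_mean[:, None]
                    + rng.normal(0.0, config.cell_scale, (n_rows, n_cells)))

    marker_genes: dict[int, list[str]] = {}
    log_fold = np.log(config.marker_fold)
    for c in range(config.n_clusters):
        lo = c * config.n_marker_genes_per_cluster
        hi = lo + config.n_marker_genes_per_cluster
        marker_genes[c] = gene_names[lo:hi]
        values[lo:hi][:, labels == c] *= np.exp(log_fold)

    if config.dropout_rate > 0:
        # endogenous + mito genes only; spike-ins are added to every well
        n_biological = config.n_genes + config.n_mito_genes
        keep = rng.random((n_biological, n_cells)) >= config.dropout_rate
        values[:n_biological] *= keep

    _rescale_columns(values)
    matrix = ExpressionMatrix(values, genes=gene_names, cells=cell_names)
    truth = SimTruth(
        cell_cluster=dict(zip(cell_names, (int(v) for v in labels))),
        marker_genes=marker_genes,
    )

    for ligand, receptor, src, tgt, fold in config.lr_signals:
        matrix, truth = plant_interaction(
            matrix, truth, ligand, receptor, src, tgt, fold,
            seed=int(rng.integers(2**31)))
    return matrix, truth


def plant_interaction(matrix: ExpressionMatrix, truth: SimTruth,
                      ligand_partner, receptor_partner,
                      source_cluster: int, target_cluster: int,
                      fold: float, *, min_fraction: float = 0.10,
                      exclusive: bool = False,
                      seed: int = 0) -> tuple[ExpressionMatrix, SimTruth]:
    """Up-shift a ligand in a source cluster and a receptor in a target cluster.

    All subunit genes of either partner are multiplied by ``fold`` in their
    cluster's cells; if dropout left a planted gene detected in fewer than
    ``min_fraction`` of the cluster, enough zero cells are revived (set to the
    gene's in-cluster positive mean) to exceed the detection filter.  Columns
    are rescaled to 1e6 afterwards.  ``fold == 1`` is a no-op on the matrix
    but still records the signal.

    With ``exclusive=True`` the planted genes are additionally silenced
    outside their cluster, emulating the cell-type-restricted expression real
    ligands and receptors show; this is what makes a planted signal
    cluster-pair-specific rather than merely elevated.
    """
    lig_genes = partner_genes(ligand_partner)
    rec_genes = partner_genes(receptor_partner)
    clusters = set(truth.cell_cluster.values())
    for c in (source_cluster, target_cluster):
        if c not in clusters:
            raise ValueError(f"unknown cluster {c}")
    for g in lig_genes + rec_genes:
        if g not in matrix.genes:
            raise ValueError(f"unknown gene {g}")
    if fold <= 0:
        raise ValueError("fold must be positive")

    lig_str = "+".join(lig_genes)
    rec_str = "+".join(rec_genes)
    signal = PlantedSignal(lig_str, rec_str, int(source_cluster),
                           int(target_cluster), float(fold))

    out = matrix.copy()
    if fold != 1.0:
        rng = np.random.default_rng(seed)
        df = out.data
        labels = truth.labels(out.cells)
        for genes, cluster in ((lig_genes, source_cluster),
                               (rec_genes, target_cluster)):
            cols = np.flatnonzero(labels == cluster)
            need = int(np.floor(min_fraction * len(cols))) + 1
            for g in genes:
                row = df.index.get_loc(g)
                vals = df.iloc[row].to_numpy()
                expressed = np.flatnonzero(vals[cols] > 0)
                n_revive = need - len(expressed)
                if n_revive > 0:
                    silent = cols[vals[cols] == 0]
                    revive = rng.choice(silent, size=min(n_revive, len(silent)),
                                        replace=False)
                    fill = (vals[cols][expressed].mean()
                            if len(expressed) else 1.0)
                    vals[revive] = fill
                vals[cols] *= fold
                if exclusive:
                    outside = np.setdiff1d(np.arange(len(vals)), cols)
                    vals[outside] = 0.0
                df.iloc[row] = vals
        arr = df.to_numpy()
        _rescale_columns(arr)
        df.iloc[:, :] = arr

    new_truth = SimTruth(dict(truth.cell_cluster), list(truth.planted),
                         set(truth.low_quality_cells),
                         dict(truth.marker_genes))
    new_truth.planted.append(signal)
    return out, new_truth


def inject_qc_failures(matrix: ExpressionMatrix, truth: SimTruth,
                       n_low_gene: int, n_high_mito: int, *,
                       min_detected_genes: int = 1500,
                       mito_prefix: str = "mt-",
                       mito_target: float = 0.30,
                       seed: int = 0) -> tuple[ExpressionMatrix, SimTruth]:
    """Corrupt cells so they fail the quality-control filters.

    ``n_low_gene`` cells are zeroed down to fewer than ``min_detected_genes``
    detected genes; ``n_high_mito`` further cells have their mitochondrial
    share raised to ``mito_target`` (strictly above the 20% QC threshold by
    default).  Affected cells are recorded in ``truth.low_quality_cells``.
    Columns are rescaled to 1e6 so the matrix stays on the TPM scale.
    """
    if n_low_gene < 0 or n_high_mito < 0:
        raise ValueError("counts must be >= 0")
    if n_low_gene + n_high_mito > matrix.n_cells:
        raise ValueError("more QC failures requested than cells available")
    if not mito_target > 0.20:
        raise ValueError("mito_target must exceed the 0.20 QC threshold")
    mito_rows = matrix.genes_with_prefix(mito_prefix)
    if n_high_mito > 0 and not mito_rows:
        raise ValueError(f"matrix has no '{mito_prefix}' rows; cannot inject "
                         "high-mitochondrial cells")
    if n_low_gene == 0 and n_high_mito == 0:
        return matrix.copy(), dataclasses.replace(
            truth, low_quality_cells=set(truth.low_quality_cells))

    rng = np.random.default_rng(seed)
    out = matrix.copy()
    df = out.data
    eligible = [c for c in out.cells if c not in truth.low_quality_cells]
    chosen = rng.choice(len(eligible), size=n_low_gene + n_high_mito,
                        replace=False)
    low_cells = [eligible[i] for i in chosen[:n_low_gene]]
    mito_cells = [eligible[i] for i in chosen[n_low_gene:]]

    keep_n = max(1, (min_detected_genes - 1) // 2)
    for cell in low_cells:
        col = df[cell].to_numpy()
        nz = np.flatnonzero(col > 0)
        if len(nz) > keep_n:
            drop = rng.choice(nz, size=len(nz) - keep_n, replace=False)
            col[drop] = 0.0
            df[cell] = col

    mito_idx = df.index.get_indexer(mito_rows)
    for cell in mito_cells:
        col = df[cell].to_numpy()
        mito_sum = col[mito_idx].sum()
        other_sum = col.sum() - mito_sum
        want = mito_target / (1.0 - mito_target) * other_sum
        if mito_sum > 0:
            col[mito_idx] *= want / mito_sum
        else:
            col[mito_idx] = want / len(mito_idx)
        df[cell] = col

    arr = df.to_numpy()
    _rescale_columns(arr)
    df.iloc[:, :] = arr

    new_truth = SimTruth(dict(truth.cell_cluster), list(truth.planted),
                         set(truth.low_quality_cells) | set(low_cells)
                         | set(mito_cells), dict(truth.marker_genes))
    return out, new_truth
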