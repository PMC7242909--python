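"""Pair-based cell-cycle phase scoring.

The score for a phase is the proportion of that phase's marker-gene pairs
(first, second) for which the cell expresses the first gene strictly more
than the second — pairs chosen, in the original training scheme, so that the
inequality holds in the phase of interest and reverses elsewhere.  Ties
(including the all-zero cell) count as "not greater".  Phase assignment takes
the top-scoring phase once it clears 0.5; unresolved ties are "unassigned".

Pair tables are consumed from CSV (``phase,first,second``); training new
pairs from a reference compendium is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["MarkerPairSet", "load_marker_pairs", "cell_cycle_score",
           "assign_phase", "score_phases"]

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class MarkerPairSet:
    """Ordered marker-gene pairs for one cell-cycle phase."""

    phase: str
    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for first, second in self.pairs:
            if first == second:
                raise ValueError(f"degenerate pair ({first}, {second})")


def load_marker_pairs(path) -> dict[str, MarkerPairSet]:
    """Read a ``phase,first,second`` CSV into per-phase pair sets."""
    df = pd.read_csv(path)
    required = {"phase", "first", "second"}
    if not required.issubset(df.columns):
        raise ValueError(f"pair table must have columns {sorted(required)}")
    out = {}
    for phase, grp in df.groupby("phase", sort=False):
        out[str(phase)] = MarkerPairSet(
            str(phase), tuple(zip(grp["first"].astype(str),
                                  grp["second"].astype(str))))
    return out


def cell_cycle_score(matrix: ExpressionMatrix,
                     pairs: MarkerPairSet) -> pd.Series:
    """Per-cell proportion of usable pairs with expr(first) > expr(second).

    A pair is usable when both genes are present in the matrix; at least one
    usable pair is required.
    """
    genes = set(matrix.genes)
    usable = [(a, b) for a, b in pairs.pairs if a in genes and b in genes]
    if not usable:
        raise ValueError(f"no usable pairs for phase {pairs.phase!r}")
    firsts = matrix.data.loc[[a for a, _ in usable]].to_numpy()
    seconds = matrix.data.loc[[b for _, b in usable]].to_numpy()
    score = (firsts > seconds).mean(axis=0)
    return pd.Series(score, index=matrix.cells, name=pairs.phase)


def score_phases(matrix: ExpressionMatrix,
                 pair_sets: dict[str, MarkerPairSet]) -> pd.DataFrame:
    """Score every phase; columns are phases, rows are cells."""
    return pd.DataFrame({ph: cell_cycle_score(matrix, ps)
                         for ph, ps in pair_sets.items()})


def assign_phase(scores: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Label each cell with its dominant phase.

    Phases scoring strictly above ``threshold`` are preferred; the argmax
    among them wins.  If none clears the threshold the plain argmax is used.
    Exact ties for the top score yield ``"unassigned"``.
    """
    vals = scores.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    phases = np.asarray(scores.columns)
    labels = []
    for row in vals:
        above = row > threshold
        cand = row.copy()
        if above.any():
            cand = np.where(above, row, -np.inf)
        top = cand.max()
        winners = np.flatnonzero(cand == top)
        labels.append(phases[winners[0]] if len(winners) == 1 else UNASSIGNED)
    return pd.Series(labels, index=scores.index, name="phase")
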