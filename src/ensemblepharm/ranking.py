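"""Feature ranking: four statistics and score-of-4 majority voting.

Every occurrence-matrix column is scored against the binding label by
(i) the one-way ANOVA F statistic, (ii) plug-in mutual information in bits,
(iii) the Shannon entropy (nats) of the diagonal-line length distribution of
the column's recurrence plot in frame-time order, and (iv) the absolute
Spearman rank correlation.  Each method ranks the columns and keeps its
top-k; a feature is selected when all four methods keep it (voting score 4).

Conventions: MI in bits so that a balanced column identical to the labels
scores exactly 1; RQA entropy in nats with minimum diagonal length 2 and the
line of identity excluded; a column that separates the label groups
perfectly gets an infinite F sentinel and ranks above every finite value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import OccurrenceMatrix

__all__ = [
    "MethodScore",
    "VoteResult",
    "anova_f",
    "mutual_information",
    "rqa_entropy",
    "spearman_score",
    "score_matrix",
    "rank_and_vote",
]


@dataclass
class MethodScore:
    feature_id: str
    f_value: float
    mi: float
    rqa_entr: float
    spearman_abs: float


@dataclass
class VoteResult:
    feature_id: str
    per_method_rank: tuple[int, int, int, int]  # F, MI, RQA, Spearman (1-based)
    score: int
    selected: bool


def _check_two_class(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    return labels


def anova_f(column, labels) -> float:
    """One-way ANOVA F between the two label groups.

    F = MS_between / MS_within.  Zero within-group variance with a nonzero
    between-group difference returns +inf (a perfect separator belongs at
    the top of the ranking, not in an error branch); zero between-group
    variance returns 0.
    """
    labels = _check_two_class(labels)
    x = np.asarray(column, dtype=float)
    if len(x) != len(labels):
        raise ValueError("column length != label length")
    groups = [x[labels == g] for g in np.unique(labels)]
    grand = x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(x) - len(groups)
    if df_within <= 0:
        raise ValueError("too few observations for ANOVA")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        return float("inf") if ms_between > 0 else 0.0
    return float(ms_between / ms_within)


def mutual_information(column, labels) -> float:
    """Plug-in mutual information of the empirical 2x2 joint table, in bits.

    0*log(0) := 0.  Equals 1 bit when the column reproduces balanced labels
    exactly, 0 when column and labels are empirically independent.
    """
    labels = _check_two_class(labels)
    x = np.asarray(column)
    n = len(x)
    if n != len(labels):
        raise ValueError("column length != label length")
    mi = 0.0
    for xv in np.unique(x):
        px = np.mean(x == xv)
        for yv in np.unique(labels):
            pxy = np.mean((x == xv) & (labels == yv))
            py = np.mean(labels == yv)
            if pxy > 0:
                mi += pxy * np.log2(pxy / (px * py))
    return float(max(mi, 0.0))


def _diagonal_line_lengths(x: np.ndarray, l_min: int) -> list[int]:
    """Maximal diagonal line lengths (>= l_min) of the recurrence plot of a
    binary series, line of identity excluded.

    R(i, j) = 1 iff x_i == x_j; for each off-main diagonal, maximal runs of
    recurrent points are collected via run-length encoding.  A run spanning
    its entire diagonal is the trivial self-similarity of a finite segment
    (its length is set by the plot border, not the dynamics) and is
    excluded — this makes a constant series carry no line structure at all.
    """
    n = len(x)
    lengths: list[int] = []
    for off in range(1, n):
        diag = x[:-off] == x[off:]  # R(i, i+off) for i = 0..n-off-1
        if diag.all():
            continue  # border-to-border line: trivial for a finite segment
        run = 0
        for v in diag:
            if v:
                run += 1
            else:
                if run >= l_min:
                    lengths.append(run)
                run = 0
        if run >= l_min:
            lengths.append(run)
    # the plot is symmetric: count each off-diagonal twice
    return lengths + lengths


def rqa_entropy(column, l_min: int = 2) -> float:
    """Shannon entropy (nats) of the diagonal-line length distribution of a
    binary presence series' recurrence plot.

    ENTR = -sum_l p(l) ln p(l) over maximal diagonals of length >= l_min,
    excluding the line of identity and lines spanning an entire diagonal
    (border-limited, hence uninformative on a finite segment).  A constant
    series therefore has no qualifying lines and ENTR = 0, as does any
    series without repeated interior structure.
    """
    x = np.asarray(column)
    if len(x) < l_min + 1:
        raise ValueError(f"series length {len(x)} < l_min + 1 = {l_min + 1}")
    lengths = _diagonal_line_lengths(x, l_min)
    if not lengths:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def spearman_score(column, labels) -> float:
    """|Spearman rho| with average ranks for ties; 0 (degenerate) for a
    constant column."""
    _check_two_class(labels)
    x = np.asarray(column, dtype=float)
    if np.all(x == x[0]):
        return 0.0
    rho = stats.spearmanr(x, np.asarray(labels, dtype=float)).statistic
    return float(abs(rho))


def score_matrix(matrix: OccurrenceMatrix, l_min: int = 2) -> pd.DataFrame:
    """All four statistics for every column, as a feature-indexed frame."""
    labels = _check_two_class(matrix.labels)
    rows = []
    for fid in matrix.data.columns:
        col = matrix.data[fid].to_numpy()
        rows.append({
            "feature_id": fid,
            "f_value": anova_f(col, labels),
            "mi": mutual_information(col, labels),
            "rqa_entr": rqa_entropy(col, l_min=l_min),
            "spearman_abs": spearman_score(col, labels),
        })
    return pd.DataFrame(rows).set_index("feature_id")


_METHODS = ("f_value", "mi", "rqa_entr", "spearman_abs")


def rank_and_vote(matrix: OccurrenceMatrix, k: int,
                  l_min: int = 2) -> pd.DataFrame:
    """Rank every non-constant column by each method and vote.

    Zero-variance columns are dropped first (they carry no signal and break
    the rank statistics).  Each method sorts descending by its statistic,
    ties broken by ascending feature id, and keeps its top-k; ``score``
    counts the methods keeping the feature and ``selected`` marks score 4 —
    the intersection of the four top-k sets.

    Returns a frame with the four statistics, the four 1-based ranks,
    ``score`` and ``selected``, sorted by descending score then feature id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    variances = matrix.data.var(axis=0)
    keep = [c for c in matrix.data.columns if variances[c] > 0]
    if k > len(keep):
        raise ValueError(
            f"k={k} exceeds the {len(keep)} non-constant columns")
    sub = OccurrenceMatrix(
        matrix.data[keep].copy(), matrix.labels,
        {c: matrix.frequencies[c] for c in keep},
        {c: matrix.features[c] for c in keep})
    scores = score_matrix(sub, l_min=l_min)
    table = scores.copy()
    in_topk = pd.DataFrame(index=scores.index)
    for method in _METHODS:
        order = sorted(scores.index,
                       key=lambda f: (-scores.at[f, method], f))
        ranks = {f: i + 1 for i, f in enumerate(order)}
        table[f"rank_{method}"] = [ranks[f] for f in scores.index]
        in_topk[method] = [ranks[f] <= k for f in scores.index]
    table["score"] = in_topk.sum(axis=1).astype(int)
    table["selected"] = table["score"] == 4
    # descending score, ties by ascending feature id (stable sort)
    return table.sort_index().sort_values("score", ascending=False,
                                          kind="mergesort")


def vote_results(table: pd.DataFrame) -> list[VoteResult]:
    """Convert a rank_and_vote table into VoteResult records."""
    out = []
    for fid, row in table.iterrows():
        out.append(VoteResult(
            feature_id=str(fid),
            per_method_rank=tuple(int(row[f"rank_{m}"]) for m in _METHODS),
            score=int(row["score"]),
            selected=bool(row["selected"])))
    return out
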