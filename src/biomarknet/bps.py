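"""The Biomarker Probability Score: rank-based fusion of model probabilities.

Different tree-ensemble models (and the same model trained on different
networks) emit class-1 probabilities on incomparable scales.  The BPS
makes them commensurable by ranking: within each prediction column the m
pairs are ranked by descending class-1 probability (rank 0 = most
probable; ties receive the arithmetic mean of the ranks they span), and

    BPS(p) = 1 - (mean over the n predictions of R[p, i]) / (m - 1)

so a pair that is top-ranked by every prediction scores exactly 1 and a
pair bottom-ranked by every prediction scores exactly 0.  Because ranking
discards the probability scale, the score is invariant under any strictly
monotone transformation applied within a column, and the mean BPS over
all pairs is always 1/2.

Ranking direction: descending, 0-indexed.  An ascending convention is
exposed behind a flag for sensitivity checks; it mirrors the score
(BPS_asc = 1 - BPS_desc) and breaks the two endpoint identities above,
which is why descending is the default.

A pair is called a biomarker candidate when its BPS strictly exceeds the
threshold (default 0.5) in at least one annotation scope; the stricter
all-scopes flag is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BPSTable",
    "rank_descending_tie_avg",
    "compute_bps",
    "build_bps_table",
    "classify_by_bps",
    "bps_vs_labels",
]


class BPSError(ValueError):
    pass


def rank_descending_tie_avg(probabilities: Sequence[float],
                            ascending: bool = False) -> np.ndarray:
    """Tie-averaged 0-indexed ranks, highest probability first.

    ``[0.9, 0.5, 0.5, 0.1] -> [0, 1.5, 1.5, 3]``.  With ``ascending`` the
    lowest probability gets rank 0 (sensitivity-check convention).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or len(p) < 2:
        raise BPSError("need a 1-d vector of at least 2 probabilities")
    data = p if ascending else -p
    return stats.rankdata(data, method="average") - 1.0


def compute_bps(prob_matrix, ascending: bool = False) -> np.ndarray:
    """BPS per pair from an (m pairs x n predictions) probability matrix.

    BPS(p) = 1 - (sum_i R[p,i] / n) / (m - 1), with tie-averaged
    descending 0-indexed ranks per column.
    """
    mat = np.asarray(prob_matrix, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.ndim != 2:
        raise BPSError("probability matrix must be 2-dimensional")
    m, n = mat.shape
    if m < 2 or n < 1:
        raise BPSError(f"need >=2 pairs and >=1 prediction, got {mat.shape}")
    if np.isnan(mat).any():
        raise BPSError("probability matrix contains missing cells; drop "
                       "incomplete prediction columns first")
    ranks = np.column_stack([
        rank_descending_tie_avg(mat[:, j], ascending=ascending)
        for j in range(n)])
    return 1.0 - ranks.mean(axis=1) / (m - 1)


@dataclass
class BPSTable:
    """Per-pair probabilities, ranks, and BPS for one annotation scope."""

    pairs: pd.MultiIndex | pd.Index
    probabilities: pd.DataFrame
    ranks: pd.DataFrame
    bps: pd.Series
    annotation_scope: str = "all"


def build_bps_table(probabilities: pd.DataFrame, annotation_scope: str = "all",
                    ascending: bool = False) -> BPSTable:
    """Rank every prediction column and fuse them into one BPS per pair."""
    mat = probabilities.to_numpy(float)
    bps = compute_bps(mat, ascending=ascending)
    ranks = pd.DataFrame(
        {col: rank_descending_tie_avg(probabilities[col].to_numpy(float),
                                      ascending=ascending)
         for col in probabilities.columns},
        index=probabilities.index)
    return BPSTable(pairs=probabilities.index, probabilities=probabilities,
                    ranks=ranks, bps=pd.Series(bps, index=probabilities.index,
                                               name="bps"),
                    annotation_scope=annotation_scope)


def classify_by_bps(tables: Mapping[str, BPSTable],
                    threshold: float = 0.5) -> pd.DataFrame:
    """Candidate calls across annotation scopes.

    A pair is a candidate when BPS > threshold (strict) in at least one
    scope; ``all_scopes`` flags pairs above the threshold in every scope
    that covers them.  Pairs missing from a scope are recorded as NaN in
    that scope's column and do not count against the all-scopes flag.
    """
    if not tables:
        raise BPSError("no BPS tables supplied")
    cols = {f"bps_{scope}": tab.bps for scope, tab in sorted(tables.items())}
    df = pd.DataFrame(cols)
    bps_values = df.to_numpy(float)
    above = bps_values > threshold
    present = ~np.isnan(bps_values)
    df["candidate"] = (above & present).any(axis=1)
    df["all_scopes"] = np.where(present.any(axis=1),
                                (above | ~present).all(axis=1), False)
    df["n_scopes_present"] = present.sum(axis=1)
    return df


@dataclass
class ConcordanceRecord:
    n_pairs: int
    n_misclassified: int
    misclassification_rate: float
    spearman_rho: float
    bps: np.ndarray


def bps_vs_labels(probabilities, labels, threshold: float = 0.5,
                  ) -> ConcordanceRecord:
    """Concordance of held-out-probability BPS with the training labels.

    ``probabilities`` is an (m x n) matrix of held-out class-1
    probabilities (e.g. one column per model from leave-one-out
    cross-validation).  Pairs with BPS > threshold are called class 1;
    the record reports how many calls disagree with the labels and the
    Spearman correlation of BPS with the label.
    """
    mat = np.asarray(probabilities, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    y = np.asarray(labels, dtype=float)
    if len(y) != mat.shape[0]:
        raise BPSError(f"{mat.shape[0]} probability rows vs {len(y)} labels")
    bps = compute_bps(mat)
    calls = (bps > threshold).astype(float)
    n_wrong = int(np.sum(calls != y))
    rho = float(stats.spearmanr(bps, y).statistic)
    return ConcordanceRecord(n_pairs=len(y), n_misclassified=n_wrong,
                             misclassification_rate=n_wrong / len(y),
                             spearman_rho=rho, bps=bps)
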