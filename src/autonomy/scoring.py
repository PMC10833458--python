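"""Composite gene-signature scoring and two-group separation statistics.

Each gene's expression is normalised to a modified Z-score centred on its
StepMiner threshold, z = (expr - SThr) / (3 * stddev), where stddev is the
gene's sample standard deviation across all samples of the dataset. The
composite score of a signature sums these per-gene scores, with
down-regulated genes subtracted (``signed`` mode, the default) or simply
added (``sum_all`` mode). Separation of two sample groups by the composite
score is reported as ROC-AUC together with Welch's unequal-variance t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import ExpressionMatrix, GeneSignature
from .stepminer import gene_threshold

logger = logging.getLogger(__name__)


def modified_zscore(expr, sthr: float, stddev: float):
    """Threshold-centred modified Z-score: (expr - sthr) / (3 * stddev)."""
    if stddev <= 0:
        raise ValueError("stddev must be > 0")
    return (np.asarray(expr, dtype=float) - sthr) / (3.0 * stddev)


def gene_zscores(matrix: ExpressionMatrix, gene: str) -> np.ndarray | None:
    """Modified Z-scores of one gene across all samples; None if stddev is 0."""
    values = matrix.gene(gene)
    sd = float(np.std(values, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        logger.warning("gene %s has zero variance; excluded from scoring", gene)
        return None
    return modified_zscore(values, gene_threshold(matrix, gene), sd)


def composite_score(matrix: ExpressionMatrix, signature: GeneSignature,
                    mode: str = "signed") -> pd.Series:
    """Per-sample composite score of a signature.

    ``signed`` (default): sum of up-gene z-scores minus sum of down-gene
    z-scores. ``sum_all``: plain sum over all signature genes regardless of
    direction. Signature genes absent from the matrix are dropped with a
    logged list; zero usable genes is an error.
    """
    if mode not in ("signed", "sum_all"):
        raise ValueError(f"unknown mode {mode!r}")
    present = [(g, d) for g, d in signature.entries if g in matrix.values.index]
    missing = [g for g, _ in signature.entries if g not in matrix.values.index]
    if missing:
        logger.warning("signature %s: %d gene(s) absent from matrix: %s",
                       signature.name, len(missing), missing)
    total = np.zeros(matrix.n_samples)
    used = 0
    for gene, direction in present:
        z = gene_zscores(matrix, gene)
        if z is None:
            continue
        total += z * (direction if mode == "signed" else 1)
        used += 1
    if used == 0:
        raise ValueError(
            f"signature {signature.name!r}: no usable genes in matrix "
            f"(missing: {missing})")
    return pd.Series(total, index=matrix.sample_ids, name="score")


def roc_auc(scores, labels) -> float:
    """ROC-AUC of the positive class having higher scores.

    Equals the Mann-Whitney U statistic normalised by n1*n2, with tied
    score pairs counted 1/2.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(labels, scores))


def welch_t(x, y) -> tuple[float, float]:
    """Welch's two-sample t-test (unpaired, unequal variance); returns (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    res = stats.ttest_ind(x, y, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both groups constant
        if x.mean() == y.mean():
            return 0.0, 1.0
        return (np.inf if x.mean() > y.mean() else -np.inf), 0.0
    return t, p


@dataclass
class ScoreReport:
    """Composite scores plus group-separation statistics for one comparison."""

    scores: pd.Series          # per-sample composite score
    groups: pd.Series          # per-sample group label, aligned to scores
    positive: str              # label treated as the positive class
    auc: float
    direction: str             # "up" if the positive group scores higher
    t: float
    p: float

    @property
    def ordering(self) -> list[str]:
        """Sample ids sorted by non-decreasing score."""
        return list(self.scores.sort_values(kind="stable").index)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "group": self.groups}
                            ).loc[self.ordering]


def score_and_classify(matrix: ExpressionMatrix, signature: GeneSignature,
                       group_field: str, positive: str | None = None,
                       mode: str = "signed") -> ScoreReport:
    """Score a signature and measure two-group separation (ROC-AUC + Welch t).

    ``positive`` selects which group label is the positive class for the
    AUC; by default the lexicographically larger of the two labels. The
    Welch statistic is positive minus negative group.
    """
    scores = composite_score(matrix, signature, mode=mode)
    groups = matrix.groups(group_field)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"group field {group_field!r} must define exactly two "
                         f"groups, found {labels}")
    if positive is None:
        positive = labels[-1]
    elif positive not in labels:
        raise ValueError(f"positive label {positive!r} not among {labels}")
    pos_scores = scores[groups == positive].to_numpy()
    neg_scores = scores[groups != positive].to_numpy()
    auc = roc_auc(scores.to_numpy(), (groups == positive).to_numpy().astype(int))
    t, p = welch_t(pos_scores, neg_scores)
    direction = "up" if pos_scores.mean() >= neg_scores.mean() else "down"
    return ScoreReport(scores=scores, groups=groups, positive=positive,
                       auc=auc, direction=direction, t=t, p=p)


def plot_scores(report: ScoreReport, path) -> None:
    """Minimal violin-style plot of composite scores by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = sorted(report.groups.unique())
    data = [report.scores[report.groups == lab].to_numpy() for lab in labels]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.violinplot(data, showmeans=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("composite score")
    ax.set_title(f"AUC={report.auc:.3f}  p={report.p:.2e}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
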