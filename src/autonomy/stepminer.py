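"""StepMiner: adaptive one-step regression over ordered value series.

A step function with a single transition at position k fits the first k
values with their mean and the remaining n-k values with theirs. The fit
evaluates every possible split 1..n-1 and keeps the one minimising the sum
of squared residuals. The associated regression statistic is

    F = [ sum_i (Xhat_i - Xbar)^2 / (m - 1) ] / [ sum_i (X_i - Xhat_i)^2 / (n - m) ]

with m = 3 model degrees of freedom for the one-step model (two segment
means plus the step position).

Applied to a gene's expression values sorted ascending across samples, the
midpoint of the two fitted segment means is the per-gene threshold (SThr)
separating "low" from "high" expression; `binarize` turns a whole matrix
into high(1)/low(0) calls with an optional intermediate margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: model degrees of freedom of the one-step fit: two means + one step position
M_STEP = 3


@dataclass(frozen=True)
class StepFit:
    """Result of fitting a one-step function to an ordered series."""

    n: int
    k: int                 # left segment = first k values
    mu_left: float
    mu_right: float
    sse: float
    fstat: float           # nan when undefined (no step, or n <= m)
    sthr: float            # midpoint of segment means; grand mean when no step
    no_step: bool = False  # zero total variance: no step exists
    m: int = M_STEP

    @property
    def fitted(self) -> np.ndarray:
        """Piecewise-constant fitted values (mu_left × k, then mu_right)."""
        return np.concatenate([np.full(self.k, self.mu_left),
                               np.full(self.n - self.k, self.mu_right)])


def fit_step(series) -> StepFit:
    """Fit a one-step function, minimising SSE over all split positions.

    Ties between equal-SSE splits break toward the smallest k, so results
    are reproducible. A zero-variance series is flagged ``no_step`` with
    the threshold at the (constant) grand mean.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    xbar = x.mean()
    tss = float(np.sum((x - xbar) ** 2))
    if tss == 0.0:
        return StepFit(n=n, k=1, mu_left=xbar, mu_right=xbar, sse=0.0,
                       fstat=float("nan"), sthr=xbar, no_step=True)

    # between-segment sum of squares for every split; maximising it
    # minimises the SSE. argmax takes the first (smallest-k) maximum.
    csum = np.cumsum(x)
    k_all = np.arange(1, n)
    left_mean = csum[:-1] / k_all
    right_mean = (csum[-1] - csum[:-1]) / (n - k_all)
    between = k_all * (left_mean - xbar) ** 2 + (n - k_all) * (right_mean - xbar) ** 2
    k = int(k_all[np.argmax(between)])

    mu_left = float(x[:k].mean())
    mu_right = float(x[k:].mean())
    sse = float(np.sum((x[:k] - mu_left) ** 2) + np.sum((x[k:] - mu_right) ** 2))
    explained = float(np.sum((np.concatenate(
        [np.full(k, mu_left), np.full(n - k, mu_right)]) - xbar) ** 2))

    if n <= M_STEP:
        fstat = float("nan")
    elif sse == 0.0:
        fstat = float("inf")
    else:
        fstat = (explained / (M_STEP - 1)) / (sse / (n - M_STEP))

    return StepFit(n=n, k=k, mu_left=mu_left, mu_right=mu_right, sse=sse,
                   fstat=fstat, sthr=(mu_left + mu_right) / 2.0)


def gene_threshold(matrix: ExpressionMatrix, gene: str) -> float:
    """StepMiner threshold for one gene: sort its values ascending, fit, return SThr.

    Sorting makes the threshold independent of sample order; a constant
    gene yields its constant value with a logged warning.
    """
    values = matrix.gene(gene)
    if values.size < 2:
        raise ValueError(f"gene {gene!r}: need at least 2 samples")
    fit = fit_step(np.sort(values))
    if fit.no_step:
        logger.warning("gene %s has zero variance; no step (threshold = %g)",
                       gene, fit.sthr)
    return fit.sthr


def fit_gene(matrix: ExpressionMatrix, gene: str) -> StepFit:
    """Full step fit on a gene's ascending-sorted values."""
    values = matrix.gene(gene)
    if values.size < 2:
        raise ValueError(f"gene {gene!r}: need at least 2 samples")
    return fit_step(np.sort(values))


def threshold_table(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene thresholds for a whole matrix: gene_id, sthr, fstat, no_step."""
    rows = []
    for gene in matrix.gene_ids:
        fit = fit_step(np.sort(matrix.gene(gene)))
        rows.append((gene, fit.sthr, fit.fstat, fit.no_step))
    return pd.DataFrame(rows, columns=["gene_id", "sthr", "fstat", "no_step"]
                        ).set_index("gene_id")


def binarize(matrix: ExpressionMatrix, margin: float = 0.0) -> pd.DataFrame:
    """Ternary high/low/intermediate calls against per-gene StepMiner thresholds.

    value > sthr + margin -> 1 (high); value <= sthr - margin -> 0 (low);
    otherwise NaN (intermediate). With the default margin of 0 the output
    is strictly binary and values exactly at the threshold call low.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    vals = matrix.values.to_numpy(dtype=float)
    sthr = np.array([gene_threshold(matrix, g) for g in matrix.gene_ids])[:, None]
    out = np.full(vals.shape, np.nan)
    out[vals > sthr + margin] = 1.0
    out[vals <= sthr - margin] = 0.0
    return pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
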