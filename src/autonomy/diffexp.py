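"""Differential expression, BH adjustment, signature derivation and ORA.

Per-gene testing is Welch's t on log2 values (the matrices this package
consumes are log-normalised CPM, so a location test on the log scale is the
matching model; count-based dispersion modelling is deliberately out of
scope). The fold-change/significance filter turns a DEG table into a
directional :class:`~autonomy.io.GeneSignature`, and a database-free
hypergeometric over-representation test scores user-supplied GMT gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSignature


def per_gene_test(matrix: ExpressionMatrix, group_field: str,
                  group_a: str | None = None,
                  group_b: str | None = None) -> pd.DataFrame:
    """Welch's t-test per gene between two sample groups.

    logFC is the mean difference of log2 values, group A minus group B
    (the first-listed group is the reference orientation). Returns a
    DataFrame indexed by gene with columns logFC, t, p.
    """
    groups = matrix.groups(group_field)
    labels = sorted(groups.unique())
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, found {labels}")
        group_a, group_b = (group_a or labels[0]), (group_b or labels[1])
        if group_a == group_b:
            group_a, group_b = labels
    for lab in (group_a, group_b):
        if lab not in set(groups):
            raise ValueError(f"group {lab!r} not present in {group_field!r}")
    mask_a = (groups == group_a).to_numpy()
    mask_b = (groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    vals = matrix.values.to_numpy(dtype=float)
    a, b = vals[:, mask_a], vals[:, mask_b]
    logfc = a.mean(axis=1) - b.mean(axis=1)
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant within both groups: t/p are NaN; equal means -> no
    # evidence (p = 1), unequal constant means -> infinitely strong (p = 0)
    degenerate = np.isnan(t)
    t[degenerate & (logfc == 0)] = 0.0
    p[degenerate & (logfc == 0)] = 1.0
    t[degenerate & (logfc != 0)] = np.sign(logfc[degenerate & (logfc != 0)]) * np.inf
    p[degenerate & (logfc != 0)] = 0.0
    return pd.DataFrame({"logFC": logfc, "t": t, "p": p}, index=matrix.values.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_table(matrix: ExpressionMatrix, group_field: str,
              lfc_cut: float = 5.0, padj_cut: float = 0.01,
              group_a: str | None = None, group_b: str | None = None) -> pd.DataFrame:
    """Full DEG table: logFC, raw p, BH-adjusted p and up/down/ns direction."""
    table = per_gene_test(matrix, group_field, group_a=group_a, group_b=group_b)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    direction = np.where(
        (table["logFC"] > lfc_cut) & (table["padj"] < padj_cut), "up",
        np.where((table["logFC"] < -lfc_cut) & (table["padj"] < padj_cut),
                 "down", "ns"))
    table["direction"] = direction
    return table


def filter_degs(table: pd.DataFrame, lfc_cut: float = 5.0,
                padj_cut: float = 0.01, name: str = "derived") -> GeneSignature:
    """Signature of genes passing |logFC| > lfc_cut and padj < padj_cut.

    Up genes get direction +1, down genes -1; genes are kept in table order.
    """
    sig = (table["padj"] < padj_cut)
    up = table.index[(table["logFC"] > lfc_cut) & sig]
    down = table.index[(table["logFC"] < -lfc_cut) & sig]
    entries = [(g, 1) for g in up] + [(g, -1) for g in down]
    if not entries:
        raise ValueError(
            f"no genes pass |logFC| > {lfc_cut} and padj < {padj_cut}")
    return GeneSignature(name=name, entries=entries)


def overrepresentation(hits, universe, collection: dict[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` against GMT sets.

    Each set is intersected with the universe; the p-value is the one-sided
    upper tail P(overlap >= observed). BH adjustment is applied across sets.
    """
    hits = set(hits)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)[:5]}")
    m_univ, n_hits = len(universe), len(hits)
    rows = []
    for set_name, members in collection.items():
        members_in = members & universe
        overlap = len(members_in & hits)
        # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|set|, N=|hits|)
        p = float(stats.hypergeom.sf(overlap - 1, m_univ, len(members_in), n_hits))
        rows.append((set_name, len(members_in), overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]
                       ).set_index("set")
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out
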