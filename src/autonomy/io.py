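"""Reading and writing of expression matrices, signatures, annotations and gene sets.

All downstream stages consume one canonical in-memory representation:
:class:`ExpressionMatrix`, a genes-by-samples matrix of log2-scale values with
per-sample annotations. Matrices are genes-in-rows; a transposed input must be
declared explicitly — there is no auto-detection, because silently transposing
a matrix is a classic corruption mode in expression analysis.

Gene identifiers are opaque, case-sensitive strings; no symbol/alias
resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_DIRECTION_TOKENS = {
    "up": 1, "+1": 1, "1": 1, "+": 1,
    "down": -1, "-1": -1, "-": -1,
}


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values plus per-sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids. Log2 scale
        unless ``log_scale`` is False (raw counts awaiting :func:`log_cpm`).
    annotations
        DataFrame indexed by sample id; may carry a group label and
        survival fields. Optional.
    log_scale
        Whether ``values`` are already on log scale.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame | None = None
    log_scale: bool = True

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_genes = idx[idx.duplicated()].unique().tolist()
        if dup_genes:
            raise ValueError(f"duplicate gene id(s): {dup_genes}")
        dup_samples = cols[cols.duplicated()].unique().tolist()
        if dup_samples:
            raise ValueError(f"duplicate sample id(s): {dup_samples}")
        if self.annotations is not None:
            missing = [s for s in cols if s not in self.annotations.index]
            if missing:
                raise ValueError(f"samples missing from annotations: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene(self, gene_id: str) -> np.ndarray:
        if gene_id not in self.values.index:
            raise KeyError(f"gene {gene_id!r} not present in matrix")
        return self.values.loc[gene_id].to_numpy(dtype=float)

    def groups(self, group_field: str) -> pd.Series:
        """Per-sample group labels from the annotation table."""
        if self.annotations is None:
            raise ValueError("matrix has no annotations")
        if group_field not in self.annotations.columns:
            raise KeyError(f"annotation field {group_field!r} not found")
        return self.annotations.loc[self.sample_ids, group_field]


@dataclass
class GeneSignature:
    """A named list of (gene, direction) pairs defining a composite score.

    Direction is +1 for up-regulated genes and -1 for down-regulated ones.
    """

    name: str
    entries: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"signature {self.name!r} has no entries")
        genes = [g for g, _ in self.entries]
        seen: set[str] = set()
        for g in genes:
            if g in seen:
                raise ValueError(f"duplicate gene in signature: {g!r}")
            seen.add(g)
        for g, d in self.entries:
            if d not in (1, -1):
                raise ValueError(f"direction for {g!r} must be +1 or -1, got {d}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def up_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == 1]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, d in self.entries if d == -1]

    def __len__(self) -> int:
        return len(self.entries)


def read_expression(path, *, dialect: str = "tsv_genes_in_rows",
                    log_scale: bool = True,
                    annotations: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header sample ids).

    ``log_scale`` records whether the body is already log2 scale; raw counts
    should be passed through :func:`log_cpm` before analysis.
    """
    if dialect != "tsv_genes_in_rows":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise ValueError(f"no header: {path} is empty") from None
    if df.shape[1] == 0:
        raise ValueError(f"no sample columns in {path}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    # locate the first non-numeric cell precisely for the error message
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"non-numeric value {df[col].iloc[i]!r} at gene {df.index[i]!r}, "
                f"sample {col!r} (row {i + 1}, column {j + 1})")
        df[col] = coerced
    return ExpressionMatrix(values=df.astype(float), annotations=annotations,
                            log_scale=log_scale)


def write_expression(matrix: ExpressionMatrix, path, *, float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format=float_format)


def log_cpm(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Log-normalised counts per million: scale each sample to 1e6, then log2(x + pc).

    The pseudocount (default 1.0) keeps zero counts finite.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts = matrix.values.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    colsums = counts.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [matrix.sample_ids[i] for i in zero]
        raise ValueError(f"all-zero column(s): {names}")
    cpm = counts / colsums * 1e6
    out = pd.DataFrame(np.log2(cpm + pseudocount),
                       index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=out, annotations=matrix.annotations, log_scale=True)


def read_signature(path, name: str | None = None) -> GeneSignature:
    """Read a two-column signature file: gene_id, direction in {up, down, +1, -1}."""
    entries: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            gene, token = parts[0].strip(), parts[1].strip().lower()
            if token not in _DIRECTION_TOKENS:
                raise ValueError(f"{path}:{lineno}: unknown direction token {parts[1]!r}")
            entries.append((gene, _DIRECTION_TOKENS[token]))
    if name is None:
        name = str(path)
    return GeneSignature(name=name, entries=entries)


def write_signature(signature: GeneSignature, path) -> None:
    with open(path, "w") as fh:
        for gene, d in signature.entries:
            fh.write(f"{gene}\t{'up' if d == 1 else 'down'}\n")


def read_annotations(path) -> pd.DataFrame:
    """Per-sample annotation TSV keyed by sample_id (first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    dups = df.index[df.index.duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"duplicate sample id(s) in annotations: {dups}")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set collection: set name, description, member genes (tab-separated)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name = parts[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def read_edge_list(path, *, score_min: float | None = None) -> list[tuple[str, str]]:
    """Two-column undirected edge list (optional third score column).

    When ``score_min`` is given, edges with score below it are dropped;
    otherwise a score column is ignored.
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
            a, b = parts[0], parts[1]
            if score_min is not None:
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: score_min set but no score column")
                try:
                    score = float(parts[2])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from None
                if score < score_min:
                    continue
            edges.append((a, b))
    return edges


def write_edge_list(edges, path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
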