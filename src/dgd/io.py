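"""Count-matrix and gene-list IO.

Counts travel as tab-separated text (first column = sample or gene IDs
per orientation) or as matrix-market sparse files with companion gene/
sample ID lists. In memory a ``CountMatrix`` is always samples × genes
with unique string IDs and an optional tissue label per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("dgd")

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_gene_list",
    "align_genes",
]


@dataclass
class CountMatrix:
    """Integer samples × genes matrix with IDs and optional tissue labels."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    tissues: list[str] | None = None
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, g = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != g:
            raise ValueError("ID lists must match matrix shape")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene IDs")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample IDs")
        if np.any(self.values < 0):
            raise ValueError("negative counts")
        if not np.issubdtype(self.values.dtype, np.integer):
            if np.any(self.values != np.floor(self.values)):
                bad = np.argwhere(self.values != np.floor(self.values))[0]
                raise ValueError(
                    f"non-integer count at sample row {bad[0]}, gene column {bad[1]}"
                )
            self.values = self.values.astype(np.int64)
        if self.tissues is not None and len(self.tissues) != n:
            raise ValueError("tissue labels must match sample count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.values.sum(axis=1)

    @property
    def sample_scales(self) -> np.ndarray:
        """Arithmetic mean count per sample — the model's scaling factor."""
        return self.values.mean(axis=1)


def read_counts(
    path,
    orientation: str = "samples-by-genes",
    fmt: str = "delimited",
    gene_file=None,
    sample_file=None,
    tissue_file=None,
) -> CountMatrix:
    """Read a count matrix from delimited text or matrix-market.

    ``orientation`` names the layout ON DISK; the result is always
    samples × genes. Matrix-market input requires companion one-ID-per-
    line gene and sample files. ``tissue_file`` optionally supplies a
    two-column TSV (sample ID, tissue).
    """
    if orientation not in ("samples-by-genes", "genes-by-samples"):
        raise ValueError(f"unknown orientation '{orientation}'")
    if fmt == "delimited":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if orientation == "genes-by-samples":
            df = df.T
        values = df.to_numpy()
        sample_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
    elif fmt == "matrix-market":
        if gene_file is None or sample_file is None:
            raise ValueError("matrix-market input needs gene and sample ID files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        if orientation == "genes-by-samples":
            mat = mat.T
        gene_ids = read_gene_list(gene_file)
        sample_ids = read_gene_list(sample_file)
        values = np.asarray(mat)
    else:
        raise ValueError(f"unknown format '{fmt}'")

    tissues = None
    metadata = None
    if tissue_file is not None:
        meta = pd.read_csv(tissue_file, sep="\t", index_col=0, comment="#")
        missing = set(meta.index.astype(str)) - set(sample_ids)
        if missing:
            raise ValueError(f"metadata rows for unknown samples: {sorted(missing)[:5]}")
        metadata = meta
        col = meta.columns[0]
        tissues = [
            str(meta.loc[s, col]) if s in meta.index else ""
            for s in sample_ids
        ]
    return CountMatrix(values, gene_ids, sample_ids, tissues, metadata)


def write_counts(cm: CountMatrix, path, header_comment: str | None = None) -> None:
    """Write samples × genes TSV (first column: sample IDs)."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df = pd.DataFrame(cm.values, index=cm.sample_ids, columns=cm.gene_ids)
        df.index.name = "sample_id"
        df.to_csv(fh, sep="\t")


def read_gene_list(path) -> list[str]:
    """One ID per line; blank lines and '#' comments skipped."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def align_genes(
    cm: CountMatrix, model_genes: list[str], strict: bool = True
) -> CountMatrix:
    """Reorder columns to the model's gene order.

    Genes missing from the input are a hard error in strict mode, or
    zero-filled with a logged count otherwise; input genes unknown to the
    model are dropped with a logged count.
    """
    if len(set(model_genes)) != len(model_genes):
        raise ValueError("model gene list contains duplicates")
    have = {g: i for i, g in enumerate(cm.gene_ids)}
    missing = [g for g in model_genes if g not in have]
    extra = len(cm.gene_ids) - (len(model_genes) - len(missing))
    if missing and strict:
        raise ValueError(
            f"{len(missing)} model genes missing from input, e.g. {missing[:5]}"
        )
    out = np.zeros((cm.n_samples, len(model_genes)), dtype=cm.values.dtype)
    for j, g in enumerate(model_genes):
        if g in have:
            out[:, j] = cm.values[:, have[g]]
    if missing:
        logger.warning("zero-filled %d genes missing from input", len(missing))
    if extra:
        logger.info("dropped %d genes not in the model", extra)
    return CountMatrix(out, list(model_genes), list(cm.sample_ids), cm.tissues,
                       cm.metadata)
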