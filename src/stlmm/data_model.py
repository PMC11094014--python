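"""Container and I/O for a single spatial transcriptomics sample.

A sample couples a gene x unit count matrix with per-unit planar coordinates
and a per-unit tissue-domain label (from histopathology or clustering).
Counts are library-size normalized and natural-log transformed before any
model fitting; coordinates are used in whatever planar length unit the
platform reports (microns, pixels, array steps) — only relative distances
matter downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.io import mmread
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "STSample",
    "SampleFormatError",
    "EmptySampleError",
    "load_sample",
    "normalize",
    "distance_matrix",
    "stratify_genes",
    "write_sample",
    "write_expr",
    "sample_summary",
]


class SampleFormatError(ValueError):
    """An input file could not be parsed into the expected table."""


class EmptySampleError(ValueError):
    """No units survive the three-way join of counts, coords and labels."""


@dataclass
class STSample:
    """One spatial transcriptomics sample.

    Attributes
    ----------
    unit_ids : list of str
        Unique identifiers of sampling units (spots / ROIs / cells).
    coords : ndarray, shape (n_units, 2)
        Planar (x, y) positions, arbitrary but consistent length units.
    counts : ndarray, shape (n_genes, n_units)
        Non-negative integer counts.
    gene_ids : list of str
        Unique gene identifiers.
    labels : ndarray of str, shape (n_units,)
        Tissue-domain / cluster assignment per unit.
    expr : ndarray or None
        Normalized log-expression, same shape as ``counts``; ``None`` until
        :func:`normalize` is called (synthetic samples may fill it directly).
    """

    unit_ids: list[str]
    coords: np.ndarray
    counts: np.ndarray | None
    gene_ids: list[str]
    labels: np.ndarray
    expr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.unit_ids)
        if self.coords.shape != (n, 2):
            raise ValueError(f"coords must be (n_units, 2); got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        if self.labels.shape != (n,):
            raise ValueError("labels length must equal number of units")
        if any(not isinstance(l, str) or l == "" for l in self.labels):
            raise ValueError("every label must be a non-empty string")
        if len(set(self.unit_ids)) != n:
            raise ValueError("unit_ids contain duplicates")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids contain duplicates")
        if self.counts is not None:
            self.counts = np.asarray(self.counts)
            if self.counts.shape != (len(self.gene_ids), n):
                raise ValueError(
                    f"counts must be (n_genes, n_units); got {self.counts.shape}"
                )
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
        if self.expr is not None:
            self.expr = np.asarray(self.expr, dtype=float)
            if self.expr.shape != (len(self.gene_ids), n):
                raise ValueError("expr shape must match (n_genes, n_units)")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def label_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        return pd.read_csv(path, sep=sep, **kw)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SampleFormatError(f"could not parse {path}: {exc}") from exc


def _read_counts(counts_source: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Return (counts, gene_ids, unit_ids) from MTX-with-sidecars or dense CSV/TSV."""
    path = Path(counts_source)
    if path.suffix.lower() == ".mtx":
        try:
            m = mmread(path)
        except Exception as exc:
            raise SampleFormatError(f"could not parse {path}: {exc}") from exc
        mat = np.asarray(m.todense() if hasattr(m, "todense") else m)
        genes_path = path.with_name("genes.tsv")
        units_path = path.with_name("barcodes.tsv")
        if not genes_path.exists() or not units_path.exists():
            raise SampleFormatError(
                f"MTX sidecars genes.tsv/barcodes.tsv not found next to {path}"
            )
        gene_ids = genes_path.read_text().split()
        unit_ids = units_path.read_text().split()
        if mat.shape != (len(gene_ids), len(unit_ids)):
            raise SampleFormatError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(gene_ids)} genes, {len(unit_ids)} units)"
            )
        return mat, gene_ids, unit_ids
    df = _read_table(path, index_col=0)
    try:
        mat = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise SampleFormatError(f"non-numeric counts in {path}") from exc
    return mat, [str(g) for g in df.index], [str(u) for u in df.columns]


def load_sample(
    counts_source: str | Path,
    coords_source: str | Path,
    labels_source: str | Path,
) -> STSample:
    """Read a sample from counts + coords + labels files and join on unit id.

    ``counts_source`` is either a dense CSV/TSV (header row = unit ids, first
    column = gene ids) or a Matrix-Market ``.mtx`` with ``genes.tsv`` and
    ``barcodes.tsv`` sidecar files (rows = genes, columns = units). Coords
    need columns ``unit_id, x, y``; labels need ``unit_id, label``. Units
    present in counts but missing coordinates or a label are dropped (count
    logged); an empty intersection raises :class:`EmptySampleError`.
    """
    counts, gene_ids, unit_ids = _read_counts(counts_source)
    coords_df = _read_table(coords_source)
    labels_df = _read_table(labels_source)
    for col in ("unit_id", "x", "y"):
        if col not in coords_df.columns:
            raise SampleFormatError(f"coords file lacks column {col!r}")
    for col in ("unit_id", "label"):
        if col not in labels_df.columns:
            raise SampleFormatError(f"labels file lacks column {col!r}")
    xy = coords_df[["x", "y"]].apply(pd.to_numeric, errors="coerce")
    if xy.isna().any().any():
        raise SampleFormatError("coords contain non-numeric x or y values")
    coords_map = dict(zip(coords_df["unit_id"].astype(str), xy.to_numpy()))
    labels_map = dict(zip(labels_df["unit_id"].astype(str), labels_df["label"].astype(str)))

    keep_idx = [
        j for j, u in enumerate(unit_ids) if u in coords_map and u in labels_map
    ]
    dropped = len(unit_ids) - len(keep_idx)
    if dropped:
        logger.warning(
            "dropped %d of %d units lacking coordinates or label", dropped, len(unit_ids)
        )
    if not keep_idx:
        raise EmptySampleError("no units shared by counts, coords and labels")
    kept = [unit_ids[j] for j in keep_idx]
    return STSample(
        unit_ids=kept,
        coords=np.array([coords_map[u] for u in kept], dtype=float),
        counts=np.asarray(np.round(counts[:, keep_idx]), dtype=np.int64),
        gene_ids=gene_ids,
        labels=np.array([labels_map[u] for u in kept], dtype=object),
    )


def normalize(sample: STSample, scale: float | str = "median-libsize") -> STSample:
    """Library-size normalize and natural-log transform counts.

    ``expr[g, s] = ln(counts[g, s] / libsize[s] * scale + 1)`` where
    ``libsize[s]`` is the column sum of counts and ``scale`` defaults to the
    median library size across units. Returns a new sample; counts are left
    untouched. A unit with zero library size is an error (it cannot be
    normalized and carries no information).
    """
    if sample.counts is None:
        raise ValueError("sample has no counts to normalize")
    libsize = sample.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"unit(s) with zero library size: {[sample.unit_ids[j] for j in zero]}"
        )
    if scale == "median-libsize":
        scale_value = float(np.median(libsize))
    else:
        scale_value = float(scale)
        if scale_value <= 0:
            raise ValueError("scale must be positive")
    expr = np.log1p(sample.counts / libsize[np.newaxis, :] * scale_value)
    return replace(sample, expr=expr)


def distance_matrix(sample: STSample | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between unit coordinates (n x n)."""
    coords = sample.coords if isinstance(sample, STSample) else np.asarray(sample, float)
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords, metric="euclidean"))


def stratify_genes(sample: STSample) -> np.ndarray:
    """Label genes 'high'/'low' by mean log-expression vs the median gene.

    The per-gene mean of ``expr`` over all units is compared against the
    median of those means; strictly above goes to ``high``, at or below to
    ``low`` (deterministic tie rule).
    """
    if sample.expr is None:
        raise ValueError("sample not normalized: expr missing")
    means = sample.expr.mean(axis=1)
    med = np.median(means)
    return np.where(means > med, "high", "low")


def write_sample(sample: STSample, outdir: str | Path, prefix: str = "sample") -> dict[str, Path]:
    """Write counts (dense CSV), coords and labels in the dialects ``load_sample`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}_counts.csv",
        "coords": outdir / f"{prefix}_coords.csv",
        "labels": outdir / f"{prefix}_labels.csv",
    }
    if sample.counts is None:
        raise ValueError("sample has no counts to write")
    pd.DataFrame(sample.counts, index=sample.gene_ids, columns=sample.unit_ids).to_csv(
        paths["counts"]
    )
    pd.DataFrame(
        {"unit_id": sample.unit_ids, "x": sample.coords[:, 0], "y": sample.coords[:, 1]}
    ).to_csv(paths["coords"], index=False)
    pd.DataFrame({"unit_id": sample.unit_ids, "label": sample.labels.astype(str)}).to_csv(
        paths["labels"], index=False
    )
    return paths


def write_expr(sample: STSample, path: str | Path) -> Path:
    """Write normalized expression as a dense TSV (genes x units)."""
    if sample.expr is None:
        raise ValueError("sample not normalized: expr missing")
    path = Path(path)
    pd.DataFrame(sample.expr, index=sample.gene_ids, columns=sample.unit_ids).to_csv(
        path, sep="\t"
    )
    return path


def sample_summary(sample: STSample) -> dict:
    """JSON-serializable summary: unit/gene counts and label composition."""
    return {
        "n_units": sample.n_units,
        "n_genes": sample.n_genes,
        "labels": sample.label_counts(),
        "normalized": sample.expr is not None,
    }


def write_summary(sample: STSample, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(sample_summary(sample), indent=2))
    return path
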