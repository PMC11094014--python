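"""Gene x tissue-domain differential expression testing.

Orchestrates, for each requested gene and domain comparison, the non-spatial
and spatial model fits from :mod:`stlmm.spatial_lmm`, collects both p-values
and both AICs, applies Benjamini-Hochberg FDR correction, and summarizes how
often the spatial model is the better fit (lower AIC) and how often its
p-value exceeds the non-spatial one.

Accounting follows the attempted-vs-completed convention: the maximum number
of tests is |tested genes| x |eligible domains|; a spatial fit that fails to
converge stays in the table with ``converged_spatial=False`` and is excluded
from model-comparison fractions but counted as attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data_model import STSample, distance_matrix, stratify_genes
from .spatial_lmm import (
    DesignSpec,
    fit_nonspatial,
    fit_spatial,
    wald_test,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEOptions",
    "DETestResult",
    "ComparisonSummary",
    "one_vs_rest",
    "pairwise",
    "adjust_pvalues",
    "compare_models",
    "export_ranked_genes",
    "results_to_frame",
]


@dataclass(frozen=True)
class DEOptions:
    """Knobs shared by the testing entry points.

    covariance : which model families to fit ("both" fits spatial and
        non-spatial; "none" skips the spatial fit, e.g. for speed checks).
    objective : spatial variance-component objective, REML (default) or ML.
    seed : master seed; each (gene, comparison) derives its own restart
        substream so results do not depend on scheduling order.
    min_units : smallest group size for a domain to be eligible.
    """

    covariance: Literal["exponential", "none", "both"] = "both"
    objective: Literal["reml", "ml"] = "reml"
    n_restarts: int = 3
    max_iter: int = 200
    seed: int = 0
    min_units: int = 2


@dataclass
class DETestResult:
    """One gene x comparison row."""

    gene_id: str
    comparison: str
    n_units: int
    estimate: float
    se: float
    statistic: float | None
    p_nonspatial: float | None
    p_spatial: float | None
    aic_nonspatial: float
    aic_spatial: float | None
    converged_spatial: bool
    mean_expr: float
    stratum: str
    fdr_nonspatial: float | None = None
    fdr_spatial: float | None = None

    @property
    def spatial_favored(self) -> bool | None:
        """Lower AIC for the spatial model; ties favor the simpler model."""
        if not self.converged_spatial or self.aic_spatial is None:
            return None
        return bool(self.aic_spatial < self.aic_nonspatial)


@dataclass
class ComparisonSummary:
    """Fractions of tests favoring the spatial model, overall and by stratum."""

    attempted: int
    completed: int
    spatial_favored_overall: float | None
    spatial_favored_by_stratum: dict[str, float | None]
    frac_p_spatial_larger: float | None
    completed_by_stratum: dict[str, int] = field(default_factory=dict)


def _substream_seed(master: int, gene_idx: int, label_idx: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=(gene_idx, label_idx))
    return np.random.default_rng(ss)


def _eligible_labels(sample: STSample, min_units: int) -> list[str]:
    counts = sample.label_counts()
    n = sample.n_units
    out = []
    for lab in sorted(counts):
        if counts[lab] >= min_units and (n - counts[lab]) >= min_units:
            out.append(lab)
        else:
            logger.info(
                "skipping label %r: %d units in group, %d in rest (need >= %d each)",
                lab, counts[lab], n - counts[lab], min_units,
            )
    return out


def _gene_indices(sample: STSample, genes) -> list[int]:
    if genes is None or genes == "all":
        return list(range(sample.n_genes))
    idx = {g: i for i, g in enumerate(sample.gene_ids)}
    missing = [g for g in genes if g not in idx]
    if missing:
        raise KeyError(f"unknown gene id(s): {missing[:5]}")
    return [idx[g] for g in genes]


def _run_tests(
    sample: STSample,
    gene_idx: Sequence[int],
    comparisons: Sequence[tuple[str, np.ndarray, str, int]],
    options: DEOptions,
) -> list[DETestResult]:
    """Shared core: ``comparisons`` holds (name, indicator, label, label_idx)."""
    if sample.expr is None:
        raise ValueError("sample not normalized: call normalize() first")
    D = distance_matrix(sample)
    strata = stratify_genes(sample)
    fit_sp = options.covariance in ("both", "exponential")
    results: list[DETestResult] = []
    for name, indicator, _lab, lab_idx in comparisons:
        design = DesignSpec(indicator)
        for gi in gene_idx:
            y = sample.expr[gi]
            ns = fit_nonspatial(y, design)
            w_ns = wald_test(ns)
            p_ns = w_ns.p_value
            est, se, stat = w_ns.estimate, w_ns.se, w_ns.statistic
            p_sp = aic_sp = None
            conv_sp = False
            if fit_sp:
                rng = _substream_seed(options.seed, gi, lab_idx)
                sp = fit_spatial(
                    y, design, D,
                    objective=options.objective,
                    n_restarts=options.n_restarts,
                    max_iter=options.max_iter,
                    rng=rng,
                )
                conv_sp = bool(sp.converged and not sp.degenerate)
                if conv_sp:
                    w_sp = wald_test(sp)
                    p_sp = w_sp.p_value
                    aic_sp = sp.aic
                    est, se, stat = w_sp.estimate, w_sp.se, w_sp.statistic
            results.append(
                DETestResult(
                    gene_id=sample.gene_ids[gi],
                    comparison=name,
                    n_units=len(indicator),
                    estimate=est,
                    se=se,
                    statistic=stat,
                    p_nonspatial=p_ns,
                    p_spatial=p_sp,
                    aic_nonspatial=ns.aic,
                    aic_spatial=aic_sp,
                    converged_spatial=conv_sp,
                    mean_expr=float(sample.expr[gi].mean()),
                    stratum=str(strata[gi]),
                )
            )
    if not results:
        raise ValueError("no tests attempted: no eligible labels or genes")
    results.sort(key=lambda r: (r.gene_id, r.comparison))
    return results


def one_vs_rest(
    sample: STSample,
    genes="all",
    options: DEOptions | None = None,
    labels: Sequence[str] | None = None,
) -> list[DETestResult]:
    """Test each gene in each eligible domain against all other units.

    For every (gene, domain) pair a binary membership indicator is regressed
    on the gene's log-expression under both models. ``labels`` restricts the
    tested domains (default: every eligible one). Attempted tests equal
    |genes| x |eligible domains|; under-populated domains are skipped with a
    logged reason.
    """
    options = options or DEOptions()
    gene_idx = _gene_indices(sample, genes)
    eligible = _eligible_labels(sample, options.min_units)
    if labels is not None:
        unknown = [l for l in labels if l not in set(sample.labels.astype(str))]
        if unknown:
            raise KeyError(f"unknown label(s): {unknown}")
        eligible = [l for l in eligible if l in set(labels)]
    comparisons = []
    for li, lab in enumerate(eligible):
        indicator = (sample.labels.astype(str) == lab).astype(float)
        comparisons.append((f"{lab} vs rest", indicator, lab, li))
    return _run_tests(sample, gene_idx, comparisons, options)


def pairwise(
    sample: STSample,
    label_a: str,
    label_b: str,
    genes="all",
    options: DEOptions | None = None,
) -> list[DETestResult]:
    """Test each gene between two domains only.

    The sample is restricted to units carrying either label before the
    distance matrix and the design are built, so the spatial covariance
    reflects only the tested units. The estimate is the mean log-expression
    of ``label_a`` minus that of ``label_b``.
    """
    options = options or DEOptions()
    present = set(sample.labels.astype(str))
    for lab in (label_a, label_b):
        if lab not in present:
            raise KeyError(f"unknown label: {lab!r}")
    if label_a == label_b:
        raise ValueError("pairwise comparison requires two distinct labels")
    mask = np.isin(sample.labels.astype(str), [label_a, label_b])
    sub = STSample(
        unit_ids=[u for u, m in zip(sample.unit_ids, mask) if m],
        coords=sample.coords[mask],
        counts=None if sample.counts is None else sample.counts[:, mask],
        gene_ids=list(sample.gene_ids),
        labels=sample.labels[mask],
        expr=None if sample.expr is None else sample.expr[:, mask],
    )
    gene_idx = _gene_indices(sub, genes)
    indicator = (sub.labels.astype(str) == label_a).astype(float)
    comparisons = [(f"{label_a} vs {label_b}", indicator, label_a, 0)]
    return _run_tests(sub, gene_idx, comparisons, options)


def adjust_pvalues(
    results: list[DETestResult],
    family: Literal["per-comparison", "global"] = "per-comparison",
) -> list[DETestResult]:
    """Benjamini-Hochberg step-up FDR within each family of tests.

    The default family groups tests by comparison (across genes), matching
    how per-domain marker tables are read; ``global`` corrects across all
    rows at once. Missing p-values are excluded from the family size m.
    Returns new result objects; input order is preserved.
    """
    out = [replace(r) for r in results]

    def families():
        if family == "global":
            yield out
        else:
            by: dict[str, list[DETestResult]] = {}
            for r in out:
                by.setdefault(r.comparison, []).append(r)
            yield from by.values()

    for fam in families():
        for attr, target in (("p_nonspatial", "fdr_nonspatial"), ("p_spatial", "fdr_spatial")):
            rows = [r for r in fam if getattr(r, attr) is not None]
            if not rows:
                continue
            pvals = np.array([getattr(r, attr) for r in rows], dtype=float)
            _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
            for r, q in zip(rows, fdr):
                setattr(r, target, float(q))
    return out


def compare_models(results: list[DETestResult]) -> ComparisonSummary:
    """Summarize spatial-vs-non-spatial model preference.

    Fractions are over completed tests (spatial fit converged): the share
    with lower spatial AIC (ties go to the non-spatial model), overall and
    within high/low expression strata, and the share of tests whose raw
    spatial p-value exceeds the non-spatial one.
    """
    if not results:
        raise ValueError("no results to summarize")
    attempted = len(results)
    completed = [r for r in results if r.converged_spatial]

    def frac(rows, pred):
        if not rows:
            return None
        return float(sum(pred(r) for r in rows)) / len(rows)

    by_stratum: dict[str, float | None] = {}
    completed_by_stratum: dict[str, int] = {}
    for stratum in ("high", "low"):
        rows = [r for r in completed if r.stratum == stratum]
        by_stratum[stratum] = frac(rows, lambda r: r.spatial_favored)
        completed_by_stratum[stratum] = len(rows)
    p_rows = [r for r in completed if r.p_spatial is not None and r.p_nonspatial is not None]
    return ComparisonSummary(
        attempted=attempted,
        completed=len(completed),
        spatial_favored_overall=frac(completed, lambda r: r.spatial_favored),
        spatial_favored_by_stratum=by_stratum,
        frac_p_spatial_larger=frac(p_rows, lambda r: r.p_spatial > r.p_nonspatial),
        completed_by_stratum=completed_by_stratum,
    )


def export_ranked_genes(
    results: list[DETestResult],
    comparison: str,
    path: str | Path,
    metric: Literal["fdr_spatial", "fdr_nonspatial"] = "fdr_spatial",
) -> Path:
    """Write a two-column ranked gene table for pre-ranked GSEA tools.

    Genes are sorted ascending by the chosen FDR (ties broken by gene id);
    the written score is ``-log10(fdr)`` signed by the direction of the
    expression difference. Genes with a missing value are omitted (logged).
    """
    rows = [r for r in results if r.comparison == comparison]
    if not rows:
        raise KeyError(f"unknown comparison: {comparison!r}")
    kept = [r for r in rows if getattr(r, metric) is not None]
    if len(kept) < len(rows):
        logger.info("omitting %d genes with missing %s", len(rows) - len(kept), metric)
    kept.sort(key=lambda r: (getattr(r, metric), r.gene_id))
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\tscore\n")
        for r in kept:
            q = max(getattr(r, metric), 1e-300)
            score = -math.log10(q) * (1.0 if r.estimate >= 0 else -1.0)
            fh.write(f"{r.gene_id}\t{score:.10g}\n")
    return path


_COLUMNS = [
    "gene_id", "comparison", "n_units", "estimate", "se", "statistic",
    "p_nonspatial", "p_spatial", "fdr_nonspatial", "fdr_spatial",
    "aic_nonspatial", "aic_spatial", "spatial_favored", "mean_expr",
    "stratum", "converged_spatial",
]


def results_to_frame(results: list[DETestResult]) -> pd.DataFrame:
    """Results as a DataFrame with the documented column order."""
    recs = []
    for r in results:
        d = {c: getattr(r, c) for c in _COLUMNS if c != "spatial_favored"}
        d["spatial_favored"] = r.spatial_favored
        recs.append(d)
    return pd.DataFrame.from_records(recs, columns=_COLUMNS)
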