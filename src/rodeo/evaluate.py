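"""Accuracy metrics and benchmarking sweeps for estimated signature matrices.

Accuracy is measured two ways, both Pearson correlations between the known
and estimated signature matrix S:

* per cell type, over genes (columns of S) — the cross matrix of all
  known x estimated pairs is reported, its diagonal being the matched
  profiles;
* per gene, over cell types (rows of S) — summarized by the median over
  genes with a defined correlation.

Root-mean-square error and Euclidean distance are available as alternative
column-wise metrics.  Two sweep procedures quantify how accuracy responds
to sample size and to noise in the proportion matrix, reporting medians over
replicate simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _replace

import numpy as np
import pandas as pd

from .containers import ProportionMatrix, SignatureMatrix
from .deconvolve import get_estimator
from .errors import AlignmentError, InsufficientDataError, ValidationError
from .robust import HuberConfig
from .simulate import SimConfig, simulate_dataset, perturb_proportions

logger = logging.getLogger(__name__)

METRICS = ("pearson", "rmse", "euclidean")


@dataclass
class EvalReport:
    """Accuracy of an estimated signature matrix against the known one.

    ``celltype_corr`` is a known x estimated cross matrix (Pearson by
    default; RMSE/Euclidean when ``metric_name`` says so); ``gene_corr``
    holds per-gene correlations over cell types, with genes whose true or
    estimated row has zero variance reported as NaN, excluded from the
    median, and counted in ``n_undefined``.
    """

    metric_name: str
    method_name: str = ""
    celltype_corr: pd.DataFrame | None = None
    gene_corr: pd.Series | None = None
    gene_corr_median: float | None = None
    n_undefined: int = 0


@dataclass
class SweepResult:
    """Median accuracies along a benchmark axis (sample size or noise level)."""

    axis_name: str
    axis_values: list[float]
    per_celltype_median: pd.DataFrame  # cell types x axis values
    gene_corr_median: pd.Series  # indexed by axis values
    n_replicates: int
    seeds: list[int]


def _shared_genes(
    S_true: SignatureMatrix, S_est: SignatureMatrix, min_genes: int = 1
) -> list[str]:
    est_set = set(S_est.gene_ids)
    common = [g for g in S_true.gene_ids if g in est_set]
    if len(common) < min_genes:
        raise InsufficientDataError(
            f"only {len(common)} genes shared between true and estimated S; "
            f"at least {min_genes} are needed"
        )
    return common


def _align_genes(S_true: SignatureMatrix, S_est: SignatureMatrix, min_genes: int = 1):
    common = _shared_genes(S_true, S_est, min_genes)
    if common == S_true.gene_ids and common == S_est.gene_ids:
        return S_true.values, S_est.values
    t_pos = {g: i for i, g in enumerate(S_true.gene_ids)}
    e_pos = {g: i for i, g in enumerate(S_est.gene_ids)}
    A = S_true.values[[t_pos[g] for g in common]]
    B = S_est.values[[e_pos[g] for g in common]]
    return A, B


def _column_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlations between every column of A and every column of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.sqrt((Ac**2).sum(axis=0))
    nb = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Ac.T @ Bc) / np.outer(na, nb)
    corr[np.isinf(corr)] = np.nan
    return corr


def celltype_correlations(
    S_true: SignatureMatrix, S_est: SignatureMatrix, method_name: str = ""
) -> EvalReport:
    """Cross matrix of Pearson correlations between known and estimated csGEPs.

    Rows are known cell types, columns estimated ones; a good estimate has
    its largest correlations on the matched (diagonal) pairs.  Zero-variance
    columns yield NaN rather than an error.
    """
    A, B = _align_genes(S_true, S_est, min_genes=3)
    corr = _column_corr(A, B)
    df = pd.DataFrame(corr, index=S_true.celltype_ids, columns=S_est.celltype_ids)
    return EvalReport(
        metric_name="pearson",
        method_name=method_name,
        celltype_corr=df,
        n_undefined=int(np.isnan(corr).sum()),
    )


def diagonal_correlations(
    S_true: SignatureMatrix, S_est: SignatureMatrix
) -> pd.Series:
    """Matched-pair csGEP correlations (the diagonal of the cross matrix)."""
    rep = celltype_correlations(S_true, S_est)
    df = rep.celltype_corr
    shared = [c for c in df.index if c in df.columns]
    if not shared:
        raise AlignmentError("no shared cell types between true and estimated S")
    return pd.Series([df.loc[c, c] for c in shared], index=shared, dtype=float)


def gene_correlations(
    S_true: SignatureMatrix, S_est: SignatureMatrix, method_name: str = ""
) -> EvalReport:
    """Per-gene Pearson correlation between true and estimated rows of S.

    Cell-type sets must match (estimated columns are reordered to the true
    order).  Genes whose true or estimated row is constant have an
    undefined correlation: NaN, excluded from the median, counted.
    """
    if set(S_true.celltype_ids) != set(S_est.celltype_ids):
        raise AlignmentError(
            f"cell-type sets differ: true {sorted(S_true.celltype_ids)} vs "
            f"estimated {sorted(S_est.celltype_ids)}"
        )
    if S_true.n_celltypes < 3:
        raise InsufficientDataError(
            "per-gene correlations need at least 3 cell types"
        )
    order = [S_est.celltype_ids.index(c) for c in S_true.celltype_ids]
    A, B = _align_genes(
        S_true,
        SignatureMatrix(S_est.values[:, order], S_est.gene_ids, S_true.celltype_ids),
    )
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = num / den
    corr[~np.isfinite(corr)] = np.nan
    series = pd.Series(corr, index=_shared_genes(S_true, S_est), dtype=float)
    defined = series.dropna()
    return EvalReport(
        metric_name="pearson",
        method_name=method_name,
        gene_corr=series,
        gene_corr_median=float(defined.median()) if len(defined) else None,
        n_undefined=int(series.isna().sum()),
    )


def accuracy_metric(
    S_true: SignatureMatrix,
    S_est: SignatureMatrix,
    metric: str = "pearson",
    method_name: str = "",
) -> EvalReport:
    """Score an estimate with Pearson correlation, RMSE or Euclidean distance.

    For ``pearson`` this combines the cell type-wise and gene-wise
    correlation reports.  For the distance metrics the cross matrix holds
    the column-wise distance between every known/estimated csGEP pair
    (lower is better); RMSE is the Euclidean distance divided by
    ``sqrt(n_genes)``.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {METRICS}")
    if metric == "pearson":
        ct = celltype_correlations(S_true, S_est, method_name)
        gc = gene_correlations(S_true, S_est, method_name)
        return EvalReport(
            metric_name="pearson",
            method_name=method_name,
            celltype_corr=ct.celltype_corr,
            gene_corr=gc.gene_corr,
            gene_corr_median=gc.gene_corr_median,
            n_undefined=ct.n_undefined + gc.n_undefined,
        )
    A, B = _align_genes(S_true, S_est)
    diff = A[:, :, None] - B[:, None, :]
    euclid = np.sqrt((diff**2).sum(axis=0))
    vals = euclid if metric == "euclidean" else euclid / np.sqrt(A.shape[0])
    df = pd.DataFrame(vals, index=S_true.celltype_ids, columns=S_est.celltype_ids)
    return EvalReport(metric_name=metric, method_name=method_name, celltype_corr=df)


# ---------------------------------------------------------------------------
# Sweeps


def _score(ds, method: str, C: ProportionMatrix | None = None,
           huber: HuberConfig | None = None):
    """Fit a named estimator on a dataset and return (diag corrs, gene median)."""
    estimator = get_estimator(method)
    kwargs = {"config": huber} if (method == "rodeo" and huber is not None) else {}
    res = estimator(ds.E, C if C is not None else ds.C, **kwargs)
    diag = diagonal_correlations(ds.truth_S, res.signature)
    gmed = gene_correlations(ds.truth_S, res.signature).gene_corr_median
    return diag, gmed


def sample_size_sweep(
    config: SimConfig,
    method: str,
    sizes,
    n_replicates: int = 10,
    base_seed: int = 0,
    subsample_pool: bool = False,
    huber: HuberConfig | None = None,
) -> SweepResult:
    """Median estimation accuracy as a function of sample size.

    For each size, ``n_replicates`` datasets are drawn (seed = base_seed + r)
    — or, with ``subsample_pool``, replicate random sample subsets of one
    pool dataset of ``config.n_samples`` samples — the estimator is run with
    the known C, and the median matched csGEP correlation per cell type and
    the median per-gene correlation are recorded.  Sizes smaller than the
    number of cell types are skipped with a warning.
    """
    get_estimator(method)
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    T = len(config.celltype_ids)
    pool = simulate_dataset(_replace(config, seed=base_seed)) if subsample_pool else None

    used_sizes: list[float] = []
    ct_cols, gene_meds, seeds = [], [], []
    for size in sizes:
        size = int(size)
        if size < T:
            logger.warning(
                "skipping sample size %d: fewer samples than the %d cell types",
                size, T,
            )
            continue
        diags, gmeds = [], []
        for r in range(n_replicates):
            seed = base_seed + r
            seeds.append(seed)
            if pool is not None:
                if size > pool.E.n_samples:
                    raise ValidationError(
                        f"size {size} exceeds the pool of {pool.E.n_samples} samples"
                    )
                rng = np.random.default_rng(seed + 100_003 * size)
                keep = sorted(rng.choice(pool.E.n_samples, size, replace=False))
                ids = [pool.E.sample_ids[i] for i in keep]
                ds = _replace(
                    pool,
                    E=type(pool.E)(pool.E.values[:, keep], list(pool.E.gene_ids), ids),
                    C=ProportionMatrix(
                        pool.C.values[:, keep], list(pool.C.celltype_ids), ids
                    ),
                )
            else:
                ds = simulate_dataset(_replace(config, n_samples=size, seed=seed))
            diag, gmed = _score(ds, method, huber=huber)
            diags.append(diag)
            gmeds.append(gmed)
        used_sizes.append(size)
        ct_cols.append(pd.concat(diags, axis=1).median(axis=1))
        gene_meds.append(float(np.median([g for g in gmeds if g is not None])))

    return SweepResult(
        axis_name="sample_size",
        axis_values=used_sizes,
        per_celltype_median=pd.concat(ct_cols, axis=1, keys=used_sizes)
        if ct_cols
        else pd.DataFrame(index=list(config.celltype_ids)),
        gene_corr_median=pd.Series(gene_meds, index=used_sizes, dtype=float),
        n_replicates=n_replicates,
        seeds=seeds,
    )


def noise_sweep(
    config: SimConfig,
    method: str,
    max_noise_values,
    n_replicates: int = 10,
    base_seed: int = 0,
    huber: HuberConfig | None = None,
) -> SweepResult:
    """Median accuracy as a function of uniform noise added to the known C.

    One dataset is generated from ``config``; per noise level and replicate
    the known C is perturbed (Uniform(0, max) entrywise, columns
    renormalized), the estimator is run with the noisy C, and the estimate
    is scored against the unperturbed truth.  Only estimators that consume
    C can be swept — all estimators in this package do.
    """
    get_estimator(method)
    levels = [float(v) for v in max_noise_values]
    if any(v < 0 for v in levels):
        raise ValidationError("noise levels must be non-negative")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    ds = simulate_dataset(config)

    ct_cols, gene_meds, seeds = [], [], []
    for j, level in enumerate(levels):
        diags, gmeds = [], []
        for r in range(n_replicates):
            seed = base_seed + j * n_replicates + r
            seeds.append(seed)
            C_noisy = perturb_proportions(ds.C, level, seed=seed)
            diag, gmed = _score(ds, method, C=C_noisy, huber=huber)
            diags.append(diag)
            gmeds.append(gmed)
        ct_cols.append(pd.concat(diags, axis=1).median(axis=1))
        gene_meds.append(float(np.median([g for g in gmeds if g is not None])))

    return SweepResult(
        axis_name="max_noise",
        axis_values=levels,
        per_celltype_median=pd.concat(ct_cols, axis=1, keys=levels),
        gene_corr_median=pd.Series(gene_meds, index=levels, dtype=float),
        n_replicates=n_replicates,
        seeds=seeds,
    )


# ---------------------------------------------------------------------------
# Optional figures


def plot_correlation_heatmap(report: EvalReport, path=None, ax=None):
    """Heatmap of the known x estimated csGEP correlation (or distance) matrix."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if report.celltype_corr is None:
        raise ValidationError("report has no cell-type matrix to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = report.celltype_corr
    im = ax.imshow(df.values, vmin=-1 if report.metric_name == "pearson" else None,
                   vmax=1 if report.metric_name == "pearson" else None,
                   cmap="RdBu_r" if report.metric_name == "pearson" else "viridis")
    ax.set_xticks(range(df.shape[1]), df.columns)
    ax.set_yticks(range(df.shape[0]), df.index)
    ax.set_xlabel("estimated csGEP")
    ax.set_ylabel("known csGEP")
    ax.set_title(f"{report.method_name} ({report.metric_name})".strip())
    ax.figure.colorbar(im, ax=ax)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_sweep(result: SweepResult, path=None, ax=None):
    """Accuracy curves per cell type (plus the gene median) along a sweep axis."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for ct, row in result.per_celltype_median.iterrows():
        ax.plot(result.axis_values, row.values, marker="o", label=f"cell type {ct}")
    ax.plot(
        result.axis_values,
        result.gene_corr_median.values,
        marker="s",
        linestyle="--",
        color="black",
        label="median gene corr.",
    )
    ax.set_xlabel(result.axis_name.replace("_", " "))
    ax.set_ylabel("median Pearson correlation")
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
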