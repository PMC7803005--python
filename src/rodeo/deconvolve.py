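"""Expression deconvolution: estimate the signature matrix S from E and C.

Three estimators solve, gene by gene, the no-intercept regression
``e_g ~ C^T s_g`` implied by the linear mixing model ``E = S @ C``:

``rodeo``
    Robust deconvolution.  Each gene is fitted by Huber IRLS; cell types
    whose coefficient comes out negative are excluded (their expression is
    set to 0) and the model is refitted on the remaining cell types, until
    every remaining coefficient is non-negative.  Per-sample Huber weights
    bound the influence of outlier samples, and because genes are fitted
    independently a sample can be downweighted for one gene while counting
    fully for the rest.
``ols_deconv``
    Unconstrained per-gene least squares, optionally clipping negative
    estimates to 0 after the fit (no refit).
``nnls_deconv``
    Per-gene least squares under the element-wise constraint ``s >= 0``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _scipy_nnls

from .containers import BulkMatrix, DeconvResult, ProportionMatrix, SignatureMatrix
from .errors import AlignmentError, RankDeficiencyError, UnderdeterminedError
from .robust import MAD_CONSISTENCY, HuberConfig, fit_huber


def align_samples(E: BulkMatrix, C: ProportionMatrix) -> ProportionMatrix:
    """Reorder C's columns to E's sample order; error on mismatched ID sets."""
    if E.sample_ids == C.sample_ids:
        return C
    e_set, c_set = set(E.sample_ids), set(C.sample_ids)
    if e_set != c_set:
        only_e = sorted(e_set - c_set)
        only_c = sorted(c_set - e_set)
        raise AlignmentError(
            "sample IDs of bulk and proportion matrices do not match; "
            f"only in bulk: {only_e}; only in proportions: {only_c}"
        )
    order = [C.sample_ids.index(s) for s in E.sample_ids]
    return ProportionMatrix(C.values[:, order], list(C.celltype_ids), list(E.sample_ids))


def _check_deconv_inputs(E: BulkMatrix, C: ProportionMatrix) -> ProportionMatrix:
    C = align_samples(E, C)
    if C.n_samples < C.n_celltypes:
        raise UnderdeterminedError(
            f"{C.n_samples} samples cannot identify {C.n_celltypes} cell types; "
            "at least as many samples as cell types are required"
        )
    X = C.values.T
    rank = np.linalg.matrix_rank(X)
    if rank < C.n_celltypes:
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        names = sorted(C.celltype_ids[int(j)] for j in piv[rank:])
        raise RankDeficiencyError(
            f"proportion matrix is rank deficient; collinear cell types: {names}"
        )
    return C


# ---------------------------------------------------------------------------
# Rodeo


def rodeo_fit_gene(
    bulk_row, C: ProportionMatrix, config: HuberConfig | None = None
) -> tuple[np.ndarray, frozenset[str], bool, np.ndarray]:
    """Rodeo's per-gene fit: Huber IRLS with negative-coefficient exclusion.

    Returns ``(signature_row, excluded_celltypes, converged, sample_weights)``
    where the signature row is non-negative with excluded cell types exactly
    0, and the weights are those of the final fit.
    """
    if config is None:
        config = HuberConfig()
    y = np.asarray(bulk_row, dtype=float).ravel()
    if y.size != C.n_samples:
        raise AlignmentError(
            f"bulk row has {y.size} samples, proportions have {C.n_samples}"
        )
    if C.n_samples < C.n_celltypes:
        raise UnderdeterminedError(
            f"{C.n_samples} samples cannot identify {C.n_celltypes} cell types"
        )
    T = C.n_celltypes
    active = list(range(T))
    row = np.zeros(T)
    weights = np.ones(C.n_samples)
    converged = True
    while active:
        fit = fit_huber(y, C.values[active].T, config)
        weights, converged = fit.weights, fit.converged
        neg = fit.coefficients < 0
        if not neg.any():
            row[active] = fit.coefficients
            break
        active = [t for t, isneg in zip(active, neg) if not isneg]
    excluded = frozenset(C.celltype_ids[t] for t in range(T) if t not in set(active))
    return row, excluded, converged, weights


def _batched_huber(Y: np.ndarray, X: np.ndarray, config: HuberConfig):
    """Huber IRLS for many responses sharing one design matrix.

    ``Y`` is observations x genes, ``X`` observations x predictors (full
    column rank).  Mirrors :func:`rodeo.robust.fit_huber` exactly — OLS
    start, zero-centred MAD scale per iteration, Huber weights, weighted
    normal equations — but batches the per-gene solves.

    Returns ``(B, W, converged)`` with ``B`` predictors x genes and ``W``
    observations x genes.
    """
    n, G = Y.shape
    p = X.shape[1]
    B = np.linalg.lstsq(X, Y, rcond=None)[0].reshape(p, G)
    W = np.ones((n, G))
    conv = np.zeros(G, dtype=bool)
    # n x p^2 tensor of outer products; weighted normal matrices are then a
    # single BLAS product per iteration.
    XX = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    active = np.arange(G)
    for _ in range(config.max_iter):
        if active.size == 0:
            break
        R = Y[:, active] - X @ B[:, active]
        s = np.median(np.abs(R), axis=0) / MAD_CONSISTENCY
        frozen = s <= config.scale_floor
        if frozen.any():
            idx = active[frozen]
            W[:, idx] = 1.0
            conv[idx] = True
            active = active[~frozen]
            R, s = R[:, ~frozen], s[~frozen]
            if active.size == 0:
                break
        bound = config.k * s
        aR = np.abs(R)
        with np.errstate(divide="ignore"):
            w = np.where(aR <= bound[None, :], 1.0, bound[None, :] / aR)
        W[:, active] = w
        A = (w.T @ XX).reshape(-1, p, p)
        b = (w * Y[:, active]).T @ X
        B_new = np.linalg.solve(A, b[:, :, None])[:, :, 0].T
        B_old = B[:, active]
        delta = np.max(
            np.abs(B_new - B_old) / np.maximum(1.0, np.abs(B_old)), axis=0
        )
        B[:, active] = B_new
        done = delta < config.tol
        conv[active[done]] = True
        active = active[~done]
    return B, W, conv


def rodeo(
    E: BulkMatrix, C: ProportionMatrix, config: HuberConfig | None = None
) -> DeconvResult:
    """Robust expression deconvolution of every gene in E.

    Genes are independent, so they are processed in batches grouped by the
    set of cell types still in each gene's model; results are identical to
    running :func:`rodeo_fit_gene` gene by gene.
    """
    if config is None:
        config = HuberConfig()
    C = _check_deconv_inputs(E, C)
    Xfull = C.values.T
    G, n = E.values.shape
    T = C.n_celltypes
    all_types = set(C.celltype_ids)

    S = np.zeros((G, T))
    Wout = np.ones((G, n))
    conv_out = np.zeros(G, dtype=bool)
    excluded: dict[str, frozenset[str]] = {}

    work: dict[tuple[int, ...], list[int]] = {tuple(range(T)): list(range(G))}
    while work:
        cols, gene_list = work.popitem()
        genes = np.asarray(gene_list)
        col_arr = np.asarray(cols)
        B, W, conv = _batched_huber(E.values[genes].T, Xfull[:, col_arr], config)
        negmask = B < 0
        has_neg = negmask.any(axis=0)

        ok = ~has_neg
        done = genes[ok]
        S[done[:, None], col_arr[None, :]] = B[:, ok].T
        Wout[done] = W[:, ok].T
        conv_out[done] = conv[ok]
        kept = frozenset(C.celltype_ids[c] for c in cols)
        excl_here = frozenset(all_types - kept)
        for g in done:
            excluded[E.gene_ids[g]] = excl_here

        for j in np.nonzero(has_neg)[0]:
            keep = tuple(int(c) for i, c in enumerate(cols) if not negmask[i, j])
            g = int(genes[j])
            if keep:
                work.setdefault(keep, []).append(g)
            else:
                # every remaining cell type went negative: all-zero row
                Wout[g] = W[:, j]
                conv_out[g] = conv[j]
                excluded[E.gene_ids[g]] = frozenset(all_types)

    sig = SignatureMatrix(S, list(E.gene_ids), list(C.celltype_ids))
    return DeconvResult(
        signature=sig,
        excluded=excluded,
        converged={g: bool(c) for g, c in zip(E.gene_ids, conv_out)},
        method_name="rodeo",
        weights=pd.DataFrame(Wout, index=E.gene_ids, columns=E.sample_ids),
    )


# ---------------------------------------------------------------------------
# Least-squares baselines


def ols_deconv(
    E: BulkMatrix, C: ProportionMatrix, clip_negative: bool = False
) -> DeconvResult:
    """Per-gene unconstrained least squares (cs-lsfit-style baseline).

    With ``clip_negative`` negative entries are set to 0 after fitting,
    without refitting the remaining cell types.
    """
    C = _check_deconv_inputs(E, C)
    B = np.linalg.lstsq(C.values.T, E.values.T, rcond=None)[0]
    S = B.T
    if clip_negative:
        S = np.where(S < 0, 0.0, S)
    sig = SignatureMatrix(S, list(E.gene_ids), list(C.celltype_ids))
    return DeconvResult(
        signature=sig,
        excluded={g: frozenset() for g in E.gene_ids},
        converged={g: True for g in E.gene_ids},
        method_name="ols_clipped" if clip_negative else "ols",
    )


def nnls_deconv(E: BulkMatrix, C: ProportionMatrix) -> DeconvResult:
    """Per-gene non-negative least squares (cs-qprog-style baseline)."""
    C = _check_deconv_inputs(E, C)
    X = C.values.T
    S = np.empty((E.n_genes, C.n_celltypes))
    for g in range(E.n_genes):
        S[g], _ = _scipy_nnls(X, E.values[g])
    sig = SignatureMatrix(S, list(E.gene_ids), list(C.celltype_ids))
    return DeconvResult(
        signature=sig,
        excluded={g: frozenset() for g in E.gene_ids},
        converged={g: True for g in E.gene_ids},
        method_name="nnls",
    )


#: Estimators addressable by name (CLI, sweeps).  Every one consumes the
#: proportion matrix C.
ESTIMATORS = {
    "rodeo": rodeo,
    "ols": ols_deconv,
    "nnls": nnls_deconv,
}


def get_estimator(name: str):
    try:
        return ESTIMATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown estimator {name!r}; available: {sorted(ESTIMATORS)}"
        ) from None
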