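"""Ground-truthed pseudo-bulk simulation.

Emulates a simulated benchmark of heterogeneous bulk samples: five cell
types with very different mean abundances (default 0.5/0.2/0.15/0.09/0.06),
10,000 genes of which 200 carry a batch effect (a shifted mean in half of
the samples, standing in for age/sex/treatment batches present in real
cohorts), log-normal base expression, Dirichlet per-sample compositions, and
multiplicative measurement noise on the bulk mixture.  Optional outlier
samples have an altered per-sample signature (a random 10% of genes scaled),
not merely an unusual composition — outliers in S are the kind that hurt
expression deconvolution, whereas atypical compositions do not.

All randomness flows from a single integer seed, so datasets are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import BulkMatrix, ProportionMatrix, SignatureMatrix
from .errors import ValidationError

DEFAULT_CELLTYPES = ("A", "B", "C", "D", "E")
DEFAULT_MEAN_PROPORTIONS = (0.5, 0.2, 0.15, 0.09, 0.06)


@dataclass(frozen=True)
class SimConfig:
    """Generation parameters for a synthetic deconvolution benchmark.

    Defaults reproduce the reference scenario: 10,000 genes, 5 cell types
    with mean proportions 0.5/0.2/0.15/0.09/0.06 over 40 samples, 200
    batch-affected genes (means doubled in the first half of samples),
    log-normal base expression (meanlog 4, sdlog 1), Dirichlet compositions
    with concentration 50, and multiplicative Gaussian measurement noise
    with a 15% coefficient of variation, truncated at 0.
    """

    n_genes: int = 10_000
    celltype_ids: tuple[str, ...] = DEFAULT_CELLTYPES
    mean_proportions: tuple[float, ...] = DEFAULT_MEAN_PROPORTIONS
    n_samples: int = 40
    n_batch_genes: int = 200
    batch_effect_size: float = 2.0
    dirichlet_concentration: float = 50.0
    expr_meanlog: float = 4.0
    expr_sdlog: float = 1.0
    noise_cv: float = 0.15
    n_outliers: int = 0
    outlier_effect_size: float = 3.0
    outlier_gene_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        mp = np.asarray(self.mean_proportions, dtype=float)
        if len(self.celltype_ids) != mp.size:
            raise ValidationError("celltype_ids and mean_proportions lengths differ")
        if np.any(mp <= 0) or abs(mp.sum() - 1.0) > 1e-8:
            raise ValidationError(
                "mean_proportions must be strictly positive and sum to 1"
            )
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValidationError("n_genes and n_samples must be >= 1")
        if not 0 <= self.n_batch_genes <= self.n_genes:
            raise ValidationError("n_batch_genes must lie in [0, n_genes]")
        if self.batch_effect_size <= 0 or self.outlier_effect_size <= 0:
            raise ValidationError("effect sizes must be positive")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("dirichlet_concentration must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")
        if self.n_outliers < 0:
            raise ValidationError("n_outliers must be non-negative")
        if not 0 < self.outlier_gene_fraction <= 1:
            raise ValidationError("outlier_gene_fraction must be in (0, 1]")


@dataclass
class SyntheticDataset:
    """Ground truth plus realized bulk data and generation metadata.

    ``truth_S`` is the base (pre-batch, pre-outlier) signature — the gold
    standard estimates are scored against; batch and outlier effects are
    nuisance structure layered on top of it.
    """

    truth_S: SignatureMatrix
    C: ProportionMatrix
    E: BulkMatrix
    batch_genes: frozenset[str]
    batch_samples: frozenset[str]
    outlier_samples: frozenset[str]
    config: SimConfig = field(repr=False)


def simulate_proportions(
    mean_proportions,
    n_samples: int,
    concentration: float = 50.0,
    seed: int = 0,
    celltype_ids=None,
    sample_ids=None,
) -> ProportionMatrix:
    """Draw per-sample compositions from Dirichlet(concentration * means).

    Columns sit exactly on the simplex; the expected composition equals
    ``mean_proportions`` and the concentration controls sample-to-sample
    variability (larger = tighter around the mean).
    """
    mp = np.asarray(mean_proportions, dtype=float)
    if np.any(mp <= 0) or abs(mp.sum() - 1.0) > 1e-8:
        raise ValidationError("mean_proportions must be positive and sum to 1")
    if concentration <= 0:
        raise ValidationError(f"concentration must be positive, got {concentration!r}")
    rng = np.random.default_rng(seed)
    V = rng.dirichlet(concentration * mp, size=n_samples).T  # celltypes x samples
    if celltype_ids is None:
        celltype_ids = [f"ct{t + 1}" for t in range(mp.size)]
    if sample_ids is None:
        sample_ids = [f"sample_{i + 1}" for i in range(n_samples)]
    return ProportionMatrix(V, list(celltype_ids), list(sample_ids))


def _mix_with_noise(S_per_sample, C_values, noise_cv, rng):
    """Bulk columns from per-sample signatures, with multiplicative noise."""
    clean = np.einsum("gts,ts->gs", S_per_sample, C_values)
    if noise_cv > 0:
        clean = clean * rng.normal(1.0, noise_cv, size=clean.shape)
    return np.clip(clean, 0.0, None)


def simulate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic benchmark dataset from a single seed."""
    if config is None:
        config = SimConfig()
    ss = np.random.SeedSequence(config.seed)
    seed_s, seed_c, seed_noise, seed_out = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )

    G, n = config.n_genes, config.n_samples
    T = len(config.celltype_ids)
    gene_ids = [f"gene_{i + 1}" for i in range(G)]
    sample_ids = [f"sample_{i + 1}" for i in range(n)]

    rng_s = np.random.default_rng(seed_s)
    base = rng_s.lognormal(config.expr_meanlog, config.expr_sdlog, size=(G, T))
    batch_idx = np.sort(
        rng_s.choice(G, size=config.n_batch_genes, replace=False)
    )
    truth_S = SignatureMatrix(base, gene_ids, list(config.celltype_ids))

    C = simulate_proportions(
        config.mean_proportions,
        n,
        config.dirichlet_concentration,
        seed=seed_c,
        celltype_ids=config.celltype_ids,
        sample_ids=sample_ids,
    )

    # Per-sample signatures: batch genes have their means scaled in the
    # first half of the samples (the same gene set in every cell type).
    n_batch_samples = n // 2
    S_per_sample = np.repeat(base[:, :, None], n, axis=2)
    if config.n_batch_genes and n_batch_samples:
        sel = np.ix_(batch_idx, np.arange(T), np.arange(n_batch_samples))
        S_per_sample[sel] *= config.batch_effect_size

    rng_noise = np.random.default_rng(seed_noise)
    Ev = _mix_with_noise(S_per_sample, C.values, config.noise_cv, rng_noise)
    E = BulkMatrix(Ev, gene_ids, sample_ids)

    ds = SyntheticDataset(
        truth_S=truth_S,
        C=C,
        E=E,
        batch_genes=frozenset(gene_ids[i] for i in batch_idx),
        batch_samples=frozenset(sample_ids[:n_batch_samples]),
        outlier_samples=frozenset(),
        config=config,
    )
    if config.n_outliers > 0:
        ds = add_outlier_samples(
            ds, config.n_outliers, config.outlier_effect_size, seed=seed_out
        )
    return ds


def add_outlier_samples(
    dataset: SyntheticDataset,
    n_outliers: int,
    effect_size: float | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Append samples whose cell type-specific expression deviates from truth.

    Each outlier gets its own per-sample signature: the base truth with a
    random fraction of genes (default 10%) scaled by ``effect_size`` across
    all cell types, mixed with a freshly drawn composition and the usual
    measurement noise.  The ground truth and the original samples' bulk
    columns are untouched.
    """
    if n_outliers < 1:
        raise ValidationError(f"n_outliers must be >= 1, got {n_outliers!r}")
    cfg = dataset.config
    if effect_size is None:
        effect_size = cfg.outlier_effect_size
    if effect_size <= 0:
        raise ValidationError(f"effect_size must be positive, got {effect_size!r}")

    rng = np.random.default_rng(seed)
    G = dataset.truth_S.n_genes
    T = dataset.truth_S.n_celltypes
    n_hit = max(1, int(round(cfg.outlier_gene_fraction * G)))
    base = dataset.truth_S.values

    S_out = np.repeat(base[:, :, None], n_outliers, axis=2)
    for j in range(n_outliers):
        hit = rng.choice(G, size=n_hit, replace=False)
        S_out[hit, :, j] *= effect_size
    C_out = rng.dirichlet(
        cfg.dirichlet_concentration * np.asarray(cfg.mean_proportions), size=n_outliers
    ).T
    E_out = _mix_with_noise(S_out, C_out, cfg.noise_cv, rng)

    out_ids = [f"outlier_{j + 1}" for j in range(n_outliers)]
    sample_ids = list(dataset.E.sample_ids) + out_ids
    E = BulkMatrix(
        np.hstack([dataset.E.values, E_out]), list(dataset.E.gene_ids), sample_ids
    )
    C = ProportionMatrix(
        np.hstack([dataset.C.values, C_out]),
        list(dataset.C.celltype_ids),
        sample_ids,
    )
    return SyntheticDataset(
        truth_S=dataset.truth_S,
        C=C,
        E=E,
        batch_genes=dataset.batch_genes,
        batch_samples=dataset.batch_samples,
        outlier_samples=dataset.outlier_samples | frozenset(out_ids),
        config=replace(cfg, n_outliers=cfg.n_outliers or n_outliers),
    )


def perturb_proportions(
    C: ProportionMatrix, max_noise: float, seed: int = 0
) -> ProportionMatrix:
    """Add Uniform(0, max_noise) noise to every entry, renormalize columns.

    Emulates working with an estimated rather than known composition.  With
    ``max_noise == 0`` the input is returned unchanged (bit-exact copy).
    """
    if max_noise < 0:
        raise ValidationError(f"max_noise must be non-negative, got {max_noise!r}")
    if max_noise == 0:
        return ProportionMatrix(
            C.values.copy(), list(C.celltype_ids), list(C.sample_ids)
        )
    rng = np.random.default_rng(seed)
    V = C.values + rng.uniform(0.0, max_noise, size=C.values.shape)
    V = V / V.sum(axis=0)
    return ProportionMatrix(V, list(C.celltype_ids), list(C.sample_ids))
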