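"""Signature-matrix estimators: Rodeo, OLS and NNLS."""

import itertools

import numpy as np
import pytest

from rodeo import (
    AlignmentError,
    BulkMatrix,
    HuberConfig,
    ProportionMatrix,
    UnderdeterminedError,
    nnls_deconv,
    ols_deconv,
    rodeo,
    rodeo_fit_gene,
)
from conftest import make_exact_instance


@pytest.fixture(scope="module")
def exact():
    return make_exact_instance(n_genes=25, n_celltypes=3, n_samples=15, seed=2)


class TestExactRecovery:
    @pytest.mark.parametrize("method", ["rodeo", "ols", "nnls"])
    def test_noise_free_recovery(self, exact, method):
        S, C, E = exact
        est = {
            "rodeo": lambda: rodeo(E, C),
            "ols": lambda: ols_deconv(E, C),
            "nnls": lambda: nnls_deconv(E, C),
        }[method]()
        np.testing.assert_allclose(est.signature.values, S.values, rtol=1e-6)

    def test_rodeo_no_exclusions_on_clean_positive_data(self, exact):
        S, C, E = exact
        res = rodeo(E, C)
        assert all(len(e) == 0 for e in res.excluded.values())
        assert all(res.converged.values())


class TestRodeoGene:
    def test_zero_bulk_row_gives_zero_signature(self, exact):
        _, C, _ = exact
        row, excluded, converged, weights = rodeo_fit_gene(np.zeros(C.n_samples), C)
        np.testing.assert_array_equal(row, 0.0)
        assert excluded == frozenset()
        assert converged
        np.testing.assert_array_equal(weights, 1.0)

    def test_negative_coefficient_excluded_and_refit(self):
        """Construct a 2-cell-type gene whose unconstrained fit is (+, -).

        The refit value must match a single-predictor least-squares oracle
        on the reduced design.
        """
        rng = np.random.default_rng(0)
        C = ProportionMatrix(
            rng.dirichlet([5, 5], size=12).T, ["a", "b"], [f"s{j}" for j in range(12)]
        )
        X = C.values.T
        # true profile (5, 0) plus structured noise pushing b negative
        y = X @ np.array([5.0, 0.0]) - 0.3 * X[:, 1] + 0.01
        y = np.clip(y, 0, None)
        full = np.linalg.lstsq(X, y, rcond=None)[0]
        assert full[1] < 0 < full[0], "instance must produce a (+,-) OLS fit"
        row, excluded, _, _ = rodeo_fit_gene(y, C, HuberConfig(k=1e6))
        assert excluded == frozenset({"b"})
        assert row[1] == 0.0
        x0 = X[:, 0]
        oracle = float(x0 @ y / (x0 @ x0))  # 1-predictor LS on reduced design
        assert row[0] == pytest.approx(oracle, rel=1e-6)

    def test_matches_whole_matrix_rodeo(self, small_dataset):
        """Batched rodeo equals the per-gene reference path."""
        ds = small_dataset
        res = rodeo(ds.E, ds.C)
        for g in [0, 7, 57, 123, 199]:
            row, excluded, converged, weights = rodeo_fit_gene(
                ds.E.values[g], ds.C
            )
            np.testing.assert_allclose(
                res.signature.values[g], row, rtol=1e-5, atol=1e-8
            )
            assert res.excluded[ds.E.gene_ids[g]] == excluded
            np.testing.assert_allclose(
                res.weights.iloc[g].to_numpy(), weights, rtol=1e-4, atol=1e-6
            )


class TestRodeoMatrix:
    def test_nonnegative_output(self, small_dataset):
        res = rodeo(small_dataset.E, small_dataset.C)
        assert (res.signature.values >= 0).all()

    def test_excluded_entries_are_exactly_zero(self, small_dataset):
        res = rodeo(small_dataset.E, small_dataset.C)
        cts = res.signature.celltype_ids
        n_excl = 0
        for i, g in enumerate(res.signature.gene_ids):
            for ct in res.excluded[g]:
                assert res.signature.values[i, cts.index(ct)] == 0.0
                n_excl += 1
        assert n_excl > 0, "noisy data should trigger some exclusions"

    def test_celltype_permutation_permutes_columns(self, exact):
        S, C, E = exact
        perm = [2, 0, 1]
        C2 = ProportionMatrix(
            C.values[perm], [C.celltype_ids[i] for i in perm], list(C.sample_ids)
        )
        a = rodeo(E, C).signature.values
        b = rodeo(E, C2).signature.values
        np.testing.assert_allclose(b, a[:, perm], rtol=1e-8)

    def test_sample_permutation_is_neutral(self, exact):
        S, C, E = exact
        rng = np.random.default_rng(3)
        perm = rng.permutation(E.n_samples)
        E2 = BulkMatrix(
            E.values[:, perm], list(E.gene_ids), [E.sample_ids[i] for i in perm]
        )
        a = rodeo(E, C).signature.values
        b = rodeo(E2, C).signature.values  # C re-aligned internally by sample ID
        np.testing.assert_allclose(b, a, rtol=1e-8)

    def test_scale_equivariance(self, small_dataset):
        ds = small_dataset
        a = rodeo(ds.E, ds.C).signature.values
        E2 = BulkMatrix(3.0 * ds.E.values, list(ds.E.gene_ids), list(ds.E.sample_ids))
        b = rodeo(E2, ds.C).signature.values
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-5, atol=1e-8)

    def test_gene_independence_under_subsetting(self, small_dataset):
        ds = small_dataset
        full = rodeo(ds.E, ds.C).signature.values
        keep = [3, 10, 40]
        sub = BulkMatrix(
            ds.E.values[keep],
            [ds.E.gene_ids[i] for i in keep],
            list(ds.E.sample_ids),
        )
        part = rodeo(sub, ds.C).signature.values
        np.testing.assert_allclose(part, full[keep], rtol=1e-10)

    def test_sample_id_mismatch_names_offenders(self, exact):
        S, C, E = exact
        C2 = ProportionMatrix(
            C.values, list(C.celltype_ids), [f"x{j}" for j in range(C.n_samples)]
        )
        with pytest.raises(AlignmentError, match="x0"):
            rodeo(E, C2)

    def test_fewer_samples_than_celltypes_unrepresentable(self):
        # a 3-cell-type C with 2 samples cannot have full row rank, so the
        # container itself rejects it (the estimator's own guard is tested
        # at the regression level)
        from rodeo import ValidationError

        S, C, E = make_exact_instance(n_genes=4, n_celltypes=3, n_samples=12, seed=0)
        with pytest.raises(ValidationError, match="rank"):
            ProportionMatrix(C.values[:, :2], list(C.celltype_ids), C.sample_ids[:2])


class TestOls:
    def test_matches_normal_equations_oracle(self, small_dataset):
        ds = small_dataset
        X = ds.C.values.T
        oracle = np.linalg.solve(X.T @ X, X.T @ ds.E.values.T).T
        est = ols_deconv(ds.E, ds.C).signature.values
        np.testing.assert_allclose(est, oracle, rtol=1e-8, atol=1e-10)

    def test_clip_negative_zeroes_without_refit(self):
        rng = np.random.default_rng(0)
        C = ProportionMatrix(
            rng.dirichlet([5, 5], size=12).T, ["a", "b"], [f"s{j}" for j in range(12)]
        )
        X = C.values.T
        y = np.clip(X @ np.array([5.0, 0.0]) - 0.3 * X[:, 1] + 0.01, 0, None)
        E = BulkMatrix(y[None, :], ["g0"], list(C.sample_ids))
        raw = ols_deconv(E, C).signature.values[0]
        clipped = ols_deconv(E, C, clip_negative=True).signature.values[0]
        assert raw[1] < 0
        assert clipped[1] == 0.0
        assert clipped[0] == raw[0]  # first coefficient untouched (no refit)


class TestNnls:
    def test_equals_ols_when_unconstrained_solution_nonnegative(self, exact):
        S, C, E = exact
        a = ols_deconv(E, C).signature.values
        assert (a >= -1e-10).all()
        b = nnls_deconv(E, C).signature.values
        np.testing.assert_allclose(b, np.clip(a, 0, None), rtol=1e-6, atol=1e-8)

    def test_nonnegative_output(self, small_dataset):
        res = nnls_deconv(small_dataset.E, small_dataset.C)
        assert (res.signature.values >= 0).all()

    def test_matches_exhaustive_active_set_oracle(self):
        """For <=3 cell types, enumerate every active set and take the best
        feasible candidate; NNLS must match it to 1e-8."""
        rng = np.random.default_rng(7)
        for trial in range(20):
            T = int(rng.integers(2, 4))
            n = 10
            X = rng.dirichlet(np.ones(T) * 2, size=n)
            y = np.abs(
                X @ rng.uniform(-5, 20, size=T) + rng.normal(scale=1.0, size=n)
            )

            best, best_rss = np.zeros(T), float(y @ y)
            for r in range(1, T + 1):
                for subset in itertools.combinations(range(T), r):
                    coef = np.linalg.lstsq(X[:, subset], y, rcond=None)[0]
                    if (coef < -1e-12).any():
                        continue  # infeasible active set
                    full = np.zeros(T)
                    full[list(subset)] = coef
                    rss = float(np.sum((y - X @ full) ** 2))
                    if rss < best_rss - 1e-12:
                        best, best_rss = full, rss
            C = ProportionMatrix(
                X.T, [f"ct{t}" for t in range(T)], [f"s{j}" for j in range(n)]
            )
            E = BulkMatrix(y[None, :], ["g"], list(C.sample_ids))
            est = nnls_deconv(E, C).signature.values[0]
            np.testing.assert_allclose(est, best, atol=1e-8)

    def test_residual_not_worse_than_clipped_ols(self):
        rng = np.random.default_rng(11)
        C = ProportionMatrix(
            rng.dirichlet([3, 3], size=10).T, ["a", "b"], [f"s{j}" for j in range(10)]
        )
        X = C.values.T
        y = np.clip(X @ np.array([4.0, 0.0]) - 0.5 * X[:, 1] + 0.05, 0, None)
        E = BulkMatrix(y[None, :], ["g"], list(C.sample_ids))
        nn = nnls_deconv(E, C).signature.values[0]
        cl = ols_deconv(E, C, clip_negative=True).signature.values[0]
        rss = lambda s: float(np.sum((y - X @ s) ** 2))
        assert rss(nn) <= rss(cl) + 1e-12
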