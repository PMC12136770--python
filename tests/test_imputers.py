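import numpy as np
import pytest

from sectormix.core_io import PeptideMatrix
from sectormix.imputers import (
    ContractViolation,
    ImputationOutput,
    ImputerSpec,
    default_registry,
    impute_bpca,
    impute_cf,
    impute_knn,
    impute_lls,
    impute_mle,
    impute_rf,
    impute_row_mean,
    impute_svd,
    register_plugin_imputer,
)
from sectormix.mask_eval import mask_entries, nrmse

from conftest import make_matrix

ALL_METHODS = ["knn", "rf", "svd", "bpca", "lls", "mle", "cf"]


@pytest.fixture(scope="module")
def masked_rank2(rank2_dataset):
    masked, mask = mask_entries(rank2_dataset, 0.10, seed=11)
    return masked, mask


class TestContract:
    @pytest.mark.parametrize("name", ALL_METHODS)
    def test_pass_through_when_complete(self, name):
        m = make_matrix(np.random.default_rng(0).normal(20, 2, (30, 6)))
        out = default_registry()[name].run(m, seed=0)
        assert out.applicable
        np.testing.assert_array_equal(out.values, m.values)

    @pytest.mark.parametrize("name", ALL_METHODS)
    def test_observed_cells_bit_identical(self, name, tiny_matrix):
        out = default_registry()[name].run(tiny_matrix, seed=0)
        if not out.applicable:
            # small-matrix refusal is part of the contract too
            assert out.reason
            return
        obs = tiny_matrix.observed
        assert np.array_equal(out.values[obs], tiny_matrix.values[obs])
        assert np.all(np.isfinite(out.values))

    def test_too_few_peptides_not_applicable(self):
        m = make_matrix(np.array([[1.0, np.nan], [2.0, 3.0]]))
        for name in ("rf", "mle", "cf"):
            out = default_registry()[name].run(m, seed=0)
            assert not out.applicable
            assert out.reason


class TestKNN:
    def test_constant_matrix(self):
        vals = np.full((6, 4), 7.5)
        vals[2, 1] = np.nan
        out = impute_knn(make_matrix(vals))
        assert out.values[2, 1] == pytest.approx(7.5)

    def test_matches_exhaustive_neighbor_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(20, 2, (8, 5))
        vals[0, 2] = np.nan
        m = make_matrix(vals)
        k, eps = 3, 1e-6
        out = impute_knn(m, k=k, eps=eps)
        # brute force: rescaled Euclidean over co-observed samples
        target = vals[0]
        dists = []
        for r in range(1, 8):
            co = np.isfinite(target) & np.isfinite(vals[r])
            d = np.sqrt(5 / co.sum() * np.nansum((target[co] - vals[r][co]) ** 2))
            dists.append((d, r))
        cand = [(d, r) for d, r in dists if np.isfinite(vals[r, 2])]
        cand.sort()
        top = cand[:k]
        w = np.array([1 / (d + eps) for d, _ in top])
        expected = float(w @ np.array([vals[r, 2] for _, r in top]) / w.sum())
        assert out.values[0, 2] == pytest.approx(expected, abs=1e-10)

    def test_row_mean_fallback_without_neighbors(self):
        # the only other peptide is unobserved in the target column
        vals = np.array([[10.0, np.nan, 12.0], [9.0, np.nan, 11.0]])
        out = impute_knn(make_matrix(vals))
        assert out.values[0, 1] == pytest.approx(11.0)


class TestRF:
    def test_duplicated_column_recovered_from_donor(self):
        rng = np.random.default_rng(2)
        base = rng.normal(20, 2, (60, 5))
        vals = np.column_stack([base, base[:, 0]])  # col 5 duplicates col 0
        vals[rng.choice(60, 12, replace=False), 5] = np.nan
        m = make_matrix(vals)
        out = impute_rf(m, n_trees=50, seed=0)
        miss = ~m.observed
        err = np.abs(out.values[miss] - base[:, 0][miss.any(axis=1)])
        assert np.median(err) < 0.5

    def test_seed_determinism(self, masked_rank2):
        masked, _ = masked_rank2
        sub = masked.subset_rows(np.arange(60))
        a = impute_rf(sub, n_trees=20, seed=3)
        b = impute_rf(sub, n_trees=20, seed=3)
        np.testing.assert_array_equal(a.values, b.values)


class TestSVD:
    def test_rank1_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        u, v = rng.uniform(1, 2, 40), rng.uniform(1, 2, 8)
        truth = np.outer(u, v)
        obs = rng.random(truth.shape) > 0.1
        obs[:, 0] = True
        m = make_matrix(np.where(obs, truth, np.nan), obs)
        out = impute_svd(m, rank=1, max_iter=1000, tol=1e-12)
        assert np.abs(out.values - truth).max() < 1e-6

    def test_rank_clipped_with_warning(self, tiny_matrix, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sectormix.imputers"):
            out = impute_svd(tiny_matrix, rank=50)
        assert out.applicable
        assert any("clipped" in r.message for r in caplog.records)


class TestBPCA:
    def test_beats_mean_baseline_on_rank2(self, masked_rank2):
        masked, mask = masked_rank2
        base = nrmse(mask, impute_row_mean(masked).values).mean_nrmse
        out = impute_bpca(masked)
        assert nrmse(mask, out.values).mean_nrmse < base

    def test_single_sample_not_applicable(self):
        m = make_matrix(np.array([[1.0], [2.0], [3.0]]))
        assert not impute_bpca(m).applicable


class TestLLS:
    def test_exact_donor_row(self):
        rng = np.random.default_rng(6)
        donor = rng.normal(20, 2, 6)
        other = rng.normal(20, 2, (4, 6))
        target = donor.copy()
        target[4] = np.nan
        vals = np.vstack([target, donor, other])
        out = impute_lls(make_matrix(vals), k_similar=2)
        assert out.values[0, 4] == pytest.approx(donor[4], abs=1e-6)

    def test_constant_matrix(self):
        vals = np.full((5, 4), 3.0)
        vals[1, 2] = np.nan
        out = impute_lls(make_matrix(vals))
        assert out.values[1, 2] == pytest.approx(3.0)


class TestMLE:
    def test_perfectly_correlated_samples(self):
        rng = np.random.default_rng(8)
        x = rng.normal(20, 2, 50)
        vals = np.column_stack([x, 2 * x - 5, rng.normal(20, 2, 50)])
        miss = rng.choice(50, 10, replace=False)
        vals[miss, 1] = np.nan
        m = make_matrix(vals)
        out = impute_mle(m, tol=1e-10, max_iter=500)
        np.testing.assert_allclose(out.values[miss, 1], 2 * x[miss] - 5, atol=1e-3)

    def test_loglik_nondecreasing(self):
        rng = np.random.default_rng(13)
        for trial in range(5):
            vals = rng.normal(0, 1, (40, 6)) + rng.normal(0, 1, (40, 1))
            drop = rng.random(vals.shape) < 0.15
            drop[:, 0] = False
            m = make_matrix(np.where(drop, np.nan, vals))
            out = impute_mle(m)
            ll = np.array(out.diagnostics["loglik_trace"])
            assert np.all(np.diff(ll) >= -1e-8 * np.maximum(1, np.abs(ll[:-1])))


class TestCF:
    def test_seed_determinism(self, masked_rank2):
        masked, _ = masked_rank2
        sub = masked.subset_rows(np.arange(50))
        a = impute_cf(sub, epochs=30, seed=1)
        b = impute_cf(sub, epochs=30, seed=1)
        np.testing.assert_array_equal(a.values, b.values)

    def test_beats_baseline_on_rank1(self):
        rng = np.random.default_rng(3)
        truth = np.add.outer(rng.normal(20, 2, 80), rng.normal(0, 1, 10))
        obs = rng.random(truth.shape) > 0.15
        obs[:, 0] = True
        m = make_matrix(np.where(obs, truth, np.nan), obs)
        masked, mask = mask_entries(m, 0.10, seed=4)
        base = nrmse(mask, impute_row_mean(masked).values).mean_nrmse
        out = impute_cf(masked, seed=0)
        assert nrmse(mask, out.values).mean_nrmse < base

    def test_tiny_sector_not_applicable(self):
        m = make_matrix(np.random.default_rng(0).normal(20, 1, (4, 6)))
        assert not impute_cf(m, n_factors=8).applicable


class TestPluginRegistry:
    def test_mean_plugin_registers_and_runs(self, tiny_matrix):
        reg = default_registry()
        register_plugin_imputer(
            reg, ImputerSpec("mean_plugin", lambda m: impute_row_mean(m))
        )
        out = reg["mean_plugin"].run(tiny_matrix)
        assert out.applicable
        assert np.all(np.isfinite(out.values))

    def test_wrong_shape_detected(self, tiny_matrix):
        def bad(m):
            return ImputationOutput(method="bad", values=np.ones((2, 2)))

        reg = register_plugin_imputer({}, ImputerSpec("bad", bad, min_peptides=1))
        with pytest.raises(ContractViolation, match="shape"):
            reg["bad"].run(tiny_matrix)

    def test_mutated_observed_cell_detected(self, tiny_matrix):
        def sneaky(m):
            vals = np.nan_to_num(m.values, nan=0.0)
            vals[0, 0] += 1.0  # corrupt an observed cell
            return ImputationOutput(method="sneaky", values=vals)

        reg = register_plugin_imputer({}, ImputerSpec("sneaky", sneaky, min_peptides=1))
        with pytest.raises(ContractViolation, match="observed"):
            reg["sneaky"].run(tiny_matrix)

    def test_duplicate_name_rejected(self):
        reg = default_registry()
        with pytest.raises(KeyError):
            register_plugin_imputer(reg, ImputerSpec("rf", impute_rf))


class TestAutoencoderPlugins:
    def test_registered_and_produce_finite_output(self):
        from sectormix.plugins import register_autoencoders

        reg = register_autoencoders({})
        assert set(reg) == {"dae", "vae"}
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 2, (40, 8))
        drop = rng.random(vals.shape) < 0.1
        drop[:, 0] = False
        m = make_matrix(np.where(drop, np.nan, vals))
        for name in ("dae", "vae"):
            reg[name].params["epochs"] = 40
            out = reg[name].run(m, seed=0)
            assert out.applicable
            assert np.all(np.isfinite(out.values))
            obs = m.observed
            assert np.array_equal(out.values[obs], m.values[obs])
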