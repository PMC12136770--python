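import numpy as np
import pandas as pd
import pytest

from sectormix.imputers import (
    ImputationOutput,
    ImputerSpec,
    impute_knn,
    impute_row_mean,
    impute_svd,
)
from sectormix.mask_eval import mask_entries, nrmse
from sectormix.mix import (
    assemble_mix,
    compare_methods_whole,
    evaluate_sector_methods,
    sector_nrmse_of,
    select_optimal,
)
from sectormix.sectorize import assign_sectors, compute_thresholds, peptide_summaries
from sectormix.synthetic import SyntheticConfig, generate

from conftest import make_matrix


def small_pipeline(seed=2, n_peptides=200, n_samples=10):
    ds = generate(SyntheticConfig(n_peptides=n_peptides, n_samples=n_samples,
                                  seed=seed))
    m = ds.observed.drop_all_missing_peptides()
    summaries = peptide_summaries(m)
    assignment = assign_sectors(summaries, compute_thresholds(summaries))
    masked, mask = mask_entries(m, 0.10, seed=seed)
    return m, assignment, masked, mask


def oracle_spec(truth_matrix):
    """A perfect imputer: returns the pre-mask ground truth."""

    def run(sub):
        # match rows of the sub-matrix by peptide id
        idx = [truth_matrix.peptide_ids.index(p) for p in sub.peptide_ids]
        vals = np.where(sub.observed, sub.values, truth_matrix.values[idx])
        # cells missing in the pre-mask matrix have no truth: peptide mean
        holes = ~np.isfinite(vals)
        if holes.any():
            row_means = np.nanmean(vals, axis=1)
            vals = np.where(holes, row_means[:, None], vals)
        return ImputationOutput(method="oracle", values=vals)

    return ImputerSpec("oracle", run, min_peptides=1)


def noisy_spec(sd=2.0):
    def run(sub):
        rng = np.random.default_rng(0)
        fill = impute_row_mean(sub).values + rng.normal(0, sd, sub.values.shape)
        vals = np.where(sub.observed, sub.values, fill)
        return ImputationOutput(method="noisy", values=vals)

    return ImputerSpec("noisy", run, min_peptides=1)


DET_REGISTRY = {
    "knn": ImputerSpec("knn", impute_knn, {"k": 5}),
    "svd": ImputerSpec("svd", impute_svd, {"rank": 3}),
}


class TestEvaluation:
    def test_single_method_chosen_everywhere(self):
        m, assignment, masked, mask = small_pipeline()
        reg = {"knn": DET_REGISTRY["knn"]}
        ev = evaluate_sector_methods(masked, assignment, mask, reg)
        plan = select_optimal(ev, fallback_method="knn")
        assert set(plan.choices.values()) <= {"knn"}

    def test_oracle_scores_zero_and_wins(self):
        m, assignment, masked, mask = small_pipeline()
        reg = {"oracle": oracle_spec(m), "noisy": noisy_spec()}
        ev = evaluate_sector_methods(masked, assignment, mask, reg)
        for (sector, method), res in ev.results.items():
            if method == "oracle":
                assert res.mean_nrmse == pytest.approx(0.0, abs=1e-12)
        plan = select_optimal(ev)
        evaluated = {s for s, _ in ev.results.items()}
        for sector, choice in plan.choices.items():
            if (sector, "oracle") in ev.results:
                assert choice == "oracle"

    def test_table_matches_independent_recomputation(self):
        m, assignment, masked, mask = small_pipeline(seed=5)
        ev = evaluate_sector_methods(masked, assignment, mask, DET_REGISTRY)
        # re-impute each sector independently and recompute
        codes = np.asarray(assignment, dtype=object)
        for (sector, method), res in ev.results.items():
            idx = np.flatnonzero(codes == sector)
            sub = masked.subset_rows(idx)
            out = DET_REGISTRY[method].run(sub)
            scope = np.isin(mask.rows, idx)
            full = np.zeros_like(masked.values)
            full[idx] = out.values
            expected = nrmse(mask, full, scope=scope).mean_nrmse
            assert res.mean_nrmse == pytest.approx(expected, abs=1e-12)


class TestSelection:
    def _ev_from_table(self, table):
        from sectormix.mix import SectorEvaluation
        from sectormix.mask_eval import EvalResult

        ev = SectorEvaluation()
        for (sector, method), val in table.items():
            ev.results[(sector, method)] = EvalResult(
                per_sample_nrmse=np.array([val]), mean_nrmse=val, ci95=0.0,
                n_cells_per_sample=np.array([2]),
            )
            ev.sector_counts.setdefault(sector, 10)
        return ev

    def test_lowest_wins(self):
        ev = self._ev_from_table({("MIMM", "rf"): 0.08, ("MIMM", "bpca"): 0.09})
        assert select_optimal(ev).choices["MIMM"] == "rf"

    def test_exact_tie_broken_by_canonical_order(self):
        ev = self._ev_from_table({("MIMM", "bpca"): 0.10, ("MIMM", "rf"): 0.10})
        plan = select_optimal(ev)
        assert plan.choices["MIMM"] == "rf"  # rf precedes bpca canonically
        assert plan.ties["MIMM"] == ["bpca"]

    def test_fallback_when_nothing_applicable(self):
        from sectormix.mix import SectorEvaluation

        ev = SectorEvaluation()
        ev.sector_counts["HIHM"] = 3
        ev.not_applicable[("HIHM", "cf")] = "too small"
        plan = select_optimal(ev, fallback_method="rf")
        assert plan.choices["HIHM"] == "rf"
        assert "HIHM" in plan.fallbacks

    def test_deterministic(self):
        ev = self._ev_from_table({("LILM", "svd"): 0.3, ("LILM", "knn"): 0.2,
                                  ("MIMM", "svd"): 0.1, ("MIMM", "knn"): 0.4})
        p1, p2 = select_optimal(ev), select_optimal(ev)
        assert p1.choices == p2.choices == {"LILM": "knn", "MIMM": "svd"}


class TestAssembly:
    def test_single_sector_equals_method_alone(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(20, 2, (30, 6))
        drop = rng.random(vals.shape) < 0.1
        drop[:, 0] = False
        m = make_matrix(np.where(drop, np.nan, vals))
        assignment = pd.Series(["MIMM"] * 30)
        from sectormix.mix import MixPlan

        plan = MixPlan(choices={"MIMM": "knn"})
        out = assemble_mix(m, assignment, plan, DET_REGISTRY)
        direct = DET_REGISTRY["knn"].run(m)
        np.testing.assert_array_equal(out.values, direct.values)

    def test_sector_nrmse_equals_evaluation_minimum(self):
        m, assignment, masked, mask = small_pipeline(seed=3)
        ev = evaluate_sector_methods(masked, assignment, mask, DET_REGISTRY)
        plan = select_optimal(ev, fallback_method="knn")
        # assemble WITHOUT the evaluation cache: methods are deterministic
        mix = assemble_mix(masked, assignment, plan, DET_REGISTRY,
                           fallback_method="knn")
        got = sector_nrmse_of(mix.values, assignment, mask)
        for sector, val in got.items():
            scored = [res.mean_nrmse for (s, meth), res in ev.results.items()
                      if s == sector]
            if scored:
                assert val == pytest.approx(min(scored), abs=1e-12)

    def test_row_order_and_observed_preserved(self):
        m, assignment, masked, mask = small_pipeline(seed=4)
        ev = evaluate_sector_methods(masked, assignment, mask, DET_REGISTRY)
        plan = select_optimal(ev, fallback_method="knn")
        mix = assemble_mix(masked, assignment, plan, DET_REGISTRY,
                           evaluation=ev, fallback_method="knn")
        obs = masked.observed
        np.testing.assert_array_equal(mix.values[obs], masked.values[obs])
        assert mix.values.shape == masked.values.shape

    def test_permutation_equivariance(self):
        m, assignment, masked, mask = small_pipeline(seed=6, n_peptides=120)
        ev = evaluate_sector_methods(masked, assignment, mask, DET_REGISTRY)
        plan = select_optimal(ev, fallback_method="knn")
        mix = assemble_mix(masked, assignment, plan, DET_REGISTRY,
                           fallback_method="knn")
        perm = np.random.default_rng(0).permutation(masked.n_peptides)
        masked_p = masked.subset_rows(perm)
        assignment_p = pd.Series(np.asarray(assignment)[perm])
        mix_p = assemble_mix(masked_p, assignment_p, plan, DET_REGISTRY,
                             fallback_method="knn")
        np.testing.assert_allclose(mix_p.values, mix.values[perm], atol=1e-10)


class TestWholeMatrixComparison:
    def test_oracle_separated_from_noise_by_tukey(self):
        m, assignment, masked, mask = small_pipeline(seed=8)
        reg = {"oracle": oracle_spec(m), "noisy": noisy_spec(sd=3.0)}
        table, anova = compare_methods_whole(masked, mask, reg)
        tab = table.set_index("method")
        assert tab.loc["oracle", "mean_nrmse"] == pytest.approx(0.0, abs=1e-12)
        assert tab.loc["noisy", "mean_nrmse"] > 0.5
        assert anova["p_value"] < 0.01
        tk = anova["tukey"]
        assert tk is not None and bool(tk.iloc[0]["reject"])

    def test_single_method_table(self):
        m, assignment, masked, mask = small_pipeline(seed=9)
        reg = {"knn": DET_REGISTRY["knn"]}
        table, anova = compare_methods_whole(masked, mask, reg)
        assert list(table["method"]) == ["knn"]
        mix = ImputationOutput(method="mix",
                               values=impute_row_mean(masked).values)
        table2, _ = compare_methods_whole(masked, mask, reg, mix_output=mix)
        assert list(table2["method"]) == ["knn", "mix"]
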