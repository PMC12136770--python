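"""Per-sector method selection and assembly of the mixed imputation.

The strategy: partition peptides into nine intensity x missing-rate
sectors, score every registered imputer on each sector's masked cells by
sample-wise NRMSE, pick the numerically best method per sector, and
assemble the final matrix sector by sector. Each method is fit on the
sector's sub-matrix only (all samples, that sector's peptides); the
whole-matrix comparison fits every method on the full matrix instead, to
quantify what stratification buys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PeptideMatrix
from .imputers import ImputationOutput, ImputerSpec, method_sort_key
from .mask_eval import EvalResult, MaskSet, nrmse

logger = logging.getLogger(__name__)


@dataclass
class SectorEvaluation:
    """Per-(sector, method) NRMSE table from one shared mask.

    ``results`` maps (sector, method) to an :class:`EvalResult`; methods
    that were not applicable in a sector are listed in ``not_applicable``
    with the reason. ``outputs`` caches each applicable method's imputed
    sector sub-matrix so assembly can reuse it instead of re-fitting.
    """

    results: dict[tuple[str, str], EvalResult] = field(default_factory=dict)
    not_applicable: dict[tuple[str, str], str] = field(default_factory=dict)
    sector_counts: dict[str, int] = field(default_factory=dict)
    unevaluable_sectors: list[str] = field(default_factory=list)
    outputs: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sector, method), res in sorted(
            self.results.items(), key=lambda kv: (kv[0][0], method_sort_key(kv[0][1]))
        ):
            rows.append({
                "sector": sector, "method": method,
                "mean_nrmse": res.mean_nrmse, "ci95": res.ci95,
                "n_samples_defined": res.n_samples_defined,
                "n_peptides": self.sector_counts.get(sector, 0),
            })
        for (sector, method), reason in sorted(self.not_applicable.items()):
            rows.append({"sector": sector, "method": method,
                         "mean_nrmse": np.nan, "ci95": np.nan,
                         "n_samples_defined": 0,
                         "n_peptides": self.sector_counts.get(sector, 0),
                         "note": reason})
        return pd.DataFrame(rows)


@dataclass
class MixPlan:
    """Chosen method per sector, with tie/fallback annotations."""

    choices: dict[str, str]
    ties: dict[str, list[str]] = field(default_factory=dict)
    fallbacks: dict[str, str] = field(default_factory=dict)  # sector -> reason

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sector in sorted(self.choices):
            rows.append({
                "sector": sector,
                "method": self.choices[sector],
                "tied_with": ",".join(self.ties.get(sector, [])),
                "fallback_reason": self.fallbacks.get(sector, ""),
            })
        return pd.DataFrame(rows)


def _sector_indices(assignment: pd.Series) -> dict[str, np.ndarray]:
    codes = np.asarray(assignment, dtype=object)
    out = {}
    for code in pd.unique(codes):
        out[str(code)] = np.flatnonzero(codes == code)
    return out


def evaluate_sector_methods(
    masked: PeptideMatrix,
    assignment: pd.Series,
    mask: MaskSet,
    registry: dict[str, ImputerSpec],
    seed: int | None = None,
) -> SectorEvaluation:
    """Score every registered method in every sector on the shared mask.

    The sector assignment must come from the pre-mask matrix and the mask
    from that same matrix. Each applicable method imputes the sector
    sub-matrix of the *masked* data; NRMSE is computed on the sector's
    masked cells, sample-wise. Sectors with no masked cells are marked
    unevaluable.
    """
    ev = SectorEvaluation()
    sectors = _sector_indices(assignment)
    for sector in sorted(sectors):
        idx = sectors[sector]
        ev.sector_counts[sector] = int(idx.size)
        in_sector = np.isin(mask.rows, idx)
        if not in_sector.any():
            logger.warning("sector %s has no masked cells; unevaluable", sector)
            ev.unevaluable_sectors.append(sector)
            continue
        sub = masked.subset_rows(idx)
        # remap mask cells into sub-matrix row coordinates
        pos = {int(g): i for i, g in enumerate(idx)}
        sub_rows = np.array([pos[int(r)] for r in mask.rows[in_sector]])
        sub_mask = MaskSet(rows=sub_rows, cols=mask.cols[in_sector],
                           truth=mask.truth[in_sector], seed=mask.seed,
                           fraction=mask.fraction)
        for name in sorted(registry, key=method_sort_key):
            out = registry[name].run(sub, seed=seed)
            if not out.applicable:
                ev.not_applicable[(sector, name)] = out.reason or "not applicable"
                continue
            try:
                res = nrmse(sub_mask, out.values)
            except ValueError as exc:
                ev.not_applicable[(sector, name)] = f"unevaluable: {exc}"
                continue
            ev.results[(sector, name)] = res
            ev.outputs[(sector, name)] = out.values
    return ev


def select_optimal(
    evaluation: SectorEvaluation,
    fallback_method: str = "rf",
) -> MixPlan:
    """Pick the lowest-NRMSE applicable method per sector.

    Exact ties are broken by the canonical method order (deterministic,
    logged). Sectors with no applicable or evaluable method fall back to
    ``fallback_method`` with a warning.
    """
    plan = MixPlan(choices={})
    sectors = sorted(
        set(evaluation.sector_counts) | {s for s, _ in evaluation.results}
    )
    for sector in sectors:
        scored = {
            m: res.mean_nrmse
            for (s, m), res in evaluation.results.items()
            if s == sector and np.isfinite(res.mean_nrmse)
        }
        if not scored:
            logger.warning(
                "sector %s: no applicable method; falling back to %s",
                sector, fallback_method,
            )
            plan.choices[sector] = fallback_method
            plan.fallbacks[sector] = "no applicable method in evaluation"
            continue
        best_val = min(scored.values())
        tied = sorted((m for m, v in scored.items() if v == best_val),
                      key=method_sort_key)
        plan.choices[sector] = tied[0]
        if len(tied) > 1:
            logger.info("sector %s: tie between %s; chose %s by canonical order",
                        sector, tied, tied[0])
            plan.ties[sector] = tied[1:]
    return plan


def assemble_mix(
    masked: PeptideMatrix,
    assignment: pd.Series,
    plan: MixPlan,
    registry: dict[str, ImputerSpec],
    seed: int | None = None,
    evaluation: SectorEvaluation | None = None,
    fallback_method: str = "rf",
) -> ImputationOutput:
    """Impute each sector with its chosen method and reassemble.

    Rows come back in the original order; observed cells pass through
    unchanged. When ``evaluation`` is supplied, its cached sector outputs
    are reused (the methods are deterministic given the seed, so this is
    an exact shortcut). A chosen method that fails at assembly time is
    replaced by ``fallback_method`` for that sector, logged.
    """
    values = masked.values.copy()
    sectors = _sector_indices(assignment)
    missing_plan = set(sectors) - set(plan.choices)
    if missing_plan:
        raise ValueError(f"plan missing sectors: {sorted(missing_plan)}")
    used: dict[str, str] = {}
    for sector, idx in sorted(sectors.items()):
        method = plan.choices[sector]
        if evaluation is not None and (sector, method) in evaluation.outputs:
            values[idx] = evaluation.outputs[(sector, method)]
            used[sector] = method
            continue
        sub = masked.subset_rows(idx)
        out = registry[method].run(sub, seed=seed)
        if not out.applicable:
            logger.warning(
                "sector %s: chosen method %s not applicable at assembly; "
                "falling back to %s", sector, method, fallback_method,
            )
            out = registry[fallback_method].run(sub, seed=seed)
            method = fallback_method
            if not out.applicable:
                # last resort for sectors too small for any model
                from .imputers import impute_row_mean

                logger.warning(
                    "sector %s: fallback %s not applicable either; using "
                    "peptide-mean fill", sector, fallback_method,
                )
                out = impute_row_mean(sub)
                method = "mean"
        values[idx] = out.values
        used[sector] = method
    still_missing = ~np.isfinite(values)
    if still_missing.any():
        raise RuntimeError("assembled matrix still has non-finite cells")
    return ImputationOutput(method="mix", values=values,
                            diagnostics={"sector_methods": used})


def compare_methods_whole(
    masked: PeptideMatrix,
    mask: MaskSet,
    registry: dict[str, ImputerSpec],
    mix_output: ImputationOutput | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Whole-matrix comparison: every method without stratification vs Mix.

    Each registered method imputes the full matrix ignoring sectors; the
    table reports mean sample-wise NRMSE with its 95% CI half-width. A
    one-way ANOVA across methods on the per-sample NRMSE values and Tukey
    HSD pairwise comparisons summarize whether methods differ.
    """
    per_sample: dict[str, np.ndarray] = {}
    rows = []
    for name in sorted(registry, key=method_sort_key):
        out = registry[name].run(masked, seed=seed)
        if not out.applicable:
            logger.info("whole-matrix comparison: %s excluded (%s)", name, out.reason)
            rows.append({"method": name, "mean_nrmse": np.nan, "ci95": np.nan,
                         "note": out.reason})
            continue
        res = nrmse(mask, out.values)
        per_sample[name] = res.per_sample_nrmse
        rows.append({"method": name, "mean_nrmse": res.mean_nrmse,
                     "ci95": res.ci95, "note": ""})
    if mix_output is not None:
        res = nrmse(mask, mix_output.values)
        per_sample["mix"] = res.per_sample_nrmse
        rows.append({"method": "mix", "mean_nrmse": res.mean_nrmse,
                     "ci95": res.ci95, "note": ""})
    table = pd.DataFrame(rows)

    anova: dict = {"f_stat": np.nan, "p_value": np.nan, "tukey": None}
    groups = {m: v[np.isfinite(v)] for m, v in per_sample.items()}
    groups = {m: v for m, v in groups.items() if v.size >= 2}
    if len(groups) >= 2:
        f, p = stats.f_oneway(*groups.values())
        anova["f_stat"], anova["p_value"] = float(f), float(p)
        try:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd

            data = np.concatenate(list(groups.values()))
            labels = np.concatenate(
                [np.full(v.size, m, dtype=object) for m, v in groups.items()]
            )
            tk = pairwise_tukeyhsd(data, labels)
            anova["tukey"] = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
        except Exception as exc:  # pragma: no cover - small-sample corner
            logger.warning("Tukey HSD unavailable: %s", exc)
    return table, anova


def sector_nrmse_of(
    values: np.ndarray,
    assignment: pd.Series,
    mask: MaskSet,
) -> dict[str, float]:
    """Mean sample-wise NRMSE of one imputed matrix, per sector."""
    out = {}
    for sector, idx in sorted(_sector_indices(assignment).items()):
        scope = np.isin(mask.rows, idx)
        if not scope.any():
            continue
        try:
            out[sector] = nrmse(mask, values, scope=scope).mean_nrmse
        except ValueError:
            out[sector] = float("nan")
    return out
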