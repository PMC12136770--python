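"""End-to-end pipeline runs behind the command-line interface.

Each run follows the three-step strategy: (1) sectorize the peptides of
the input matrix, (2) hide a seeded fraction of observed cells and score
every registered imputer per sector by sample-wise NRMSE, (3) pick the
per-sector winners and assemble the mixed imputation. The production
output imputes the *original* missing cells of the unmasked matrix with
the per-sector methods chosen on the masked evaluation. Every run writes
a YAML manifest (thresholds, seeds, sector sizes, chosen methods)
sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .core_io import (
    GroupDesign,
    PeptideMatrix,
    read_abundance_table,
    read_group_design,
    write_abundance_table,
    write_group_design,
)
from .diffexpr import moderated_t_test, reproducibility, roc_curve
from .imputers import ImputerSpec, default_registry
from .mask_eval import MaskSet, mask_entries, nrmse, spearman_masked
from .mix import (
    MixPlan,
    SectorEvaluation,
    assemble_mix,
    compare_methods_whole,
    evaluate_sector_methods,
    sector_nrmse_of,
    select_optimal,
)
from .sectorize import (
    SectorGrid,
    assign_sectors,
    compute_thresholds,
    intensity_missingness_regression,
    peptide_summaries,
    sector_sizes,
)
from .synthetic import SyntheticConfig, SyntheticDataset, config_to_dict, generate

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ["knn", "rf", "svd", "bpca", "lls", "mle", "cf"]


class RunConfig(BaseModel):
    """Validated configuration for a pipeline run.

    Defaults mirror the reference protocol: intensity thresholds at the
    25%/75% quantiles, missing-rate thresholds at 25%/75%, a 10% masked
    fraction, and significance at BH-adjusted p < 0.05.
    """

    model_config = {"extra": "forbid"}

    input_path: str | None = None
    design_path: str | None = None
    synthetic: dict | None = None
    na_codes: list[str] = ["", "NA", "NaN"]
    zero_is_missing: bool = False
    log_transform: bool = False
    intensity_quantiles: tuple[float, float] = (0.25, 0.75)
    miss_thresholds: tuple[float, float] = (0.25, 0.75)
    mask_fraction: float = Field(0.10, gt=0.0, lt=1.0)
    seed: int = 0
    methods: list[str] = Field(default_factory=lambda: list(DEFAULT_METHODS))
    method_params: dict[str, dict] = Field(default_factory=dict)
    fallback_method: str = "rf"
    confirmation_mask: bool = False
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    out_dir: str = "sectormix_out"

    @model_validator(mode="after")
    def _check(self):
        if self.input_path is None and self.synthetic is None:
            raise ValueError("provide input_path or a synthetic block")
        qlo, qhi = self.intensity_quantiles
        if not (0 < qlo < qhi < 1):
            raise ValueError("intensity_quantiles must be increasing in (0,1)")
        mlo, mhi = self.miss_thresholds
        if not (0 < mlo < mhi < 1):
            raise ValueError("miss_thresholds must be increasing in (0,1)")
        unknown = set(self.method_params) - set(self.methods)
        if unknown:
            raise ValueError(f"method_params for unlisted method(s): {sorted(unknown)}")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def build_registry(config: RunConfig) -> dict[str, ImputerSpec]:
    base = default_registry()
    registry: dict[str, ImputerSpec] = {}
    for name in config.methods:
        if name in base:
            registry[name] = base[name]
        elif name in ("dae", "vae"):
            from .plugins import register_autoencoders

            tmp: dict[str, ImputerSpec] = {}
            register_autoencoders(tmp)
            registry[name] = tmp[name]
        else:
            raise ValueError(f"unknown imputation method {name!r}")
        if name in config.method_params:
            registry[name].params.update(config.method_params[name])
    return registry


def load_matrix(config: RunConfig) -> tuple[PeptideMatrix, SyntheticDataset | None]:
    if config.input_path is not None:
        matrix = read_abundance_table(
            config.input_path,
            na_codes=config.na_codes,
            zero_is_missing=config.zero_is_missing,
            log_transform=config.log_transform,
        )
        return matrix, None
    syn = generate(SyntheticConfig(**config.synthetic))
    return syn.observed.drop_all_missing_peptides(), syn


def load_design(config: RunConfig, syn: SyntheticDataset | None) -> GroupDesign | None:
    if config.design_path is not None:
        return read_group_design(config.design_path)
    if syn is not None:
        return syn.design
    return None


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(path: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "sectormix_version": __version__,
        "config": config.model_dump(mode="json"),
        "config_hash": _config_hash(config),
        **extra,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def cmd_simulate(config: RunConfig) -> dict[str, Path]:
    """Generate a synthetic dataset and write truth/observed/label files."""
    if config.synthetic is None:
        raise ValueError("simulate requires a synthetic block in the config")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    syn = generate(SyntheticConfig(**config.synthetic))
    paths = {
        "truth": out / "truth.tsv",
        "observed": out / "observed.tsv",
        "labels": out / "labels.tsv",
        "manifest": out / "manifest.yaml",
    }
    write_abundance_table(syn.truth, paths["truth"])
    write_abundance_table(syn.observed, paths["observed"])
    pd.DataFrame(
        {"peptide_id": syn.truth.peptide_ids, "true_de": syn.true_de_labels}
    ).to_csv(paths["labels"], sep="\t", index=False)
    if syn.design is not None:
        paths["design"] = out / "design.tsv"
        write_group_design(syn.design, paths["design"])
    write_manifest(paths["manifest"], config, {
        "stage": "simulate",
        "synthetic_config": config_to_dict(syn.config),
        "missing_fraction": float(syn.observed.missing_fraction),
    })
    return paths


class ImputeRun:
    """Result bundle of one mix-imputation run (see :func:`run_impute`)."""

    def __init__(self, **kw):
        self.__dict__.update(kw)


def run_impute(config: RunConfig) -> ImputeRun:
    """Sectorize, mask, evaluate, select, assemble; impute original MVs."""
    registry = build_registry(config)
    matrix, syn = load_matrix(config)

    stage = "sectorize"
    try:
        summaries = peptide_summaries(matrix)
        grid = compute_thresholds(summaries, config.intensity_quantiles,
                                  config.miss_thresholds)
        assignment = assign_sectors(summaries, grid)
        regression = intensity_missingness_regression(summaries)

        stage = "mask"
        masked, mask = mask_entries(matrix, config.mask_fraction, config.seed)

        stage = "sector evaluation"
        evaluation = evaluate_sector_methods(masked, assignment, mask,
                                             registry, seed=config.seed)

        stage = "selection"
        plan = select_optimal(evaluation, fallback_method=config.fallback_method)

        stage = "mix assembly"
        mix_eval = assemble_mix(masked, assignment, plan, registry,
                                seed=config.seed, evaluation=evaluation,
                                fallback_method=config.fallback_method)
        mix_sector_nrmse = sector_nrmse_of(mix_eval.values, assignment, mask)
        mix_overall = nrmse(mask, mix_eval.values)

        confirmation = None
        if config.confirmation_mask:
            stage = "confirmation mask"
            masked2, mask2 = mask_entries(matrix, config.mask_fraction,
                                          config.seed + 104729)
            mix2 = assemble_mix(masked2, assignment, plan, registry,
                                seed=config.seed,
                                fallback_method=config.fallback_method)
            confirmation = nrmse(mask2, mix2.values)

        stage = "final imputation"
        final = assemble_mix(matrix, assignment, plan, registry,
                             seed=config.seed,
                             fallback_method=config.fallback_method)
    except Exception as exc:
        raise RuntimeError(f"impute pipeline failed at stage: {stage}") from exc

    imputed = PeptideMatrix(
        values=final.values,
        observed=np.ones_like(matrix.observed),
        peptide_ids=list(matrix.peptide_ids),
        sample_ids=list(matrix.sample_ids),
        groups=list(matrix.groups) if matrix.groups is not None else None,
    )
    return ImputeRun(
        config=config, registry=registry, matrix=matrix, synthetic=syn,
        summaries=summaries, grid=grid, assignment=assignment,
        regression=regression, masked=masked, mask=mask,
        evaluation=evaluation, plan=plan, mix_eval=mix_eval,
        mix_sector_nrmse=mix_sector_nrmse, mix_overall=mix_overall,
        confirmation=confirmation, imputed=imputed,
    )


def cmd_impute(config: RunConfig) -> dict[str, Path]:
    """CLI entry: run :func:`run_impute` and write all artifacts."""
    run = run_impute(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "imputed": out / "imputed.tsv",
        "sector_nrmse": out / "sector_nrmse.tsv",
        "mixplan": out / "mixplan.tsv",
        "assignment": out / "sectors.tsv",
        "manifest": out / "manifest.yaml",
    }
    write_abundance_table(run.imputed, paths["imputed"])
    run.evaluation.to_frame().to_csv(paths["sector_nrmse"], sep="\t", index=False)
    run.plan.to_frame().to_csv(paths["mixplan"], sep="\t", index=False)
    pd.DataFrame({
        "peptide_id": run.summaries["peptide_id"], "sector": run.assignment,
    }).to_csv(paths["assignment"], sep="\t", index=False)
    extra = {
        "stage": "impute",
        "thresholds": {
            "intensity_low": run.grid.intensity_low,
            "intensity_high": run.grid.intensity_high,
            "miss_low": run.grid.miss_low,
            "miss_high": run.grid.miss_high,
        },
        "sector_sizes": {k: int(v) for k, v in
                         sector_sizes(run.assignment).items()},
        "sector_methods": {k: str(v) for k, v in run.plan.choices.items()},
        "mask": {"n_cells": run.mask.n_cells, "deficit": run.mask.deficit,
                 "fraction": run.mask.fraction, "seed": run.mask.seed},
        "mix_nrmse_selection_mask": float(run.mix_overall.mean_nrmse),
        "mix_nrmse_note": (
            "NRMSE on the selection mask is optimistically biased because the "
            "same mask chose the per-sector methods; enable confirmation_mask "
            "for an unbiased estimate"
        ),
        "intensity_missingness": {
            "slope": run.regression.slope, "r2": run.regression.r2,
            "p_value": run.regression.p_value,
        },
    }
    if run.confirmation is not None:
        extra["mix_nrmse_confirmation_mask"] = float(run.confirmation.mean_nrmse)
    write_manifest(paths["manifest"], config, extra)
    return paths


def run_evaluate(config: RunConfig) -> dict:
    """Whole-matrix method comparison (no stratification) plus Mix."""
    run = run_impute(config)
    table, anova = compare_methods_whole(run.masked, run.mask, run.registry,
                                         mix_output=run.mix_eval,
                                         seed=config.seed)
    # Spearman of truth vs imputed at masked cells, per method and for Mix
    rhos = {}
    for name, spec in sorted(run.registry.items()):
        out_m = spec.run(run.masked, seed=config.seed)
        if out_m.applicable:
            rhos[name] = spearman_masked(run.mask, out_m.values)
    rhos["mix"] = spearman_masked(run.mask, run.mix_eval.values)
    table["spearman_rho"] = table["method"].map(rhos)
    return {"run": run, "table": table, "anova": anova}


def cmd_evaluate(config: RunConfig) -> dict[str, Path]:
    res = run_evaluate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"comparison": out / "whole_matrix_comparison.tsv",
             "manifest": out / "manifest.yaml"}
    res["table"].to_csv(paths["comparison"], sep="\t", index=False)
    if res["anova"]["tukey"] is not None:
        paths["tukey"] = out / "tukey.tsv"
        res["anova"]["tukey"].to_csv(paths["tukey"], sep="\t", index=False)
    write_manifest(paths["manifest"], config, {
        "stage": "evaluate",
        "anova_f": float(res["anova"]["f_stat"]),
        "anova_p": float(res["anova"]["p_value"]),
    })
    return paths


def run_diffexp(config: RunConfig) -> dict:
    """Differential expression on imputed data, vs the unmasked reference.

    The reference significant set comes from the unmasked matrix imputed
    with the mix plan; each method (and Mix) is then scored after the
    masked run, by reproducibility of the reference set and, when true
    labels exist (synthetic spike-in), by ROC AUC.
    """
    run = run_impute(config)
    design = load_design(config, run.synthetic)
    if design is None:
        raise ValueError("diffexp requires a group design (design_path or "
                         "a synthetic two-group config)")
    alpha = config.alpha
    reference_de = moderated_t_test(run.imputed, design, alpha=alpha)
    ref_sig = set(reference_de.loc[reference_de["significant"], "peptide_id"])

    labels = None
    if run.synthetic is not None and run.synthetic.true_de_labels.any():
        by_id = dict(zip(run.synthetic.truth.peptide_ids,
                         run.synthetic.true_de_labels))
        labels = np.array([by_id[p] for p in run.matrix.peptide_ids])

    rows = []
    de_tables = {"reference": reference_de}
    roc_results = {}

    def _score(name: str, values: np.ndarray):
        imput = PeptideMatrix(values=values,
                              observed=np.ones_like(run.matrix.observed),
                              peptide_ids=list(run.matrix.peptide_ids),
                              sample_ids=list(run.matrix.sample_ids),
                              groups=list(run.matrix.groups)
                              if run.matrix.groups is not None else None)
        de = moderated_t_test(imput, design, alpha=alpha)
        de_tables[name] = de
        sig = set(de.loc[de["significant"], "peptide_id"])
        rep = reproducibility(ref_sig, sig)
        row = {"method": name, "n_significant": len(sig),
               "reproducibility": rep["fraction"]}
        if labels is not None and np.unique(labels).size == 2:
            roc = roc_curve(de, labels, alpha=alpha)
            roc_results[name] = roc
            row.update(auc=roc.auc, tpr=roc.operating_tpr, fpr=roc.operating_fpr)
        rows.append(row)

    _score("mix", run.mix_eval.values)
    for name, spec in sorted(run.registry.items()):
        out_m = spec.run(run.masked, seed=config.seed)
        if out_m.applicable:
            _score(name, out_m.values)
        else:
            rows.append({"method": name, "n_significant": 0,
                         "reproducibility": float("nan")})
    table = pd.DataFrame(rows)
    return {"run": run, "table": table, "reference_de": reference_de,
            "de_tables": de_tables, "roc": roc_results,
            "n_reference_sig": len(ref_sig)}


def cmd_diffexp(config: RunConfig) -> dict[str, Path]:
    res = run_diffexp(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"summary": out / "diffexp_summary.tsv",
             "reference_de": out / "reference_de.tsv",
             "manifest": out / "manifest.yaml"}
    res["table"].to_csv(paths["summary"], sep="\t", index=False)
    res["reference_de"].to_csv(paths["reference_de"], sep="\t", index=False)
    for name, roc in res["roc"].items():
        p = out / f"roc_{name}.tsv"
        pd.DataFrame({"threshold_p": roc.thresholds, "fpr": roc.fpr,
                      "tpr": roc.tpr}).to_csv(p, sep="\t", index=False)
        paths[f"roc_{name}"] = p
    write_manifest(paths["manifest"], config, {
        "stage": "diffexp",
        "n_reference_significant": int(res["n_reference_sig"]),
        "alpha": config.alpha,
    })
    return paths
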