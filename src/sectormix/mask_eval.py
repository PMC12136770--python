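"""Masked-entry evaluation: seeded random masking, NRMSE and Spearman.

To score an imputer without external ground truth, a seeded random subset
of *observed* cells is hidden ("masked"), the matrix is imputed, and the
imputed values at the masked cells are compared to the held-back truth.

The error metric is the sample-wise normalized root mean square error:
for each sample, over its masked cells,

    NRMSE = RMSE / sigma = sqrt(mean((S_i - O_i)^2)) / sd(O_i)

where S are imputed and O ground-truth values and sd uses the N-1
denominator. Per-sample values are aggregated by their unweighted mean,
with a t-distribution 95% confidence half-width across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PeptideMatrix

logger = logging.getLogger(__name__)


@dataclass
class MaskSet:
    """Cells hidden for evaluation, with their ground-truth values.

    ``rows``/``cols`` index into the matrix the mask was drawn from;
    ``truth`` holds the original log2 values. ``deficit`` counts how far
    the achieved mask fell short of ``round(fraction * n_observed)``
    because of the retain-one-observed-value-per-peptide constraint.
    """

    rows: np.ndarray
    cols: np.ndarray
    truth: np.ndarray
    seed: int
    fraction: float
    deficit: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        self.truth = np.asarray(self.truth, dtype=float)
        if not (self.rows.shape == self.cols.shape == self.truth.shape):
            raise ValueError("rows, cols and truth must have equal length")
        if len({(int(r), int(c)) for r, c in zip(self.rows, self.cols)}) != self.rows.size:
            raise ValueError("mask cells must be unique")

    @property
    def n_cells(self) -> int:
        return int(self.rows.size)

    def to_frame(self, matrix: PeptideMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peptide_id": [matrix.peptide_ids[r] for r in self.rows],
                "sample_id": [matrix.sample_ids[c] for c in self.cols],
                "truth": self.truth,
            }
        )


@dataclass
class EvalResult:
    """Sample-wise NRMSE summary for one imputation on one mask scope."""

    per_sample_nrmse: np.ndarray  # NaN where undefined (<2 cells or sigma = 0)
    mean_nrmse: float
    ci95: float
    n_cells_per_sample: np.ndarray

    @property
    def n_samples_defined(self) -> int:
        return int(np.isfinite(self.per_sample_nrmse).sum())


def mask_entries(
    matrix: PeptideMatrix, fraction: float, seed: int
) -> tuple[PeptideMatrix, MaskSet]:
    """Hide a seeded uniform random fraction of observed cells.

    The target count is ``round(fraction * n_observed)``. Cells are drawn
    without replacement from the observed cells, subject to every peptide
    retaining at least one observed value (several imputers are undefined
    for fully missing rows); any shortfall is logged and recorded as
    ``deficit``. The returned matrix has the masked cells set missing; the
    ground truth lives in the :class:`MaskSet`.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    obs_rows, obs_cols = np.nonzero(matrix.observed)
    n_observed = obs_rows.size
    target = int(round(fraction * n_observed))
    if target == 0:
        raise ValueError("fraction too small: zero cells would be masked")

    order = rng.permutation(n_observed)
    remaining = matrix.observed.sum(axis=1).astype(int)
    take_rows: list[int] = []
    take_cols: list[int] = []
    for idx in order:
        if len(take_rows) == target:
            break
        r, c = int(obs_rows[idx]), int(obs_cols[idx])
        if remaining[r] <= 1:
            continue  # retain >=1 observed value per peptide
        remaining[r] -= 1
        take_rows.append(r)
        take_cols.append(c)
    deficit = target - len(take_rows)
    if deficit:
        logger.warning(
            "retain-one constraint left mask %d cell(s) short of target %d",
            deficit, target,
        )
    rows = np.array(take_rows, dtype=int)
    cols = np.array(take_cols, dtype=int)
    truth = matrix.values[rows, cols].copy()

    masked = matrix.copy()
    masked.values[rows, cols] = np.nan
    masked.observed[rows, cols] = False
    mask = MaskSet(rows=rows, cols=cols, truth=truth, seed=seed,
                   fraction=fraction, deficit=deficit)
    return masked, mask


def restore_truth(masked: PeptideMatrix, mask: MaskSet) -> PeptideMatrix:
    """Put the ground-truth values back; inverse of :func:`mask_entries`."""
    out = masked.copy()
    out.values[mask.rows, mask.cols] = mask.truth
    out.observed[mask.rows, mask.cols] = True
    return out


def nrmse(
    mask: MaskSet,
    imputed: PeptideMatrix | np.ndarray,
    scope: np.ndarray | None = None,
) -> EvalResult:
    """Sample-wise NRMSE of imputed values at masked cells.

    ``scope`` optionally restricts the evaluation to a boolean subset of
    the mask's cells (e.g. one sector's peptides). Per sample, the RMSE
    over its scoped masked cells is divided by the N-1 standard deviation
    of that sample's scoped ground-truth values; samples with fewer than
    two scoped cells, or with zero truth variance, are undefined and are
    excluded from the mean (logged).
    """
    values = imputed.values if isinstance(imputed, PeptideMatrix) else np.asarray(imputed)
    if scope is None:
        scope = np.ones(mask.n_cells, dtype=bool)
    else:
        scope = np.asarray(scope, dtype=bool)
        if scope.shape != (mask.n_cells,):
            raise ValueError("scope must be a boolean vector over mask cells")
    if not scope.any():
        raise ValueError("empty evaluation scope")

    rows, cols, truth = mask.rows[scope], mask.cols[scope], mask.truth[scope]
    est = values[rows, cols]
    if not np.all(np.isfinite(est)):
        raise ValueError("imputed matrix has non-finite values at scoped masked cells")

    n_samples = values.shape[1]
    per_sample = np.full(n_samples, np.nan)
    n_cells = np.zeros(n_samples, dtype=int)
    for s in range(n_samples):
        in_s = cols == s
        n = int(in_s.sum())
        n_cells[s] = n
        if n < 2:
            continue
        o = truth[in_s]
        sd = float(np.std(o, ddof=1))
        if sd == 0.0:
            logger.info("sample %d: zero truth variance, NRMSE undefined", s)
            continue
        rmse = float(np.sqrt(np.mean((est[in_s] - o) ** 2)))
        per_sample[s] = rmse / sd

    defined = per_sample[np.isfinite(per_sample)]
    if defined.size == 0:
        raise ValueError("NRMSE undefined in every sample for this scope")
    skipped = n_samples - defined.size
    if skipped:
        logger.info("%d sample(s) excluded from mean NRMSE (undefined)", skipped)
    mean = float(defined.mean())
    if defined.size > 1:
        sem = float(np.std(defined, ddof=1) / np.sqrt(defined.size))
        ci95 = float(stats.t.ppf(0.975, defined.size - 1) * sem)
    else:
        ci95 = float("nan")
    return EvalResult(per_sample_nrmse=per_sample, mean_nrmse=mean,
                      ci95=ci95, n_cells_per_sample=n_cells)


def spearman_masked(mask: MaskSet, imputed: PeptideMatrix | np.ndarray) -> float:
    """Spearman rank correlation between truth and imputed at masked cells.

    Pooled across samples; average ranks for ties. Returns NaN when either
    vector is constant (correlation undefined).
    """
    values = imputed.values if isinstance(imputed, PeptideMatrix) else np.asarray(imputed)
    if mask.n_cells < 3:
        raise ValueError("need at least 3 masked cells for a rank correlation")
    est = values[mask.rows, mask.cols]
    if np.unique(mask.truth).size < 2 or np.unique(est).size < 2:
        logger.warning("constant vector: Spearman correlation undefined")
        return float("nan")
    rho, _ = stats.spearmanr(mask.truth, est)
    return float(rho)
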