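"""Peptide stratification into nine intensity x missing-rate sectors.

Peptides are summarized by their mean observed log2 intensity and their
missing rate across samples, then partitioned by four thresholds:

* intensity: the 25% and 75% empirical quantiles (linear interpolation
  between order statistics, i.e. numpy's default) of the per-peptide mean
  intensities — Low / Medium / High Intensity bands (LI / MI / HI);
* missing rate: fixed fractions of samples, 25% and 75% by default —
  Low / Medium / High Missing bands (LM / MM / HM).

Sector codes concatenate the two band codes, e.g. ``HIHM`` = High
Intensity, High Missing rate. Boundary values fall in the middle band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import PeptideMatrix

logger = logging.getLogger(__name__)

INTENSITY_BANDS = ("LI", "MI", "HI")
MISSING_BANDS = ("LM", "MM", "HM")
#: Canonical sector order (intensity-major) used for all tabular output.
SECTOR_CODES = tuple(i + m for i in INTENSITY_BANDS for m in MISSING_BANDS)


@dataclass(frozen=True)
class SectorGrid:
    """The four thresholds defining the 9-sector partition."""

    intensity_low: float
    intensity_high: float
    miss_low: float
    miss_high: float

    def __post_init__(self) -> None:
        if not self.intensity_low <= self.intensity_high:
            raise ValueError("intensity_low must be <= intensity_high")
        if not (0.0 < self.miss_low < self.miss_high < 1.0):
            raise ValueError("require 0 < miss_low < miss_high < 1")


def peptide_summaries(matrix: PeptideMatrix) -> pd.DataFrame:
    """Per-peptide mean observed log2 intensity and missing rate.

    Returns a DataFrame with columns ``peptide_id``, ``mean_intensity``,
    ``missing_rate`` and ``n_observed``. Means are over observed cells
    only; the matrix must already be filtered so every peptide has at
    least one observed value.
    """
    n_obs = matrix.observed.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("matrix contains peptides with no observed value; filter first")
    with np.errstate(invalid="ignore"):
        means = np.nansum(np.where(matrix.observed, matrix.values, 0.0), axis=1) / n_obs
    return pd.DataFrame(
        {
            "peptide_id": matrix.peptide_ids,
            "mean_intensity": means,
            "missing_rate": 1.0 - n_obs / matrix.n_samples,
            "n_observed": n_obs.astype(int),
        }
    )


def compute_thresholds(
    summaries: pd.DataFrame,
    intensity_quantiles: tuple[float, float] = (0.25, 0.75),
    miss_thresholds: tuple[float, float] = (0.25, 0.75),
) -> SectorGrid:
    """Derive the :class:`SectorGrid` from peptide summaries.

    Intensity thresholds are empirical quantiles of ``mean_intensity``
    (linear interpolation). Missing-rate thresholds are fractions of
    samples passed through verbatim — they are *not* quantiles of the
    observed missing-rate distribution.
    """
    qlo, qhi = intensity_quantiles
    if not (0.0 < qlo < qhi < 1.0):
        raise ValueError("intensity_quantiles must be strictly increasing in (0,1)")
    mlo, mhi = miss_thresholds
    if len(summaries) < 4:
        raise ValueError("need at least 4 peptides to set quantile thresholds")
    x = summaries["mean_intensity"].to_numpy(dtype=float)
    ilo, ihi = np.quantile(x, [qlo, qhi], method="linear")
    if ilo == ihi:
        warnings.warn(
            "degenerate intensity distribution: both intensity thresholds equal; "
            "the medium-intensity band will be empty",
            stacklevel=2,
        )
    return SectorGrid(intensity_low=float(ilo), intensity_high=float(ihi),
                      miss_low=float(mlo), miss_high=float(mhi))


def _band(value: float, low: float, high: float, bands: tuple[str, str, str]) -> str:
    # Boundary ties go to the middle band.
    if value < low:
        return bands[0]
    if value > high:
        return bands[2]
    return bands[1]


def assign_sectors(summaries: pd.DataFrame, grid: SectorGrid) -> pd.Series:
    """Assign each peptide a four-letter sector code.

    Returns a Series of codes indexed like ``summaries`` (values from
    :data:`SECTOR_CODES`); the nine sector sets partition the peptides.
    """
    means = summaries["mean_intensity"].to_numpy(dtype=float)
    rates = summaries["missing_rate"].to_numpy(dtype=float)
    codes = [
        _band(m, grid.intensity_low, grid.intensity_high, INTENSITY_BANDS)
        + _band(r, grid.miss_low, grid.miss_high, MISSING_BANDS)
        for m, r in zip(means, rates)
    ]
    return pd.Series(codes, index=summaries.index, name="sector")


def sector_sizes(assignment: pd.Series) -> pd.Series:
    """Peptide counts per sector, in canonical order (zeros included)."""
    counts = assignment.value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in SECTOR_CODES}, name="n_peptides")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p_value: float


def intensity_missingness_regression(summaries: pd.DataFrame) -> RegressionResult:
    """OLS of missing rate on mean intensity across peptides.

    On MS data the slope is characteristically negative: low-abundance
    peptides sit near the detection limit and are missed more often.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 peptides for the regression")
    x = summaries["mean_intensity"].to_numpy(dtype=float)
    y = summaries["missing_rate"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("mean intensities are all identical; regression undefined")
    if np.unique(y).size < 2:
        # flat response: zero slope, nothing explained
        return RegressionResult(slope=0.0, intercept=float(y[0]), r2=0.0, p_value=1.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
    )


def summarize_match_types(matrix: PeptideMatrix, assignment: pd.Series) -> pd.DataFrame:
    """Per-sector proportions of spectrum match types over observed cells.

    Requires per-cell ``match_type`` annotations on the matrix. Empty
    sectors are omitted (with a log notice). Proportions per sector sum
    to 1.
    """
    if matrix.match_type is None:
        raise ValueError(
            "matrix has no match_type annotations; omit the match-type summary"
        )
    from .core_io import MATCH_TYPES

    rows = []
    codes = np.asarray(assignment, dtype=object)
    for code in SECTOR_CODES:
        idx = np.flatnonzero(codes == code)
        if idx.size == 0:
            logger.info("sector %s is empty; omitted from match-type table", code)
            continue
        cells = matrix.match_type[idx][matrix.observed[idx]]
        total = cells.size
        row: dict[str, object] = {"sector": code, "n_cells": int(total)}
        for mt in MATCH_TYPES:
            n = int((cells == mt).sum())
            row[f"count_{mt}"] = n
            row[f"prop_{mt}"] = n / total if total else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def export_assignment(assignment: pd.Series, summaries: pd.DataFrame, path) -> None:
    """Write the (peptide_id, sector) assignment as a two-column TSV."""
    pd.DataFrame(
        {"peptide_id": summaries["peptide_id"], "sector": assignment}
    ).to_csv(path, sep="\t", index=False)
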