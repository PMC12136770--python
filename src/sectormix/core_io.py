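"""Peptide abundance matrices and delimited-table readers/writers.

The central container is :class:`PeptideMatrix`: a wide log2-abundance
matrix (rows = peptides, columns = samples) carrying an explicit boolean
missingness mask. All downstream computation in this package works on the
log2 scale; raw-intensity input must be flagged for transformation at read
time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell tokens treated as missing by default. FragPipe-style reports encode
#: missing quantities as 0, which is opted into via ``zero_is_missing``.
DEFAULT_NA_CODES = frozenset({"", "NA", "NaN", "nan", "NAN"})

MATCH_TYPES = ("MS/MS", "MBR", "unmatched")


class PeptideMatrixError(ValueError):
    """Raised when a table or matrix violates the data-model invariants."""


@dataclass
class PeptideMatrix:
    """Log2 peptide abundance matrix with an explicit missingness mask.

    Parameters
    ----------
    values
        ``(n_peptides, n_samples)`` float array of log2 abundances. Entries
        where ``observed`` is False carry no meaningful value (they are set
        to NaN on construction).
    observed
        Boolean mask of the same shape; True where a value was quantified.
    peptide_ids, sample_ids
        Unique row / column identifiers.
    groups
        Optional per-sample categorical label (e.g. high/low dose).
    match_type
        Optional per-cell spectrum-match annotation in
        ``{"MS/MS", "MBR", "unmatched"}``.
    """

    values: np.ndarray
    observed: np.ndarray
    peptide_ids: list[str]
    sample_ids: list[str]
    groups: list[str] | None = None
    match_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).copy()
        self.observed = np.asarray(self.observed, dtype=bool).copy()
        self.peptide_ids = [str(p) for p in self.peptide_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise PeptideMatrixError("values must be a 2-D array")
        if self.values.shape != self.observed.shape:
            raise PeptideMatrixError("values and observed shapes differ")
        n_pep, n_samp = self.values.shape
        if len(self.peptide_ids) != n_pep:
            raise PeptideMatrixError("peptide_ids length mismatch")
        if len(self.sample_ids) != n_samp:
            raise PeptideMatrixError("sample_ids length mismatch")
        _check_unique(self.peptide_ids, "peptide_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if self.groups is not None and len(self.groups) != n_samp:
            raise PeptideMatrixError("groups length mismatch")
        if self.match_type is not None:
            self.match_type = np.asarray(self.match_type, dtype=object)
            if self.match_type.shape != self.values.shape:
                raise PeptideMatrixError("match_type shape mismatch")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise PeptideMatrixError("non-finite value at an observed cell")
        # Unobserved cells carry no value.
        self.values[~self.observed] = np.nan

    # -- basic geometry -------------------------------------------------
    @property
    def n_peptides(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.n_observed / self.values.size

    def copy(self) -> "PeptideMatrix":
        return PeptideMatrix(
            values=self.values,
            observed=self.observed,
            peptide_ids=list(self.peptide_ids),
            sample_ids=list(self.sample_ids),
            groups=list(self.groups) if self.groups is not None else None,
            match_type=self.match_type,
        )

    def subset_rows(self, index: Sequence[int] | np.ndarray) -> "PeptideMatrix":
        """Row-subset view (copy) preserving sample metadata."""
        index = np.asarray(index, dtype=int)
        return PeptideMatrix(
            values=self.values[index],
            observed=self.observed[index],
            peptide_ids=[self.peptide_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            groups=list(self.groups) if self.groups is not None else None,
            match_type=self.match_type[index] if self.match_type is not None else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame (peptides x samples) with NaN at missing cells."""
        return pd.DataFrame(
            self.values, index=pd.Index(self.peptide_ids, name="peptide_id"),
            columns=self.sample_ids,
        )

    def drop_all_missing_peptides(self) -> "PeptideMatrix":
        """Remove peptides with no observed value in any sample.

        The number of dropped peptides is logged; peptides with at least
        one observed value are always kept.
        """
        keep = self.observed.any(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropped %d peptide(s) missing in all samples", n_drop)
        if not keep.any():
            raise PeptideMatrixError("matrix empty after removing all-missing peptides")
        if keep.all():
            return self
        return self.subset_rows(np.flatnonzero(keep))


@dataclass(frozen=True)
class GroupDesign:
    """Two-level sample grouping for differential expression."""

    sample_ids: tuple[str, ...]
    group: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.group):
            raise PeptideMatrixError("sample_ids and group lengths differ")
        levels = sorted(set(self.group))
        if len(levels) != 2:
            raise PeptideMatrixError(
                f"design must have exactly two group levels, got {levels}"
            )
        for lev in levels:
            n = sum(g == lev for g in self.group)
            if n < 2:
                logger.warning(
                    "group %r has only %d sample(s); variance estimation "
                    "requires >=2 per group", lev, n,
                )

    @property
    def levels(self) -> tuple[str, str]:
        lv = sorted(set(self.group))
        return lv[0], lv[1]

    def indices(self, level: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.group) if g == level])


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
        if seen[x] == 2:
            dups.append(x)
    if dups:
        raise PeptideMatrixError(f"duplicate {what}: {dups[:10]}")


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    na_codes: Iterable[str] = DEFAULT_NA_CODES,
    zero_is_missing: bool = False,
    log_transform: bool = False,
    delimiter: str | None = None,
) -> PeptideMatrix:
    """Read a wide delimited peptide table into a :class:`PeptideMatrix`.

    The first column holds peptide identifiers (taken verbatim), remaining
    columns are per-sample abundances. Cells matching ``na_codes`` (and
    zeros when ``zero_is_missing``) become missing. With ``log_transform``,
    positive raw intensities are log2-transformed; non-positive observed
    values are treated as missing in that case.

    Peptides missing in every sample are dropped (count logged).
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    na_codes = frozenset(str(c) for c in na_codes)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise PeptideMatrixError(f"{path}: need an ID column plus >=1 sample column")
    peptide_ids = [s.strip() for s in df.iloc[:, 0].tolist()]
    sample_ids = [str(c) for c in df.columns[1:]]
    _check_unique(peptide_ids, "peptide_ids")
    _check_unique(sample_ids, "sample_ids")

    n_pep, n_samp = len(peptide_ids), len(sample_ids)
    values = np.full((n_pep, n_samp), np.nan)
    observed = np.zeros((n_pep, n_samp), dtype=bool)
    for j, col in enumerate(df.columns[1:]):
        raw = df[col].astype(str).str.strip()
        is_na = raw.isin(na_codes)
        parsed = pd.to_numeric(raw.where(~is_na), errors="coerce")
        bad = (~is_na) & parsed.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise PeptideMatrixError(
                f"{path}: non-numeric cell {raw.iloc[i]!r} at row "
                f"{peptide_ids[i]!r}, column {col!r}"
            )
        col_vals = parsed.to_numpy(dtype=float)
        col_obs = ~is_na.to_numpy()
        if zero_is_missing:
            col_obs &= ~(col_vals == 0.0)
        values[:, j] = col_vals
        observed[:, j] = col_obs

    if log_transform:
        nonpos = observed & ~(values > 0)
        if nonpos.any():
            logger.warning(
                "%d non-positive cell(s) treated as missing under log transform",
                int(nonpos.sum()),
            )
            observed &= ~nonpos
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(observed, np.log2(np.where(values > 0, values, np.nan)), np.nan)

    matrix = PeptideMatrix(values=values, observed=observed,
                           peptide_ids=peptide_ids, sample_ids=sample_ids)
    return matrix.drop_all_missing_peptides()


def write_abundance_table(
    matrix: PeptideMatrix,
    path: str | Path,
    na_token: str = "NA",
    delimiter: str | None = None,
) -> Path:
    """Write a :class:`PeptideMatrix` as a wide delimited table.

    Round-trip safe with :func:`read_abundance_table`: observed values are
    serialized with 12 significant digits, missing cells as ``na_token``.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide_id" + sep + sep.join(matrix.sample_ids) + "\n")
        for i, pid in enumerate(matrix.peptide_ids):
            cells = [
                format(matrix.values[i, j], ".12g") if matrix.observed[i, j] else na_token
                for j in range(matrix.n_samples)
            ]
            fh.write(pid + sep + sep.join(cells) + "\n")
    return path


def read_group_design(path: str | Path, delimiter: str | None = None) -> GroupDesign:
    """Read a two-column (sample_id, group) design table."""
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise PeptideMatrixError(f"{path}: expected columns sample_id, group")
    return GroupDesign(
        sample_ids=tuple(df.iloc[:, 0].astype(str)),
        group=tuple(df.iloc[:, 1].astype(str)),
    )


def write_group_design(design: GroupDesign, path: str | Path) -> Path:
    path = Path(path)
    sep = _infer_delimiter(path, None)
    pd.DataFrame({"sample_id": design.sample_ids, "group": design.group}).to_csv(
        path, sep=sep, index=False
    )
    return path
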