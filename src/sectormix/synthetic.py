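"""Seeded generator of proteomics-like peptide matrices.

Emulates the statistical structure of bottom-up LC-MS/MS peptide
reports that the pipeline is built for:

* log-normal peptide abundances — per-peptide baseline means drawn from
  a Normal on the log2 scale;
* between-peptide correlation through a low-rank latent-factor term, so
  similarity- and structure-based imputers have recoverable signal;
* a missingness mixture of a random (MCAR) floor and an
  intensity-dependent (MNAR) logistic component that reproduces the
  characteristic negative correlation between peptide mean intensity
  and missing rate, plus a per-peptide propensity term (real peptides
  can be systematically hard to detect regardless of abundance — poor
  ionization, digestion artifacts) which populates the
  high-intensity/high-missing corner seen in real data;
* an optional two-group design with a spiked-in fold-change subset
  mimicking a two-proteome benchmark where the spiked species differs
  3:1 between dose groups and everything else is equimolar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_io import GroupDesign, PeptideMatrix

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a 2000 x 24 matrix with ~30% MVs.

    ``mnar_midpoint``/``mnar_steepness`` place the logistic missingness
    curve on the log2 intensity axis (midpoint about one standard
    deviation below the typical abundance, so low-intensity peptides are
    missed often but high-intensity ones rarely);
    ``peptide_effect_sd`` is the spread (log2 units) of the per-peptide
    detectability offset. ``spike_log2fc`` defaults to log2(3): a 3:1
    between-group ratio.
    """

    n_peptides: int = 2000
    n_samples: int = 24
    mean_center: float = 20.0
    mean_sd: float = 2.0
    n_factors: int = 3
    factor_sd: float = 0.8
    noise_sd: float = 0.3
    mnar_midpoint: float = 18.0
    mnar_steepness: float = 0.8
    mcar_rate: float = 0.05
    peptide_effect_sd: float = 2.5
    groups: tuple[int, int] | None = None
    spike_fraction: float = 0.0
    spike_log2fc: float = float(np.log2(3.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 1 or self.n_samples < 2:
            raise ValueError("need n_peptides >= 1 and n_samples >= 2")
        if not (0.0 <= self.mcar_rate < 1.0):
            raise ValueError("mcar_rate must be in [0, 1)")
        for name in ("mean_sd", "factor_sd", "noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.spike_fraction <= 1.0):
            raise ValueError("spike_fraction must be in [0, 1]")
        if self.spike_fraction > 0 and self.groups is None:
            raise ValueError("spike_fraction requires a two-group design")
        if self.groups is not None:
            g1, g2 = self.groups
            if g1 + g2 != self.n_samples:
                raise ValueError("group sizes must sum to n_samples")
            if g1 < 1 or g2 < 1:
                raise ValueError("both groups need >= 1 sample")
        if self.peptide_effect_sd < 0:
            raise ValueError("peptide_effect_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Complete truth, observed (post-missingness) matrix, and labels."""

    truth: PeptideMatrix
    observed: PeptideMatrix
    true_de_labels: np.ndarray
    config: SyntheticConfig

    @property
    def design(self) -> GroupDesign | None:
        if self.truth.groups is None:
            return None
        return GroupDesign(sample_ids=tuple(self.truth.sample_ids),
                           group=tuple(self.truth.groups))


def spike_in_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A two-proteome benchmark-style config: 3 vs 3 samples, 10% of
    peptides spiked at a 3:1 (log2FC = 1.585) between-group ratio.

    Uses a tighter latent-factor spread than the base default: factor
    variability acts as sample-level noise shared within a group, and the
    mixture benchmark this emulates runs technical replicates of one
    lysate, not biological replicates.
    """
    base = dict(n_peptides=2000, n_samples=6, groups=(3, 3),
                spike_fraction=0.10, noise_sd=0.3, factor_sd=0.5,
                mnar_midpoint=18.0, mnar_steepness=0.8, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


def generate_complete_matrix(
    config: SyntheticConfig,
) -> tuple[PeptideMatrix, np.ndarray]:
    """Draw the complete (no missing values) truth matrix and DE labels.

    ``value(p, s) = mu_p + sum_f L[p,f] F[f,s] + spike + eps`` with all
    draws from the generator seeded by ``config.seed``. Exactly
    ``round(spike_fraction * n_peptides)`` peptides carry the group-2
    offset ``spike_log2fc``.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_peptides, config.n_samples
    mu = rng.normal(config.mean_center, config.mean_sd, size=n)
    L = rng.normal(0.0, config.factor_sd, size=(n, config.n_factors))
    F = rng.normal(0.0, config.factor_sd, size=(config.n_factors, d))
    eps = rng.normal(0.0, config.noise_sd, size=(n, d))
    values = mu[:, None] + L @ F + eps

    labels = np.zeros(n, dtype=int)
    groups = None
    if config.groups is not None:
        g1, g2 = config.groups
        groups = ["group1"] * g1 + ["group2"] * g2
        n_spike = int(round(config.spike_fraction * n))
        if n_spike:
            spiked = rng.choice(n, size=n_spike, replace=False)
            labels[spiked] = 1
            values[np.ix_(spiked, np.arange(g1, g1 + g2))] += config.spike_log2fc

    matrix = PeptideMatrix(
        values=values,
        observed=np.ones((n, d), dtype=bool),
        peptide_ids=[f"PEP{i:05d}" for i in range(n)],
        sample_ids=[f"S{j:02d}" for j in range(d)],
        groups=groups,
    )
    return matrix, labels


def apply_missingness(truth: PeptideMatrix, config: SyntheticConfig) -> PeptideMatrix:
    """Drop cells with an MCAR + intensity-dependent MNAR mixture.

    ``p_miss = mcar + (1 - mcar) * logistic(-k * (value - midpoint - eta_p))``
    with ``eta_p ~ N(0, peptide_effect_sd)`` the per-peptide
    detectability offset and independent seeded Bernoulli draws. Rows
    rendered fully missing get one seeded cell restored (logged) so the
    >=1-observed invariant holds.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, d = truth.values.shape
    eta = rng.normal(0.0, config.peptide_effect_sd, size=n) \
        if config.peptide_effect_sd > 0 else np.zeros(n)
    from scipy.special import expit

    z = -config.mnar_steepness * (truth.values - config.mnar_midpoint - eta[:, None])
    p_mnar = expit(z)
    p_miss = config.mcar_rate + (1.0 - config.mcar_rate) * p_mnar
    if np.all(p_miss >= 1.0):
        raise ValueError("missingness parameters make every cell missing")
    missing = rng.random((n, d)) < p_miss
    fully_missing = np.flatnonzero(missing.all(axis=1))
    for r in fully_missing:
        missing[r, rng.integers(d)] = False
    if fully_missing.size:
        logger.info("restored one cell in %d fully-missing peptide row(s)",
                    fully_missing.size)
    observed = ~missing
    return PeptideMatrix(
        values=np.where(observed, truth.values, np.nan),
        observed=observed,
        peptide_ids=list(truth.peptide_ids),
        sample_ids=list(truth.sample_ids),
        groups=list(truth.groups) if truth.groups is not None else None,
    )


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Full generator: complete truth plus the post-missingness matrix."""
    truth, labels = generate_complete_matrix(config)
    observed = apply_missingness(truth, config)
    logger.info("synthetic dataset: %d x %d, %.1f%% missing",
                config.n_peptides, config.n_samples,
                100 * observed.missing_fraction)
    return SyntheticDataset(truth=truth, observed=observed,
                            true_de_labels=labels, config=config)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    if d["groups"] is not None:
        d["groups"] = list(d["groups"])
    return d
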