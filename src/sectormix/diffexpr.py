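"""Two-group differential expression, ROC benchmarking, reproducibility.

The test is a limma-style moderated t: per-peptide two-group linear
contrasts on log2 values whose residual variances are shrunk toward a
common prior fitted by empirical Bayes. The prior (d0 degrees of
freedom, location s0^2) is estimated from the distribution of log sample
variances via the method of moments (digamma/trigamma matching); the
moderated statistic

    t_i = logFC_i / (s_tilde_i * sqrt(1/n1 + 1/n2)),
    s_tilde_i^2 = (d0 * s0^2 + d_i * s_i^2) / (d0 + d_i)

is referred to a t distribution with d0 + d_i degrees of freedom. With
d0 -> infinity all peptides share one variance; with d0 = 0 the ordinary
pooled t is recovered. An ordinary Welch t-test is available as a
fallback/diagnostic mode for designs with singleton groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import GroupDesign, PeptideMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# empirical Bayes variance prior
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment fit of a scaled inverse-chi-square prior to sample variances.

    Given residual variances ``s2`` each on ``df`` degrees of freedom,
    returns ``(d0, s0_sq)``: the prior degrees of freedom (may be inf
    when the variances are no more dispersed than chi-square sampling
    alone explains) and the prior variance location.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2[ok])) if ok.any() else float(np.mean(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    excess = float(np.mean((e - e_bar) ** 2) * ok.sum() / (ok.sum() - 1)
                   - special.polygamma(1, df / 2.0))
    if excess <= 0:
        return np.inf, float(np.exp(e_bar))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


# ---------------------------------------------------------------------------
# moderated t-test
# ---------------------------------------------------------------------------

def moderated_t_test(
    matrix: PeptideMatrix,
    design: GroupDesign,
    prior_mode: str = "moderated",
    alpha: float = 0.05,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> pd.DataFrame:
    """Per-peptide two-group test on a complete (imputed) matrix.

    Returns a DataFrame with columns ``peptide_id``, the two group means,
    ``log_fc`` (difference of group means, level2 - level1 on log2
    scale), ``t``, ``p``, ``p_adj`` (Benjamini-Hochberg) and
    ``significant`` (``p_adj < alpha``).

    ``prior_mode='moderated'`` applies empirical-Bayes variance
    shrinkage and requires >=2 samples per group; ``'ordinary'`` runs
    Welch's t-test instead. ``prior_df``/``prior_var`` override the
    fitted prior (diagnostics: ``prior_df=0`` recovers the ordinary
    pooled-variance t, large values pool all peptides toward one
    variance).
    """
    if prior_mode not in ("moderated", "ordinary"):
        raise ValueError("prior_mode must be 'moderated' or 'ordinary'")
    if not np.all(matrix.observed):
        raise ValueError("matrix has missing values; impute before testing")
    if list(design.sample_ids) != list(matrix.sample_ids):
        raise ValueError("design sample_ids do not match matrix sample order")

    lv1, lv2 = design.levels
    i1, i2 = design.indices(lv1), design.indices(lv2)
    n1, n2 = i1.size, i2.size
    X1, X2 = matrix.values[:, i1], matrix.values[:, i2]
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    log_fc = m2 - m1

    if prior_mode == "moderated":
        if n1 < 2 or n2 < 2:
            raise ValueError(
                "moderated mode needs >=2 samples per group; use prior_mode='ordinary'"
            )
        df_resid = n1 + n2 - 2
        ss = ((X1 - m1[:, None]) ** 2).sum(axis=1) + ((X2 - m2[:, None]) ** 2).sum(axis=1)
        s2 = ss / df_resid
        if prior_df is not None:
            d0 = float(prior_df)
            s0_sq = float(prior_var) if prior_var is not None else float(np.median(s2))
        else:
            d0, s0_sq = fit_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log_fc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        diag = {"d0": d0, "s0_sq": s0_sq}
    else:
        t, p = stats.ttest_ind(X2, X1, axis=1, equal_var=False)
        t = np.nan_to_num(np.asarray(t), nan=0.0)
        p = np.where(np.isfinite(p), p, 1.0)
        diag = {}

    p = np.clip(p, 0.0, 1.0)
    p_adj = bh_adjust(p)
    out = pd.DataFrame(
        {
            "peptide_id": matrix.peptide_ids,
            f"mean_{lv1}": m1,
            f"mean_{lv2}": m2,
            "log_fc": log_fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "significant": p_adj < alpha,
        }
    )
    out.attrs.update(diag)
    return out


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, scale ``p_(i) * m / i``, enforce monotonicity from
    the largest rank downward, cap at 1, return in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# ROC against known labels
# ---------------------------------------------------------------------------

@dataclass
class ROCResult:
    """ROC curve over the p-value ranking plus the alpha operating point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    operating_tpr: float
    operating_fpr: float
    alpha: float


def roc_curve(de: pd.DataFrame, labels, alpha: float = 0.05) -> ROCResult:
    """ROC of the differential-expression ranking against binary labels.

    Peptides are ranked by raw p ascending (smaller p = stronger call);
    the curve sweeps all thresholds and the AUC is the trapezoid area
    (equivalently the rank concordance between labels and the score).
    The single operating point of the ``p_adj < alpha`` decision rule is
    reported alongside.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != len(de):
        raise ValueError("labels length does not match DE table")
    if np.unique(y).size < 2:
        raise ValueError("need both label classes for a ROC curve")
    from sklearn.metrics import roc_curve as _sk_roc, auc as _sk_auc

    score = -de["p"].to_numpy()
    fpr, tpr, thr = _sk_roc(y, score)
    auc_val = float(_sk_auc(fpr, tpr))
    calls = de["p_adj"].to_numpy() < alpha
    pos, neg = y == 1, y == 0
    op_tpr = float(calls[pos].mean()) if pos.any() else float("nan")
    op_fpr = float(calls[neg].mean()) if neg.any() else float("nan")
    return ROCResult(thresholds=-thr, fpr=fpr, tpr=tpr, auc=auc_val,
                     operating_tpr=op_tpr, operating_fpr=op_fpr, alpha=alpha)


def reproducibility(reference_sig: set, method_sig: set, universe=None) -> dict:
    """Overlap of a method's significant set with the unmasked reference.

    The headline fraction is ``|method ∩ reference| / |reference|``; the
    2x2 overlap counts support UpSet-style reporting (``neither`` needs
    the peptide universe).
    """
    reference_sig, method_sig = set(reference_sig), set(method_sig)
    both = len(reference_sig & method_sig)
    counts = {
        "both": both,
        "reference_only": len(reference_sig - method_sig),
        "method_only": len(method_sig - reference_sig),
    }
    if universe is not None:
        counts["neither"] = len(set(universe) - reference_sig - method_sig)
    if not reference_sig:
        logger.warning("empty reference set: reproducibility undefined")
        return {"fraction": float("nan"), **counts}
    return {"fraction": both / len(reference_sig), **counts}
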