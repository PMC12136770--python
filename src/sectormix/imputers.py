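"""Missing-value imputation methods behind a uniform contract.

Seven built-in methods cover the two families used in proteomics
benchmarking: local-similarity methods that borrow information from
similar peptides (kNN, random forest, local least squares) and
global-structure methods that exploit the low-dimensional layout of the
abundance matrix (SVD, Bayesian PCA, multivariate-normal MLE,
collaborative filtering). Neural plugins (denoising / variational
autoencoders) can be registered through the same contract but are kept
out of the default registry: on matrices with tens of samples they tend
to underfit badly.

Contract shared by every method:

* input: a :class:`~sectormix.core_io.PeptideMatrix` with >=1 observed
  value per peptide and >=2 samples;
* output: an :class:`ImputationOutput` whose ``values`` array has the
  input's shape with every cell finite, and with observed cells passed
  through bit-identically;
* a method that cannot run on the given matrix (too few peptides for its
  model) returns a typed not-applicable result instead of raising, so
  per-sector selection can simply skip it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics.pairwise import nan_euclidean_distances

from .core_io import PeptideMatrix

logger = logging.getLogger(__name__)

#: Canonical method order: used for deterministic tie-breaking during
#: per-sector selection and for all tabular output.
METHOD_ORDER = ("rf", "bpca", "lls", "svd", "cf", "knn", "mle", "dae", "vae")


@dataclass
class ImputationOutput:
    """Result of one imputation run."""

    method: str
    values: np.ndarray | None
    applicable: bool = True
    converged: bool = True
    iterations: int = 0
    diagnostics: dict = field(default_factory=dict)
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.applicable and self.values is None:
            raise ValueError("applicable result must carry values")


def not_applicable(method: str, reason: str) -> ImputationOutput:
    logger.info("%s not applicable: %s", method, reason)
    return ImputationOutput(method=method, values=None, applicable=False,
                            converged=False, reason=reason)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _as_arrays(matrix: PeptideMatrix) -> tuple[np.ndarray, np.ndarray]:
    return matrix.values, matrix.observed


def _row_mean_fill(values: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Fill missing cells with the peptide (row) mean of observed values."""
    n_obs = observed.sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("row with no observed value; filter the matrix first")
    means = np.where(observed, values, 0.0).sum(axis=1) / n_obs
    out = np.where(observed, values, means[:, None])
    return out


def impute_row_mean(matrix: PeptideMatrix) -> ImputationOutput:
    """Peptide-mean imputation: the baseline every real method must beat."""
    values, observed = _as_arrays(matrix)
    return ImputationOutput(method="mean", values=_row_mean_fill(values, observed))


def _finish(method: str, matrix: PeptideMatrix, filled: np.ndarray,
            **kwargs) -> ImputationOutput:
    # Observed-cell pass-through is enforced by construction.
    out = np.where(matrix.observed, matrix.values, filled)
    if not np.all(np.isfinite(out)):
        raise RuntimeError(f"{method}: non-finite imputed values")
    return ImputationOutput(method=method, values=out, **kwargs)


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------

def impute_knn(matrix: PeptideMatrix, k: int = 10, eps: float = 1e-6) -> ImputationOutput:
    """k-nearest-neighbour imputation over peptide rows.

    For each missing cell, the k peptides closest in Euclidean distance
    over co-observed samples (distances rescaled by
    ``sqrt(n_samples / n_co_observed)`` so rows with different overlap are
    comparable) that are observed in the target sample contribute a
    ``1/(d + eps)``-weighted mean. Falls back to the available neighbours
    when fewer than k exist, and to the peptide mean when none do.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    if n < 2:
        return not_applicable("knn", "need at least 2 peptides")
    if not (~observed).any():
        return ImputationOutput(method="knn", values=values.copy())

    X = np.where(observed, values, np.nan)
    with np.errstate(invalid="ignore"):
        dist = nan_euclidean_distances(X, X)
    np.fill_diagonal(dist, np.nan)

    filled = _row_mean_fill(values, observed)
    n_fallback = 0
    miss_rows, miss_cols = np.nonzero(~observed)
    for r, c in zip(miss_rows, miss_cols):
        cand = np.flatnonzero(observed[:, c] & np.isfinite(dist[r]))
        if cand.size == 0:
            n_fallback += 1
            continue  # keep the row-mean fallback
        dd = dist[r, cand]
        if cand.size > k:
            top = np.argpartition(dd, k)[:k]
            cand, dd = cand[top], dd[top]
        w = 1.0 / (dd + eps)
        filled[r, c] = float(np.dot(w, values[cand, c]) / w.sum())
    return _finish("knn", matrix, filled,
                   diagnostics={"n_mean_fallback": n_fallback, "k": k})


# ---------------------------------------------------------------------------
# random forest (missForest-style)
# ---------------------------------------------------------------------------

def impute_rf(matrix: PeptideMatrix, n_trees: int = 100, max_iter: int = 10,
              seed: int = 0, max_features: float | str = "sqrt",
              tol: float = 1e-5) -> ImputationOutput:
    """Iterative random-forest imputation over sample columns.

    Missing cells are initialized with peptide means; columns are then
    revisited in order of increasing missingness, each regressed on all
    other columns with a seeded random forest trained on the rows observed
    in that column (``max_features`` candidate predictors per split, as in
    missForest's mtry subsampling). Sweeps stop when the summed squared
    change of the imputed cells increases (the previous sweep's values are
    kept), falls below ``tol`` relative to the imputed values' magnitude,
    or after ``max_iter`` sweeps.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    if n < 5:
        return not_applicable("rf", "need at least 5 peptides")
    missing = ~observed
    if not missing.any():
        return ImputationOutput(method="rf", values=values.copy())

    X = _row_mean_fill(values, observed)
    col_order = np.argsort(missing.sum(axis=0), kind="stable")
    rng = np.random.default_rng(seed)
    prev_delta = np.inf
    best = X.copy()
    it = 0
    converged = False
    deltas = []
    for it in range(1, max_iter + 1):
        X_old = X.copy()
        for c in col_order:
            miss_c = missing[:, c]
            if not miss_c.any():
                continue
            obs_c = observed[:, c]
            if obs_c.sum() < 2:
                continue  # nothing to train on; keep initialization
            other = np.delete(np.arange(d), c)
            model = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=max_features,
                random_state=int(rng.integers(2 ** 31 - 1)),
                n_jobs=1,
            )
            model.fit(X[obs_c][:, other], values[obs_c, c])
            X[miss_c, c] = model.predict(X[miss_c][:, other])
        num = float(((X - X_old)[missing] ** 2).sum())
        den = float((X[missing] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        deltas.append(delta)
        if delta >= prev_delta:
            X = best  # stopping rule: keep the sweep before the increase
            converged = True
            break
        best = X.copy()
        prev_delta = delta
        if delta < tol:
            converged = True
            break
    return _finish("rf", matrix, X, converged=converged, iterations=it,
                   diagnostics={"delta_trajectory": deltas})


# ---------------------------------------------------------------------------
# SVD (low-rank EM)
# ---------------------------------------------------------------------------

def impute_svd(matrix: PeptideMatrix, rank: int = 5, max_iter: int = 100,
               tol: float = 1e-4) -> ImputationOutput:
    """Iterative low-rank SVD imputation.

    Missing cells start at peptide means; the matrix is alternately
    approximated by its rank-``rank`` truncated SVD and the missing cells
    refilled from the reconstruction, until the relative Frobenius change
    drops below ``tol``.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    if n < 2:
        return not_applicable("svd", "need at least 2 peptides")
    missing = ~observed
    if not missing.any():
        return ImputationOutput(method="svd", values=values.copy())
    r = min(rank, n, d)
    if r < rank:
        logger.warning("svd: rank %d clipped to %d (matrix is %dx%d)", rank, r, n, d)

    X = _row_mean_fill(values, observed)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        recon = (U[:, :r] * s[:r]) @ Vt[:r]
        X_new = np.where(observed, values, recon)
        denom = float(np.linalg.norm(X)) or 1.0
        delta = float(np.linalg.norm(X_new - X)) / denom
        X = X_new
        if delta < tol:
            converged = True
            break
    return _finish("svd", matrix, X, converged=converged, iterations=it,
                   diagnostics={"rank": r})


# ---------------------------------------------------------------------------
# Bayesian PCA with automatic relevance determination
# ---------------------------------------------------------------------------

def impute_bpca(matrix: PeptideMatrix, n_components: int | None = None,
                max_iter: int = 200, tol: float = 1e-4) -> ImputationOutput:
    """Bayesian PCA imputation with ARD over component precisions.

    Peptide rows are modelled as ``y = W x + mu + eps`` with isotropic
    noise and a per-component Gaussian prior on the columns of W whose
    precisions (ARD hyperparameters) prune superfluous components.
    Missing cells are refilled from the posterior-mean reconstruction
    each EM sweep; iteration stops when the relative parameter change
    drops below ``tol``.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    if d < 2:
        return not_applicable("bpca", "need at least 2 samples")
    if n < 3:
        return not_applicable("bpca", "need at least 3 peptides")
    missing = ~observed
    if not missing.any():
        return ImputationOutput(method="bpca", values=values.copy())
    q = n_components if n_components is not None else min(d - 1, 10)
    q = max(1, min(q, d - 1, n - 1))

    X = _row_mean_fill(values, observed)
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = (Vt[:q].T * s[:q]) / np.sqrt(n)              # (d, q)
    resid = max(float(np.var(Xc)) - float(np.sum(s[:q] ** 2)) / (n * d), 1e-8)
    sigma2 = resid
    alpha = np.full(q, 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        W_old, sigma2_old = W.copy(), sigma2
        # E-step on the currently completed matrix
        M = W.T @ W + sigma2 * np.eye(q)
        Minv = np.linalg.inv(M)
        scores = Xc @ W @ Minv.T                      # (n, q) posterior means
        SXX = scores.T @ scores + n * sigma2 * Minv   # E[sum x x^T]
        # M-step with ARD shrinkage on W's columns
        A = SXX + sigma2 * np.diag(alpha)
        W = np.linalg.solve(A.T, (Xc.T @ scores).T).T  # (d, q)
        recon_c = scores @ W.T
        err = float(np.sum((Xc - recon_c) ** 2))
        sigma2 = (err + n * sigma2 * float(np.trace(Minv @ (W.T @ W)))) / (n * d)
        sigma2 = max(sigma2, 1e-10)
        alpha = d / (np.sum(W ** 2, axis=0) + 1e-10)
        # refill missing cells from the posterior-mean reconstruction
        recon = recon_c + mu
        X = np.where(observed, values, recon)
        mu = X.mean(axis=0)
        Xc = X - mu
        dW = float(np.linalg.norm(W - W_old)) / (float(np.linalg.norm(W_old)) or 1.0)
        ds = abs(sigma2 - sigma2_old) / max(sigma2_old, 1e-12)
        if max(dW, ds) < tol:
            converged = True
            break
    return _finish("bpca", matrix, X, converged=converged, iterations=it,
                   diagnostics={"n_components": q, "sigma2": sigma2,
                                "alpha": alpha.tolist()})


# ---------------------------------------------------------------------------
# local least squares
# ---------------------------------------------------------------------------

def impute_lls(matrix: PeptideMatrix, k_similar: int = 20) -> ImputationOutput:
    """Local least squares imputation.

    Each peptide with missing values is regressed on its ``k_similar``
    most correlated peptides (absolute Pearson over the target's observed
    samples, neighbour gaps pre-filled with peptide means): the
    least-squares combination of the neighbours that best reproduces the
    target's observed values is used to predict its missing ones. When
    the system is degenerate the method falls back to a
    correlation-weighted neighbour mean.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    if n < 3:
        return not_applicable("lls", "need at least 3 peptides")
    missing = ~observed
    if not missing.any():
        return ImputationOutput(method="lls", values=values.copy())

    X0 = _row_mean_fill(values, observed)
    filled = X0.copy()
    n_fallback = 0
    k = min(k_similar, n - 1)
    for t in np.flatnonzero(missing.any(axis=1)):
        O = np.flatnonzero(observed[t])
        M = np.flatnonzero(missing[t])
        if O.size == 0:
            continue
        y = values[t, O]
        B = X0[:, O]
        yc = y - y.mean()
        Bc = B - B.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Bc, axis=1) * (np.linalg.norm(yc) or 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(Bc @ yc) / np.where(denom > 0, denom, np.inf)
        corr[t] = -np.inf
        nbrs = np.argsort(-corr, kind="stable")[:k]
        A = X0[nbrs][:, O]                    # (k, |O|)
        try:
            w, _, rank, _ = np.linalg.lstsq(A.T, y, rcond=None)
            pred = w @ X0[nbrs][:, M]
            ok = np.all(np.isfinite(pred))
        except np.linalg.LinAlgError:
            ok = False
        if not ok:
            n_fallback += 1
            wgt = np.clip(corr[nbrs], 0.0, None) + 1e-9
            pred = (wgt @ X0[nbrs][:, M]) / wgt.sum()
        filled[t, M] = pred
    return _finish("lls", matrix, filled,
                   diagnostics={"k_similar": k, "n_fallback": n_fallback})


# ---------------------------------------------------------------------------
# multivariate-normal maximum likelihood (EM)
# ---------------------------------------------------------------------------

def _mvn_loglik(values: np.ndarray, observed: np.ndarray, mu: np.ndarray,
                sigma: np.ndarray, patterns: dict) -> float:
    ll = 0.0
    for key, rows in patterns.items():
        o = np.flatnonzero(np.frombuffer(key, dtype=bool))
        Y = values[np.ix_(rows, o)]
        S_oo = sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(S_oo)
        if sign <= 0:
            return -np.inf
        diff = Y - mu[o]
        sol = np.linalg.solve(S_oo, diff.T)
        quad = float(np.sum(diff.T * sol))
        k = o.size
        ll += -0.5 * (len(rows) * (k * np.log(2 * np.pi) + logdet) + quad)
    return ll


def impute_mle(matrix: PeptideMatrix, max_iter: int = 100, tol: float = 1e-4,
               ridge: float = 1e-3) -> ImputationOutput:
    """EM imputation under a multivariate normal over the samples.

    Peptide rows are treated as i.i.d. draws from ``N(mu, Sigma)`` with
    ``Sigma`` of dimension ``n_samples`` (samples are few relative to
    peptides, so the covariance is estimable). Each E-step computes
    conditional expectations of the missing coordinates given the
    observed ones; the M-step re-estimates ``mu`` and ``Sigma``, with a
    ``ridge``-scaled identity added only when the updated covariance is
    not positive definite. Missing cells are imputed with their
    conditional means at convergence of the observed-data log-likelihood.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    if d < 2:
        return not_applicable("mle", "need at least 2 samples")
    if n < 5:
        return not_applicable("mle", "need at least 5 peptides")
    missing = ~observed
    if not missing.any():
        return ImputationOutput(method="mle", values=values.copy())

    vals0 = np.where(observed, values, np.nan)
    # group rows by missingness pattern for vectorized E-steps
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(observed[i].tobytes(), []).append(i)

    col_n = observed.sum(axis=0)
    if (col_n == 0).any():
        return not_applicable("mle", "a sample has no observed values")
    mu = np.nansum(vals0, axis=0) / col_n
    Xfill = np.where(observed, values, mu)
    sigma = np.cov(Xfill, rowvar=False)
    sigma = _ensure_pd(sigma, ridge)

    ll_prev = -np.inf
    ll_trace: list[float] = []
    converged = False
    n_ridge = 0
    it = 0
    for it in range(1, max_iter + 1):
        S1 = np.zeros(d)
        S2 = np.zeros((d, d))
        for key, rows in patterns.items():
            obs = np.frombuffer(key, dtype=bool)
            o = np.flatnonzero(obs)
            m = np.flatnonzero(~obs)
            Y = values[np.ix_(rows, o)]
            nr = len(rows)
            if m.size == 0:
                S1 += Y.sum(axis=0)
                S2 += Y.T @ Y
                continue
            S_oo = sigma[np.ix_(o, o)]
            S_mo = sigma[np.ix_(m, o)]
            B = np.linalg.solve(S_oo, S_mo.T).T          # (|m|, |o|)
            cond_mean = mu[m] + (Y - mu[o]) @ B.T        # (nr, |m|)
            C = sigma[np.ix_(m, m)] - B @ S_mo.T         # conditional covariance
            full = np.empty((nr, d))
            full[:, o] = Y
            full[:, m] = cond_mean
            S1 += full.sum(axis=0)
            S2 += full.T @ full
            S2[np.ix_(m, m)] += nr * C
        mu = S1 / n
        sigma = S2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        sigma, ridged = _ensure_pd(sigma, ridge, report=True)
        n_ridge += int(ridged)
        ll = _mvn_loglik(values, observed, mu, sigma, patterns)
        ll_trace.append(ll)
        if np.isfinite(ll) and np.isfinite(ll_prev):
            if abs(ll - ll_prev) / max(abs(ll_prev), 1.0) < tol:
                converged = True
                break
        ll_prev = ll

    filled = np.where(observed, values, 0.0)
    for key, rows in patterns.items():
        obs = np.frombuffer(key, dtype=bool)
        o, m = np.flatnonzero(obs), np.flatnonzero(~obs)
        if m.size == 0:
            continue
        S_oo = sigma[np.ix_(o, o)]
        S_mo = sigma[np.ix_(m, o)]
        B = np.linalg.solve(S_oo, S_mo.T).T
        Y = values[np.ix_(rows, o)]
        filled[np.ix_(rows, m)] = mu[m] + (Y - mu[o]) @ B.T
    return _finish("mle", matrix, filled, converged=converged, iterations=it,
                   diagnostics={"loglik_trace": ll_trace, "n_ridge": n_ridge})


def _ensure_pd(sigma: np.ndarray, ridge: float, report: bool = False):
    """Add ridge*I only when the matrix fails a Cholesky test."""
    ridged = False
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        sigma = sigma + ridge * np.eye(sigma.shape[0])
        ridged = True
        logger.info("covariance not positive definite; added ridge %.1e", ridge)
    return (sigma, ridged) if report else sigma


# ---------------------------------------------------------------------------
# collaborative filtering (biased matrix factorization)
# ---------------------------------------------------------------------------

def impute_cf(matrix: PeptideMatrix, n_factors: int = 8, epochs: int = 200,
              lr: float = 0.01, reg: float = 0.02, seed: int = 0,
              batch_size: int = 1024) -> ImputationOutput:
    """Biased matrix factorization fitted by mini-batch SGD.

    Observed cells are modelled as ``mu + b_peptide + b_sample + p . q``
    with L2 regularization on biases and factors, trained by seeded
    stochastic gradient descent over shuffled mini-batches of observed
    cells. Missing cells are imputed from the fitted model.
    """
    values, observed = _as_arrays(matrix)
    n, d = values.shape
    min_pep = max(5, n_factors + 1)
    if n < min_pep:
        return not_applicable("cf", f"need at least {min_pep} peptides for {n_factors} factors")
    rows, cols = np.nonzero(observed)
    y = values[rows, cols]
    if rows.size < 2 * n_factors:
        return not_applicable("cf", "too few observed cells to fit latent factors")

    rng = np.random.default_rng(seed)
    gmu = float(y.mean())
    bp = np.zeros(n)
    bs = np.zeros(d)
    P = rng.normal(0.0, 0.1, size=(n, n_factors))
    Q = rng.normal(0.0, 0.1, size=(d, n_factors))
    losses = []
    for _ in range(epochs):
        perm = rng.permutation(rows.size)
        sse = 0.0
        for start in range(0, rows.size, batch_size):
            b = perm[start:start + batch_size]
            r, c = rows[b], cols[b]
            pred = gmu + bp[r] + bs[c] + np.einsum("ij,ij->i", P[r], Q[c])
            err = y[b] - pred
            sse += float(err @ err)
            Pr, Qc = P[r], Q[c]
            np.add.at(bp, r, lr * (err - reg * bp[r]))
            np.add.at(bs, c, lr * (err - reg * bs[c]))
            np.add.at(P, r, lr * (err[:, None] * Qc - reg * Pr))
            np.add.at(Q, c, lr * (err[:, None] * Pr - reg * Qc))
        losses.append(sse / rows.size)
    recon = gmu + bp[:, None] + bs[None, :] + P @ Q.T
    return _finish("cf", matrix, recon, iterations=epochs,
                   diagnostics={"loss_trajectory": losses[-10:],
                                "final_loss": losses[-1]})


# ---------------------------------------------------------------------------
# registry and plugin contract
# ---------------------------------------------------------------------------

@dataclass
class ImputerSpec:
    """Registry entry: a named imputer plus its settings and applicability."""

    name: str
    func: Callable[..., ImputationOutput]
    params: dict = field(default_factory=dict)
    min_peptides: int = 5
    min_samples: int = 2
    seeded: bool = False

    def run(self, matrix: PeptideMatrix, seed: int | None = None) -> ImputationOutput:
        """Run the imputer with contract enforcement.

        Checks applicability minimums first; after the call, validates
        output shape, finiteness, and bit-identical observed-cell
        pass-through (plugins violating the contract raise).
        """
        if matrix.n_peptides < self.min_peptides:
            return not_applicable(
                self.name,
                f"sector has {matrix.n_peptides} peptides, fewer than "
                f"minimum {self.min_peptides}",
            )
        if matrix.n_samples < self.min_samples:
            return not_applicable(self.name, "too few samples")
        kwargs = dict(self.params)
        if self.seeded and seed is not None:
            kwargs.setdefault("seed", seed)
        out = self.func(matrix, **kwargs)
        if not out.applicable:
            return out
        if out.values.shape != matrix.values.shape:
            raise ContractViolation(
                f"{self.name}: output shape {out.values.shape} != input "
                f"{matrix.values.shape}"
            )
        if not np.all(np.isfinite(out.values)):
            raise ContractViolation(f"{self.name}: non-finite imputed values")
        obs = matrix.observed
        if not np.array_equal(out.values[obs], matrix.values[obs]):
            raise ContractViolation(
                f"{self.name}: observed cells were not passed through unchanged"
            )
        return out


class ContractViolation(RuntimeError):
    """An imputer broke the uniform output contract."""


def default_registry(overrides: dict[str, dict] | None = None) -> dict[str, ImputerSpec]:
    """The seven built-in methods with field-standard default settings.

    ``overrides`` maps method name -> parameter dict merged over the
    defaults; unknown names raise.
    """
    specs = {
        "knn": ImputerSpec("knn", impute_knn, {"k": 10}),
        "rf": ImputerSpec("rf", impute_rf, {"n_trees": 100, "max_iter": 10},
                          seeded=True),
        "svd": ImputerSpec("svd", impute_svd, {"rank": 5}),
        "bpca": ImputerSpec("bpca", impute_bpca, {}),
        "lls": ImputerSpec("lls", impute_lls, {"k_similar": 20}),
        "mle": ImputerSpec("mle", impute_mle, {}),
        "cf": ImputerSpec("cf", impute_cf, {"n_factors": 8, "epochs": 200},
                          min_peptides=9, seeded=True),
    }
    if overrides:
        unknown = set(overrides) - set(specs)
        if unknown:
            raise KeyError(f"unknown imputer(s) in overrides: {sorted(unknown)}")
        for name, params in overrides.items():
            specs[name].params.update(params)
    return specs


def register_plugin_imputer(
    registry: dict[str, ImputerSpec],
    spec: ImputerSpec,
    replace: bool = False,
) -> dict[str, ImputerSpec]:
    """Add a plugin imputer (e.g. dae/vae) to a registry.

    The plugin is called through the same :meth:`ImputerSpec.run` contract
    enforcement as the built-ins: wrong output shape or mutated observed
    cells surface as :class:`ContractViolation` at call time.
    """
    if spec.name in registry and not replace:
        raise KeyError(f"imputer {spec.name!r} already registered")
    registry[spec.name] = spec
    return registry


def method_sort_key(name: str) -> tuple[int, str]:
    """Deterministic ordering: canonical methods first, then alphabetical."""
    try:
        return (METHOD_ORDER.index(name), name)
    except ValueError:
        return (len(METHOD_ORDER), name)
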