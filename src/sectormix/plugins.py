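"""Reference autoencoder imputer plugins.

Compact fully connected denoising (DAE) and variational (VAE)
autoencoders implemented in numpy, provided as registrable plugins.
They are deliberately small — one hidden layer, trained by Adam on the
masked reconstruction loss over observed cells, with input corruption
(DAE) or a stochastic latent with a KL penalty (VAE). They are excluded
from the default registry: with only tens of samples per peptide these
models underfit and are routinely outperformed by the classical methods.
"""

from __future__ import annotations

import numpy as np

from .core_io import PeptideMatrix
from .imputers import (
    ImputationOutput,
    ImputerSpec,
    _row_mean_fill,
    not_applicable,
    register_plugin_imputer,
)


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mh = m / (1 - b1 ** self.t)
            vh = v / (1 - b2 ** self.t)
            p -= self.lr * mh / (np.sqrt(vh) + eps)


def _autoencoder_impute(
    matrix: PeptideMatrix,
    variational: bool,
    hidden: int,
    latent: int,
    epochs: int,
    lr: float,
    corruption: float,
    kl_weight: float,
    seed: int,
) -> ImputationOutput:
    name = "vae" if variational else "dae"
    values, observed = matrix.values, matrix.observed
    n, d = values.shape
    if n < 10 or d < 3:
        return not_applicable(name, "autoencoder needs >=10 peptides and >=3 samples")
    if not (~observed).any():
        return ImputationOutput(method=name, values=values.copy())

    rng = np.random.default_rng(seed)
    X = _row_mean_fill(values, observed)
    col_mu = X.mean(axis=0)
    col_sd = X.std(axis=0)
    col_sd[col_sd == 0] = 1.0
    Z = (X - col_mu) / col_sd
    mask = observed.astype(float)

    h = min(hidden, max(2, d))
    q = min(latent, h)
    W1 = rng.normal(0, 1 / np.sqrt(d), (d, h))
    b1 = np.zeros(h)
    Wm = rng.normal(0, 1 / np.sqrt(h), (h, q))
    bm = np.zeros(q)
    Wv = np.zeros((h, q))  # log-variance head (VAE only)
    bv = np.full(q, -2.0)
    W2 = rng.normal(0, 1 / np.sqrt(q), (q, d))
    b2 = np.zeros(d)
    params = [W1, b1, Wm, bm, Wv, bv, W2, b2]
    opt = _Adam(params, lr)

    def forward(Zin, sample_eps):
        H = np.tanh(Zin @ W1 + b1)
        mu_z = H @ Wm + bm
        logv = H @ Wv + bv if variational else None
        if variational:
            z = mu_z + np.exp(0.5 * logv) * sample_eps
        else:
            z = mu_z
        out = z @ W2 + b2
        return H, mu_z, logv, z, out

    for _ in range(epochs):
        Zin = Z.copy()
        if not variational and corruption > 0:
            drop = rng.random((n, d)) < corruption
            Zin[drop] = 0.0
        eps = rng.standard_normal((n, q)) if variational else None
        H, mu_z, logv, z, out = forward(Zin, eps)
        # masked reconstruction loss over observed cells
        diff = (out - Z) * mask
        n_obs = mask.sum()
        g_out = 2 * diff / n_obs
        gW2 = z.T @ g_out
        gb2 = g_out.sum(axis=0)
        g_z = g_out @ W2.T
        if variational:
            g_mu = g_z + kl_weight * mu_z / n
            g_logv = g_z * eps * 0.5 * np.exp(0.5 * logv) \
                + kl_weight * 0.5 * (np.exp(logv) - 1.0) / n
        else:
            g_mu = g_z
            g_logv = np.zeros_like(mu_z)
        gWm = H.T @ g_mu
        gbm = g_mu.sum(axis=0)
        gWv = H.T @ g_logv
        gbv = g_logv.sum(axis=0)
        g_h = (g_mu @ Wm.T + g_logv @ Wv.T) * (1 - H ** 2)
        gW1 = Zin.T @ g_h
        gb1 = g_h.sum(axis=0)
        opt.step([gW1, gb1, gWm, gbm, gWv, gbv, gW2, gb2])

    _, mu_z, logv, z, out = forward(Z, np.zeros((n, q)) if variational else None)
    recon = out * col_sd + col_mu
    filled = np.where(observed, values, recon)
    if not np.all(np.isfinite(filled)):
        return not_applicable(name, "training diverged to non-finite values")
    return ImputationOutput(method=name, values=filled, iterations=epochs,
                            diagnostics={"hidden": h, "latent": q})


def impute_dae(matrix: PeptideMatrix, hidden: int = 32, latent: int = 8,
               epochs: int = 300, lr: float = 1e-2, corruption: float = 0.2,
               seed: int = 0) -> ImputationOutput:
    """Denoising-autoencoder imputation (single hidden layer, numpy)."""
    return _autoencoder_impute(matrix, variational=False, hidden=hidden,
                               latent=latent, epochs=epochs, lr=lr,
                               corruption=corruption, kl_weight=0.0, seed=seed)


def impute_vae(matrix: PeptideMatrix, hidden: int = 32, latent: int = 8,
               epochs: int = 300, lr: float = 1e-2, kl_weight: float = 1e-3,
               seed: int = 0) -> ImputationOutput:
    """Variational-autoencoder imputation (single hidden layer, numpy)."""
    return _autoencoder_impute(matrix, variational=True, hidden=hidden,
                               latent=latent, epochs=epochs, lr=lr,
                               corruption=0.0, kl_weight=kl_weight, seed=seed)


def register_autoencoders(registry: dict[str, ImputerSpec]) -> dict[str, ImputerSpec]:
    """Add the dae/vae reference plugins to a registry."""
    register_plugin_imputer(
        registry, ImputerSpec("dae", impute_dae, {}, min_peptides=10, seeded=True)
    )
    register_plugin_imputer(
        registry, ImputerSpec("vae", impute_vae, {}, min_peptides=10, seeded=True)
    )
    return registry
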