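"""Empirical-Bayes location/scale harmonization of multi-site feature matrices.

Implements the parametric ComBat model for removing site/scanner effects
from subject-level feature matrices (here: voxelwise Fisher-z maps) while
preserving specified biological covariates:

    y_vij = alpha_v + x_ij beta_v + gamma_iv + delta_iv eps_vij

with feature v, site i, subject j. After standardizing by the covariate fit,
per-site additive effects gamma and multiplicative effects delta^2 receive
Normal and Inverse-Gamma priors whose hyperparameters are estimated by
method of moments across features; the conditional posterior means gamma*,
delta*^2 are found by iterative substitution and used to adjust the data:

    y*_vij = sigma_v / delta*_iv (z_vij - gamma*_iv) + alpha_v + x_ij beta_v

Features containing missing values, and zero-variance features, are passed
through unharmonized with a logged report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class CombatModel:
    """Fitted harmonization model (features refer to the fitted subset)."""

    batches: list[str]
    batch_sizes: dict[str, int]
    alpha_hat: np.ndarray  # (p,) grand intercept per feature
    beta_hat: np.ndarray  # (k, p) covariate coefficients
    sigma_hat: np.ndarray  # (p,) pooled residual SD
    gamma_star: np.ndarray  # (n_batch, p) EB additive site effect
    delta_star_sq: np.ndarray  # (n_batch, p) EB multiplicative site variance
    prior_params: dict[str, dict[str, float]]  # per site: gamma_bar, tau_sq, lambda, theta
    fitted_features: np.ndarray  # (P,) bool: features entering the EB fit
    n_iter: int


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, lam, theta):
    return (0.5 * sum2 + theta) / (n / 2.0 + lam - 1.0)


def _it_solve(z_batch: np.ndarray, g_hat, d_hat, g_bar, t2, lam, theta,
              conv: float = 1e-4, max_iter: int = 200):
    """Iterative conditional EB estimates for one site."""
    n = z_batch.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, lam, theta)
        change = max(np.abs(g_new - g_old).max(), np.abs(d_new - d_old).max())
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old, it


def _aprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(d_hat):
    m, s2 = d_hat.mean(), d_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _design_matrix(batch_labels, batches, design):
    n = len(batch_labels)
    B = np.zeros((n, len(batches)))
    for i, b in enumerate(batches):
        B[np.asarray(batch_labels) == b, i] = 1.0
    if design is None:
        return B, np.zeros((n, 0))
    X = np.atleast_2d(np.asarray(design, dtype=float))
    if X.shape[0] != n:
        X = X.T
    return B, X


def fit_combat(data: np.ndarray, batch, design=None,
               conv: float = 1e-4, max_iter: int = 200) -> CombatModel:
    """Fit the parametric EB harmonization model.

    Parameters
    ----------
    data : (features, subjects) matrix. NaN marks missing; features with any
        missing value are excluded from the fit and later passed through.
    batch : per-subject site labels (length subjects).
    design : optional (subjects, k) covariate matrix whose effects are
        preserved (do NOT include an intercept or the batch indicator).
    """
    data = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    if data.ndim != 2 or data.shape[1] != batch.size:
        raise ValueError("data must be features x subjects, aligned with batch")
    batches = sorted(dict.fromkeys(batch.tolist()))
    if len(batches) < 2:
        raise ValueError(
            "only one site present: skip harmonization instead of fitting ComBat"
        )
    sizes = {b: int((batch == b).sum()) for b in batches}
    if min(sizes.values()) < 2:
        raise ValueError("every site needs at least 2 subjects")

    B, X = _design_matrix(batch, batches, design)
    M = np.hstack([B, X])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("rank-deficient design (collinear batch/covariates)")

    finite = np.isfinite(data).all(axis=1)
    if not finite.all():
        logger.warning(
            "%d features with missing values passed through unharmonized",
            int((~finite).sum()),
        )
    Y = data[finite]  # p x n
    n = Y.shape[1]

    # covariate fit on the full (batch + covariate) design
    Bhat = np.linalg.solve(M.T @ M, M.T @ Y.T)  # (nb+k) x p
    nb = len(batches)
    props = np.array([sizes[b] for b in batches], dtype=float) / n
    alpha_hat = props @ Bhat[:nb]
    beta_hat = Bhat[nb:]
    resid = Y - (M @ Bhat).T
    var_pooled = (resid**2).mean(axis=1)
    zero_var = var_pooled <= 0
    if zero_var.any():
        logger.warning(
            "%d zero-variance features passed through unharmonized",
            int(zero_var.sum()),
        )
        keep = ~zero_var
    else:
        keep = np.ones(Y.shape[0], dtype=bool)
    fitted = finite.copy()
    fitted[np.flatnonzero(finite)[~keep]] = False
    Y = Y[keep]
    alpha_hat, beta_hat = alpha_hat[keep], beta_hat[:, keep]
    var_pooled = var_pooled[keep]
    sigma_hat = np.sqrt(var_pooled)

    stand_mean = alpha_hat[:, None] + (X @ beta_hat).T
    Z = (Y - stand_mean) / sigma_hat[:, None]

    gamma_star = np.empty((nb, Y.shape[0]))
    delta_star_sq = np.empty((nb, Y.shape[0]))
    priors: dict[str, dict[str, float]] = {}
    n_iter = 0
    for i, b in enumerate(batches):
        zb = Z[:, batch == b]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = float(g_hat.mean()), float(g_hat.var(ddof=1))
        lam, theta = float(_aprior(d_hat)), float(_bprior(d_hat))
        g_star, d_star, it = _it_solve(zb, g_hat, d_hat, g_bar, t2, lam, theta,
                                       conv=conv, max_iter=max_iter)
        gamma_star[i], delta_star_sq[i] = g_star, d_star
        priors[b] = {"gamma_bar": g_bar, "tau_sq": t2, "lambda": lam, "theta": theta}
        n_iter = max(n_iter, it)

    return CombatModel(
        batches=batches,
        batch_sizes=sizes,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        sigma_hat=sigma_hat,
        gamma_star=gamma_star,
        delta_star_sq=delta_star_sq,
        prior_params=priors,
        fitted_features=fitted,
        n_iter=n_iter,
    )


def apply_combat(model: CombatModel, data: np.ndarray, batch, design=None) -> np.ndarray:
    """Adjust a feature matrix with a fitted harmonization model.

    Missing markers and features excluded from the fit pass through
    unchanged; subjects from sites unseen at fit time are rejected.
    """
    data = np.asarray(data, dtype=float)
    batch = np.asarray(batch)
    unseen = set(batch.tolist()) - set(model.batches)
    if unseen:
        raise ValueError(f"sites not present in the fitted model: {sorted(unseen)}")
    _, X = _design_matrix(batch, model.batches, design)
    if X.shape[1] != model.beta_hat.shape[0]:
        raise ValueError("covariate design does not match the fitted model")

    out = data.copy()
    Y = data[model.fitted_features]
    stand_mean = model.alpha_hat[:, None] + (X @ model.beta_hat).T
    Z = (Y - stand_mean) / model.sigma_hat[:, None]
    adj = np.empty_like(Y)
    for i, b in enumerate(model.batches):
        cols = batch == b
        if not cols.any():
            continue
        adj[:, cols] = (
            model.sigma_hat[:, None]
            / np.sqrt(model.delta_star_sq[i])[:, None]
            * (Z[:, cols] - model.gamma_star[i][:, None])
            + stand_mean[:, cols]
        )
    out[model.fitted_features] = adj
    return out


def harmonize(data: np.ndarray, batch, design=None,
              conv: float = 1e-4, max_iter: int = 200) -> np.ndarray:
    """Fit-and-apply convenience wrapper; identity when only one site."""
    if len(set(np.asarray(batch).tolist())) < 2:
        logger.info("single site: harmonization bypassed")
        return np.asarray(data, dtype=float).copy()
    model = fit_combat(data, batch, design, conv=conv, max_iter=max_iter)
    return apply_combat(model, data, batch, design)
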