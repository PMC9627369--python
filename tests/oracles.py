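"""Independent reference implementations used only to cross-check results.

Each oracle is written as directly as possible from first principles and
shares no code with the package.
"""

import numpy as np
from scipy import stats


def pooled_two_sample_t(x: np.ndarray, y: np.ndarray) -> float:
    """Classical equal-variance two-sample t statistic."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (
        nx + ny - 2
    )
    return (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))


def bh_stepup(p: np.ndarray, q: float):
    """Benjamini-Hochberg by literal enumeration of the step-up rule."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject


def plsc_reference(X: np.ndarray, Y: np.ndarray):
    """Direct SVD of the cross-block correlation matrix of z-scored blocks."""
    n = X.shape[0]
    Xz = (X - X.mean(0)) / X.std(0, ddof=1)
    Yz = (Y - Y.mean(0)) / Y.std(0, ddof=1)
    R = Yz.T @ Xz / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    return U, s, Vt.T


def oneway_anova_f(groups) -> tuple[float, float]:
    return stats.f_oneway(*groups)


def combat_reference(Y: np.ndarray, batch: np.ndarray,
                     n_iter: int = 2000, conv: float = 1e-12):
    """Covariate-free parametric EB location/scale adjustment, coded directly
    from the model equations (standardize, moment-match priors, iterate the
    two conditional posterior-mean formulas, adjust)."""
    batches = sorted(set(batch.tolist()))
    n = Y.shape[1]
    means = {b: Y[:, batch == b].mean(axis=1) for b in batches}
    props = {b: (batch == b).sum() / n for b in batches}
    grand = sum(props[b] * means[b] for b in batches)
    resid = Y.copy()
    for b in batches:
        resid[:, batch == b] -= means[b][:, None]
    var_pooled = (resid**2).sum(axis=1) / n
    Z = (Y - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    out = Y.copy().astype(float)
    for b in batches:
        zb = Z[:, batch == b]
        nb = zb.shape[1]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        lam = (2 * s2 + m**2) / s2
        theta = (m * s2 + m**3) / s2
        g, d = g_hat.copy(), d_hat.copy()
        for _ in range(n_iter):
            g_new = (t2 * nb * g_hat + d * g_bar) / (t2 * nb + d)
            d_new = (theta + 0.5 * ((zb - g_new[:, None]) ** 2).sum(axis=1)) / (
                nb / 2 + lam - 1
            )
            if max(np.abs(g_new - g).max(), np.abs(d_new - d).max()) < conv:
                g, d = g_new, d_new
                break
            g, d = g_new, d_new
        out[:, batch == b] = (
            np.sqrt(var_pooled)[:, None] / np.sqrt(d)[:, None]
            * (zb - g[:, None])
            + grand[:, None]
        )
    return out
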