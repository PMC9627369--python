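"""Behavioral partial least squares correlation (PLSC) with resampling.

Given an imaging block X (subjects x voxels of Fisher-z connectivity inside
one seed's significant network) and a behavior block Y (subjects x clinical
scores), both columns are z-scored and the cross-block correlation matrix

    R = Y_z' X_z / (n - 1)

is decomposed by SVD, R = U S V'. Each latent variable (LV) pairs a
behavioral salience (column of U) with an imaging salience (column of V);
s_i^2 / sum_j s_j^2 is the fraction of cross-block covariance an LV explains.
Composite scores are X_z V (imaging) and Y_z U (behavioral).

Inference follows the standard behavioral-PLSC recipe:

* permutation test -- rows of Y permuted jointly, singular values compared
  by LV position, p_i = (1 + #{s_i^perm >= s_i^obs}) / (1 + N);
* bootstrap -- subjects resampled with replacement, resampled saliences
  aligned to the original by orthogonal Procrustes rotation; a voxel's
  bootstrap ratio (BSR) is its observed salience over its bootstrap SD, and
  a behavior's loading (its correlation with the LV imaging score) gets a
  percentile confidence interval.

The permutation and bootstrap draw from independent substreams of one root
seed, so results do not depend on execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

logger = logging.getLogger(__name__)

BSR_CAP = 1e6  # reported magnitude when the bootstrap SD collapses to zero


@dataclass
class PLSBlocks:
    """Row-aligned imaging (X) and behavior (Y) matrices."""

    X: np.ndarray  # subjects x voxels
    Y: np.ndarray  # subjects x behaviors
    row_ids: list[str]
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if self.X.shape[0] != self.Y.shape[0] or self.X.shape[0] != len(self.row_ids):
            raise ValueError("X, Y and row_ids disagree on the subject count")
        for name, M in (("X", self.X), ("Y", self.Y)):
            if np.any(~np.isfinite(M)):
                raise ValueError(f"missing values in block {name}: "
                                 "apply listwise deletion first")
        zero = (_zero_variance_columns(self.X, "X:")
                + _zero_variance_columns(self.Y, "Y:"))
        if zero:
            raise ValueError(f"zero-variance columns: {zero}")


@dataclass
class PLSResult:
    singular_values: np.ndarray  # (L,) descending
    cov_explained: np.ndarray  # (L,) fractions summing to 1
    imaging_saliences: np.ndarray  # voxels x L
    behavioral_saliences: np.ndarray  # behaviors x L
    imaging_scores: np.ndarray  # subjects x L
    behavioral_scores: np.ndarray  # subjects x L
    x_names: list[str]
    y_names: list[str]
    perm_p: np.ndarray | None = None
    bootstrap_ratios: np.ndarray | None = None  # voxels x L
    behavioral_loadings: np.ndarray | None = None  # behaviors x L (observed r)
    loading_ci: np.ndarray | None = None  # behaviors x L x 2
    loading_significant: np.ndarray | None = None  # behaviors x L bool
    bsr_significant: np.ndarray | None = None  # voxels x L bool
    n_redrawn_resamples: int = 0


def _zero_variance_columns(M: np.ndarray, prefix: str = "") -> list[str]:
    sd = M.std(axis=0, ddof=1)
    return [f"{prefix}{i}" for i in np.flatnonzero(sd == 0)]


def _zscore(M: np.ndarray) -> np.ndarray:
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


def residualize(M: np.ndarray, nuisance: np.ndarray,
                names=None) -> np.ndarray:
    """Replace each column of M by its OLS residual on [intercept, nuisance].

    Residual columns are exactly orthogonal to every nuisance column (and
    mean-centered). With an empty nuisance set this is plain centering.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    Z = np.column_stack([np.ones(n)] +
                        ([np.asarray(nuisance, dtype=float)] if np.size(nuisance) else []))
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # name the offending columns via pivoted QR
        _, _, piv = sla.qr(Z, pivoting=True, mode="economic")
        bad = sorted(piv[rank:].tolist())
        labels = ["intercept"] + (list(names) if names is not None
                                  else [f"nuisance_{i}" for i in range(Z.shape[1] - 1)])
        raise ValueError("collinear nuisance columns: "
                         f"{[labels[i] for i in bad]}")
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def plsc_fit(blocks: PLSBlocks) -> PLSResult:
    """SVD of the cross-block correlation matrix.

    Columns of X and Y are z-scored (ddof = 1); R = Y_z' X_z / (n - 1) is a
    behaviors x voxels correlation matrix. Sign convention: within each LV
    the largest-magnitude behavioral salience is made positive.
    """
    blocks.validate()
    n, q = blocks.Y.shape
    if n < max(3, q + 1):
        raise ValueError(f"need at least max(3, behaviors+1) = "
                         f"{max(3, q + 1)} subjects, got {n}")
    Xz, Yz = _zscore(blocks.X), _zscore(blocks.Y)
    R = Yz.T @ Xz / (n - 1)
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    V = Vt.T
    # sign convention
    for i in range(s.size):
        j = int(np.argmax(np.abs(U[:, i])))
        if U[j, i] < 0:
            U[:, i] *= -1
            V[:, i] *= -1
    cov = s**2 / (s**2).sum()
    return PLSResult(
        singular_values=s,
        cov_explained=cov,
        imaging_saliences=V,
        behavioral_saliences=U,
        imaging_scores=Xz @ V,
        behavioral_scores=Yz @ U,
        x_names=list(blocks.x_names),
        y_names=list(blocks.y_names),
    )


def permutation_test(blocks: PLSBlocks, n_perm: int = 1000,
                     seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Permutation p-value per LV: rows of Y shuffled, X fixed.

    Permuted singular values are compared to the observed ones by LV
    position; p_i = (1 + #{s_i^perm >= s_i^obs}) / (1 + N).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; permutation p has coarse "
                       "resolution", n_perm)
    obs = plsc_fit(blocks)
    rng = np.random.default_rng(seed)
    n = blocks.X.shape[0]
    Xz, Yz = _zscore(blocks.X), _zscore(blocks.Y)
    count = np.zeros(obs.singular_values.size)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = Yz[perm]
        R = Yp.T @ Xz / (n - 1)
        s = np.linalg.svd(R, compute_uv=False)
        count += s >= obs.singular_values
    return (1.0 + count) / (1.0 + n_perm)


def _procrustes_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Orthogonal T minimizing ||A T - B||_F."""
    P, _, Qt = np.linalg.svd(A.T @ B)
    return P @ Qt


def bootstrap_inference(blocks: PLSBlocks, n_boot: int = 1000,
                        seed: int | np.random.SeedSequence = 0,
                        result: PLSResult | None = None,
                        max_redraws: int = 50) -> PLSResult:
    """Bootstrap ratios for voxels and percentile CIs for behavior loadings.

    Subjects are resampled with replacement (X and Y rows paired); each
    resample's saliences are Procrustes-aligned to the observed solution in
    the behavioral space. Following the standard behavioral-PLSC convention
    the bootstrap distribution is formed over singular-value-weighted
    saliences (v s), whose SE absorbs the LV-strength fluctuation, so the
    ratio BSR_v = v_obs s_obs / SD_boot(v s) is approximately standard normal
    under the null; it is capped at 1e6 when the SD degenerates to zero. A
    behavior's loading per resample is the correlation of its (resampled)
    scores with the resample's LV imaging score. A resample producing a
    zero-variance column is redrawn (counted, at most ``max_redraws`` times
    overall).
    """
    n = blocks.X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 subjects for the bootstrap")
    res = result if result is not None else plsc_fit(blocks)
    L = res.singular_values.size
    p_vox, q_beh = blocks.X.shape[1], blocks.Y.shape[1]
    rng = np.random.default_rng(seed)

    V_boot = np.empty((n_boot, p_vox, L))
    load_boot = np.empty((n_boot, q_beh, L))
    redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        Xb, Yb = blocks.X[idx], blocks.Y[idx]
        if (Xb.std(axis=0, ddof=1) == 0).any() or (Yb.std(axis=0, ddof=1) == 0).any():
            redrawn += 1
            if redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        Xz, Yz = _zscore(Xb), _zscore(Yb)
        R = Yz.T @ Xz / (n - 1)
        Ub, sb, Vbt = np.linalg.svd(R, full_matrices=False)
        Vb = Vbt.T
        T = _procrustes_rotation(Ub, res.behavioral_saliences)
        Ub, Vb = Ub @ T, Vb @ T
        V_boot[b] = (Vbt.T * sb) @ T  # weighted salience, aligned
        scores_b = Xz @ Vb
        sc = _zscore(scores_b)
        load_boot[b] = Yz.T @ sc / (n - 1)  # Pearson r per behavior/LV
        b += 1
    if redrawn:
        logger.info("redrew %d degenerate bootstrap resamples", redrawn)

    weighted_obs = res.imaging_saliences * res.singular_values
    sd = V_boot.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = weighted_obs / sd
    bsr[sd == 0] = np.sign(res.imaging_saliences[sd == 0]) * BSR_CAP
    bsr = np.clip(bsr, -BSR_CAP, BSR_CAP)

    obs_scores = _zscore(res.imaging_scores)
    Yz_full = _zscore(blocks.Y)
    loadings = Yz_full.T @ obs_scores / (n - 1)
    ci = np.percentile(load_boot, [2.5, 97.5], axis=0)  # 2 x q x L
    ci = np.moveaxis(ci, 0, -1)  # q x L x 2
    sig = (ci[..., 0] > 0) | (ci[..., 1] < 0)

    res.bootstrap_ratios = bsr
    res.bsr_significant = np.abs(bsr) > 3.3
    res.behavioral_loadings = loadings
    res.loading_ci = ci
    res.loading_significant = sig
    res.n_redrawn_resamples = redrawn
    return res


def score_correlation(result: PLSResult) -> np.ndarray:
    """Pearson r between imaging and behavioral composite scores, per LV."""
    I, B = result.imaging_scores, result.behavioral_scores
    Iz, Bz = _zscore(I), _zscore(B)
    n = I.shape[0]
    return np.einsum("ni,ni->i", Iz, Bz) / (n - 1)


def run_plsc(blocks: PLSBlocks, n_perm: int = 1000, n_boot: int = 1000,
             seed: int | np.random.SeedSequence = 0) -> PLSResult:
    """Fit + permutation + bootstrap with independent substreams of one seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    perm_ss, boot_ss = ss.spawn(2)
    res = plsc_fit(blocks)
    res.perm_p = permutation_test(blocks, n_perm=n_perm, seed=perm_ss)
    res = bootstrap_inference(blocks, n_boot=n_boot, seed=boot_ss, result=res)
    return res
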