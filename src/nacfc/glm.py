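"""Voxelwise group contrasts, FDR and cluster-extent control, volume ANCOVA.

The group analysis regresses each voxel's Fisher-z value on an intercept,
a PD-vs-HC indicator and nuisance covariates, tests the group coefficient,
controls the false discovery rate over the in-mask voxels of one seed's map
(Benjamini-Hochberg), and removes surviving clusters smaller than a minimum
extent. Seeds whose map survives nowhere yield an empty significance mask
and are excluded from the multivariate brain-behavior analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GLMResult:
    seed_name: str
    t_map: np.ndarray  # 3D; NaN where the voxel was excluded
    p_map: np.ndarray  # 3D two-sided p; NaN where excluded
    df: int
    contrast: str = "PD-HC"
    n_excluded_voxels: int = 0


@dataclass
class SignificanceMask:
    seed_name: str
    mask: np.ndarray  # 3D bool
    cluster_labels: np.ndarray  # 3D int, 0 = background
    q: float
    k_min: int

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def cluster_table(self, t_map: np.ndarray | None = None) -> pd.DataFrame:
        """Label, size and (optionally) peak statistic per surviving cluster."""
        rows = []
        for lab in np.unique(self.cluster_labels[self.cluster_labels > 0]):
            where = self.cluster_labels == lab
            row = {"label": int(lab), "size": int(where.sum())}
            if t_map is not None:
                vals = np.where(where, np.abs(t_map), -np.inf)
                peak = np.unravel_index(np.nanargmax(vals), vals.shape)
                row["peak_t"] = float(t_map[peak])
                row["peak_i"], row["peak_j"], row["peak_k"] = map(int, peak)
            rows.append(row)
        return pd.DataFrame(rows)


def _encode_column(col: pd.Series) -> np.ndarray:
    if col.dtype == object or str(col.dtype) == "category":
        levels = sorted(col.astype(str).unique())
        if len(levels) > 2:
            raise ValueError(f"cannot encode multi-level column {col.name!r}")
        return (col.astype(str) == levels[-1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def build_design(cohort: pd.DataFrame, covariates=()) -> tuple[np.ndarray, list[str]]:
    """[intercept, group(PD=1), covariates...] design matrix."""
    cols = [np.ones(len(cohort)), (cohort["group"] == "PD").to_numpy(float)]
    names = ["intercept", "group"]
    for c in covariates:
        if c not in cohort.columns:
            raise ValueError(f"covariate {c!r} not in cohort table")
        cols.append(_encode_column(cohort[c]))
        names.append(c)
    return np.column_stack(cols), names


def voxelwise_group_contrast(zmaps, cohort: pd.DataFrame, covariates=()) -> GLMResult:
    """OLS of Fisher-z on group plus covariates, per voxel.

    `zmaps` is a list of FCMap (one per cohort row, same seed). Voxels missing
    (NaN) in any subject are excluded from the test with a reported count.
    Returns the t and two-sided p maps for the group (PD - HC) coefficient.
    """
    ids = [m.subject_id for m in zmaps]
    if list(cohort["subject_id"]) != ids:
        order = {s: i for i, s in enumerate(ids)}
        missing = [s for s in cohort["subject_id"] if s not in order]
        if missing:
            raise ValueError(f"z-maps missing for subjects {missing[:5]}")
        zmaps = [zmaps[order[s]] for s in cohort["subject_id"]]
    seed_name = zmaps[0].seed_name
    groups = cohort["group"].value_counts()
    if groups.min() < 2 or len(groups) < 2:
        raise ValueError("need at least 2 subjects in each of two groups")

    X, names = build_design(cohort, covariates)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    n = X.shape[0]
    df = n - rank

    Y = np.stack([m.values.reshape(-1) for m in zmaps])  # subjects x voxels
    ok = np.isfinite(Y).all(axis=0)
    n_excluded = int(np.sum(~ok & np.isfinite(Y).any(axis=0)))
    if n_excluded:
        logger.info("excluded %d voxels with missing values in some subject",
                    n_excluded)
    Yok = Y[:, ok]

    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Yok
    resid = Yok - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    g = names.index("group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[g] / np.sqrt(sigma2 * XtX_inv[g, g])
    p = 2.0 * stats.t.sf(np.abs(t), df)

    shape = zmaps[0].values.shape
    t_map = np.full(np.prod(shape), np.nan)
    p_map = np.full(np.prod(shape), np.nan)
    t_map[ok], p_map[ok] = t, p
    return GLMResult(seed_name, t_map.reshape(shape), p_map.reshape(shape),
                     df, "PD-HC", n_excluded)


def fdr_correct(p_values: np.ndarray, q: float = 0.05):
    """Benjamini-Hochberg step-up over a flat vector of p-values.

    Returns (reject, p_adjusted) aligned with the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_extent_filter(mask: np.ndarray, k_min: int = 20,
                          connectivity: int = 26,
                          seed_name: str = "", q: float = 0.05) -> SignificanceMask:
    """Drop connected components smaller than ``k_min`` voxels.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full neighborhood).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3D volume")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n:
        sizes = np.bincount(labels.reshape(-1))
        small = np.flatnonzero(sizes < k_min)
        labels[np.isin(labels, small[small > 0])] = 0
        # relabel compactly
        kept = np.unique(labels[labels > 0])
        remap = np.zeros(sizes.size, dtype=labels.dtype)
        remap[kept] = np.arange(1, kept.size + 1)
        labels = remap[labels]
    return SignificanceMask(seed_name, labels > 0, labels, q, k_min)


def significance_network(result: GLMResult, q: float = 0.05, k_min: int = 20,
                         connectivity: int = 26) -> SignificanceMask:
    """FDR over the tested voxels, then the extent filter, for one seed."""
    ok = np.isfinite(result.p_map)
    reject = np.zeros(result.p_map.shape, dtype=bool)
    rej, _ = fdr_correct(result.p_map[ok], q)
    reject[ok] = rej
    sig = cluster_extent_filter(reject, k_min, connectivity,
                                seed_name=result.seed_name, q=q)
    if sig.n_voxels == 0:
        logger.info("seed %s: no voxels survive FDR q=%g with extent %d; "
                    "excluded from PLS", result.seed_name, q, k_min)
    return sig


def ancova_volumes(cohort: pd.DataFrame, roi: str,
                   covariates=("age", "sex", "education")) -> tuple[float, float]:
    """Group F-test for an ROI volume adjusting for covariates.

    Fits volume ~ group + covariates by OLS and returns the partial
    (type-II) F statistic and p-value for the group factor; with no
    covariates this is the classical one-way ANOVA F.
    """
    col = roi if roi in cohort.columns else f"vol_{roi}"
    if col not in cohort.columns:
        raise ValueError(f"no volume column for ROI {roi!r}")
    y = cohort[col].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"missing values in volume column {col!r}")
    X_full, names = build_design(cohort, covariates)
    X_red = np.delete(X_full, names.index("group"), axis=1)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    df_full = len(y) - np.linalg.matrix_rank(X_full)
    rss_full, rss_red = rss(X_full), rss(X_red)
    F = (rss_red - rss_full) / 1.0 / (rss_full / df_full)
    p = float(stats.f.sf(F, 1, df_full))
    return float(F), p
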