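"""Seed time-course extraction, voxelwise correlation, Fisher r-to-z.

The connectivity map of one subject for one seed is the voxelwise Pearson
correlation between the seed's probability-weighted mean time course and
every brain-mask voxel, variance-stabilized with z = atanh(r). Out-of-mask
and zero-variance voxels carry NaN as an explicit missing marker and are
excluded (never zero-filled) by every later stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: |r| at or beyond this bound is clipped before atanh
R_CLIP = 1.0 - 1e-7


@dataclass
class FCMap:
    """One subject x one seed voxelwise Fisher-z connectivity map."""

    subject_id: str
    seed_name: str
    values: np.ndarray  # 3D; NaN marks out-of-mask / undefined voxels


def extract_roi_timecourse(bold, roi: np.ndarray) -> np.ndarray:
    """Probability-weighted mean time course of a seed region.

    Returns sum_v p_v x_v(t) / sum_v p_v over voxels with p_v > 0. With a
    binarized map this is the plain ROI mean.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.shape != bold.data.shape[:-1]:
        raise ValueError("ROI map and BOLD grid differ")
    vox = roi > 0
    total = roi[vox].sum()
    if not np.any(vox) or total <= 0:
        raise ValueError("empty ROI: no voxels with positive probability")
    weights = roi[vox] / total
    return weights @ bold.data[vox]


def voxelwise_fc(bold, reference: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pearson correlation of every mask voxel with a reference time course.

    Zero-variance voxels are returned as NaN with a logged warning; voxels
    outside the mask are NaN.
    """
    reference = np.asarray(reference, dtype=float)
    T = reference.size
    if T < 3:
        raise ValueError("need at least 3 time points for a correlation")
    if bold.data.shape[-1] != T:
        raise ValueError("reference length does not match BOLD series")
    ref = reference - reference.mean()
    ref_ss = float(ref @ ref)
    if ref_ss == 0:
        raise ValueError("reference time course is constant")

    mask = np.asarray(mask, dtype=bool)
    X = bold.data[mask]  # voxels x T
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("vt,vt->v", Xc, Xc)
    degenerate = ss == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance voxels set to missing in %s/%s",
            int(degenerate.sum()), bold.subject_id, "fc",
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ref) / np.sqrt(ss * ref_ss)
    r[degenerate] = np.nan
    r = np.clip(r, -1.0, 1.0)

    out = np.full(bold.data.shape[:-1], np.nan)
    out[mask] = r
    return out


def fisher_z(rmap: np.ndarray, subject_id: str = "", seed_name: str = "") -> FCMap:
    """Variance-stabilize a correlation map: z = atanh(r).

    |r| >= 1 - 1e-7 is clipped to the bound before the transform (logged).
    NaN is the missing marker and passes through; infinities are rejected.
    """
    rmap = np.asarray(rmap, dtype=float)
    if np.isinf(rmap).any():
        raise ValueError("non-finite correlation values")
    finite = ~np.isnan(rmap)
    if np.any(np.abs(rmap[finite]) > 1):
        raise ValueError("correlations outside [-1, 1]")
    n_clip = int(np.sum(np.abs(rmap[finite]) >= R_CLIP))
    if n_clip:
        logger.info("clipped %d near-unit correlations before atanh", n_clip)
    z = np.arctanh(np.clip(rmap, -R_CLIP, R_CLIP))
    z[~finite] = np.nan
    return FCMap(subject_id, seed_name, z)


def seed_fc_maps(bold, atlas, seeds=None) -> dict[str, FCMap]:
    """All per-seed Fisher-z maps for one subject."""
    out = {}
    for name in seeds or atlas.rois:
        ref = extract_roi_timecourse(bold, atlas.rois[name])
        r = voxelwise_fc(bold, ref, atlas.brain_mask)
        out[name] = fisher_z(r, bold.subject_id, name)
    return out
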