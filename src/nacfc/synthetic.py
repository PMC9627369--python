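"""Synthetic cohorts, atlases and BOLD series with planted ground truth.

The generator emulates the study design the downstream analysis assumes: a
two-site Parkinson's disease (PD) / healthy control (HC) resting-state cohort
in which seed-voxel connectivity of NAc subregions is attenuated in patients,
site membership adds location/scale batch effects to the connectivity maps,
and a single latent severity factor couples the connectivity loss to a
weighted combination of non-motor symptom scores.

Every draw is controlled by a single root seed; per-subject BOLD streams are
derived from (root seed, subject id) so that regeneration of any one subject
is independent of iteration order.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROI_NAMES = ("core_L", "shell_L", "core_R", "shell_R")

#: clinical instruments and their valid score ranges
SCORE_RANGES = {
    "QUIP": (0.0, 13.0),
    "MoCA": (0.0, 30.0),
    "GDS": (0.0, 15.0),
    "STAI": (20.0, 80.0),
    "apathy": (0.0, 4.0),
    "RBDSQ": (0.0, 13.0),
    "ESS": (0.0, 24.0),
    "UPSIT": (0.0, 40.0),
}
CLINICAL_COLS = tuple(SCORE_RANGES)

# group-level score distributions (mean, SD) used when no latent coupling is
# requested; PD shifts follow the direction expected in a PD cohort
_PD_SCORE_DIST = {
    "QUIP": (0.10, 0.31),
    "MoCA": (24.41, 4.15),
    "GDS": (2.76, 2.38),
    "STAI": (36.03, 10.40),
    "apathy": (0.56, 0.79),
    "RBDSQ": (4.74, 2.69),
    "ESS": (5.56, 4.56),
    "UPSIT": (24.74, 9.20),
}
_HC_SCORE_DIST = {
    "QUIP": (0.0, 0.0),
    "MoCA": (26.03, 2.75),
    "GDS": (0.0, 0.0),
    "STAI": (27.77, 3.99),
    "apathy": (0.02, 0.14),
    "RBDSQ": (3.76, 1.90),
    "ESS": (3.90, 2.34),
    "UPSIT": (34.43, 3.46),
}

_VOLUME_DIST = {  # mm^3 subregion volumes; cm^3 TIV / gray matter
    "vol_core_L": ((376.90, 47.22), (378.71, 39.29)),
    "vol_shell_L": ((503.36, 62.30), (503.31, 46.38)),
    "vol_core_R": ((296.17, 37.05), (298.91, 34.60)),
    "vol_shell_R": ((598.93, 67.59), (600.88, 57.39)),
    "tiv": ((1485.50, 137.33), (1449.29, 132.86)),
    "gm": ((641.89, 57.13), (644.44, 51.38)),
}

#: default per-score weight of the latent severity factor (score units per
#: unit severity); signs follow the clinical direction of worsening
DEFAULT_BEHAVIOR_LOADINGS = {
    "QUIP": 0.3,
    "MoCA": -5.0,
    "GDS": 3.0,
    "STAI": 12.0,
    "apathy": 1.0,
    "RBDSQ": 3.0,
    "ESS": 5.0,
    "UPSIT": -10.0,
}


@dataclass(frozen=True)
class RoiSpec:
    """One seed region: a Gaussian probability blob on the voxel grid."""

    name: str
    center: tuple[int, int, int]
    sigma: float  # voxels; 0 collapses to a single-voxel ROI


@dataclass(frozen=True)
class AtlasSpec:
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    rois: tuple[RoiSpec, ...] = (
        RoiSpec("core_L", (7, 13, 10), 1.5),
        RoiSpec("shell_L", (7, 8, 12), 1.5),
        RoiSpec("core_R", (16, 13, 10), 1.5),
        RoiSpec("shell_R", (16, 8, 12), 1.5),
    )


@dataclass
class ProbabilisticAtlas:
    """Named seed probability maps plus the brain mask, on one grid."""

    grid_dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    rois: dict[str, np.ndarray]  # name -> 3D float map in [0, 1]
    brain_mask: np.ndarray  # 3D bool

    def validate(self) -> None:
        for name, pmap in self.rois.items():
            if pmap.shape != tuple(self.grid_dims):
                raise ValueError(f"ROI {name!r} not on the atlas grid")
            if np.any((pmap < 0) | (pmap > 1)):
                raise ValueError(f"ROI {name!r} has probabilities outside [0, 1]")
            if np.any((pmap > 0) & ~self.brain_mask):
                raise ValueError(f"ROI {name!r} extends outside the brain mask")
            if int(np.sum(pmap > 0.5)) < 1:
                raise ValueError(f"ROI {name!r} has no high-probability voxels")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        return aff


@dataclass
class BOLDSeries:
    """One subject's 4D BOLD signal (x, y, z, t) and repetition time."""

    subject_id: str
    data: np.ndarray
    tr: float


@dataclass(frozen=True)
class SiteSpec:
    """One acquisition site with its additive/multiplicative batch effect."""

    name: str
    fraction: float  # fraction of the cohort scanned here
    gamma: float = 0.0  # additive offset on Fisher-z maps
    delta: float = 1.0  # scale factor on Fisher-z maps


@dataclass(frozen=True)
class SimulationSpec:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the study conditions: ~116/100 retained subjects arise
    from 129 PD / 106 HC with a handful of motion exclusions, two sites of
    unequal size, and a single latent severity factor that both attenuates
    seed-target coupling and drives the non-motor symptom scores.
    """

    n_pd: int = 129
    n_hc: int = 106
    sites: tuple[SiteSpec, ...] = (
        SiteSpec("center", 0.8, 0.0, 1.0),
        SiteSpec("ppmi", 0.2, 0.3, 1.2),
    )
    coupling_hc: float = 0.6  # seed-target amplitude in HC (signal units)
    coupling_loss_slope: float = 0.4  # amplitude loss per unit latent severity
    noise_sd: float = 1.0
    behavior_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_LOADINGS)
    )
    n_timepoints: int = 200
    tr: float = 2.0
    ar_rho: float = 0.3  # AR(1) coefficient of the latent seed signal
    n_target_voxels: int = 200  # per seed with a planted effect
    n_target_blobs: int = 3  # contiguous clusters the targets split into
    effect_seeds: tuple[str, ...] = ("core_L", "shell_L", "core_R")
    fd_flag_threshold: float = 0.5  # mm, mean framewise displacement
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd < 2 or self.n_hc < 2:
            raise ValueError("need at least 2 subjects per group")
        fr = sum(s.fraction for s in self.sites)
        if not np.isclose(fr, 1.0):
            raise ValueError(f"site fractions sum to {fr}, expected 1")
        if any(s.delta <= 0 for s in self.sites):
            raise ValueError("site scale factors must be positive")
        # latent severity lives on [0, 1]
        if self.coupling_hc - self.coupling_loss_slope < 0:
            raise ValueError(
                "coupling_loss_slope would drive the seed-target amplitude "
                "negative at maximal latent severity"
            )
        unknown = set(self.behavior_loadings) - set(CLINICAL_COLS)
        if unknown:
            raise ValueError(f"unknown clinical scores in behavior_loadings: {unknown}")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["sites"] = [asdict(s) for s in self.sites]
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        if "sites" in d:
            d["sites"] = tuple(SiteSpec(**s) for s in d["sites"])
        for key in ("effect_seeds",):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _grid_distances(grid: tuple[int, int, int], center: tuple[int, int, int]) -> np.ndarray:
    ii, jj, kk = np.ogrid[: grid[0], : grid[1], : grid[2]]
    return np.sqrt(
        (ii - center[0]) ** 2.0 + (jj - center[1]) ** 2.0 + (kk - center[2]) ** 2.0
    )


def generate_atlas(spec: AtlasSpec = AtlasSpec(), seed: int = 0) -> ProbabilisticAtlas:
    """Build a probabilistic seed atlas of Gaussian blobs on a regular grid.

    Each ROI's probability map is exp(-d^2 / (2 sigma^2)) around its center,
    truncated below 0.01; sigma = 0 degenerates to a single voxel with
    probability 1. The brain mask is a centered ellipsoid covering all ROIs.
    The construction is deterministic; `seed` is accepted for interface
    uniformity and recorded nowhere.
    """
    grid = tuple(spec.grid_dims)
    if min(grid) < 20:
        raise ValueError("atlas grid must be at least 20 voxels per axis")
    rois: dict[str, np.ndarray] = {}
    for roi in spec.rois:
        if not all(0 <= c < g for c, g in zip(roi.center, grid)):
            raise ValueError(f"ROI {roi.name!r} center outside grid")
        d = _grid_distances(grid, roi.center)
        if roi.sigma <= 0:
            pmap = np.zeros(grid)
            pmap[roi.center] = 1.0
        else:
            pmap = np.exp(-(d**2) / (2.0 * roi.sigma**2))
            pmap[pmap < 0.01] = 0.0
        rois[roi.name] = pmap
    names = list(rois)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any((rois[a] > 0.5) & (rois[b] > 0.5)):
                raise ValueError(
                    f"ROIs {a!r} and {b!r} overlap at probability > 0.5"
                )
    center = [(g - 1) / 2.0 for g in grid]
    semi = [0.48 * g for g in grid]
    ii, jj, kk = np.ogrid[: grid[0], : grid[1], : grid[2]]
    mask = (
        ((ii - center[0]) / semi[0]) ** 2
        + ((jj - center[1]) / semi[1]) ** 2
        + ((kk - center[2]) / semi[2]) ** 2
    ) <= 1.0
    for pmap in rois.values():
        mask |= pmap > 0
    atlas = ProbabilisticAtlas(grid, tuple(spec.voxel_size), rois, mask)
    atlas.validate()
    return atlas


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    """Normal draw clipped to the instrument range."""
    if np.isscalar(sd) and sd == 0:
        return np.full(size, float(mean))
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def generate_cohort(spec: SimulationSpec) -> pd.DataFrame:
    """Draw a PD/HC cohort table with a planted rank-1 symptom structure.

    PD subjects receive a latent severity drawn uniformly on [0, 1]; each
    clinical score is its group-level draw plus ``loading * (severity - 1/2)``
    clipped to the instrument range. HC severity is 0 and HC scores come from
    the control distributions (several degenerate at 0, as in real PD/HC
    tables). The `latent_severity` column is simulation ground truth and must
    be dropped before any analysis that claims to be blind to it.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 101])
    n = spec.n_pd + spec.n_hc
    group = np.array(["PD"] * spec.n_pd + ["HC"] * spec.n_hc)
    subject_id = np.array(
        [f"pd{i:04d}" for i in range(spec.n_pd)]
        + [f"hc{i:04d}" for i in range(spec.n_hc)]
    )

    # deterministic site assignment honouring the requested fractions,
    # shuffled so that site and group are independent
    site = np.empty(n, dtype=object)
    for grp, ngrp in (("PD", spec.n_pd), ("HC", spec.n_hc)):
        counts = np.floor([s.fraction * ngrp for s in spec.sites]).astype(int)
        while counts.sum() < ngrp:
            counts[int(np.argmax([s.fraction for s in spec.sites]))] += 1
        labels = np.concatenate(
            [np.repeat(s.name, c) for s, c in zip(spec.sites, counts)]
        )
        rng.shuffle(labels)
        site[group == grp] = labels

    pd_mask = group == "PD"
    age = np.where(
        pd_mask, rng.normal(59.51, 9.40, n), rng.normal(60.40, 8.56, n)
    ).clip(30, 90)
    sex = np.where(rng.random(n) < np.where(pd_mask, 0.51, 0.45), "M", "F")
    education = rng.normal(10.5, 4.0, n).clip(0, 22)

    mean_fd = rng.gamma(shape=3.0, scale=0.06, size=n)  # right-skewed, ~0.18 mm
    motion_flag = mean_fd > spec.fd_flag_threshold

    duration = np.where(pd_mask, rng.normal(3.68, 3.74, n).clip(0.1, 25), 0.0)
    ledd = np.where(pd_mask, rng.normal(312.46, 306.92, n).clip(0, 2000), 0.0)
    updrs3 = np.where(pd_mask, rng.normal(25.66, 12.12, n).clip(0, 80), 0.0)
    hy = np.where(pd_mask, rng.normal(1.72, 0.59, n).clip(1, 5), 0.0)

    latent = np.where(pd_mask, rng.uniform(0.0, 1.0, n), 0.0)

    cols: dict[str, np.ndarray] = {}
    for score, (lo, hi) in SCORE_RANGES.items():
        mu_pd, sd_pd = _PD_SCORE_DIST[score]
        mu_hc, sd_hc = _HC_SCORE_DIST[score]
        noise = rng.normal(0.0, 1.0, n)
        raw = np.where(
            pd_mask,
            mu_pd
            + spec.behavior_loadings.get(score, 0.0) * (latent - 0.5)
            + sd_pd * noise,
            mu_hc + sd_hc * noise,
        )
        cols[score] = np.clip(raw, lo, hi)

    vols = {
        name: np.where(
            pd_mask,
            rng.normal(*dist_pd, n),
            rng.normal(*dist_hc, n),
        ).clip(0.1, None)
        for name, (dist_pd, dist_hc) in _VOLUME_DIST.items()
    }

    table = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "site": site,
            "age": age,
            "sex": sex,
            "education": education,
            "mean_fd": mean_fd,
            "motion_flag": motion_flag,
            "duration": duration,
            "ledd": ledd,
            "updrs3": updrs3,
            "hy": hy,
            **vols,
            **cols,
            "latent_severity": latent,
        }
    )
    return table


def assign_targets(
    atlas: ProbabilisticAtlas, spec: SimulationSpec
) -> dict[str, np.ndarray]:
    """Choose disjoint target-voxel sets for each seed with a planted effect.

    Targets are compact contiguous blobs (``spec.n_target_blobs`` per seed,
    grown by nearest-neighbour accretion around random centers) inside the
    brain mask, outside every ROI's support, and disjoint across seeds —
    emulating the clustered topography of real group differences so the
    cluster-extent filter behaves as it would on real maps. Seeds not listed
    in ``spec.effect_seeds`` get an empty target set (their group contrast is
    null by construction).
    """
    rng = np.random.default_rng([spec.seed, 202])
    forbidden = np.zeros(atlas.grid_dims, dtype=bool)
    for pmap in atlas.rois.values():
        forbidden |= pmap > 0
    available = atlas.brain_mask & ~forbidden
    need = spec.n_target_voxels * len(spec.effect_seeds)
    if need > int(available.sum()):
        raise ValueError(
            f"grid too small: need {need} target voxels, have {int(available.sum())}"
        )
    grid = tuple(atlas.grid_dims)
    coords_all = np.argwhere(available)
    taken = np.zeros(len(coords_all), dtype=bool)
    targets: dict[str, np.ndarray] = {name: np.zeros(grid, dtype=bool)
                                      for name in atlas.rois}
    sizes = np.full(spec.n_target_blobs, spec.n_target_voxels // spec.n_target_blobs)
    sizes[: spec.n_target_voxels % spec.n_target_blobs] += 1
    for name in spec.effect_seeds:
        if name not in targets:
            raise ValueError(f"effect seed {name!r} not in the atlas")
        for size in sizes:
            if size == 0:
                continue
            free = np.flatnonzero(~taken)
            center = coords_all[rng.choice(free)]
            d = np.linalg.norm(coords_all[free] - center, axis=1)
            grab = free[np.argsort(d, kind="stable")[:size]]
            taken[grab] = True
            targets[name][tuple(coords_all[grab].T)] = True
    return targets


def _subject_rng(spec_seed: int, subject_id: str) -> np.random.Generator:
    # crc32 is stable across runs/platforms, unlike hash()
    return np.random.default_rng([spec_seed, zlib.crc32(subject_id.encode())])


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Unit-variance stationary AR(1) series."""
    if rho == 0:
        return rng.standard_normal(n)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * np.sqrt(1.0 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + innov[t - 1]
    return x


def generate_bold(
    subject: pd.Series,
    atlas: ProbabilisticAtlas,
    targets: dict[str, np.ndarray],
    spec: SimulationSpec,
) -> BOLDSeries:
    """Simulate one subject's 4D BOLD series with planted seed-target coupling.

    Each seed ROI carries its own unit-variance AR(1) latent signal s_k(t);
    ROI voxels observe s_k(t) + noise, that seed's target voxels observe
    a * s_k(t) + noise with amplitude a = coupling_hc -
    coupling_loss_slope * latent_severity, and all remaining voxels are pure
    noise. The population seed-target correlation is therefore
    a / sqrt(a^2 + noise_sd^2). Deterministic given (spec.seed, subject_id).
    """
    T = spec.n_timepoints
    if T < 30:
        raise ValueError("need at least 30 time points")
    sev = float(subject.get("latent_severity", 0.0))
    a = spec.coupling_hc - spec.coupling_loss_slope * sev
    if a < 0:
        raise ValueError("negative seed-target amplitude; check SimulationSpec")
    rng = _subject_rng(spec.seed, str(subject["subject_id"]))

    grid = tuple(atlas.grid_dims)
    nvox = int(np.prod(grid))
    signals = {name: _ar1(rng, T, spec.ar_rho).astype(np.float32)
               for name in atlas.rois}
    # single-precision noise, drawn only inside the brain mask (the analysis
    # domain); out-of-mask voxels stay identically zero
    data = np.zeros((nvox, T), dtype=np.float32)
    mask_flat = np.flatnonzero(atlas.brain_mask.reshape(-1))
    noise = rng.standard_normal((mask_flat.size, T), dtype=np.float32)
    if spec.noise_sd != 1.0:
        noise *= np.float32(spec.noise_sd)
    data[mask_flat] = noise

    # assign each ROI-support voxel to its maximum-probability ROI
    probs = np.stack([atlas.rois[name].reshape(-1) for name in atlas.rois])
    support = probs.max(axis=0) > 0
    owner = probs.argmax(axis=0)
    names = list(atlas.rois)
    for k, name in enumerate(names):
        vox = np.flatnonzero(support & (owner == k))
        data[vox] += signals[name][None, :]
        tgt = np.flatnonzero(targets.get(name, np.zeros(grid, bool)).reshape(-1))
        data[tgt] += a * signals[name][None, :]

    return BOLDSeries(str(subject["subject_id"]), data.reshape(grid + (T,)), spec.tr)


def apply_site_effects(fcmaps, table: pd.DataFrame, spec: SimulationSpec):
    """Scale-and-shift each subject's z-map by its site's batch parameters.

    For subject j at site i the harmonization target is created as
    z' = delta_i * z + gamma_i, the exact location/scale structure the
    empirical-Bayes harmonizer assumes.
    """
    site_of = dict(zip(table["subject_id"], table["site"]))
    params = {s.name: (s.gamma, s.delta) for s in spec.sites}
    out = []
    for fcmap in fcmaps:
        site = site_of.get(fcmap.subject_id)
        if site is None or site not in params:
            raise ValueError(f"subject {fcmap.subject_id!r} has no known site")
        gamma, delta = params[site]
        from nacfc.fc import FCMap  # local import to avoid a cycle

        out.append(
            FCMap(fcmap.subject_id, fcmap.seed_name, delta * fcmap.values + gamma)
        )
    return out


def qc_filter(
    table: pd.DataFrame,
    flag_col: str | None = "motion_flag",
    fd_threshold: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Exclude subjects with excessive head motion.

    Either an explicit boolean flag column or a mean-FD threshold (default
    0.5 mm when neither is given) decides exclusion. Returns the retained
    table and the number excluded per group.
    """
    if fd_threshold is not None:
        if "mean_fd" not in table.columns:
            raise ValueError("fd_threshold given but no 'mean_fd' column")
        flagged = table["mean_fd"] > fd_threshold
    elif flag_col is not None:
        if flag_col not in table.columns:
            raise ValueError(f"missing motion flag column {flag_col!r}")
        flagged = table[flag_col].astype(bool)
    else:
        if "mean_fd" not in table.columns:
            raise ValueError("no motion criterion resolvable")
        flagged = table["mean_fd"] > 0.5
    kept = table.loc[~flagged].reset_index(drop=True)
    excluded = {
        str(g): int(n)
        for g, n in table.loc[flagged, "group"].value_counts().items()
    }
    for g in table["group"].unique():
        excluded.setdefault(str(g), 0)
    if kept.empty:
        warnings.warn("all subjects excluded by the motion criterion")
    logger.info("qc_filter excluded %s", excluded)
    return kept, excluded
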