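"""Pipeline orchestration: simulate -> fc -> harmonize -> glm -> pls.

`run_pipeline` executes the enabled stages in order on a single
configuration object and returns a manifest (parameters, content hashes of
every numeric output, per-stage notes) plus the stage results. Reruns with
an identical configuration reproduce identical numbers; the manifest makes
that checkable by hash comparison.

The brain-behavior stage mirrors the two-pass protocol of the study design:
a first PLS pass in which the behavior block carries the non-motor symptom
scores together with demographic/clinical nuisance variables, then a rerun
on nuisance-residualized blocks (both sides) with the eight symptom scores
only.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from nacfc import combat, glm as glm_mod, io, plsc
from nacfc.fc import FCMap, seed_fc_maps
from nacfc.synthetic import (
    AtlasSpec,
    SimulationSpec,
    apply_site_effects,
    assign_targets,
    generate_atlas,
    generate_bold,
    generate_cohort,
    qc_filter,
)

logger = logging.getLogger(__name__)

NMS_BEHAVIORS = ("QUIP", "MoCA", "GDS", "STAI", "apathy", "RBDSQ", "ESS", "UPSIT")
DEFAULT_NUISANCE = ("age", "education", "duration", "ledd", "updrs3", "hy",
                    "tiv", "gm")  # the seed's own volume column is appended


@dataclass
class PipelineConfig:
    sim: SimulationSpec = field(default_factory=SimulationSpec)
    atlas: AtlasSpec = field(default_factory=AtlasSpec)
    out_dir: str | None = None  # None: keep everything in memory
    q: float = 0.05
    k_min: int = 20
    connectivity: int = 26
    n_perm: int = 1000
    n_boot: int = 1000
    glm_covariates: tuple[str, ...] = ("sex", "age", "education", "mean_fd")
    harmonize_preserve: tuple[str, ...] = ("group", "age", "sex", "education")
    behaviors: tuple[str, ...] = NMS_BEHAVIORS
    nuisance: tuple[str, ...] = DEFAULT_NUISANCE
    qc_flag_col: str | None = "motion_flag"
    qc_fd_threshold: float | None = None
    first_pass: bool = True
    stages: tuple[str, ...] = ("simulate", "fc", "harmonize", "glm", "pls")
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        for s in self.stages:
            if s not in ("simulate", "fc", "harmonize", "glm", "pls"):
                raise ValueError(f"unknown stage {s!r}")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_json_dict()
        # the output location is not a parameter of the computation: two runs
        # of one configuration must produce identical manifests
        d.pop("out_dir", None)
        return d


def _hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        if isinstance(a, pd.DataFrame):
            h.update(a.to_csv(index=False).encode())
        else:
            a = np.ascontiguousarray(a)
            h.update(str(a.dtype).encode() + str(a.shape).encode())
            h.update(a.tobytes())
    return h.hexdigest()


def _encode(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        levels = sorted(col.astype(str).unique())
        return (col.astype(str) == levels[-1]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def compute_zmaps(atlas, cohort, targets, spec) -> dict[str, list[FCMap]]:
    """Stream BOLD simulation -> per-seed Fisher-z maps for every subject."""
    out: dict[str, list[FCMap]] = {name: [] for name in atlas.rois}
    for _, row in cohort.iterrows():
        bold = generate_bold(row, atlas, targets, spec)
        for name, fcmap in seed_fc_maps(bold, atlas).items():
            out[name].append(fcmap)
    return out


def _harmonize_seed(fcmaps, cohort, preserve):
    mat = np.stack([m.values.reshape(-1) for m in fcmaps], axis=1)  # vox x subj
    design = np.column_stack([_encode(cohort[c]) for c in preserve]) if preserve else None
    ok = np.isfinite(mat).all(axis=1)  # out-of-mask voxels stay untouched
    adj = mat.copy()
    adj[ok] = combat.harmonize(mat[ok], cohort["site"].to_numpy(), design)
    shape = fcmaps[0].values.shape
    return [FCMap(m.subject_id, m.seed_name, adj[:, j].reshape(shape))
            for j, m in enumerate(fcmaps)]


def _pls_blocks(fcmaps, mask, cohort, behavior_cols):
    pd_rows = cohort["group"] == "PD"
    idx = np.flatnonzero(pd_rows.to_numpy())
    flat = mask.reshape(-1)
    X = np.stack([fcmaps[i].values.reshape(-1)[flat] for i in idx])
    Y = np.column_stack([_encode(cohort.iloc[idx][c]) for c in behavior_cols])
    ok = np.isfinite(X).all(axis=1) & np.isfinite(Y).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("listwise deletion dropped %d PD subjects", dropped)
    row_ids = cohort.iloc[idx[ok]]["subject_id"].tolist()
    vox_names = [str(v) for v in np.flatnonzero(flat)]
    return plsc.PLSBlocks(X[ok], Y[ok], row_ids,
                          x_names=vox_names, y_names=list(behavior_cols)), idx[ok]


def _summarize_pls(res: plsc.PLSResult) -> dict:
    r = plsc.score_correlation(res)
    return {
        "singular_values": res.singular_values,
        "cov_explained": res.cov_explained,
        "perm_p": res.perm_p,
        "behaviors": res.y_names,
        "behavioral_loadings_lv1": None if res.behavioral_loadings is None
        else res.behavioral_loadings[:, 0],
        "loading_ci_lv1": None if res.loading_ci is None else res.loading_ci[:, 0, :],
        "loading_significant_lv1": None if res.loading_significant is None
        else res.loading_significant[:, 0],
        "n_bsr_significant_lv1": None if res.bsr_significant is None
        else int(res.bsr_significant[:, 0].sum()),
        "score_correlation": r,
    }


def run_pipeline(config: PipelineConfig):
    """Execute the enabled stages; return (manifest, results)."""
    config.validate()
    manifest: dict = {"config": config.to_json_dict(), "stages": {}}
    results: dict = {}
    out_dir = Path(config.out_dir) if config.out_dir else None
    stages = config.stages

    atlas = cohort = targets = None
    if "simulate" in stages:
        atlas = generate_atlas(config.atlas, seed=config.sim.seed)
        targets = assign_targets(atlas, config.sim)
        cohort_raw = generate_cohort(config.sim)
        cohort, excluded = qc_filter(cohort_raw,
                                     flag_col=config.qc_flag_col,
                                     fd_threshold=config.qc_fd_threshold)
        manifest["stages"]["simulate"] = {
            "cohort_hash": _hash(cohort_raw),
            "retained": {g: int(n) for g, n in
                         cohort["group"].value_counts().items()},
            "excluded": excluded,
            "atlas_hash": _hash(*[atlas.rois[k] for k in sorted(atlas.rois)],
                                atlas.brain_mask),
        }
        results["atlas"], results["cohort"], results["targets"] = atlas, cohort, targets
        if out_dir:
            io.save_atlas(atlas, out_dir / "atlas")
            io.save_cohort(cohort, out_dir / "cohort.tsv")
            io.dump_json(config.sim.to_json_dict(), out_dir / "simulation_spec.json")

    zmaps: dict[str, list[FCMap]] | None = None
    if "fc" in stages:
        if atlas is None:
            raise ValueError("fc stage requires the simulate stage (or load "
                             "data and call the library functions directly)")
        zmaps = compute_zmaps(atlas, cohort, targets, config.sim)
        zmaps = {name: apply_site_effects(maps, cohort, config.sim)
                 for name, maps in zmaps.items()}
        manifest["stages"]["fc"] = {
            "n_subjects": len(cohort),
            "zmap_hash": {name: _hash(*[m.values for m in maps])
                          for name, maps in zmaps.items()},
        }
        results["zmaps_raw"] = zmaps
        if out_dir:
            for maps in zmaps.values():
                for m in maps:
                    io.save_fcmap(m, out_dir / "zmaps", atlas.voxel_size)

    if "harmonize" in stages:
        if zmaps is None:
            raise ValueError("harmonize stage requires fc outputs")
        zmaps = {name: _harmonize_seed(maps, cohort, config.harmonize_preserve)
                 for name, maps in zmaps.items()}
        manifest["stages"]["harmonize"] = {
            "preserve": list(config.harmonize_preserve),
            "zmap_hash": {name: _hash(*[m.values for m in maps])
                          for name, maps in zmaps.items()},
        }
        results["zmaps"] = zmaps
        if out_dir:
            for maps in zmaps.values():
                for m in maps:
                    io.save_fcmap(m, out_dir / "zmaps_harmonized", atlas.voxel_size)

    networks: dict[str, glm_mod.SignificanceMask] = {}
    if "glm" in stages:
        if zmaps is None:
            raise ValueError("glm stage requires fc outputs")
        glm_out = {}
        for name, maps in zmaps.items():
            res = glm_mod.voxelwise_group_contrast(maps, cohort,
                                                   config.glm_covariates)
            sig = glm_mod.significance_network(res, q=config.q,
                                               k_min=config.k_min,
                                               connectivity=config.connectivity)
            glm_out[name] = (res, sig)
            networks[name] = sig
        manifest["stages"]["glm"] = {
            "covariates": list(config.glm_covariates),
            "q": config.q, "k_min": config.k_min,
            "n_sig_voxels": {n: s.n_voxels for n, (r, s) in glm_out.items()},
            "t_hash": {n: _hash(r.t_map) for n, (r, s) in glm_out.items()},
        }
        results["glm"] = glm_out
        if out_dir:
            aff = atlas.affine
            import nibabel as nib
            gdir = out_dir / "glm"
            gdir.mkdir(parents=True, exist_ok=True)
            for n, (r, s) in glm_out.items():
                nib.save(nib.Nifti1Image(r.t_map.astype(np.float32), aff),
                         gdir / f"tmap_{n}.nii")
                nib.save(nib.Nifti1Image(s.mask.astype(np.float32), aff),
                         gdir / f"network_{n}.nii")
                s.cluster_table(r.t_map).to_csv(gdir / f"clusters_{n}.tsv",
                                                sep="\t", index=False)

    if "pls" in stages:
        if zmaps is None or not networks:
            raise ValueError("pls stage requires glm outputs")
        ss = np.random.SeedSequence([config.seed, 7])
        pls_out = {}
        for i, (name, sig) in enumerate(networks.items()):
            if sig.n_voxels == 0:
                logger.info("seed %s: empty significance network, PLS skipped",
                            name)
                pls_out[name] = None
                continue
            nuisance_cols = list(config.nuisance) + [f"vol_{name}"]
            seed_i = np.random.SeedSequence([config.seed, 7, i])
            entry = {}
            if config.first_pass:
                ext_cols = list(config.behaviors) + ["sex"] + nuisance_cols
                blocks_ext, _ = _pls_blocks(zmaps[name], sig.mask, cohort, ext_cols)
                res1 = plsc.run_plsc(blocks_ext, config.n_perm, config.n_boot,
                                     seed=_sub_seed(seed_i, 0))
                entry["first_pass"] = _summarize_pls(res1)
            blocks, idx = _pls_blocks(zmaps[name], sig.mask, cohort,
                                      config.behaviors)
            nuis = np.column_stack([_encode(cohort.iloc[idx][c])
                                    for c in nuisance_cols])
            blocks = plsc.PLSBlocks(
                plsc.residualize(blocks.X, nuis, nuisance_cols),
                plsc.residualize(blocks.Y, nuis, nuisance_cols),
                blocks.row_ids, blocks.x_names, blocks.y_names)
            res2 = plsc.run_plsc(blocks, config.n_perm, config.n_boot,
                                 seed=_sub_seed(seed_i, 1))
            entry["residualized"] = _summarize_pls(res2)
            entry["n_voxels"] = sig.n_voxels
            entry["result"] = res2
            pls_out[name] = entry
        manifest["stages"]["pls"] = {
            "n_perm": config.n_perm, "n_boot": config.n_boot,
            "summary": {
                n: (None if e is None else {
                    "n_voxels": e["n_voxels"],
                    "lv1_cov_explained": float(e["residualized"]["cov_explained"][0]),
                    "lv1_perm_p": float(e["residualized"]["perm_p"][0]),
                    "lv1_score_r": float(e["residualized"]["score_correlation"][0]),
                })
                for n, e in pls_out.items()
            },
        }
        results["pls"] = pls_out
        if out_dir:
            for n, e in pls_out.items():
                if e is None:
                    continue
                payload = {k: e[k] for k in ("first_pass", "residualized")
                           if k in e}
                payload["n_voxels"] = e["n_voxels"]
                io.dump_json(payload, out_dir / f"pls_{n}.json")

    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        io.dump_json(manifest, out_dir / "manifest.json")
        (out_dir / "report.txt").write_text(write_report(manifest, results))
    return manifest, results


def _sub_seed(ss: np.random.SeedSequence, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(list(ss.entropy if isinstance(ss.entropy, list)
                                       else [ss.entropy]) + [k])


def write_report(manifest: dict, results: dict) -> str:
    """Human-readable per-seed summary of the brain-behavior analysis."""
    lines = ["Seed-based NAc connectivity / non-motor symptom analysis",
             "=" * 58, ""]
    sim = manifest.get("stages", {}).get("simulate")
    if sim:
        lines.append(f"Cohort retained after motion QC: {sim['retained']} "
                     f"(excluded {sim['excluded']})")
        lines.append("")
    pls_out = results.get("pls") or {}
    significant = {n: e for n, e in pls_out.items() if e is not None}
    if not significant:
        lines += ["No significant seeds", "-" * 22,
                  "No seed produced a surviving significance network; "
                  "the brain-behavior analysis was not run."]
        return "\n".join(lines) + "\n"
    for name, e in pls_out.items():
        lines.append(f"Seed {name}")
        lines.append("-" * (5 + len(name)))
        if e is None:
            lines.append("  no surviving voxels in the group contrast; "
                         "PLS skipped\n")
            continue
        r = e["residualized"]
        lines.append(f"  network voxels:        {e['n_voxels']}")
        lines.append(f"  LV-I cov explained:    {100 * r['cov_explained'][0]:.0f}%")
        lines.append(f"  LV-I permutation p:    {r['perm_p'][0]:.4g}")
        lines.append(f"  imaging-behavior r:    {r['score_correlation'][0]:.2f}")
        lines.append("  significant behaviors (loading [95% CI]):")
        for b, load, ci, sig in zip(r["behaviors"],
                                    r["behavioral_loadings_lv1"],
                                    r["loading_ci_lv1"],
                                    r["loading_significant_lv1"]):
            if sig:
                lines.append(f"    {b:8s} R = {load:+.2f} "
                             f"[{ci[0]:+.2f}, {ci[1]:+.2f}]")
        lines.append("")
    return "\n".join(lines) + "\n"
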