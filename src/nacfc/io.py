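"""NIfTI / TSV / JSON readers and writers for pipeline artifacts.

All images are NIfTI-1 with a diagonal affine built from the voxel size;
voxel indices in tables are 0-based. Connectivity maps are float32 with NaN
as the missing marker. Uncompressed ``.nii`` is used so that reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from nacfc.fc import FCMap
from nacfc.synthetic import BOLDSeries, ProbabilisticAtlas


def _img(data: np.ndarray, affine: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    return img


def save_atlas(atlas: ProbabilisticAtlas, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = atlas.affine
    nib.save(_img(atlas.brain_mask.astype(np.float32), aff), out / "brain_mask.nii")
    for name, pmap in atlas.rois.items():
        nib.save(_img(pmap, aff), out / f"roi_{name}.nii")
    meta = {"grid_dims": list(atlas.grid_dims),
            "voxel_size": list(atlas.voxel_size),
            "rois": list(atlas.rois)}
    (out / "atlas.json").write_text(json.dumps(meta, indent=1))


def load_atlas(in_dir: str | Path) -> ProbabilisticAtlas:
    p = Path(in_dir)
    meta = json.loads((p / "atlas.json").read_text())
    mask = np.asarray(nib.load(p / "brain_mask.nii").dataobj) > 0.5
    rois = {
        name: np.asarray(nib.load(p / f"roi_{name}.nii").dataobj, dtype=float)
        for name in meta["rois"]
    }
    return ProbabilisticAtlas(tuple(meta["grid_dims"]), tuple(meta["voxel_size"]),
                              rois, mask)


def save_bold(bold: BOLDSeries, path: str | Path,
              voxel_size=(3.0, 3.0, 3.0)) -> None:
    aff = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), aff)
    img.header["pixdim"][4] = bold.tr
    nib.save(img, str(path))


def load_bold(path: str | Path, subject_id: str | None = None) -> BOLDSeries:
    img = nib.load(str(path))
    tr = float(img.header["pixdim"][4]) or 1.0
    sid = subject_id or Path(path).name.split(".")[0]
    return BOLDSeries(sid, np.asarray(img.dataobj, dtype=float), tr)


def zmap_filename(subject_id: str, seed_name: str) -> str:
    return f"{subject_id}_{seed_name}_zmap.nii"


def save_fcmap(fcmap: FCMap, out_dir: str | Path,
               voxel_size=(3.0, 3.0, 3.0)) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = np.diag(list(voxel_size) + [1.0])
    path = out / zmap_filename(fcmap.subject_id, fcmap.seed_name)
    nib.save(_img(fcmap.values, aff), path)
    return path


def load_fcmap(path: str | Path, subject_id: str | None = None,
               seed_name: str | None = None) -> FCMap:
    """Read a z-map written as ``<subject>_<seed>_zmap.nii``.

    Seed names follow the ``<region>_<hemisphere>`` convention (two
    underscore-separated tokens, e.g. ``core_L``); pass ``subject_id`` /
    ``seed_name`` explicitly for files that do not follow it.
    """
    name = Path(path).name
    stem = name[: -len("_zmap.nii")] if name.endswith("_zmap.nii") else name
    if subject_id is None or seed_name is None:
        sub, region, hemi = stem.rsplit("_", 2)
        subject_id = subject_id or sub
        seed_name = seed_name or f"{region}_{hemi}"
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return FCMap(subject_id, seed_name, data)


def save_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


class NumpyJSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, cls=NumpyJSONEncoder,
                                     sort_keys=True))
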