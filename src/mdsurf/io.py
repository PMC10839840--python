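"""Reading and writing the pipeline's on-disk formats.

Surface geometry, labels and per-vertex scalars travel as GIFTI
(.surf.gii / .label.gii / .func.gii) via nibabel, each with a plain-CSV
fallback; cohorts as one metric file per subject per task plus a JSON
manifest; connectivity as a dense .npy with a JSON sidecar.

CSV schemas
-----------
surface:  vertices ``v,x,y,z[,component]`` and triangles ``a,b,c`` in two
          files (``*_vertices.csv`` / ``*_triangles.csv``)
labels:   ``v,label``
metric:   ``v,value`` (one column per map for multi-column variants)
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .activation import ContrastCohort
from .fingerprint import ConnectivityMatrix
from .geometry import Parcellation, SurfaceMesh

__all__ = [
    "save_surface_gifti",
    "load_surface_gifti",
    "save_labels_gifti",
    "load_labels_gifti",
    "save_metric_gifti",
    "load_metric_gifti",
    "save_surface_csv",
    "load_surface_csv",
    "save_labels_csv",
    "load_labels_csv",
    "save_metric_csv",
    "load_metric_csv",
    "save_cohort",
    "load_cohort",
    "save_connectivity",
    "load_connectivity",
]


# -- GIFTI ------------------------------------------------------------------


def save_surface_gifti(mesh: SurfaceMesh, path) -> None:
    img = nib.gifti.GiftiImage()
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
    )
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(
            mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
    )
    meta = {
        "component_id": json.dumps(np.asarray(mesh.component_id).tolist()),
        "homolog_map": json.dumps(
            {str(k): int(v) for k, v in mesh.homolog_map.items()}
        ),
    }
    img.meta = nib.gifti.GiftiMetaData(meta)
    nib.save(img, str(path))


def load_surface_gifti(path) -> SurfaceMesh:
    img = nib.load(str(path))
    coords = tris = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            tris = np.asarray(da.data, dtype=np.int64)
    if coords is None or tris is None:
        raise ValueError(f"{path}: not a surface GIFTI (needs pointset + triangle)")
    meta = dict(img.meta)
    comp = None
    if "component_id" in meta:
        comp = np.asarray(json.loads(meta["component_id"]), dtype=object)
    homologs = {}
    if "homolog_map" in meta:
        homologs = {int(k): int(v) for k, v in json.loads(meta["homolog_map"]).items()}
    return SurfaceMesh(
        vertex_coords=coords, triangles=tris, component_id=comp, homolog_map=homologs
    )


def save_labels_gifti(parc: Parcellation, path) -> None:
    areas = parc.areas
    key_of = {a: i + 1 for i, a in enumerate(areas)}
    data = np.asarray([key_of[a] for a in parc.area_label], dtype=np.int32)
    table = nib.gifti.GiftiLabelTable()
    for a, k in key_of.items():
        lab = nib.gifti.GiftiLabel(key=k, red=0.5, green=0.5, blue=0.5, alpha=1.0)
        lab.label = str(a)
        table.labels.append(lab)
    img = nib.gifti.GiftiImage(labeltable=table)
    img.add_gifti_data_array(
        nib.gifti.GiftiDataArray(data, intent="NIFTI_INTENT_LABEL")
    )
    img.meta = nib.gifti.GiftiMetaData(
        {
            "area_network": json.dumps({str(k): v for k, v in parc.area_network.items()}),
            "area_role": json.dumps({str(k): v for k, v in parc.area_role.items()}),
        }
    )
    nib.save(img, str(path))


def load_labels_gifti(path) -> Parcellation:
    img = nib.load(str(path))
    data = np.asarray(img.darrays[0].data, dtype=np.int64)
    name_of = {lab.key: lab.label for lab in img.labeltable.labels}
    labels = np.asarray([name_of[k] for k in data], dtype=object)
    meta = dict(img.meta)
    network = json.loads(meta.get("area_network", "{}"))
    role = json.loads(meta.get("area_role", "{}"))
    return Parcellation(area_label=labels, area_network=network, area_role=role)


def save_metric_gifti(values: np.ndarray, path, names: list[str] | None = None) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    img = nib.gifti.GiftiImage()
    for i, row in enumerate(values):
        da = nib.gifti.GiftiDataArray(
            row.astype(np.float32), intent="NIFTI_INTENT_NONE"
        )
        if names is not None:
            da.meta = nib.gifti.GiftiMetaData({"Name": names[i]})
        img.add_gifti_data_array(da)
    nib.save(img, str(path))


def load_metric_gifti(path) -> np.ndarray:
    img = nib.load(str(path))
    rows = [np.asarray(da.data, dtype=float) for da in img.darrays]
    out = np.stack(rows)
    return out[0] if out.shape[0] == 1 else out


# -- CSV fallbacks ----------------------------------------------------------


def save_surface_csv(mesh: SurfaceMesh, stem) -> None:
    stem = Path(stem)
    pd.DataFrame(
        {
            "v": np.arange(mesh.n_vertices),
            "x": mesh.vertex_coords[:, 0],
            "y": mesh.vertex_coords[:, 1],
            "z": mesh.vertex_coords[:, 2],
            "component": np.asarray(mesh.component_id, dtype=str),
        }
    ).to_csv(stem.with_name(stem.name + "_vertices.csv"), index=False)
    pd.DataFrame(mesh.triangles, columns=["a", "b", "c"]).to_csv(
        stem.with_name(stem.name + "_triangles.csv"), index=False
    )


def load_surface_csv(stem) -> SurfaceMesh:
    stem = Path(stem)
    v = pd.read_csv(stem.with_name(stem.name + "_vertices.csv"))
    t = pd.read_csv(stem.with_name(stem.name + "_triangles.csv"))
    return SurfaceMesh(
        vertex_coords=v[["x", "y", "z"]].to_numpy(),
        triangles=t[["a", "b", "c"]].to_numpy(),
        component_id=v["component"].to_numpy(dtype=object)
        if "component" in v
        else None,
    )


def save_labels_csv(parc: Parcellation, path) -> None:
    pd.DataFrame(
        {"v": np.arange(parc.area_label.shape[0]), "label": parc.area_label}
    ).to_csv(path, index=False)


def load_labels_csv(path) -> Parcellation:
    df = pd.read_csv(path)
    return Parcellation(area_label=df["label"].to_numpy(dtype=object))


def save_metric_csv(values: np.ndarray, path, names: list[str] | None = None) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = names or [f"map{i}" for i in range(values.shape[0])]
    df = pd.DataFrame({"v": np.arange(values.shape[1])})
    for name, row in zip(cols, values):
        df[name] = row
    df.to_csv(path, index=False)


def load_metric_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    out = df.drop(columns=["v"]).to_numpy(dtype=float).T
    return out[0] if out.shape[0] == 1 else out


# -- cohorts ----------------------------------------------------------------


def save_cohort(cohort: ContrastCohort, directory) -> None:
    """One metric file per subject per task plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_ids": list(map(str, cohort.subject_ids)),
        "task_names": list(cohort.task_names),
        "se_df": None if np.isinf(cohort.se_df) else cohort.se_df,
        "files": {},
        "se_files": {},
    }
    for s, sid in enumerate(cohort.subject_ids):
        for t, task in enumerate(cohort.task_names):
            fname = f"{sid}_{task}.func.gii"
            save_metric_gifti(cohort.values[s, t], directory / fname)
            manifest["files"][f"{sid}/{task}"] = fname
            if cohort.se is not None:
                sename = f"{sid}_{task}_se.func.gii"
                save_metric_gifti(cohort.se[s, t], directory / sename)
                manifest["se_files"][f"{sid}/{task}"] = sename
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_cohort(directory) -> ContrastCohort:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    subs = manifest["subject_ids"]
    tasks = manifest["task_names"]
    values, ses = [], []
    for sid in subs:
        row, serow = [], []
        for task in tasks:
            row.append(load_metric_gifti(directory / manifest["files"][f"{sid}/{task}"]))
            key = f"{sid}/{task}"
            if key in manifest.get("se_files", {}):
                serow.append(load_metric_gifti(directory / manifest["se_files"][key]))
        values.append(row)
        if serow:
            ses.append(serow)
    se_df = manifest.get("se_df")
    return ContrastCohort(
        values=np.asarray(values),
        task_names=tasks,
        subject_ids=subs,
        se=np.asarray(ses) if ses else None,
        se_df=np.inf if se_df is None else se_df,
    )


# -- connectivity -----------------------------------------------------------


def save_connectivity(conn: ConnectivityMatrix, stem) -> None:
    stem = Path(stem)
    np.save(stem.with_suffix(".npy"), conn.matrix)
    stem.with_suffix(".json").write_text(
        json.dumps({"shape": list(conn.matrix.shape), "format": "dense-npy"})
    )


def load_connectivity(stem) -> ConnectivityMatrix:
    stem = Path(stem)
    m = np.load(stem.with_suffix(".npy"))
    return ConnectivityMatrix(matrix=m)
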