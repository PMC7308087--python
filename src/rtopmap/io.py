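"""Readers and writers for the standard neuroimaging formats used here.

dMRI volumes travel as NIfTI with FSL-style bval/bvec text files (one
whitespace-delimited row of b-values; three rows of direction components),
surfaces as GIFTI (.surf.gii) with label GIFTI (.label.gii), resting-state
runs as 4-D NIfTI plus a frames x 6 motion text table, and tabular outputs
as CSV/JSON.  All volumetric outputs are float32 NIfTI with a JSON sidecar
recording units.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .scheme import AcquisitionScheme
from .synthetic import SurfaceMesh

__all__ = [
    "save_dmri", "load_dmri",
    "save_volume", "load_volume",
    "save_surface", "load_surface",
    "save_labels", "load_labels",
    "save_motion", "load_motion",
    "save_json",
]

LABEL_CODES = {"background": 0, "vAI": 1, "dAI": 2, "PI": 3}


def save_dmri(
    path: Path | str,
    data: np.ndarray,
    scheme: AcquisitionScheme,
    affine: np.ndarray | None = None,
) -> None:
    """Write a 4-D dMRI volume as NIfTI + .bval/.bvec + timing sidecar."""
    path = Path(path)
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
    stem = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    np.savetxt(stem.with_suffix(".bval"), scheme.b_values[None], fmt="%.1f")
    np.savetxt(stem.with_suffix(".bvec"), scheme.directions.T, fmt="%.8f")
    save_json(stem.with_suffix(".json"), {
        "small_delta_s": scheme.small_delta,
        "big_delta_s": scheme.big_delta,
        "tau_s": scheme.tau,
    })


def load_dmri(path: Path | str) -> tuple[np.ndarray, np.ndarray, AcquisitionScheme]:
    """Read NIfTI + bval/bvec (+ timing sidecar); returns (data, affine, scheme).

    Pulse timings are required: they come from the JSON sidecar written by
    :func:`save_dmri`; without them tau is undefined and loading fails.
    """
    path = Path(path)
    img = nib.load(path)
    stem = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
    bvals = np.loadtxt(stem.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(stem.with_suffix(".bvec"))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    sidecar = stem.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"{sidecar} missing: pulse timings (small_delta, big_delta) are "
            "required to define the diffusion time"
        )
    meta = json.loads(sidecar.read_text())
    scheme = AcquisitionScheme(
        bvals, bvecs, meta["small_delta_s"], meta["big_delta_s"]
    )
    return np.asarray(img.dataobj, dtype=float), img.affine, scheme


def save_volume(path: Path | str, data: np.ndarray, affine: np.ndarray,
                units: str | None = None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), path)
    if units is not None:
        stem = path.with_suffix("").with_suffix("") if path.name.endswith(".nii.gz") else path.with_suffix("")
        save_json(stem.with_suffix(".json"), {"units": units})


def load_volume(path: Path | str) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(Path(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_surface(path: Path | str, mesh: SurfaceMesh) -> None:
    """Write a triangle mesh as a GIFTI .surf.gii."""
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(
            mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(
            mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, Path(path))


def load_surface(path: Path | str) -> SurfaceMesh:
    img = nib.load(Path(path))
    verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
    tris = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    return SurfaceMesh(np.asarray(verts, float), np.asarray(tris, np.int64))


def save_labels(path: Path | str, labels: np.ndarray,
                codes: dict[str, int] | None = None) -> None:
    """Write per-vertex categorical labels as a GIFTI .label.gii."""
    codes = codes or LABEL_CODES
    arr = np.array([codes[str(l)] for l in labels], dtype=np.int32)
    table = nib.gifti.GiftiLabelTable()
    for name, code in codes.items():
        lab = nib.gifti.GiftiLabel(key=code)
        lab.label = name
        table.labels.append(lab)
    img = nib.gifti.GiftiImage(labeltable=table, darrays=[
        nib.gifti.GiftiDataArray(arr, intent="NIFTI_INTENT_LABEL",
                                 datatype="NIFTI_TYPE_INT32"),
    ])
    nib.save(img, Path(path))


def load_labels(path: Path | str) -> np.ndarray:
    img = nib.load(Path(path))
    codes = img.labeltable.get_labels_as_dict()
    data = img.darrays[0].data
    return np.array([codes[int(v)] for v in data], dtype=object).astype(str)


def save_motion(path: Path | str, motion: np.ndarray) -> None:
    np.savetxt(Path(path), motion, fmt="%.8f")


def load_motion(path: Path | str) -> np.ndarray:
    m = np.loadtxt(Path(path))
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion table must be frames x 6")
    return m


def save_json(path: Path | str, obj: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
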