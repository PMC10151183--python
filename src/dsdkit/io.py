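"""Readers/writers for every external representation the pipeline touches.

Volumes are NIfTI-1/2 via nibabel; streamlines are TRK/TCK via
``nibabel.streamlines`` (always returned in world mm, RAS+); score tables are
CSV/TSV with a ``max_scale`` header row or JSON sidecar; fitted models are a
zip archive of ``.npy`` arrays plus ``manifest.json`` (the embedding
estimator itself is stored as a declared pickle entry inside the archive).
"""

from __future__ import annotations

import io as _io
import json
import pickle
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DimensionalityError,
    StreamlineFormatError,
    VolumeFormatError,
)
from .types import ScoreTable, StreamlineBundle, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "read_lesion",
    "read_streamlines",
    "write_streamlines",
    "read_scores",
    "write_scores",
    "save_model_bundle",
    "load_model_bundle",
    "ModelBundle",
]

BUNDLE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, allow_4d: bool = False) -> Volume3D:
    """Read a NIfTI image as a :class:`Volume3D`.

    4-D images are rejected unless ``allow_4d`` (in which case trailing
    singleton dimensions are squeezed; true 4-D data still fails — use
    :func:`read_signal_volume` for normative time series).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        if not allow_4d or data.ndim != 4:
            raise DimensionalityError(
                f"{path} is {data.ndim}-D; a 3-D volume is required"
            )
    return Volume3D(
        data=np.asarray(data, dtype=float),
        affine=np.asarray(img.affine, dtype=float),
        space_tag=str(img.header.get("descrip", b""), errors="ignore")
        if hasattr(img, "header")
        else "",
        volume_id=path.name.split(".")[0],
    )


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)
    if volume.space_tag:
        img.header["descrip"] = volume.space_tag.encode()[:79]
    nib.save(img, str(path))
    return path


def read_lesion(path: str | Path) -> Volume3D:
    """Read a lesion mask, binarising at > 0.5.

    Upstream registration can leave fractional voxel values; the pipeline
    assumes binary lesions.
    """
    vol = read_volume(path)
    return vol.with_data((vol.data > 0.5).astype(np.uint8))


def read_signal_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 4-D normative signal volume; returns (data_4d, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise DimensionalityError(f"{path} is {data.ndim}-D; 4-D signal required")
    return np.asarray(data, dtype=float), np.asarray(img.affine, dtype=float)


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------

_SUPPORTED_TRACTOGRAMS = (".trk", ".tck")


def read_streamlines(path: str | Path) -> StreamlineBundle:
    """Read a TRK/TCK tractogram; polylines come back in world mm (RAS+)."""
    path = Path(path)
    if not any(str(path).endswith(ext) for ext in _SUPPORTED_TRACTOGRAMS):
        raise StreamlineFormatError(
            f"unsupported tractogram format {path.suffix!r}; "
            f"supported: {', '.join(_SUPPORTED_TRACTOGRAMS)}"
        )
    try:
        tfile = nib.streamlines.load(str(path))
    except Exception as exc:
        raise StreamlineFormatError(f"cannot read tractogram {path}: {exc}") from exc
    streamlines = [np.asarray(s, dtype=float) for s in tfile.streamlines]
    if not streamlines:
        warnings.warn(f"tractogram {path} contains no streamlines", stacklevel=2)
    return StreamlineBundle(
        subject_id=path.name.split(".")[0], streamlines=streamlines
    )


def write_streamlines(
    bundle: StreamlineBundle,
    path: str | Path,
    reference: Volume3D | None = None,
) -> Path:
    """Write a bundle as TRK or TCK.

    TRK needs raster geometry; pass ``reference`` (any volume on the target
    grid) when writing ``.trk``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tractogram = nib.streamlines.Tractogram(
        bundle.streamlines, affine_to_rasmm=np.eye(4)
    )
    if str(path).endswith(".trk"):
        if reference is None:
            raise ConfigurationError("writing TRK requires a reference volume")
        header = {
            nib.streamlines.Field.VOXEL_TO_RASMM: reference.affine.astype(np.float32),
            nib.streamlines.Field.VOXEL_SIZES: reference.voxel_size.astype(
                np.float32
            ),
            nib.streamlines.Field.DIMENSIONS: np.asarray(
                reference.grid, dtype=np.int16
            ),
        }
        nib.streamlines.save(tractogram, str(path), header=header)
    elif str(path).endswith(".tck"):
        nib.streamlines.save(tractogram, str(path))
    else:
        raise StreamlineFormatError(
            f"unsupported tractogram format {path.suffix!r}; "
            f"supported: {', '.join(_SUPPORTED_TRACTOGRAMS)}"
        )
    return path


# ---------------------------------------------------------------------------
# score tables
# ---------------------------------------------------------------------------

_COVARIATE_COLUMNS = ("age", "lesion_volume")
_MAX_SCALE_ROW = "max_scale"


def read_scores(path: str | Path) -> ScoreTable:
    """Read a patient-by-score table.

    Layout: a ``patient_id`` column (or first column), score columns, and the
    per-score maximum scale either as a row whose patient id is
    ``max_scale`` or as a JSON sidecar ``<path>.max_scale.json``.  Columns
    named ``age``/``lesion_volume`` become covariates, not scores.  Empty and
    ``NA`` cells are flagged missing, never imputed.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    id_col = "patient_id" if "patient_id" in df.columns else df.columns[0]
    df = df.set_index(id_col)

    max_scale_map: dict[str, float] = {}
    if _MAX_SCALE_ROW in df.index:
        row = df.loc[_MAX_SCALE_ROW]
        max_scale_map = {
            c: float(row[c]) for c in df.columns if pd.notna(row[c])
        }
        df = df.drop(index=_MAX_SCALE_ROW)
    else:
        sidecar = path.with_name(path.name + ".max_scale.json")
        if sidecar.exists():
            max_scale_map = {
                k: float(v) for k, v in json.loads(sidecar.read_text()).items()
            }

    score_cols = [c for c in df.columns if c not in _COVARIATE_COLUMNS]
    missing_scale = [c for c in score_cols if c not in max_scale_map]
    if missing_scale:
        raise ConfigurationError(
            "max_scale missing for score(s) "
            f"{missing_scale}: provide a 'max_scale' row or a "
            f"'{path.name}.max_scale.json' sidecar (required to normalise MAE%)"
        )

    values = df[score_cols].apply(pd.to_numeric, errors="coerce").to_numpy(float)
    covariates = None
    cov_cols = [c for c in _COVARIATE_COLUMNS if c in df.columns]
    if cov_cols:
        covariates = (
            df[cov_cols].apply(pd.to_numeric, errors="coerce").reset_index(drop=True)
        )
    return ScoreTable(
        patient_ids=[str(i) for i in df.index],
        score_names=score_cols,
        values=values,
        max_scale=np.array([max_scale_map[c] for c in score_cols]),
        covariates=covariates,
    )


def write_scores(table: ScoreTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = table.to_dataframe()
    if table.covariates is not None:
        for c in table.covariates.columns:
            df[c] = table.covariates[c].to_numpy()
    scale_row = {name: table.scale_of(name) for name in table.score_names}
    out = pd.concat(
        [pd.DataFrame(scale_row, index=pd.Index([_MAX_SCALE_ROW], name="patient_id")), df]
    )
    out.to_csv(path, sep=sep)
    return path


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A persisted morphospace and (optionally) fitted per-score models."""

    morphospace: Any = None
    results: Any = None
    metadata: dict | None = None


def _write_state(
    zf: zipfile.ZipFile, prefix: str, state: tuple[dict, dict, dict]
) -> dict:
    meta, arrays, blobs = state
    entry = {"meta": meta, "arrays": {}, "pickles": {}}
    for name, arr in arrays.items():
        arcname = f"{prefix}/{name}.npy"
        buf = _io.BytesIO()
        np.save(buf, np.asarray(arr))
        zf.writestr(arcname, buf.getvalue())
        entry["arrays"][name] = arcname
    for name, obj in blobs.items():
        arcname = f"{prefix}/{name}.pkl"
        zf.writestr(arcname, pickle.dumps(obj, protocol=4))
        entry["pickles"][name] = arcname
    return entry


def _read_state(zf: zipfile.ZipFile, entry: dict) -> tuple[dict, dict, dict]:
    arrays = {
        name: np.load(_io.BytesIO(zf.read(arc)), allow_pickle=False)
        for name, arc in entry["arrays"].items()
    }
    blobs = {
        name: pickle.loads(zf.read(arc)) for name, arc in entry["pickles"].items()
    }
    return entry["meta"], arrays, blobs


def save_model_bundle(
    path: str | Path,
    morphospace: Any = None,
    results: Any = None,
    metadata: dict | None = None,
) -> Path:
    """Persist a fitted morphospace and/or DSD results to a zip archive."""
    import sklearn
    import umap

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "versions": {
            "numpy": np.__version__,
            "scikit-learn": sklearn.__version__,
            "umap-learn": umap.__version__,
        },
        "metadata": metadata or {},
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        if morphospace is not None:
            manifest["morphospace"] = _write_state(
                zf, "morphospace", morphospace.to_state()
            )
        if results is not None:
            manifest["results"] = _write_state(zf, "results", results.to_state())
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_model_bundle(path: str | Path) -> ModelBundle:
    from .composite import DSDResults
    from .morphospace import MorphospaceModel

    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except Exception as exc:
        raise VolumeFormatError(f"cannot open model bundle {path}: {exc}") from exc
    with zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise ConfigurationError(
                f"unsupported bundle format version in {path}"
            )
        bundle = ModelBundle(metadata=manifest.get("metadata", {}))
        if "morphospace" in manifest:
            bundle.morphospace = MorphospaceModel.from_state(
                *_read_state(zf, manifest["morphospace"])
            )
        if "results" in manifest:
            bundle.results = DSDResults.from_state(
                *_read_state(zf, manifest["results"]), morphospace=bundle.morphospace
            )
    return bundle
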