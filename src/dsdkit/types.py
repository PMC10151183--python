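"""Core in-memory containers shared across the pipeline.

All volumetric objects live in :class:`Volume3D` (data + voxel-to-world
affine); streamlines are ordered polylines in world millimetres; clinical
scores travel in :class:`ScoreTable` together with the per-score maximum
scale value needed for MAE% normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DimensionalityError, GridMismatchError

__all__ = [
    "Volume3D",
    "StreamlineBundle",
    "ScoreTable",
    "check_same_grid",
]


@dataclass
class Volume3D:
    """A 3-D scalar image with a voxel-to-world affine.

    Parameters
    ----------
    data:
        3-D array of voxel values.
    affine:
        4x4 voxel-index -> world-mm map (NIfTI convention, 0-based indices).
    space_tag:
        Free-text template label (e.g. ``"MNI152_2mm"`` or ``"mini-template"``).
    """

    data: np.ndarray
    affine: np.ndarray
    space_tag: str = ""
    volume_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"Volume3D requires 3-D data, got {self.data.ndim}-D"
            )
        if self.affine.shape != (4, 4):
            raise ConfigurationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ConfigurationError("affine is not invertible")
        if np.any(self.voxel_size <= 0):
            raise ConfigurationError("voxel sizes must be strictly positive")

    @property
    def grid(self) -> tuple[int, int, int]:
        return tuple(int(s) for s in self.data.shape)  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray, volume_id: str | None = None) -> "Volume3D":
        """New volume on the same grid with different voxel values."""
        return Volume3D(
            data=data,
            affine=self.affine.copy(),
            space_tag=self.space_tag,
            volume_id=self.volume_id if volume_id is None else volume_id,
        )

    def world_to_voxel(self, points_mm: np.ndarray) -> np.ndarray:
        """Map (k,3) world-mm points to floating voxel indices."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


def check_same_grid(a: Volume3D, b: Volume3D, context: str = "") -> None:
    """Raise :class:`GridMismatchError` unless the two volumes share a grid."""
    if a.grid != b.grid or not np.allclose(a.affine, b.affine, atol=1e-6):
        where = f" ({context})" if context else ""
        raise GridMismatchError(
            f"volumes are not on the same grid{where}: "
            f"{a.grid} vs {b.grid}"
        )


@dataclass
class StreamlineBundle:
    """A subject's streamlines: polylines of world-mm points.

    ``labels`` optionally tags each streamline with a tract id (used by the
    synthetic cohort's ground-truth bookkeeping; real tractograms leave it
    ``None``).
    """

    subject_id: str
    streamlines: list[np.ndarray]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ConfigurationError(
                    "each streamline must be a (k>=2, 3) array of mm points"
                )
            if not np.all(np.isfinite(s)):
                raise ConfigurationError("streamline coordinates must be finite")
        if self.labels is not None and len(self.labels) != len(self.streamlines):
            raise ConfigurationError("labels must match number of streamlines")

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, idx: np.ndarray) -> "StreamlineBundle":
        idx = np.asarray(idx)
        return StreamlineBundle(
            subject_id=self.subject_id,
            streamlines=[self.streamlines[i] for i in idx],
            labels=None if self.labels is None else [self.labels[i] for i in idx],
        )


@dataclass
class ScoreTable:
    """Patient-by-score matrix with per-score maximum scale values.

    ``values`` holds NaN where a score is missing; missingness is flagged,
    never imputed.  ``covariates`` optionally carries per-patient ``age`` and
    ``lesion_volume`` columns for the volume+age comparator model.
    """

    patient_ids: list[str]
    score_names: list[str]
    values: np.ndarray
    max_scale: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.max_scale = np.asarray(self.max_scale, dtype=float)
        n, s = len(self.patient_ids), len(self.score_names)
        if self.values.shape != (n, s):
            raise ConfigurationError(
                f"values shape {self.values.shape} != ({n} patients, {s} scores)"
            )
        if self.max_scale.shape != (s,):
            raise ConfigurationError("max_scale must have one entry per score")
        if np.any(~np.isfinite(self.max_scale)) or np.any(self.max_scale <= 0):
            bad = [
                self.score_names[i]
                for i in range(s)
                if not np.isfinite(self.max_scale[i]) or self.max_scale[i] <= 0
            ]
            raise ConfigurationError(f"max_scale must be > 0 for scores: {bad}")
        with np.errstate(invalid="ignore"):
            over = np.nansum(self.values > self.max_scale[None, :])
        if over:
            import warnings

            warnings.warn(
                f"{int(over)} score cells exceed their max_scale", stacklevel=2
            )

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where a cell is missing."""
        return ~np.isfinite(self.values)

    def score(self, name: str) -> np.ndarray:
        return self.values[:, self.score_names.index(name)]

    def scale_of(self, name: str) -> float:
        return float(self.max_scale[self.score_names.index(name)])

    def subset(self, idx: np.ndarray) -> "ScoreTable":
        idx = np.asarray(idx)
        cov = None
        if self.covariates is not None:
            cov = self.covariates.iloc[idx].reset_index(drop=True)
        return ScoreTable(
            patient_ids=[self.patient_ids[i] for i in idx],
            score_names=list(self.score_names),
            values=self.values[idx],
            max_scale=self.max_scale.copy(),
            covariates=cov,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.patient_ids, name="patient_id"),
            columns=self.score_names,
        )
        return df
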