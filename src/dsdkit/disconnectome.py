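"""Structural and functional disconnection maps from a normative population.

A lesion's structural disconnectome is built by (i) filtering each normative
subject's tractogram to the streamlines passing through the lesion, (ii)
binarising the filtered streamlines into a voxel visitation mask, and (iii)
averaging the masks across subjects, giving at each voxel the fraction of
normative subjects disconnected there (values k/n in [0, 1]).

Streamline-lesion intersection uses an any-point test on streamlines
resampled to at most half-voxel spacing; the error of this approximation is
bounded by the resampling density (constant ``INTERSECTION_MODE`` records
the choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._geometry import densify_polyline
from .errors import ConfigurationError, DegenerateDataError, EmptyLesionError
from .types import StreamlineBundle, Volume3D, check_same_grid

__all__ = [
    "DisconnectomeMap",
    "FunctionalDisconnectionMap",
    "streamlines_through_lesion",
    "subject_disconnection_mask",
    "disconnectome_map",
    "disconnectome_map_from_visitations",
    "NormativeSet",
    "functional_disconnection_map",
    "lesion_volume",
]

INTERSECTION_MODE = "densified-any-point"  # vs exact segment-voxel clipping


@dataclass
class DisconnectomeMap:
    """Fraction of normative subjects disconnected at each voxel."""

    volume: Volume3D
    lesion_id: str
    n_normative: int

    def __post_init__(self) -> None:
        d = self.volume.data
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ConfigurationError("disconnectome values must lie in [0, 1]")


@dataclass
class FunctionalDisconnectionMap:
    """Group-average lesion-to-voxel signal correlation, in [-1, 1]."""

    volume: Volume3D
    lesion_id: str


def _streamline_voxels(
    streamline: np.ndarray, reference: Volume3D, spacing: float
) -> np.ndarray:
    """Unique flat indices of voxels containing a densified streamline point."""
    dense = densify_polyline(streamline, spacing)
    # half-up rounding (not banker's) so boundary points resolve consistently
    vox = np.floor(reference.world_to_voxel(dense) + 0.5).astype(int)
    shape = np.asarray(reference.grid)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[ok]
    if len(vox) == 0:
        return np.empty(0, dtype=np.intp)
    return np.unique(np.ravel_multi_index(vox.T, tuple(shape)))


def streamlines_through_lesion(
    bundle: StreamlineBundle, lesion: Volume3D
) -> StreamlineBundle:
    """Keep exactly the streamlines with >= 1 densified point in the lesion."""
    if lesion.data.sum() == 0:
        raise EmptyLesionError("empty lesion mask")
    spacing = float(np.min(lesion.voxel_size)) / 2.0
    flat = lesion.data.reshape(-1) > 0
    keep = [
        i
        for i, s in enumerate(bundle.streamlines)
        if (v := _streamline_voxels(s, lesion, spacing)).size and flat[v].any()
    ]
    return bundle.subset(np.asarray(keep, dtype=int))


def subject_disconnection_mask(
    filtered: StreamlineBundle, grid: Volume3D
) -> Volume3D:
    """Binary visitation volume: 1 wherever any filtered streamline passes."""
    spacing = float(np.min(grid.voxel_size)) / 2.0
    mask = np.zeros(grid.grid, dtype=np.uint8)
    flat = mask.reshape(-1)
    for s in filtered.streamlines:
        flat[_streamline_voxels(s, grid, spacing)] = 1
    return grid.with_data(mask, volume_id=f"visitation_{filtered.subject_id}")


def disconnectome_map(
    lesion: Volume3D, normative: list[StreamlineBundle]
) -> DisconnectomeMap:
    """Average the per-subject binary visitation masks of lesion-filtered
    tractograms into a fraction-disconnected map."""
    if not normative:
        raise ConfigurationError("need >= 1 normative subject")
    acc = np.zeros(lesion.grid, dtype=np.float64)
    for bundle in normative:
        filtered = streamlines_through_lesion(bundle, lesion)
        acc += subject_disconnection_mask(filtered, lesion).data
    return DisconnectomeMap(
        volume=lesion.with_data(acc / len(normative), volume_id=lesion.volume_id),
        lesion_id=lesion.volume_id,
        n_normative=len(normative),
    )


def disconnectome_map_from_visitations(
    lesion: Volume3D, visitations: list[Volume3D]
) -> DisconnectomeMap:
    """Second code path: average precomputed per-subject (lesion-filtered)
    visitation volumes; must equal :func:`disconnectome_map` on the same
    bundles."""
    if not visitations:
        raise ConfigurationError("need >= 1 visitation volume")
    for v in visitations:
        check_same_grid(lesion, v, "lesion vs visitation volume")
    acc = np.zeros(lesion.grid, dtype=np.float64)
    for v in visitations:
        acc += (v.data > 0).astype(np.float64)
    return DisconnectomeMap(
        volume=lesion.with_data(acc / len(visitations), volume_id=lesion.volume_id),
        lesion_id=lesion.volume_id,
        n_normative=len(visitations),
    )


class NormativeSet:
    """Precomputed voxel traversal of a normative streamline set.

    Filtering 176 tractograms per lesion is wasteful when mapping a cohort;
    this caches, per subject, every streamline's visited voxels once, after
    which a disconnectome map per lesion is two array lookups.  Output is
    contractually identical to :func:`disconnectome_map`.
    """

    def __init__(self, bundles: list[StreamlineBundle], reference: Volume3D):
        if not bundles:
            raise ConfigurationError("need >= 1 normative subject")
        self.reference = reference
        self.n_normative = len(bundles)
        spacing = float(np.min(reference.voxel_size)) / 2.0
        self._subjects = []
        for b in bundles:
            voxels, stream_ids = [], []
            for i, s in enumerate(b.streamlines):
                v = _streamline_voxels(s, reference, spacing)
                voxels.append(v)
                stream_ids.append(np.full(len(v), i, dtype=np.intp))
            self._subjects.append(
                (
                    np.concatenate(voxels) if voxels else np.empty(0, np.intp),
                    np.concatenate(stream_ids) if stream_ids else np.empty(0, np.intp),
                )
            )

    def map_for(self, lesion: Volume3D) -> DisconnectomeMap:
        check_same_grid(self.reference, lesion, "lesion vs normative reference")
        if lesion.data.sum() == 0:
            raise EmptyLesionError("empty lesion mask")
        flat = lesion.data.reshape(-1) > 0
        acc = np.zeros(flat.shape, dtype=np.float64)
        for voxels, stream_ids in self._subjects:
            if len(voxels) == 0:
                continue
            hit_streams = np.unique(stream_ids[flat[voxels]])
            if len(hit_streams) == 0:
                continue
            visited = np.unique(voxels[np.isin(stream_ids, hit_streams)])
            acc[visited] += 1.0
        return DisconnectomeMap(
            volume=lesion.with_data(
                acc.reshape(lesion.grid) / self.n_normative,
                volume_id=lesion.volume_id,
            ),
            lesion_id=lesion.volume_id,
            n_normative=self.n_normative,
        )

    def map_cohort(self, lesions: list[Volume3D]) -> list[DisconnectomeMap]:
        return [self.map_for(l) for l in lesions]


def functional_disconnection_map(
    lesion: Volume3D, signals: list[np.ndarray]
) -> FunctionalDisconnectionMap:
    """Average, over normative subjects, the Pearson correlation between the
    mean signal inside the lesion and every in-brain voxel's signal.

    The brain mask is defined per subject as voxels with nonzero signal
    variance.  Subjects with a constant lesion time course are skipped with
    a warning; if all are skipped an error is raised.
    """
    if lesion.data.sum() == 0:
        raise EmptyLesionError("empty lesion mask")
    les = lesion.data > 0
    maps, skipped = [], 0
    for k, sig in enumerate(signals):
        sig = np.asarray(sig, dtype=float)
        if sig.ndim != 4 or sig.shape[:3] != lesion.grid:
            raise ConfigurationError(
                f"signal volume {k} shape {sig.shape} does not match lesion grid"
            )
        ts = sig[les].mean(axis=0)
        ts = ts - ts.mean()
        denom_l = np.sqrt((ts**2).sum())
        if denom_l == 0:
            skipped += 1
            warnings.warn(
                f"subject {k}: constant lesion time course, skipped", stacklevel=2
            )
            continue
        centred = sig - sig.mean(axis=3, keepdims=True)
        denom_v = np.sqrt((centred**2).sum(axis=3))
        brain = denom_v > 0
        r = np.zeros(lesion.grid)
        r[brain] = (centred[brain] @ ts) / (denom_v[brain] * denom_l)
        maps.append(np.clip(r, -1.0, 1.0))
    if not maps:
        raise DegenerateDataError(
            "all normative subjects had constant lesion time courses"
        )
    avg = np.mean(maps, axis=0)
    return FunctionalDisconnectionMap(
        volume=lesion.with_data(avg, volume_id=lesion.volume_id),
        lesion_id=lesion.volume_id,
    )


def lesion_volume(lesion: Volume3D) -> float:
    """Lesion volume in mm^3 (voxel count x voxel volume)."""
    return float((lesion.data > 0).sum()) * lesion.voxel_volume
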