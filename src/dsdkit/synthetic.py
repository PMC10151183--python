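"""Synthetic normative atlases, lesion cohorts and score tables.

The generator plants a known ground truth: each score is a linear function
of per-tract disconnection loads plus Gaussian noise, optionally confounded
by lesion volume.  Tracts are jittered fascicles around hand-designed
centerlines on a miniature 2 mm template grid (40x48x40 voxels), with a
mirrored left/right layout so hemispheric segregation in the embedding is
testable.  Everything is bit-reproducible from a seed.

The per-tract disconnection loads used for the ground truth are computed by
a brute-force streamline-lesion intersection implemented here, independent
of the disconnectome module, so the two can be cross-checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import densify_polyline
from ._seeds import stage_rng
from .errors import ConfigurationError
from .types import ScoreTable, StreamlineBundle, Volume3D

__all__ = [
    "TractSpec",
    "CohortTruth",
    "mini_template",
    "default_tract_specs",
    "make_tract_atlas",
    "make_lesion_cohort",
    "make_scores",
    "streamline_lesion_loads",
    "simulate_cohort",
    "SyntheticCohort",
]

DEFAULT_GRID = (40, 48, 40)
DEFAULT_VOXEL_MM = 2.0


@dataclass
class TractSpec:
    """A synthetic tract: a centerline polyline with a fascicle radius."""

    tract_id: str
    centerline: np.ndarray  # (k, 3) world mm
    radius: float  # mm; streamline displacement is bounded by this
    hemisphere: str = "commissural"  # "left" | "right" | "commissural"

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise ConfigurationError("centerline needs >= 2 points")
        if self.radius <= 0:
            raise ConfigurationError("tract radius must be > 0")


@dataclass
class CohortTruth:
    """Ground truth behind a generated score table."""

    loads: np.ndarray  # (n_patients, n_tracts) in [0, 1]
    tract_ids: list[str]
    weights: np.ndarray  # (n_scores, n_tracts)
    intercepts: np.ndarray  # (n_scores,)
    noise_sd: np.ndarray  # (n_scores,)
    volume_confound: float
    lesion_volumes: np.ndarray  # mm^3 per patient
    seed: int


def mini_template(
    shape: tuple[int, int, int] = DEFAULT_GRID,
    voxel_mm: float = DEFAULT_VOXEL_MM,
) -> Volume3D:
    """An empty miniature template volume centred on the world origin."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = voxel_mm
    affine[:3, 3] = -(np.asarray(shape, dtype=float) - 1) / 2.0 * voxel_mm
    return Volume3D(
        data=np.zeros(shape, dtype=np.uint8),
        affine=affine,
        space_tag="mini-template",
    )


def default_tract_specs(radius: float = 6.0) -> list[TractSpec]:
    """Three tracts on the default template: mirrored left/right projection
    tracts and one commissural arc."""

    def line(p0, p1, n=30):
        return np.linspace(np.asarray(p0, float), np.asarray(p1, float), n)

    theta = np.linspace(np.pi, 0.0, 40)
    arc = np.stack(
        [24.0 * np.cos(theta), np.full_like(theta, 12.0), 14.0 * np.sin(theta)],
        axis=1,
    )
    return [
        TractSpec("proj_left", line((-20, -10, -28), (-20, -10, 28)), radius, "left"),
        TractSpec("proj_right", line((20, -10, -28), (20, -10, 28)), radius, "right"),
        TractSpec("commissure", arc, radius, "commissural"),
    ]


def _check_inside_grid(points: np.ndarray, template: Volume3D, what: str) -> None:
    vox = template.world_to_voxel(points)
    hi = np.asarray(template.grid, dtype=float)
    if np.any(vox < -0.5) or np.any(vox >= hi - 0.5):
        raise ConfigurationError(f"{what} exits the template grid")


def make_tract_atlas(
    n_subjects: int,
    tract_specs: list[TractSpec],
    jitter_mm: float = 1.0,
    seed: int = 0,
    n_streamlines: int = 15,
    template: Volume3D | None = None,
) -> list[StreamlineBundle]:
    """Generate per-subject streamline bundles around the tract centerlines.

    Each streamline is a densified copy of its tract centerline displaced by
    a Gaussian offset (sd ``jitter_mm`` per axis) whose norm is truncated at
    the tract radius, so every streamline stays within the fascicle.  Points
    that leave the grid after jitter are clipped to the grid with a warning.
    Inter-point spacing is <= half the voxel size.
    """
    if jitter_mm < 0:
        raise ConfigurationError("jitter_mm must be >= 0")
    template = template if template is not None else mini_template()
    for spec in tract_specs:
        _check_inside_grid(spec.centerline, template, f"tract {spec.tract_id}")
    spacing = float(np.min(template.voxel_size)) / 2.0
    rng = stage_rng(seed, "tract-atlas")
    lo_w = template.affine[:3, 3] - 0.49 * template.voxel_size
    hi_w = (
        template.affine[:3, 3]
        + (np.asarray(template.grid) - 0.51) * template.voxel_size
    )

    bundles: list[StreamlineBundle] = []
    clipped = 0
    for s in range(n_subjects):
        streamlines: list[np.ndarray] = []
        labels: list[str] = []
        for spec in tract_specs:
            dense = densify_polyline(spec.centerline, spacing)
            for _ in range(n_streamlines):
                offset = rng.normal(0.0, jitter_mm, size=3) if jitter_mm > 0 else np.zeros(3)
                norm = np.linalg.norm(offset)
                while norm > spec.radius:  # truncate to fascicle radius
                    offset = rng.normal(0.0, jitter_mm, size=3)
                    norm = np.linalg.norm(offset)
                pts = dense + offset
                if np.any(pts < lo_w) or np.any(pts > hi_w):
                    clipped += 1
                    pts = np.clip(pts, lo_w, hi_w)
                streamlines.append(pts)
                labels.append(spec.tract_id)
        bundles.append(
            StreamlineBundle(
                subject_id=f"normative_{s:03d}", streamlines=streamlines, labels=labels
            )
        )
    if clipped:
        warnings.warn(
            f"{clipped} jittered streamlines clipped to the grid", stacklevel=2
        )
    return bundles


def make_lesion_cohort(
    n: int,
    size_range_mm: tuple[float, float] = (6.0, 9.0),
    placement: str = "uniform-over-tracts",
    seed: int = 0,
    tract_specs: list[TractSpec] | None = None,
    template: Volume3D | None = None,
) -> list[Volume3D]:
    """Generate ``n`` binary ellipsoidal lesion masks.

    ``placement="uniform-over-tracts"`` centres each lesion on a uniformly
    chosen centerline point of a uniformly chosen tract, planting the
    disconnection structure; ``"uniform-over-grid"`` scatters lesions over
    the template interior.  ``size_range_mm`` bounds the ellipsoid semi-axes.
    """
    template = template if template is not None else mini_template()
    lo, hi = float(size_range_mm[0]), float(size_range_mm[1])
    extent = np.asarray(template.grid) * template.voxel_size
    if not (0 < lo <= hi) or hi > float(extent.min()) / 2.0:
        raise ConfigurationError(
            f"infeasible lesion size range {size_range_mm} for grid extent {extent}"
        )
    if placement not in ("uniform-over-tracts", "uniform-over-grid"):
        raise ConfigurationError(f"unknown placement {placement!r}")
    if placement == "uniform-over-tracts" and not tract_specs:
        raise ConfigurationError("uniform-over-tracts placement needs tract_specs")

    rng = stage_rng(seed, "lesion-cohort")
    # world coordinates of voxel centres
    ii, jj, kk = np.meshgrid(
        *[np.arange(s) for s in template.grid], indexing="ij"
    )
    vox = np.stack([ii, jj, kk], axis=-1).astype(float)
    world = vox @ template.affine[:3, :3].T + template.affine[:3, 3]

    lo_w = template.affine[:3, 3]
    hi_w = lo_w + (np.asarray(template.grid) - 1) * template.voxel_size
    lesions: list[Volume3D] = []
    for i in range(n):
        semi = rng.uniform(lo, hi, size=3)
        if placement == "uniform-over-tracts":
            spec = tract_specs[rng.integers(len(tract_specs))]
            center = spec.centerline[rng.integers(len(spec.centerline))]
        else:
            center = rng.uniform(lo_w + hi, hi_w - hi)
        mask = (((world - center) / semi) ** 2).sum(axis=-1) <= 1.0
        lesions.append(
            template.with_data(mask.astype(np.uint8), volume_id=f"lesion_{i:04d}")
        )
    return lesions


# ---------------------------------------------------------------------------
# ground-truth loads: brute-force streamline-lesion intersection oracle
# ---------------------------------------------------------------------------

def _flat_voxel_indices(
    points: np.ndarray, volume: Volume3D, spacing: float
) -> np.ndarray:
    """Unique flat voxel indices visited by a polyline (densified)."""
    dense = densify_polyline(points, spacing)
    inv = np.linalg.inv(volume.affine)
    vox = np.floor(dense @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
    shape = np.asarray(volume.grid)
    ok = np.all((vox >= 0) & (vox < shape), axis=1)
    vox = vox[ok]
    if len(vox) == 0:
        return np.empty(0, dtype=np.intp)
    return np.unique(np.ravel_multi_index(vox.T, tuple(shape)))


def streamline_lesion_loads(
    lesions: list[Volume3D],
    atlas: list[StreamlineBundle],
) -> tuple[np.ndarray, list[str]]:
    """Per-patient, per-tract fraction of atlas streamlines cut by the lesion.

    Brute-force oracle: a streamline is cut when any of its densified points
    falls inside a lesion voxel.  Requires labelled (synthetic) bundles.
    """
    if any(b.labels is None for b in atlas):
        raise ConfigurationError("ground-truth loads need labelled tract bundles")
    ref = lesions[0] if lesions else None
    tract_ids: list[str] = []
    for b in atlas:
        for lab in b.labels:  # type: ignore[union-attr]
            if lab not in tract_ids:
                tract_ids.append(lab)
    if ref is None:
        return np.zeros((0, len(tract_ids))), tract_ids

    spacing = float(np.min(ref.voxel_size)) / 2.0
    per_tract_voxels: dict[str, list[np.ndarray]] = {t: [] for t in tract_ids}
    for b in atlas:
        for sl, lab in zip(b.streamlines, b.labels):  # type: ignore[arg-type]
            per_tract_voxels[lab].append(_flat_voxel_indices(sl, ref, spacing))

    loads = np.zeros((len(lesions), len(tract_ids)))
    for p, lesion in enumerate(lesions):
        flat = lesion.data.reshape(-1) > 0
        for t, tid in enumerate(tract_ids):
            stream_voxels = per_tract_voxels[tid]
            hits = sum(1 for v in stream_voxels if len(v) and flat[v].any())
            loads[p, t] = hits / len(stream_voxels)
    return loads, tract_ids


def make_scores(
    lesions: list[Volume3D],
    atlas: list[StreamlineBundle],
    weights: np.ndarray,
    noise_sd: float | np.ndarray = 0.0,
    max_scale: float | np.ndarray = 100.0,
    volume_confound: float = 0.0,
    seed: int = 0,
    intercepts: np.ndarray | None = None,
    score_names: list[str] | None = None,
) -> tuple[ScoreTable, CohortTruth]:
    """Generate scores linear in tract disconnection loads.

    ``score = clip(intercept + loads @ weights.T + volume_confound * vol_z
    + N(0, noise_sd), 0, max_scale)``, with loads from the brute-force
    intersection oracle.  Ages (54 +/- 11 y, clipped to 19-83) and lesion
    volumes are attached as covariates for the volume+age comparator.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if not np.all(np.isfinite(weights)):
        raise ConfigurationError("weights must be finite")
    n_scores, n_tracts = weights.shape
    max_scale = np.broadcast_to(
        np.asarray(max_scale, dtype=float), (n_scores,)
    ).copy()
    if np.any(max_scale <= 0):
        raise ConfigurationError("max_scale must be > 0")
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_scores,)).copy()
    if np.any(noise_sd < 0):
        raise ConfigurationError("noise_sd must be >= 0")
    intercepts = (
        max_scale / 2.0
        if intercepts is None
        else np.broadcast_to(np.asarray(intercepts, dtype=float), (n_scores,)).copy()
    )
    score_names = score_names or [f"score_{i}" for i in range(n_scores)]

    loads, tract_ids = streamline_lesion_loads(lesions, atlas)
    if loads.shape[1] != n_tracts:
        raise ConfigurationError(
            f"weights expect {n_tracts} tracts, atlas has {loads.shape[1]}"
        )
    volumes = np.array([float(l.data.sum()) * l.voxel_volume for l in lesions])
    vol_sd = volumes.std()
    vol_z = (volumes - volumes.mean()) / vol_sd if vol_sd > 0 else np.zeros_like(volumes)

    rng = stage_rng(seed, "scores")
    noise = rng.standard_normal((len(lesions), n_scores)) * noise_sd[None, :]
    raw = (
        intercepts[None, :]
        + loads @ weights.T
        + volume_confound * vol_z[:, None]
        + noise
    )
    values = np.clip(raw, 0.0, max_scale[None, :])

    ages = np.clip(rng.normal(54.0, 11.0, size=len(lesions)), 19.0, 83.0)
    covariates = pd.DataFrame({"age": ages, "lesion_volume": volumes})
    table = ScoreTable(
        patient_ids=[l.volume_id or f"lesion_{i:04d}" for i, l in enumerate(lesions)],
        score_names=list(score_names),
        values=values,
        max_scale=max_scale,
        covariates=covariates,
    )
    truth = CohortTruth(
        loads=loads,
        tract_ids=tract_ids,
        weights=weights,
        intercepts=intercepts,
        noise_sd=noise_sd,
        volume_confound=volume_confound,
        lesion_volumes=volumes,
        seed=seed,
    )
    return table, truth


@dataclass
class SyntheticCohort:
    """Everything one simulated study needs, with its ground truth."""

    template: Volume3D
    tract_specs: list[TractSpec]
    atlas: list[StreamlineBundle]
    lesions: list[Volume3D]
    scores: ScoreTable
    truth: CohortTruth
    seed: int


def simulate_cohort(
    n_patients: int,
    n_normative: int = 6,
    weights: np.ndarray | None = None,
    noise_sd: float | np.ndarray = 0.0,
    max_scale: float | np.ndarray = 100.0,
    volume_confound: float = 0.0,
    lesion_size_range: tuple[float, float] = (6.5, 8.0),
    jitter_mm: float = 1.0,
    seed: int = 0,
    score_names: list[str] | None = None,
) -> SyntheticCohort:
    """One-call simulated study on the default template and tract layout.

    Default weights plant two informative scores with distinct per-tract
    weight patterns plus one pure-noise score.
    """
    template = mini_template()
    specs = default_tract_specs()
    if weights is None:
        weights = np.array(
            [
                [40.0, -10.0, 15.0],
                [-5.0, 35.0, -20.0],
                [0.0, 0.0, 0.0],
            ]
        )
        score_names = score_names or ["planted_a", "planted_b", "noise_only"]
    atlas = make_tract_atlas(
        n_normative, specs, jitter_mm=jitter_mm, seed=seed, template=template
    )
    lesions = make_lesion_cohort(
        n_patients,
        size_range_mm=lesion_size_range,
        placement="uniform-over-tracts",
        seed=seed,
        tract_specs=specs,
        template=template,
    )
    scores, truth = make_scores(
        lesions,
        atlas,
        weights=weights,
        noise_sd=noise_sd,
        max_scale=max_scale,
        volume_confound=volume_confound,
        seed=seed,
        score_names=score_names,
    )
    return SyntheticCohort(
        template=template,
        tract_specs=specs,
        atlas=atlas,
        lesions=lesions,
        scores=scores,
        truth=truth,
        seed=seed,
    )
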