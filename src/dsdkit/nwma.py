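"""Neuropsychological white-matter atlas: project fitted composite models
back to voxel space.

For every modeled score, each of the three spatial-PCA patient scores is
regressed voxel-wise on disconnectome values across a reference cohort; the
slope t-statistic is converted to Cohen's f-squared (f2 = t^2/df, i.e.
R2/(1-R2)) and the voxel-wise maximum over the three components gives the
score's effect-size map.  Across scores, the largest f2 wins the summary
label map (only where it reaches the medium threshold 0.15) and the
versatility map counts the scores exceeding the large threshold 0.35 per
voxel.  Reproducibility is the Pearson correlation between effect-size maps
derived from two disjoint cohort halves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seeds import stage_rng
from .composite import DSDResults
from .errors import ConfigurationError, DegenerateDataError
from .evaluation import T_CAP, _as_feature_matrix
from .morphospace import MorphospaceModel
from .types import Volume3D

__all__ = [
    "EffectSizeVolume",
    "SummaryAtlas",
    "MEDIUM_F2",
    "LARGE_F2",
    "project_pca_scores",
    "voxelwise_glm",
    "t_to_f2",
    "max_over_components",
    "summary_label_map",
    "versatility_map",
    "derive_atlas",
    "effect_map_correlation",
    "split_half_reproducibility",
]

MEDIUM_F2 = 0.15
LARGE_F2 = 0.35


@dataclass
class EffectSizeVolume:
    """Per-score voxel-wise f-squared map (max over the 3 PCA components)."""

    volume: Volume3D
    score_name: str
    component_provenance: np.ndarray  # which component won each voxel (0-2)

    def __post_init__(self) -> None:
        if self.volume.data.min() < 0:
            raise ConfigurationError("f-squared must be >= 0 everywhere")


@dataclass
class SummaryAtlas:
    """Find-the-biggest label volume plus versatility counts."""

    labels: Volume3D  # integer score index per voxel, 0 = none
    versatility: Volume3D  # count of scores with f2 >= large threshold
    score_names: list[str]  # label i corresponds to score_names[i-1]
    medium_threshold: float = MEDIUM_F2
    large_threshold: float = LARGE_F2


def project_pca_scores(
    results: DSDResults,
    maps: list,
    morphospace: MorphospaceModel | None = None,
) -> dict[str, np.ndarray]:
    """Embed -> rasterize -> spatial-PCA scores for each modeled score.

    Returns ``{score_name: (n_subjects, 3) array}``.
    """
    morphospace = morphospace or results.morphospace
    if morphospace is None:
        raise ConfigurationError("no morphospace available for projection")
    if len(maps) == 0:
        return {name: np.zeros((0, 3)) for name in results.modeled_scores}
    coords = morphospace.embed(maps)
    locmaps = results.raster_grid.rasterize_cohort(coords)
    return {
        name: results.pca_scores_for(locmaps, name)
        for name in results.modeled_scores
    }


def voxelwise_glm(
    maps,
    y: np.ndarray,
    n_perm: int = 0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Per-voxel simple OLS of ``y`` on the voxel's disconnection value.

    Returns the slope t-statistic per voxel (|t| capped at 1e6; zero-variance
    voxels get t = 0) and, when ``n_perm`` > 0, label-permutation two-sided
    p-values (randomise-style, uncorrected)."""
    X = _as_feature_matrix(maps)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ConfigurationError("maps / dependent variable length mismatch")
    if X.shape[0] < 10:
        raise ConfigurationError("voxel-wise GLM needs >= 10 subjects")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    # constant voxels: sd indistinguishable from cancellation noise -> t = 0
    live = sx > 1e-12 * np.abs(X).max(axis=0)

    def tmap(yv: np.ndarray) -> np.ndarray:
        yc = yv - yv.mean()
        sy = np.sqrt((yc**2).sum())
        r = np.zeros(X.shape[1])
        if sy > 0:
            r[live] = np.clip((Xc[:, live].T @ yc) / (sx[live] * sy), -1.0, 1.0)
        df = len(yv) - 2
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        return np.clip(t, -T_CAP, T_CAP)

    t_obs = tmap(y)
    if n_perm <= 0:
        return t_obs, None
    rng = stage_rng(seed, "nwma-glm-permutations")
    exceed = np.ones(X.shape[1])  # the unpermuted labelling counts once
    for _ in range(n_perm):
        exceed += np.abs(tmap(rng.permutation(y))) >= np.abs(t_obs)
    return t_obs, exceed / (n_perm + 1)


def t_to_f2(t: np.ndarray | float, df: int) -> np.ndarray | float:
    """Cohen's f-squared from a t-statistic: t^2/df == R2/(1-R2) with
    R2 = t^2/(t^2+df)."""
    if df < 1:
        raise ConfigurationError("df must be >= 1")
    return np.asarray(t, dtype=float) ** 2 / df if np.ndim(t) else float(t) ** 2 / df


def max_over_components(
    f2_maps: list[np.ndarray], reference: Volume3D, score_name: str = ""
) -> EffectSizeVolume:
    """Voxel-wise maximum f2 across the three components, with provenance."""
    if len(f2_maps) != 3:
        raise ConfigurationError("expected 3 component f2 maps")
    stack = np.stack([np.asarray(m, dtype=float) for m in f2_maps])
    if any(m.shape != stack[0].shape for m in stack):
        raise ConfigurationError("component maps are incongruent")
    prov = stack.argmax(axis=0)
    return EffectSizeVolume(
        volume=reference.with_data(stack.max(axis=0), volume_id=f"f2_{score_name}"),
        score_name=score_name,
        component_provenance=prov,
    )


def summary_label_map(
    effect_maps: list[EffectSizeVolume],
    medium_threshold: float = MEDIUM_F2,
    large_threshold: float = LARGE_F2,
) -> SummaryAtlas:
    """Find-the-biggest: per voxel, the 1-based index of the score with the
    largest f2, labelled only where that f2 reaches the medium threshold.
    Ties break to the lowest score index."""
    if not effect_maps:
        raise ConfigurationError("need >= 1 effect-size map")
    stack = np.stack([e.volume.data for e in effect_maps])
    winner = stack.argmax(axis=0)  # argmax takes the lowest index on ties
    best = stack.max(axis=0)
    labels = np.where(best >= medium_threshold, winner + 1, 0).astype(np.int32)
    versa = (stack >= large_threshold).sum(axis=0).astype(np.int32)
    ref = effect_maps[0].volume
    return SummaryAtlas(
        labels=ref.with_data(labels, volume_id="nwma_labels"),
        versatility=ref.with_data(versa, volume_id="nwma_versatility"),
        score_names=[e.score_name for e in effect_maps],
        medium_threshold=medium_threshold,
        large_threshold=large_threshold,
    )


def versatility_map(
    effect_maps: list[EffectSizeVolume], large_threshold: float = LARGE_F2
) -> Volume3D:
    """Per voxel, the count of scores with f2 >= the large-effect threshold."""
    if not effect_maps:
        raise ConfigurationError("need >= 1 effect-size map")
    stack = np.stack([e.volume.data for e in effect_maps])
    return effect_maps[0].volume.with_data(
        (stack >= large_threshold).sum(axis=0).astype(np.int32),
        volume_id="nwma_versatility",
    )


def derive_atlas(
    results: DSDResults,
    maps: list,
    morphospace: MorphospaceModel | None = None,
    pca_scores: dict[str, np.ndarray] | None = None,
) -> tuple[list[EffectSizeVolume], SummaryAtlas]:
    """Full NWMA derivation on a reference cohort of disconnectome maps."""
    if pca_scores is None:
        pca_scores = project_pca_scores(results, maps, morphospace)
    ref = maps[0].volume if hasattr(maps[0], "volume") else maps[0]
    df = len(maps) - 2
    effect_maps = []
    for name, S in pca_scores.items():
        comps = []
        for c in range(3):
            t, _ = voxelwise_glm(maps, S[:, c])
            comps.append(t_to_f2(t, df).reshape(ref.grid))
        effect_maps.append(max_over_components(comps, ref, score_name=name))
    return effect_maps, summary_label_map(effect_maps)


def effect_map_correlation(vals_a: np.ndarray, vals_b: np.ndarray) -> float:
    """Pearson correlation between two stacked effect-size vectors."""
    a = np.asarray(vals_a, dtype=float).reshape(-1)
    b = np.asarray(vals_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ConfigurationError("effect-size vectors differ in length")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn(
            "constant effect-size vector; reproducibility undefined", stacklevel=2
        )
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def split_half_reproducibility(
    maps_a: list,
    maps_b: list,
    results: DSDResults,
    morphospace: MorphospaceModel | None = None,
    ids_a: list[str] | None = None,
    ids_b: list[str] | None = None,
    allow_overlap: bool = False,
) -> float:
    """Derive the atlas on two disjoint subject halves and correlate the
    stacked per-score effect-size vectors over in-mask voxels.

    The mask is the set of voxels with nonzero disconnection variance in
    both halves.  Overlapping halves are refused unless ``allow_overlap``
    (used only for the R = 1 sanity case).
    """
    if ids_a is not None and ids_b is not None and not allow_overlap:
        if set(ids_a) & set(ids_b):
            raise ConfigurationError("split halves share subjects")
    Xa = _as_feature_matrix(maps_a)
    Xb = _as_feature_matrix(maps_b)
    mask = (Xa.std(axis=0) > 0) & (Xb.std(axis=0) > 0)
    if not mask.any():
        raise DegenerateDataError("no voxel varies in both halves")
    eff_a, _ = derive_atlas(results, maps_a, morphospace)
    eff_b, _ = derive_atlas(results, maps_b, morphospace)
    va = np.concatenate([e.volume.data.reshape(-1)[mask] for e in eff_a])
    vb = np.concatenate([e.volume.data.reshape(-1)[mask] for e in eff_b])
    return effect_map_correlation(va, vb)
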