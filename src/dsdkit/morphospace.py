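"""The 2-D disconnectome morphospace.

Disconnectome maps are vectorised (voxels that are zero in every training
map are dropped as inert constant features, and the per-voxel training
minimum is subtracted so a constant background cannot perturb the distance
computation), embedded with UMAP
(n_neighbors=15, min_dist=0.1, Euclidean, 2 components by default), and the
coordinate scales are shifted so the training cloud has only positive
coordinates with zero as origin.  The fitted transform is stored so unseen
patients can be projected into the same space.

Out-of-sample projection uses the library's native transform.  One
guarantee the library does not give — a query identical to a training map
must return that map's stored coordinate — is provided by an exact
duplicate-row shortcut before the transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .disconnectome import DisconnectomeMap
from .errors import ConfigurationError, GridMismatchError
from .types import Volume3D

__all__ = [
    "MorphospaceConfig",
    "MorphospaceModel",
    "fit_morphospace",
    "embed",
    "fit_lesion_morphospace",
]


@dataclass
class MorphospaceConfig:
    n_neighbors: int = 15
    min_dist: float = 0.1
    metric: str = "euclidean"
    n_components: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_components != 2:
            raise ConfigurationError(
                "the standard pipeline uses a 2-D morphospace (n_components=2)"
            )
        if self.n_neighbors < 2 or self.min_dist < 0:
            raise ConfigurationError("invalid UMAP parameters")


def _as_volume(m: DisconnectomeMap | Volume3D) -> Volume3D:
    return m.volume if isinstance(m, DisconnectomeMap) else m


def _stack_features(
    maps: list, grid: tuple | None = None, affine: np.ndarray | None = None
) -> tuple[np.ndarray, tuple, np.ndarray]:
    vols = [_as_volume(m) for m in maps]
    if grid is None:
        grid, affine = vols[0].grid, vols[0].affine
    X = np.empty((len(vols), int(np.prod(grid))), dtype=np.float32)
    for i, v in enumerate(vols):
        if v.grid != tuple(grid) or not np.allclose(v.affine, affine, atol=1e-6):
            raise GridMismatchError(
                f"map {i} grid {v.grid} does not match the training grid {tuple(grid)}"
            )
        X[i] = v.data.reshape(-1)
    return X, tuple(grid), np.asarray(affine)


@dataclass
class MorphospaceModel:
    """A fitted 2-D embedding with its positivity offset and raster inputs."""

    umap_model: object
    training_coords: np.ndarray  # (n, 2), shifted: columnwise min == 0
    offset: np.ndarray  # (2,)
    feature_mask: np.ndarray  # flat bool over the grid
    feature_min: np.ndarray  # per-feature training minimum, subtracted
    grid: tuple
    affine: np.ndarray
    training_features: np.ndarray  # (n, n_masked) float32
    config: MorphospaceConfig
    feature_kind: str = "disconnectome"  # or "lesion"
    _row_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._row_index = {
            r.tobytes(): i for i, r in enumerate(self.training_features)
        }

    def features_of(self, maps: list) -> np.ndarray:
        X, _, _ = _stack_features(maps, self.grid, self.affine)
        return X[:, self.feature_mask] - self.feature_min[None, :]

    def embed(self, maps: list) -> np.ndarray:
        """Project maps into the morphospace; returns (n, 2) coordinates.

        Rows exactly equal to a training map return the stored training
        coordinate; all others go through the fitted UMAP transform (plus
        the positivity offset).
        """
        if len(maps) == 0:
            return np.zeros((0, 2))
        F = self.features_of(maps)
        coords = np.zeros((len(F), 2))
        new_rows = []
        for i, row in enumerate(F):
            j = self._row_index.get(row.tobytes())
            if j is not None and np.array_equal(self.training_features[j], row):
                coords[i] = self.training_coords[j]
            else:
                new_rows.append(i)
        if new_rows:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                raw = self.umap_model.transform(F[new_rows])
            coords[new_rows] = raw + self.offset[None, :]
        return coords

    # -- serialisation ------------------------------------------------------
    def to_state(self) -> tuple[dict, dict, dict]:
        meta = {
            "config": asdict(self.config),
            "grid": list(self.grid),
            "feature_kind": self.feature_kind,
        }
        arrays = {
            "training_coords": self.training_coords,
            "offset": self.offset,
            "feature_mask": self.feature_mask,
            "feature_min": self.feature_min,
            "affine": self.affine,
            "training_features": self.training_features,
        }
        return meta, arrays, {"umap_model": self.umap_model}

    @classmethod
    def from_state(cls, meta: dict, arrays: dict, blobs: dict) -> "MorphospaceModel":
        return cls(
            umap_model=blobs["umap_model"],
            training_coords=arrays["training_coords"],
            offset=arrays["offset"],
            feature_mask=arrays["feature_mask"].astype(bool),
            feature_min=arrays["feature_min"],
            grid=tuple(meta["grid"]),
            affine=arrays["affine"],
            training_features=arrays["training_features"],
            config=MorphospaceConfig(**meta["config"]),
            feature_kind=meta["feature_kind"],
        )


def fit_morphospace(
    maps: list,
    config: MorphospaceConfig | None = None,
    feature_kind: str = "disconnectome",
) -> MorphospaceModel:
    """Fit the 2-D morphospace on a reference cohort of maps.

    Deterministic given ``config.seed``.  Requires more maps than
    ``n_neighbors``.
    """
    import umap

    config = config or MorphospaceConfig()
    if len(maps) < config.n_neighbors + 1:
        raise ConfigurationError(
            f"{len(maps)} maps < n_neighbors+1 ({config.n_neighbors + 1}); "
            "reduce n_neighbors"
        )
    X, grid, affine = _stack_features(maps)
    # non-constant voxels only: constant features are inert in the Euclidean
    # metric and only perturb the distance computation numerically
    feature_mask = X.max(axis=0) != X.min(axis=0)
    if not feature_mask.any():
        raise ConfigurationError("all training maps are identical")
    F = X[:, feature_mask]
    feature_min = F.min(axis=0)
    F = F - feature_min[None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
            metric=config.metric,
            n_components=config.n_components,
            random_state=config.seed,
        )
        raw = reducer.fit_transform(F)
    offset = -raw.min(axis=0)
    return MorphospaceModel(
        umap_model=reducer,
        training_coords=raw + offset[None, :],
        offset=offset,
        feature_mask=feature_mask,
        feature_min=feature_min,
        grid=grid,
        affine=affine,
        training_features=F,
        config=config,
        feature_kind=feature_kind,
    )


def embed(model: MorphospaceModel, maps: list) -> np.ndarray:
    """Module-level alias for :meth:`MorphospaceModel.embed`."""
    return model.embed(maps)


def fit_lesion_morphospace(
    lesions: list[Volume3D], config: MorphospaceConfig | None = None
) -> MorphospaceModel:
    """Morphospace of raw binary lesion masks (the L-SD comparator)."""
    return fit_morphospace(lesions, config, feature_kind="lesion")
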