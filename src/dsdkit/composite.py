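"""The composite morphospace model: embedded coordinates -> probability-of-
localization maps -> score-associated territories -> spatial PCA -> per-score
linear regression.

Each patient's morphospace coordinate is rasterised onto a high-resolution
2-D grid (260 x 260 pixels of 0.05 mm by default) as a unit impulse smoothed
with a Gaussian kernel (sigma 1 mm = 20 pixels) and renormalised to sum 1 —
a probability of localization.  Pixel-wise Pearson correlation of these
probabilities with a clinical score defines territories (|R| > 0.2,
8-connected components containing patient peaks, at most three).  The
patients x territory-pixels matrix is compressed by a 3-component PCA and an
ordinary least squares model predicts the score from the three PCA scores:

    score_hat = c + sum_i w_i * s_i        (i = 1..3)

The model/results pair at the bottom packages the per-score loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    GridMismatchError,
    NoTerritoryError,
)
from .morphospace import MorphospaceModel
from .types import ScoreTable

__all__ = [
    "RasterConfig",
    "RasterGrid",
    "LocalizationMap",
    "CorrelationMap2D",
    "TerritoryMask",
    "SpatialPCA",
    "ScoreModel",
    "rasterize_coordinate",
    "correlation_map",
    "extract_territories",
    "spatial_pca",
    "pca_scores",
    "fit_score_model",
    "predict_score",
    "DisconnectomeSymptomDiscoverer",
    "DSDResults",
    "fit_composite",
]


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

@dataclass
class RasterConfig:
    """Geometry of the morphospace raster.

    Defaults give a 260 x 260 grid of 0.05 mm pixels smoothed with a 1 mm
    (20 pixel) Gaussian.  ``mapping_mode="direct"`` treats morphospace units
    as mm over the [0, grid_size*pixel_size) window; ``"autoscale"`` min-max
    scales the training coordinates into the window with a 3*sigma margin.
    """

    grid_size: int = 260
    pixel_size: float = 0.05
    smoothing_sigma: float = 1.0  # mm
    mapping_mode: str = "direct"

    def __post_init__(self) -> None:
        if self.grid_size <= 0 or self.pixel_size <= 0 or self.smoothing_sigma < 0:
            raise ConfigurationError("invalid raster geometry")
        if self.mapping_mode not in ("direct", "autoscale"):
            raise ConfigurationError(
                f"mapping_mode must be 'direct' or 'autoscale', got {self.mapping_mode!r}"
            )
        if self.grid_size < 8 * self.sigma_pixels:
            raise ConfigurationError(
                "grid_size must be >= 8 * smoothing sigma in pixels"
            )

    @property
    def sigma_pixels(self) -> float:
        return self.smoothing_sigma / self.pixel_size

    @property
    def extent_mm(self) -> float:
        return self.grid_size * self.pixel_size

    def fit(self, training_coords: np.ndarray | None = None) -> "RasterGrid":
        """Freeze the coordinate->mm mapping (identity for direct mode)."""
        if self.mapping_mode == "direct":
            return RasterGrid(self, np.ones(2), np.zeros(2))
        if training_coords is None or len(training_coords) == 0:
            raise ConfigurationError("autoscale mapping needs training coordinates")
        c = np.asarray(training_coords, dtype=float)
        margin = 3.0 * self.smoothing_sigma
        span = c.max(axis=0) - c.min(axis=0)
        usable = self.extent_mm - 2.0 * margin
        if usable <= 0:
            raise ConfigurationError("raster window too small for 3*sigma margins")
        scale = np.where(span > 0, usable / np.where(span > 0, span, 1.0), 1.0)
        shift = margin - c.min(axis=0) * scale
        # degenerate axis: centre it
        centre = margin + usable / 2.0
        shift = np.where(span > 0, shift, centre - c.mean(axis=0) * scale)
        return RasterGrid(self, scale, shift)


@dataclass
class LocalizationMap:
    """A patient's smoothed probability-of-localization grid (sums to 1)."""

    grid: np.ndarray  # (G, G) nonnegative
    patient_id: str
    pixel: tuple[int, int]  # pixel containing the embedded coordinate


@dataclass
class RasterGrid:
    """A raster config with a frozen coordinate -> mm mapping."""

    config: RasterConfig
    scale: np.ndarray  # mm = coord * scale + shift, per axis
    shift: np.ndarray
    clipped_count: int = 0

    _kernel: np.ndarray | None = field(default=None, repr=False)

    def to_pixel(self, coords: np.ndarray) -> np.ndarray:
        """Map (n, 2) morphospace coordinates to integer pixel indices.

        Coordinates landing outside the window are clipped to the border
        (counted in ``clipped_count``) with a warning.
        """
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        mm = c * self.scale[None, :] + self.shift[None, :]
        pix = np.floor(mm / self.config.pixel_size).astype(int)
        out = (pix < 0) | (pix >= self.config.grid_size)
        n_out = int(out.any(axis=1).sum())
        if n_out:
            self.clipped_count += n_out
            warnings.warn(
                f"{n_out} coordinate(s) outside the raster window were clipped",
                stacklevel=2,
            )
        return np.clip(pix, 0, self.config.grid_size - 1)

    def kernel(self) -> np.ndarray:
        """2-D Gaussian kernel truncated at 4 sigma, unit sum."""
        if self._kernel is None:
            s = self.config.sigma_pixels
            if s == 0:
                self._kernel = np.ones((1, 1))
            else:
                half = int(np.ceil(4.0 * s))
                d = np.arange(-half, half + 1, dtype=float)
                g = np.exp(-0.5 * (d / s) ** 2)
                k = np.outer(g, g)
                self._kernel = k / k.sum()
        return self._kernel

    def rasterize(self, coord: np.ndarray, patient_id: str = "") -> LocalizationMap:
        return rasterize_coordinate(coord, self, patient_id)

    def rasterize_cohort(
        self, coords: np.ndarray, patient_ids: list[str] | None = None
    ) -> list[LocalizationMap]:
        coords = np.atleast_2d(coords)
        ids = patient_ids or [f"patient_{i:04d}" for i in range(len(coords))]
        return [self.rasterize(c, pid) for c, pid in zip(coords, ids)]

    def to_state(self) -> dict:
        return {
            "config": asdict(self.config),
            "scale": self.scale.tolist(),
            "shift": self.shift.tolist(),
        }

    @classmethod
    def from_state(cls, state: dict) -> "RasterGrid":
        return cls(
            config=RasterConfig(**state["config"]),
            scale=np.asarray(state["scale"], dtype=float),
            shift=np.asarray(state["shift"], dtype=float),
        )


def rasterize_coordinate(
    coord: np.ndarray, raster: RasterGrid, patient_id: str = ""
) -> LocalizationMap:
    """Unit impulse at the coordinate's pixel, Gaussian-smoothed (truncated
    at 4 sigma) and renormalised to sum exactly 1."""
    (ix, iy) = raster.to_pixel(np.asarray(coord, dtype=float))[0]
    g = raster.config.grid_size
    k = raster.kernel()
    half = (k.shape[0] - 1) // 2
    grid = np.zeros((g, g))
    x0, x1 = max(0, ix - half), min(g, ix + half + 1)
    y0, y1 = max(0, iy - half), min(g, iy + half + 1)
    grid[x0:x1, y0:y1] = k[
        x0 - ix + half : x1 - ix + half, y0 - iy + half : y1 - iy + half
    ]
    grid /= grid.sum()  # border patients keep unit mass
    return LocalizationMap(grid=grid, patient_id=patient_id, pixel=(int(ix), int(iy)))


# ---------------------------------------------------------------------------
# pixel-wise correlation and territories
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap2D:
    """Pixel-wise Pearson R between localization probability and a score."""

    r: np.ndarray  # (G, G) in [-1, 1]
    n_patients: int
    n_zero_variance_pixels: int = 0


def _locmap_matrix(locmaps: list[LocalizationMap]) -> np.ndarray:
    shape = locmaps[0].grid.shape
    for m in locmaps:
        if m.grid.shape != shape:
            raise GridMismatchError("localization maps have incongruent grids")
    return np.stack([m.grid.reshape(-1) for m in locmaps])


def correlation_map(
    locmaps: list[LocalizationMap], scores: np.ndarray
) -> CorrelationMap2D:
    """Per-pixel Pearson correlation across patients.

    Pixels with zero variance across patients get r = 0 (flagged), keeping
    the later connected-component analysis total.
    """
    scores = np.asarray(scores, dtype=float)
    if len(locmaps) != len(scores):
        raise ConfigurationError("locmaps and scores length mismatch")
    if len(scores) < 3:
        raise ConfigurationError("need >= 3 patients with non-missing score")
    if np.any(~np.isfinite(scores)):
        raise ConfigurationError("scores must be non-missing here (filter first)")
    if np.ptp(scores) == 0:
        raise DegenerateDataError("score has no variance")
    X = _locmap_matrix(locmaps)
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    yc = scores - scores.mean()
    sy = np.sqrt((yc**2).sum())
    dead = sx <= 1e-12 * np.abs(X).max(axis=0)
    r = np.zeros(X.shape[1])
    r[~dead] = (Xc[:, ~dead].T @ yc) / (sx[~dead] * sy)
    shape = locmaps[0].grid.shape
    return CorrelationMap2D(
        r=np.clip(r, -1.0, 1.0).reshape(shape),
        n_patients=len(scores),
        n_zero_variance_pixels=int(dead.sum()),
    )


@dataclass
class TerritoryMask:
    """Score-associated morphospace territory (union of kept components)."""

    mask: np.ndarray  # (G, G) bool
    labels: np.ndarray  # (G, G) int component labels of the thresholded map
    kept_labels: list[int]
    n_clusters_with_patients: int


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def extract_territories(
    rmap: CorrelationMap2D,
    patient_pixels: np.ndarray,
    threshold: float = 0.2,
) -> TerritoryMask:
    """8-connected components of |R| > threshold; keep the (<= 3) components
    containing at least one training patient's peak pixel.

    More than three qualifying components: keep the three with most patients
    (ties: larger area, then lower label index).
    """
    supra = np.abs(rmap.r) > threshold
    if not supra.any():
        raise NoTerritoryError(
            f"no informative territory for score: no pixel with |R| > {threshold}"
        )
    labels, n_comp = ndimage.label(supra, structure=_EIGHT_CONNECTED)
    pix = np.atleast_2d(np.asarray(patient_pixels, dtype=int))
    patient_labels = labels[pix[:, 0], pix[:, 1]]
    counts = np.bincount(patient_labels[patient_labels > 0], minlength=n_comp + 1)
    candidates = [l for l in range(1, n_comp + 1) if counts[l] > 0]
    if not candidates:
        raise NoTerritoryError(
            "no informative territory for score: no suprathreshold component "
            "contains a patient's peak pixel"
        )
    if len(candidates) > 3:
        areas = np.bincount(labels.reshape(-1), minlength=n_comp + 1)
        candidates = sorted(candidates, key=lambda l: (-counts[l], -areas[l], l))[:3]
        warnings.warn(
            f"{n_comp} components qualified; kept 3 with most patients",
            stacklevel=2,
        )
    mask = np.isin(labels, candidates)
    return TerritoryMask(
        mask=mask,
        labels=labels,
        kept_labels=sorted(int(l) for l in candidates),
        n_clusters_with_patients=len(candidates),
    )


# ---------------------------------------------------------------------------
# spatial PCA
# ---------------------------------------------------------------------------

@dataclass
class SpatialPCA:
    """PCA of the patients x territory-pixels probability matrix."""

    components: np.ndarray  # (k, m) orthonormal
    variance_ratios: np.ndarray  # (k,), non-increasing
    mean: np.ndarray  # (m,)
    mask: np.ndarray  # (G, G) bool territory

    @property
    def explained_variance(self) -> float:
        return float(self.variance_ratios.sum())


def _pca_svd(Xc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact economy-SVD path: components (k, m) and all singular values."""
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    return Vt[:k], s**2


def _canonical_complement(basis: list[np.ndarray], m: int) -> np.ndarray:
    """First coordinate axis with a substantial part orthogonal to ``basis``.

    Deterministic completion for directions the data does not determine
    (numerically zero eigenvalues)."""
    for j in range(m):
        v = np.zeros(m)
        v[j] = 1.0
        for b in basis:
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if n > 0.5:
            return v / n
    raise DegenerateDataError("cannot complete an orthonormal basis")


def _pca_gram(Xc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Gram-matrix PCA for n << m; mathematically identical to the SVD.

    Eigenvectors of the n x n Gram matrix are lifted to pixel space and
    re-orthonormalised; directions with numerically zero variance are
    completed deterministically (their explained variance is 0).
    """
    G = Xc @ Xc.T
    w, U = np.linalg.eigh(G)  # ascending
    w = w[::-1]
    U = U[:, ::-1]
    lam = np.maximum(w, 0.0)
    tol = 1e-12 * (lam[0] if lam[0] > 0 else 1.0)
    basis: list[np.ndarray] = []
    for i in range(k):
        v = Xc.T @ U[:, i]
        for b in basis:  # modified Gram-Schmidt touch-up
            v -= (v @ b) * b
        n = np.linalg.norm(v)
        if lam[i] > tol and n > 0:
            v /= n
        else:
            v = _canonical_complement(basis, Xc.shape[1])
            lam[i] = 0.0
        basis.append(v)
    return np.asarray(basis), lam


def spatial_pca(
    locmaps: list[LocalizationMap], territory: TerritoryMask, k: int = 3
) -> SpatialPCA:
    """Column-centred PCA over territory pixels; warns when the first three
    components explain < 80% of the variance.

    For the typical shape (hundreds of patients x tens of thousands of
    pixels) the eigendecomposition of the n x n Gram matrix is used; it is
    exact and an order of magnitude faster than a dense SVD of the data.
    """
    if len(locmaps) < k + 1:
        raise ConfigurationError(f"spatial PCA needs >= {k + 1} patients")
    m = int(territory.mask.sum())
    if m == 0:
        raise NoTerritoryError("empty territory mask")
    if m < k:
        raise DegenerateDataError(
            f"territory has {m} pixels < {k} requested components"
        )
    X = np.stack([lm.grid[territory.mask] for lm in locmaps])
    if np.allclose(X, X[0], atol=0.0):
        raise DegenerateDataError("degenerate localization matrix")
    mean = X.mean(axis=0)
    Xc = X - mean
    if min(Xc.shape) > 50:
        comps, lam = _pca_gram(Xc, k)
    else:
        comps, lam = _pca_svd(Xc, k)
    # deterministic sign: largest-|entry| of each component is positive
    for c in comps:
        j = np.argmax(np.abs(c))
        if c[j] < 0:
            c *= -1.0
    total = float(lam.sum())
    ratios = lam[:k] / total if total > 0 else np.zeros(k)
    spca = SpatialPCA(
        components=comps,
        variance_ratios=ratios,
        mean=mean,
        mask=territory.mask,
    )
    if spca.explained_variance < 0.80:
        warnings.warn(
            f"3-component explained variance {spca.explained_variance:.2f} < 0.80",
            stacklevel=2,
        )
    return spca


def pca_scores(locmap: LocalizationMap, pca: SpatialPCA) -> np.ndarray:
    """Inner products of the centred localization probabilities with the PCA
    components: the patient's 3-vector of spatial PCA scores."""
    x = locmap.grid[pca.mask] - pca.mean
    return pca.components @ x


def _pca_scores_matrix(locmaps: list[LocalizationMap], pca: SpatialPCA) -> np.ndarray:
    X = np.stack([lm.grid[pca.mask] for lm in locmaps]) - pca.mean[None, :]
    return X @ pca.components.T


# ---------------------------------------------------------------------------
# per-score regression
# ---------------------------------------------------------------------------

@dataclass
class ScoreModel:
    """score_hat = intercept + w . pca_scores"""

    score_name: str
    intercept: float
    weights: np.ndarray  # (3,)
    n_train: int
    r2_train: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (3,):
            raise ConfigurationError("ScoreModel carries exactly 3 weights")


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def fit_score_model(
    pca_score_matrix: np.ndarray, scores: np.ndarray, score_name: str = ""
) -> ScoreModel:
    """Ordinary least squares of the score on the three PCA scores.

    Collinear predictors fall back to the minimum-norm solution (with a
    warning) via the lstsq pseudo-inverse.
    """
    S = np.atleast_2d(np.asarray(pca_score_matrix, dtype=float))
    y = np.asarray(scores, dtype=float)
    if S.shape[0] != len(y):
        raise ConfigurationError("pca scores / scores length mismatch")
    if len(y) < 5:
        raise ConfigurationError("need >= 5 non-missing patients per score")
    X = np.column_stack([np.ones(len(y)), S])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"collinear PCA predictors for {score_name or 'score'}: "
            "minimum-norm solution used",
            stacklevel=2,
        )
    yhat = X @ beta
    return ScoreModel(
        score_name=score_name,
        intercept=float(beta[0]),
        weights=beta[1:],
        n_train=len(y),
        r2_train=_pearson_r2(y, yhat),
    )


def predict_score(
    model: ScoreModel,
    pca_score_vec: np.ndarray,
    clip_range: tuple[float, float] | None = None,
) -> float | np.ndarray:
    """c + sum_i w_i s_i; optional clipping to the score scale."""
    s = np.asarray(pca_score_vec, dtype=float)
    pred = model.intercept + s @ model.weights if s.ndim == 2 else (
        model.intercept + float(s @ model.weights)
    )
    if clip_range is not None:
        pred = np.clip(pred, clip_range[0], clip_range[1])
    return pred


# ---------------------------------------------------------------------------
# the DSD model / results pair
# ---------------------------------------------------------------------------

@dataclass
class ScoreFit:
    """Everything fitted for one score."""

    territory: TerritoryMask
    pca: SpatialPCA
    model: ScoreModel
    patient_index: np.ndarray  # rows of the training cohort used


class DisconnectomeSymptomDiscoverer:
    """Composite per-score prediction model over a fitted morphospace.

    Built from per-patient localization maps and a score table; ``fit()``
    loops correlation map -> territory extraction -> spatial PCA -> OLS per
    score and returns a :class:`DSDResults`.  Scores whose territory
    extraction or PCA fails are recorded as unmodelable, not fatal.

    Use :meth:`from_maps` to go straight from disconnectome maps and a
    fitted :class:`~dsdkit.morphospace.MorphospaceModel`.
    """

    def __init__(
        self,
        locmaps: list[LocalizationMap],
        score_table: ScoreTable,
        raster_grid: RasterGrid,
        threshold: float = 0.2,
        n_components: int = 3,
        min_patients: int = 5,
        morphospace: MorphospaceModel | None = None,
    ):
        if len(locmaps) != score_table.n_patients:
            raise ConfigurationError("locmaps / score table size mismatch")
        self.locmaps = locmaps
        self.score_table = score_table
        self.raster_grid = raster_grid
        self.threshold = threshold
        self.n_components = n_components
        self.min_patients = min_patients
        self.morphospace = morphospace

    @classmethod
    def from_maps(
        cls,
        morphospace: MorphospaceModel,
        maps: list,
        score_table: ScoreTable,
        raster: RasterConfig | None = None,
        **kwargs,
    ) -> "DisconnectomeSymptomDiscoverer":
        raster = raster or RasterConfig(mapping_mode="autoscale")
        coords = morphospace.embed(maps)
        grid = raster.fit(coords)
        locmaps = grid.rasterize_cohort(coords, list(score_table.patient_ids))
        return cls(locmaps, score_table, grid, morphospace=morphospace, **kwargs)

    def fit(self) -> "DSDResults":
        table = self.score_table
        peaks = np.array([lm.pixel for lm in self.locmaps], dtype=int)
        fits: dict[str, ScoreFit] = {}
        unmodelable: dict[str, str] = {}
        for j, name in enumerate(table.score_names):
            y = table.values[:, j]
            keep = np.where(np.isfinite(y))[0]
            if len(keep) < self.min_patients:
                unmodelable[name] = f"only {len(keep)} non-missing patients"
                continue
            sub_maps = [self.locmaps[i] for i in keep]
            try:
                rmap = correlation_map(sub_maps, y[keep])
                territory = extract_territories(rmap, peaks[keep], self.threshold)
                pca = spatial_pca(sub_maps, territory, k=self.n_components)
                S = _pca_scores_matrix(sub_maps, pca)
                model = fit_score_model(S, y[keep], score_name=name)
            except (NoTerritoryError, DegenerateDataError, ConfigurationError) as exc:
                unmodelable[name] = str(exc)
                continue
            fits[name] = ScoreFit(
                territory=territory, pca=pca, model=model, patient_index=keep
            )
        return DSDResults(
            score_fits=fits,
            unmodelable=unmodelable,
            raster_grid=self.raster_grid,
            score_names=list(table.score_names),
            max_scale={n: table.scale_of(n) for n in table.score_names},
            morphospace=self.morphospace,
            threshold=self.threshold,
        )


@dataclass
class DSDResults:
    """Fitted composite models, one per modelable score."""

    score_fits: dict[str, ScoreFit]
    unmodelable: dict[str, str]
    raster_grid: RasterGrid
    score_names: list[str]
    max_scale: dict[str, float]
    morphospace: MorphospaceModel | None = None
    threshold: float = 0.2

    @property
    def modeled_scores(self) -> list[str]:
        return list(self.score_fits)

    def pca_scores_for(
        self, locmaps: list[LocalizationMap], score_name: str
    ) -> np.ndarray:
        """(n, 3) spatial-PCA scores of new patients under one score's fit."""
        return _pca_scores_matrix(locmaps, self.score_fits[score_name].pca)

    def predict_from_locmaps(
        self,
        locmaps: list[LocalizationMap],
        clip: bool = False,
        scores: list[str] | None = None,
    ) -> pd.DataFrame:
        names = scores or self.modeled_scores
        out = {}
        for name in names:
            fit = self.score_fits[name]
            S = _pca_scores_matrix(locmaps, fit.pca)
            rng = (0.0, self.max_scale[name]) if clip else None
            out[name] = predict_score(fit.model, S, clip_range=rng)
        ids = [lm.patient_id for lm in locmaps]
        return pd.DataFrame(out, index=pd.Index(ids, name="patient_id"))

    def locmaps_for(self, maps: list, patient_ids: list[str] | None = None):
        if self.morphospace is None:
            raise ConfigurationError("no morphospace attached to these results")
        coords = self.morphospace.embed(maps)
        return self.raster_grid.rasterize_cohort(coords, patient_ids)

    def predict(self, maps: list, clip: bool = False) -> pd.DataFrame:
        """Embed disconnectome maps, rasterize, and predict all modeled scores."""
        ids = [
            getattr(m, "lesion_id", None)
            or getattr(m, "volume_id", None)
            or f"patient_{i:04d}"
            for i, m in enumerate(maps)
        ]
        return self.predict_from_locmaps(self.locmaps_for(maps, ids), clip=clip)

    def summary(self) -> str:
        """Human-readable per-score fit table."""
        lines = [
            "Disconnectome Symptoms Discoverer — fitted composite models",
            f"  modeled scores: {len(self.score_fits)} / {len(self.score_names)}"
            f"   (|R| threshold {self.threshold}, 3 PCA components)",
            "",
            f"{'score':<24}{'n':>5}{'territ.px':>11}{'clusters':>9}"
            f"{'var.expl':>10}{'R2(train)':>11}",
        ]
        for name, fit in self.score_fits.items():
            lines.append(
                f"{name:<24}{fit.model.n_train:>5}"
                f"{int(fit.territory.mask.sum()):>11}"
                f"{fit.territory.n_clusters_with_patients:>9}"
                f"{fit.pca.explained_variance:>10.3f}"
                f"{fit.model.r2_train:>11.3f}"
            )
        for name, reason in self.unmodelable.items():
            lines.append(f"{name:<24}  unmodelable: {reason}")
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------
    def to_state(self) -> tuple[dict, dict, dict]:
        meta = {
            "score_names": self.score_names,
            "max_scale": self.max_scale,
            "unmodelable": self.unmodelable,
            "threshold": self.threshold,
            "raster_grid": self.raster_grid.to_state(),
            "fits": {},
        }
        arrays: dict[str, np.ndarray] = {}
        for name, fit in self.score_fits.items():
            key = f"fit_{name}"
            meta["fits"][name] = {
                "key": key,
                "intercept": fit.model.intercept,
                "n_train": fit.model.n_train,
                "r2_train": fit.model.r2_train,
                "kept_labels": fit.territory.kept_labels,
                "n_clusters": fit.territory.n_clusters_with_patients,
            }
            arrays[f"{key}_mask"] = fit.territory.mask
            arrays[f"{key}_labels"] = fit.territory.labels
            arrays[f"{key}_components"] = fit.pca.components
            arrays[f"{key}_ratios"] = fit.pca.variance_ratios
            arrays[f"{key}_mean"] = fit.pca.mean
            arrays[f"{key}_weights"] = fit.model.weights
            arrays[f"{key}_patient_index"] = fit.patient_index
        return meta, arrays, {}

    @classmethod
    def from_state(
        cls, meta: dict, arrays: dict, blobs: dict, morphospace=None
    ) -> "DSDResults":
        fits: dict[str, ScoreFit] = {}
        for name, info in meta["fits"].items():
            key = info["key"]
            mask = arrays[f"{key}_mask"].astype(bool)
            territory = TerritoryMask(
                mask=mask,
                labels=arrays[f"{key}_labels"],
                kept_labels=[int(l) for l in info["kept_labels"]],
                n_clusters_with_patients=int(info["n_clusters"]),
            )
            pca = SpatialPCA(
                components=arrays[f"{key}_components"],
                variance_ratios=arrays[f"{key}_ratios"],
                mean=arrays[f"{key}_mean"],
                mask=mask,
            )
            model = ScoreModel(
                score_name=name,
                intercept=float(info["intercept"]),
                weights=arrays[f"{key}_weights"],
                n_train=int(info["n_train"]),
                r2_train=float(info["r2_train"]),
            )
            fits[name] = ScoreFit(
                territory=territory,
                pca=pca,
                model=model,
                patient_index=arrays[f"{key}_patient_index"],
            )
        return cls(
            score_fits=fits,
            unmodelable=dict(meta["unmodelable"]),
            raster_grid=RasterGrid.from_state(meta["raster_grid"]),
            score_names=list(meta["score_names"]),
            max_scale={k: float(v) for k, v in meta["max_scale"].items()},
            morphospace=morphospace,
            threshold=float(meta["threshold"]),
        )


def fit_composite(
    train_locmaps: list[LocalizationMap],
    score_table: ScoreTable,
    raster_grid: RasterGrid,
    threshold: float = 0.2,
    n_components: int = 3,
    morphospace: MorphospaceModel | None = None,
) -> DSDResults:
    """Functional wrapper: build the model and fit in one call."""
    return DisconnectomeSymptomDiscoverer(
        train_locmaps,
        score_table,
        raster_grid,
        threshold=threshold,
        n_components=n_components,
        morphospace=morphospace,
    ).fit()
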