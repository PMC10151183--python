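"""Prediction scoring (MAE%, R-squared), k-fold stability, the six
comparator models, and the paired model comparison test.

MAE% is the mean absolute error normalised by the score's maximum scale
value, times 100, so accuracy is comparable across clinical scales.  The
goodness of fit is the squared Pearson correlation from regressing measured
on predicted scores; by contract it is reported only for n > 20 patients
(a soft gate with an override for small synthetic cohorts) and is 0 for a
constant predictor, which pins the group-mean comparator to R-squared = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng
from .composite import RasterGrid, fit_composite, LocalizationMap
from .disconnectome import DisconnectomeMap
from .errors import ConfigurationError, DegenerateDataError
from .types import ScoreTable

__all__ = [
    "PredictionResult",
    "mae_percent",
    "goodness_of_fit",
    "evaluate_predictions",
    "KFoldResult",
    "kfold_stability",
    "VoxelBasedResult",
    "voxel_based_model",
    "volage_model",
    "GroupMeanModel",
    "group_mean_model",
    "ModelComparisonResult",
    "compare_models",
]

R2_MIN_N = 20  # R-squared is reported only above this cohort size
T_CAP = 1e6


def mae_percent(
    measured: np.ndarray, predicted: np.ndarray, max_scale: float
) -> float:
    """(mean |measured - predicted| / max_scale) * 100."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.size == 0:
        raise ConfigurationError("measured/predicted must have equal length >= 1")
    if max_scale <= 0:
        raise ConfigurationError("max_scale must be > 0")
    return float(np.mean(np.abs(m - p)) / max_scale * 100.0)


def goodness_of_fit(
    measured: np.ndarray, predicted: np.ndarray, allow_small_n: bool = False
) -> float:
    """Squared Pearson correlation between measured and predicted scores.

    Returns 0 when the predictor (or the measured vector) has no variance.
    Refuses n <= 20 unless ``allow_small_n`` (reporting contract).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ConfigurationError("measured/predicted must have equal length")
    if len(m) <= R2_MIN_N and not allow_small_n:
        raise ConfigurationError(
            f"R-squared is reported only for n > {R2_MIN_N} subjects "
            f"(got n={len(m)}); pass allow_small_n=True to override"
        )
    if len(m) <= R2_MIN_N and allow_small_n:
        warnings.warn(
            f"R-squared computed on n={len(m)} <= {R2_MIN_N} by override",
            stacklevel=2,
        )
    if np.ptp(p) == 0 or np.ptp(m) == 0:
        return 0.0
    return float(np.corrcoef(m, p)[0, 1] ** 2)


@dataclass
class PredictionResult:
    """Per-score accuracy summary of a set of predictions."""

    score_name: str
    measured: np.ndarray
    predicted: np.ndarray
    max_scale: float
    n: int
    mae_percent: float
    r_squared: float | None  # None when n <= 20 and not overridden


def evaluate_predictions(
    measured: np.ndarray,
    predicted: np.ndarray,
    max_scale: float,
    score_name: str = "",
    allow_small_n: bool = False,
) -> PredictionResult:
    """Bundle MAE% and (when reportable) R-squared for one score."""
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ok = np.isfinite(m) & np.isfinite(p)
    m, p = m[ok], p[ok]
    r2 = None
    if len(m) > R2_MIN_N or allow_small_n:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2 = goodness_of_fit(m, p, allow_small_n=True)
    return PredictionResult(
        score_name=score_name,
        measured=m,
        predicted=p,
        max_scale=float(max_scale),
        n=len(m),
        mae_percent=mae_percent(m, p, max_scale),
        r_squared=r2,
    )


# ---------------------------------------------------------------------------
# k-fold stability
# ---------------------------------------------------------------------------

@dataclass
class KFoldResult:
    """R-squared distribution per score over random 70/30 refits."""

    r2: pd.DataFrame  # (n_iter, scores); NaN where the iteration failed
    failures: pd.DataFrame  # bool, True where territory extraction failed

    @property
    def median(self) -> pd.Series:
        return self.r2.median(axis=0, skipna=True)


def kfold_stability(
    locmaps: list[LocalizationMap],
    score_table: ScoreTable,
    raster_grid: RasterGrid,
    n_iter: int = 100,
    train_frac: float = 0.7,
    seed: int = 0,
    threshold: float = 0.2,
    refit_territories: bool = True,
) -> KFoldResult:
    """Random 70/30 refits of the composite model on a fixed morphospace.

    Each iteration refits territories, PCA and regression on the training
    split (no leakage from the full cohort) unless ``refit_territories``
    is disabled, in which case a single full-cohort fit is reused and only
    the regression is refit.  Failed iterations are recorded, not dropped.
    """
    n = score_table.n_patients
    n_train = int(round(train_frac * n))
    if n - n_train < 5:
        raise ConfigurationError("test folds would have < 5 patients")
    rng = stage_rng(seed, "kfold")
    names = list(score_table.score_names)
    r2 = np.full((n_iter, len(names)), np.nan)
    failed = np.zeros((n_iter, len(names)), dtype=bool)

    full_fit = None
    if not refit_territories:
        full_fit = fit_composite(
            locmaps, score_table, raster_grid, threshold=threshold
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for it in range(n_iter):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            train_maps = [locmaps[i] for i in tr]
            if refit_territories:
                res = fit_composite(
                    train_maps, score_table.subset(tr), raster_grid,
                    threshold=threshold,
                )
            else:
                res = _refit_regressions(full_fit, train_maps, score_table.subset(tr))
            test_maps = [locmaps[i] for i in te]
            for j, name in enumerate(names):
                if name not in res.score_fits:
                    failed[it, j] = True
                    continue
                y = score_table.values[te, j]
                ok = np.isfinite(y)
                if ok.sum() < 3:
                    failed[it, j] = True
                    continue
                pred = res.predict_from_locmaps(
                    [test_maps[i] for i in np.where(ok)[0]], scores=[name]
                )[name].to_numpy()
                r2[it, j] = goodness_of_fit(y[ok], pred, allow_small_n=True)
    return KFoldResult(
        r2=pd.DataFrame(r2, columns=names),
        failures=pd.DataFrame(failed, columns=names),
    )


def _refit_regressions(full_res, train_maps, train_table):
    """Reuse full-cohort territories/PCA, refit only the OLS weights."""
    from .composite import DSDResults, ScoreFit, _pca_scores_matrix, fit_score_model

    fits = {}
    for name, fit in full_res.score_fits.items():
        j = train_table.score_names.index(name)
        y = train_table.values[:, j]
        keep = np.where(np.isfinite(y))[0]
        if len(keep) < 5:
            continue
        S = _pca_scores_matrix([train_maps[i] for i in keep], fit.pca)
        model = fit_score_model(S, y[keep], score_name=name)
        fits[name] = ScoreFit(fit.territory, fit.pca, model, keep)
    return DSDResults(
        score_fits=fits,
        unmodelable={},
        raster_grid=full_res.raster_grid,
        score_names=full_res.score_names,
        max_scale=full_res.max_scale,
        threshold=full_res.threshold,
    )


# ---------------------------------------------------------------------------
# voxel-based comparators (D-VB, L-VB, f-VB share this engine)
# ---------------------------------------------------------------------------

@dataclass
class VoxelBasedResult:
    """Mass-univariate voxel model summarised over the top-|t| voxels."""

    r_squared: float
    n_selected: int
    t_threshold: float
    selected: np.ndarray  # flat indices of the top-|t| voxels
    null: np.ndarray  # permutation null of the same statistic
    p_value: float


def _as_feature_matrix(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps.reshape(len(maps), -1).astype(float)
    rows = []
    for m in maps:
        vol = m.volume if isinstance(m, DisconnectomeMap) else m
        rows.append(np.asarray(vol.data, dtype=float).reshape(-1))
    return np.stack(rows)


def _vb_statistic(
    Xc: np.ndarray, sx: np.ndarray, live: np.ndarray, y: np.ndarray,
    percentile: float, aggregate: str
) -> tuple[float, np.ndarray, float]:
    n = len(y)
    df = n - 2
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    r = np.zeros(Xc.shape[1])
    r[live] = np.clip((Xc[:, live].T @ yc) / (sx[live] * sy), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    t = np.clip(t, -T_CAP, T_CAP)
    at = np.abs(t)
    thr = float(np.percentile(at, percentile))
    sel = at >= thr
    r2v = t[sel] ** 2 / (t[sel] ** 2 + df)
    stat = float(r2v.max() if aggregate == "max" else r2v.mean())
    return stat, np.where(sel)[0], thr


def voxel_based_model(
    maps,
    scores: np.ndarray,
    n_perm: int = 5000,
    percentile: float = 98.0,
    seed: int = 0,
    aggregate: str = "mean",
) -> VoxelBasedResult:
    """Voxel-wise association t-map; keep voxels at/above the |t| percentile
    and report their mean R-squared (t^2 / (t^2 + df) per voxel), with a
    permutation null of the same statistic for calibration.
    """
    X = _as_feature_matrix(maps)
    y = np.asarray(scores, dtype=float)
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    if len(y) < 10:
        raise ConfigurationError("voxel-based model needs >= 10 patients")
    if np.ptp(y) == 0:
        raise DegenerateDataError("score has no variance")
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    live = sx > 1e-12 * np.abs(X).max(axis=0)
    if not live.any():
        raise DegenerateDataError("all voxels constant across patients")
    if aggregate not in ("mean", "max"):
        raise ConfigurationError("aggregate must be 'mean' or 'max'")
    stat, selected, thr = _vb_statistic(Xc, sx, live, y, percentile, aggregate)
    rng = stage_rng(seed, "vb-permutations")
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _vb_statistic(
            Xc, sx, live, rng.permutation(y), percentile, aggregate
        )[0]
    p = float((1 + np.sum(null >= stat)) / (n_perm + 1))
    return VoxelBasedResult(
        r_squared=stat, n_selected=len(selected), t_threshold=thr,
        selected=selected, null=null, p_value=p,
    )


# ---------------------------------------------------------------------------
# VolAge and group-mean comparators
# ---------------------------------------------------------------------------

def volage_model(
    volumes: np.ndarray,
    ages: np.ndarray,
    scores: np.ndarray,
    max_scale: float,
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    score_name: str = "",
) -> PredictionResult:
    """OLS of the score on standardised lesion volume and age.

    Patients with a missing covariate or score are dropped with a warning.
    A constant covariate is excluded from the design (warning).  Without an
    explicit split, training predictions are evaluated.
    """
    v = np.asarray(volumes, dtype=float)
    a = np.asarray(ages, dtype=float)
    y = np.asarray(scores, dtype=float)
    n = len(y)
    if train_idx is None:
        train_idx = np.arange(n)
    if test_idx is None:
        test_idx = train_idx
    ok = np.isfinite(v) & np.isfinite(a) & np.isfinite(y)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} patients dropped for missing covariate/score",
            stacklevel=2,
        )
    train = np.asarray([i for i in train_idx if ok[i]])
    test = np.asarray([i for i in test_idx if ok[i]])

    cols = []
    for name, x in (("lesion volume", v), ("age", a)):
        sd = x[train].std()
        if sd == 0:
            warnings.warn(f"{name} is constant; excluded from the fit", stacklevel=2)
            continue
        cols.append((x - x[train].mean()) / sd)
    X_all = (
        np.column_stack([np.ones(n)] + [c for c in cols])
        if cols
        else np.ones((n, 1))
    )
    beta, *_ = np.linalg.lstsq(X_all[train], y[train], rcond=None)
    pred = X_all[test] @ beta
    return evaluate_predictions(
        y[test], pred, max_scale, score_name=score_name, allow_small_n=True
    )


@dataclass
class GroupMeanModel:
    """Predicts the training mean for everyone; R-squared = 0 by contract."""

    mean: float

    def predict(self, n: int) -> np.ndarray:
        return np.full(n, self.mean)


def group_mean_model(scores_train: np.ndarray) -> GroupMeanModel:
    y = np.asarray(scores_train, dtype=float)
    y = y[np.isfinite(y)]
    if len(y) < 1:
        raise ConfigurationError("need >= 1 training value")
    return GroupMeanModel(mean=float(y.mean()))


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparisonResult:
    """Paired t-tests of the reference model's R-squared against comparators."""

    r2_table: pd.DataFrame  # models x scores
    reference: str
    t_stats: dict[str, float]
    p_raw: dict[str, float]
    p_adjusted: dict[str, float]  # Bonferroni: min(1, p * n_comparisons)
    n_shared: dict[str, int]

    def summary(self) -> str:
        lines = [f"Paired t-tests: {self.reference} vs comparators "
                 f"(two-tailed, Bonferroni x{len(self.t_stats)})"]
        for m in self.t_stats:
            lines.append(
                f"  {m:<12} t={self.t_stats[m]:+8.3f}  p_adj={self.p_adjusted[m]:.4g}"
                f"  (n={self.n_shared[m]} scores)"
            )
        return "\n".join(lines)


def compare_models(
    r2_table: pd.DataFrame, reference: str = "DSD"
) -> ModelComparisonResult:
    """Two-tailed paired t-test of the reference row against every other row
    across shared scores, Bonferroni-corrected over the comparators."""
    if reference not in r2_table.index:
        raise ConfigurationError(f"reference model {reference!r} not in table")
    comparators = [m for m in r2_table.index if m != reference]
    if len(comparators) < 1 or r2_table.shape[1] < 3:
        raise ConfigurationError("need >= 2 models and >= 3 scores")
    t_stats, p_raw, p_adj, n_shared = {}, {}, {}, {}
    for m in comparators:
        both = r2_table.loc[[reference, m]].dropna(axis=1)
        if both.shape[1] < 3:
            raise ConfigurationError(
                f"models {reference!r} and {m!r} share < 3 scores"
            )
        d = both.loc[reference] - both.loc[m]
        if np.ptp(d.to_numpy()) == 0 and d.iloc[0] == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(both.loc[reference], both.loc[m])
            t, p = float(t), float(p)
            if not np.isfinite(p):  # zero-variance nonzero difference
                p = 0.0
        t_stats[m], p_raw[m] = t, p
        p_adj[m] = min(1.0, p * len(comparators))
        n_shared[m] = int(both.shape[1])
    return ModelComparisonResult(
        r2_table=r2_table,
        reference=reference,
        t_stats=t_stats,
        p_raw=p_raw,
        p_adjusted=p_adj,
        n_shared=n_shared,
    )
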