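"""End-to-end simulation studies on synthetic cohorts.

These drive the package's own validation: parameter recovery of planted
score-tract relationships through the full pipeline, k-fold stability,
split-half reproducibility of the voxel atlas, and null calibration of the
voxel-based comparator.  Problem sizes follow the package's desk-scale
study conditions: a 40x48x40 voxel 2 mm template, 3 tracts, 150/50
train/test cohorts, measurement noise at 10% of each planted score's range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._seeds import stage_rng, stage_seed
from .composite import DisconnectomeSymptomDiscoverer, RasterConfig
from .disconnectome import NormativeSet
from .evaluation import (
    evaluate_predictions,
    goodness_of_fit,
    group_mean_model,
    kfold_stability,
    voxel_based_model,
    volage_model,
)
from .morphospace import MorphospaceConfig, fit_morphospace
from .nwma import split_half_reproducibility
from .synthetic import (
    default_tract_specs,
    make_lesion_cohort,
    make_scores,
    make_tract_atlas,
    mini_template,
)

__all__ = [
    "build_planted_cohort",
    "RecoveryRun",
    "parameter_recovery",
    "parameter_recovery_study",
    "kfold_benchmark",
    "split_half_benchmark",
    "split_half_study",
    "vb_null_calibration",
]

PLANTED_WEIGHTS = np.array(
    [
        [40.0, -10.0, 15.0],  # planted_a
        [-5.0, 35.0, -20.0],  # planted_b
        [0.0, 0.0, 0.0],  # noise_only
    ]
)
SCORE_NAMES = ["planted_a", "planted_b", "noise_only"]
PLANTED = ["planted_a", "planted_b"]
MAX_SCALE = 100.0


@dataclass
class PlantedCohort:
    template: object
    atlas: list
    lesions: list
    maps: list
    scores: object
    truth: object


def build_planted_cohort(
    seed: int,
    n_patients: int,
    n_normative: int = 6,
    noise_frac: float = 0.10,
    jitter_mm: float = 1.0,
) -> PlantedCohort:
    """Cohort whose scores are linear in tract disconnection loads.

    Lesion semi-axes are drawn from a narrow range (6.5-8 mm) so lesion
    volume is nearly constant and tract identity, not size, drives the
    scores.  Noise sd is ``noise_frac`` of each planted score's noiseless
    range (pure-noise score: ``noise_frac`` of the scale).
    """
    template = mini_template()
    specs = default_tract_specs()
    atlas = make_tract_atlas(
        n_normative, specs, jitter_mm=jitter_mm, seed=seed, template=template
    )
    lesions = make_lesion_cohort(
        n_patients,
        size_range_mm=(6.5, 8.0),
        placement="uniform-over-tracts",
        seed=seed,
        tract_specs=specs,
        template=template,
    )
    # noiseless pass fixes the per-score signal range
    scores0, _ = make_scores(
        lesions, atlas, PLANTED_WEIGHTS, noise_sd=0.0, max_scale=MAX_SCALE,
        seed=seed, score_names=SCORE_NAMES,
    )
    ranges = np.ptp(scores0.values, axis=0)
    noise_sd = noise_frac * np.where(ranges > 0, ranges, MAX_SCALE)
    scores, truth = make_scores(
        lesions, atlas, PLANTED_WEIGHTS, noise_sd=noise_sd, max_scale=MAX_SCALE,
        seed=seed, score_names=SCORE_NAMES,
    )
    normative = NormativeSet(atlas, template)
    maps = normative.map_cohort(lesions)
    return PlantedCohort(template, atlas, lesions, maps, scores, truth)


def _fit_dsd(cohort: PlantedCohort, idx: np.ndarray, seed: int):
    train_maps = [cohort.maps[i] for i in idx]
    space = fit_morphospace(
        train_maps, MorphospaceConfig(seed=stage_seed(seed, "umap"))
    )
    model = DisconnectomeSymptomDiscoverer.from_maps(
        space,
        train_maps,
        cohort.scores.subset(idx),
        raster=RasterConfig(mapping_mode="autoscale"),
    )
    return space, model.fit()


@dataclass
class RecoveryRun:
    """Held-out accuracy of one simulated train/test study."""

    dsd_r2: dict[str, float]
    dsd_mae_percent: dict[str, float]
    volage_r2: dict[str, float]
    group_mean_r2: float
    modeled: list[str]
    seed: int

    @property
    def recovered(self) -> bool:
        """All planted scores modeled with R2 >= 0.5 and MAE% <= 15."""
        return all(
            s in self.dsd_r2
            and self.dsd_r2[s] >= 0.5
            and self.dsd_mae_percent[s] <= 15.0
            for s in PLANTED
        )

    @property
    def beats_comparators(self) -> bool:
        """DSD held-out R2 above VolAge and group-mean for every planted score."""
        return all(
            s in self.dsd_r2
            and self.dsd_r2[s] > self.volage_r2.get(s, np.inf)
            and self.dsd_r2[s] > self.group_mean_r2
            for s in PLANTED
        )


def parameter_recovery(
    seed: int,
    n_train: int = 150,
    n_test: int = 50,
    noise_frac: float = 0.10,
) -> RecoveryRun:
    """Full-pipeline recovery of planted score-tract relationships."""
    cohort = build_planted_cohort(seed, n_train + n_test, noise_frac=noise_frac)
    tr = np.arange(n_train)
    te = np.arange(n_train, n_train + n_test)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        space, results = _fit_dsd(cohort, tr, seed)
        test_locmaps = results.locmaps_for(
            [cohort.maps[i] for i in te],
            [cohort.scores.patient_ids[i] for i in te],
        )
        pred = results.predict_from_locmaps(test_locmaps)

        dsd_r2, dsd_mae, volage_r2 = {}, {}, {}
        cov = cohort.scores.covariates
        volumes = cov["lesion_volume"].to_numpy()
        ages = cov["age"].to_numpy()
        gm_r2 = None
        for name in PLANTED:
            y_te = cohort.scores.score(name)[te]
            if name in results.score_fits:
                res = evaluate_predictions(
                    y_te, pred[name].to_numpy(), MAX_SCALE, score_name=name
                )
                dsd_r2[name] = res.r_squared
                dsd_mae[name] = res.mae_percent
            va = volage_model(
                volumes, ages, cohort.scores.score(name), MAX_SCALE,
                train_idx=tr, test_idx=te, score_name=name,
            )
            volage_r2[name] = va.r_squared
            gm = group_mean_model(cohort.scores.score(name)[tr])
            gm_r2 = goodness_of_fit(y_te, gm.predict(len(te)), allow_small_n=True)
    return RecoveryRun(
        dsd_r2=dsd_r2,
        dsd_mae_percent=dsd_mae,
        volage_r2=volage_r2,
        group_mean_r2=gm_r2,
        modeled=results.modeled_scores,
        seed=seed,
    )


def parameter_recovery_study(base_seed: int = 0, n_seeds: int = 10) -> dict:
    """Repeat :func:`parameter_recovery` over seeds and summarise."""
    runs = [
        parameter_recovery(stage_seed(base_seed, f"recovery-{i}"))
        for i in range(n_seeds)
    ]
    r2_all = [v for r in runs for v in r.dsd_r2.values()]
    mae_all = [v for r in runs for v in r.dsd_mae_percent.values()]
    return {
        "runs": runs,
        "n_seeds": n_seeds,
        "n_recovered": sum(r.recovered for r in runs),
        "n_beats_comparators": sum(r.beats_comparators for r in runs),
        "median_r2": float(np.median(r2_all)) if r2_all else float("nan"),
        "median_mae_percent": float(np.median(mae_all)) if mae_all else float("nan"),
        "median_volage_r2": float(
            np.median([v for r in runs for v in r.volage_r2.values()])
        ),
    }


def kfold_benchmark(seed: int = 0, n_patients: int = 150, n_iter: int = 100):
    """100-iteration 70/30 k-fold on a noiseless planted cohort.

    Returns the :class:`~dsdkit.evaluation.KFoldResult` plus the median R2
    of the planted scores.
    """
    cohort = build_planted_cohort(seed, n_patients, noise_frac=0.0)
    idx = np.arange(n_patients)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        space, results = _fit_dsd(cohort, idx, seed)
        locmaps = results.locmaps_for(cohort.maps, list(cohort.scores.patient_ids))
        kf = kfold_stability(
            locmaps, cohort.scores, results.raster_grid,
            n_iter=n_iter, train_frac=0.7, seed=stage_seed(seed, "kfold-bench"),
        )
    median = float(np.median([kf.median[s] for s in PLANTED]))
    return kf, median


def split_half_benchmark(seed: int = 0, n_half: int = 60) -> float:
    """Split-half reproducibility of the effect-size atlas on a planted
    cohort (two disjoint halves of ``n_half`` subjects)."""
    cohort = build_planted_cohort(seed, 2 * n_half, noise_frac=0.10)
    idx = np.arange(2 * n_half)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        space, results = _fit_dsd(cohort, idx, seed)
        half_a, half_b = idx[:n_half], idx[n_half:]
        return split_half_reproducibility(
            [cohort.maps[i] for i in half_a],
            [cohort.maps[i] for i in half_b],
            results,
            morphospace=space,
            ids_a=[cohort.scores.patient_ids[i] for i in half_a],
            ids_b=[cohort.scores.patient_ids[i] for i in half_b],
        )


def split_half_study(base_seed: int = 0, n_seeds: int = 10, n_half: int = 60) -> dict:
    rs = [
        split_half_benchmark(stage_seed(base_seed, f"split-{i}"), n_half=n_half)
        for i in range(n_seeds)
    ]
    return {
        "r_values": rs,
        "n_seeds": n_seeds,
        "n_reproducible": int(sum(r >= 0.8 for r in rs)),
        "median_r": float(np.median(rs)),
    }


def vb_null_calibration(
    base_seed: int = 0,
    n_seeds: int = 20,
    n_patients: int = 30,
    grid: tuple = (10, 10, 10),
    n_perm: int = 200,
) -> dict:
    """Null calibration of the voxel-based model.

    Structured random maps (latent loads times spatial patterns plus noise)
    with scores permuted to break any association: the observed statistic
    should fall below the 95th percentile of its own permutation null in
    ~95% of seeds.
    """
    n_vox = int(np.prod(grid))
    below = []
    stats = []
    for i in range(n_seeds):
        rng = stage_rng(base_seed, f"vb-null-{i}")
        patterns = rng.random((3, n_vox)) * (rng.random((3, n_vox)) > 0.7)
        loads = rng.random((n_patients, 3))
        X = loads @ patterns + 0.05 * rng.standard_normal((n_patients, n_vox))
        scores = 50.0 + loads @ np.array([30.0, -20.0, 10.0])
        permuted = rng.permutation(scores)
        res = voxel_based_model(
            X, permuted, n_perm=n_perm, percentile=98.0,
            seed=stage_seed(base_seed, f"vb-null-perm-{i}"),
        )
        ok = res.r_squared < np.percentile(res.null, 95.0)
        below.append(bool(ok))
        stats.append(res.r_squared)
    return {
        "n_seeds": n_seeds,
        "n_below_95th": int(sum(below)),
        "rate": float(np.mean(below)),
        "observed": stats,
    }
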