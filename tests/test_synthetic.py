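"""Generator determinism, planted structure, and the truth-load oracle."""

import numpy as np
import pytest

from dsdkit.disconnectome import NormativeSet
from dsdkit.errors import ConfigurationError
from dsdkit.synthetic import (
    TractSpec,
    default_tract_specs,
    make_lesion_cohort,
    make_scores,
    make_tract_atlas,
    streamline_lesion_loads,
)


@pytest.fixture
def specs():
    return default_tract_specs()


class TestTractAtlas:
    def test_zero_jitter_reproduces_centerline_path(self, template, specs):
        atlas = make_tract_atlas(1, specs[:1], jitter_mm=0.0, seed=1,
                                 n_streamlines=3, template=template)
        dense_y = atlas[0].streamlines[0][:, 1]
        assert np.allclose(dense_y, specs[0].centerline[0, 1])
        for s in atlas[0].streamlines:
            # densified copies of the same straight centerline
            np.testing.assert_allclose(s[0], specs[0].centerline[0])
            np.testing.assert_allclose(s[-1], specs[0].centerline[-1])

    def test_densification_spacing_below_half_voxel(self, template, specs):
        atlas = make_tract_atlas(1, specs, jitter_mm=0.5, seed=2,
                                 n_streamlines=2, template=template)
        for s in atlas[0].streamlines:
            gaps = np.linalg.norm(np.diff(s, axis=0), axis=1)
            assert gaps.max() <= np.min(template.voxel_size) / 2 + 1e-9

    def test_same_seed_identical(self, template, specs):
        a = make_tract_atlas(3, specs, jitter_mm=1.0, seed=5, template=template)
        b = make_tract_atlas(3, specs, jitter_mm=1.0, seed=5, template=template)
        for ba, bb in zip(a, b):
            for sa, sb in zip(ba.streamlines, bb.streamlines):
                np.testing.assert_array_equal(sa, sb)

    def test_normative_cohort_size_and_fascicles(self, template, specs):
        atlas = make_tract_atlas(176, specs, jitter_mm=0.0, seed=0,
                                 n_streamlines=2, template=template)
        assert len(atlas) == 176
        assert all(set(b.labels) == {s.tract_id for s in specs} for b in atlas)

    def test_tract_outside_grid_rejected(self, template):
        bad = TractSpec("far", np.array([[500.0, 0, 0], [510.0, 0, 0]]), 3.0)
        with pytest.raises(ConfigurationError, match="exits the template grid"):
            make_tract_atlas(1, [bad], template=template)


class TestLesionCohort:
    def test_n_zero_gives_empty_list(self, template, specs):
        assert make_lesion_cohort(0, tract_specs=specs, template=template) == []

    def test_same_seed_identical_masks(self, template, specs):
        a = make_lesion_cohort(4, seed=3, tract_specs=specs, template=template)
        b = make_lesion_cohort(4, seed=3, tract_specs=specs, template=template)
        for la, lb in zip(a, b):
            np.testing.assert_array_equal(la.data, lb.data)

    def test_infeasible_size_rejected(self, template, specs):
        with pytest.raises(ConfigurationError, match="infeasible"):
            make_lesion_cohort(1, size_range_mm=(100.0, 200.0),
                               tract_specs=specs, template=template)

    def test_masks_are_binary_and_nonempty(self, template, specs):
        for lesion in make_lesion_cohort(6, seed=1, tract_specs=specs,
                                         template=template):
            assert set(np.unique(lesion.data)) <= {0, 1}
            assert lesion.data.sum() > 0


class TestTruthLoads:
    def test_full_ablation_load_one(self, template, specs):
        """A lesion covering a tract cross-section severs every streamline."""
        atlas = make_tract_atlas(2, specs, jitter_mm=1.0, seed=4,
                                 template=template)
        spec = specs[0]
        center = spec.centerline[len(spec.centerline) // 2]
        lesion = make_lesion_cohort(  # deterministic big sphere via direct mask
            1, size_range_mm=(spec.radius + 2.0, spec.radius + 2.0),
            placement="uniform-over-grid", seed=0, template=template,
        )[0]
        # recentre the ellipsoid on the tract midpoint
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in template.grid],
                                 indexing="ij")
        world = (np.stack([ii, jj, kk], -1) @ template.affine[:3, :3].T
                 + template.affine[:3, 3])
        r = spec.radius + 2.0
        mask = (((world - center) / r) ** 2).sum(-1) <= 1.0
        lesion = template.with_data(mask.astype(np.uint8), volume_id="on_tract")
        loads, tract_ids = streamline_lesion_loads([lesion], atlas)
        assert tract_ids == [s.tract_id for s in specs]
        assert loads[0, 0] == 1.0
        assert loads[0, 1] == 0.0  # mirrored tract untouched

    def test_truth_agrees_with_disconnectome_module(self, template, specs):
        """Cross-module oracle agreement on a jitter-free atlas: the truth
        load equals the fraction of streamlines the disconnectome filter
        keeps."""
        from dsdkit.disconnectome import streamlines_through_lesion

        atlas = make_tract_atlas(3, specs, jitter_mm=0.0, seed=0,
                                 n_streamlines=4, template=template)
        lesions = make_lesion_cohort(5, seed=9, tract_specs=specs,
                                     template=template)
        loads, tract_ids = streamline_lesion_loads(lesions, atlas)
        for p, lesion in enumerate(lesions):
            kept = {t: 0 for t in tract_ids}
            total = {t: 0 for t in tract_ids}
            for b in atlas:
                f = streamlines_through_lesion(b, lesion)
                for lab in f.labels or []:
                    kept[lab] += 1
                for lab in b.labels:
                    total[lab] += 1
            for t, tid in enumerate(tract_ids):
                assert abs(loads[p, t] - kept[tid] / total[tid]) <= 0.05


class TestScores:
    def test_noiseless_scores_exactly_linear_in_loads(self, template, specs):
        atlas = make_tract_atlas(2, specs, jitter_mm=0.5, seed=2,
                                 template=template)
        lesions = make_lesion_cohort(12, seed=2, tract_specs=specs,
                                     template=template)
        W = np.array([[30.0, -10.0, 5.0]])
        table, truth = make_scores(lesions, atlas, W, noise_sd=0.0,
                                   max_scale=100.0, seed=2)
        X = np.column_stack([np.ones(12), truth.loads])
        beta, *_ = np.linalg.lstsq(X, table.values[:, 0], rcond=None)
        resid = table.values[:, 0] - X @ beta
        assert np.abs(resid).max() < 1e-8

    def test_zero_weights_give_intercept(self, template, specs):
        atlas = make_tract_atlas(1, specs, jitter_mm=0.0, seed=0,
                                 n_streamlines=2, template=template)
        lesions = make_lesion_cohort(5, seed=5, tract_specs=specs,
                                     template=template)
        table, _ = make_scores(lesions, atlas, np.zeros((1, 3)), noise_sd=0.0,
                               max_scale=60.0, seed=0)
        np.testing.assert_allclose(table.values[:, 0], 30.0)

    def test_planted_weight_shows_in_score_difference(self, template, specs):
        """Fully ablating tract A vs sparing it moves the score by the
        planted weight (noiseless)."""
        atlas = make_tract_atlas(2, specs, jitter_mm=1.0, seed=7,
                                 template=template)
        spec = specs[0]
        ii, jj, kk = np.meshgrid(*[np.arange(s) for s in template.grid],
                                 indexing="ij")
        world = (np.stack([ii, jj, kk], -1) @ template.affine[:3, :3].T
                 + template.affine[:3, 3])
        r = spec.radius + 2.0
        hit = (((world - spec.centerline[len(spec.centerline) // 2]) / r) ** 2
               ).sum(-1) <= 1.0
        far = (((world - np.array([30.0, 30.0, -30.0])) / 4.0) ** 2).sum(-1) <= 1.0
        lesions = [
            template.with_data(hit.astype(np.uint8), volume_id="hit"),
            template.with_data(far.astype(np.uint8), volume_id="spare"),
        ]
        W = np.array([[10.0, 0.0, 0.0]])
        table, truth = make_scores(lesions, atlas, W, noise_sd=0.0,
                                   max_scale=100.0, seed=0)
        assert truth.loads[0, 0] == 1.0
        assert truth.loads[1].max() == 0.0
        assert table.values[0, 0] - table.values[1, 0] == pytest.approx(10.0)

    def test_truth_matches_disconnectome_within_tract_mask(self, template, specs):
        """Mean disconnectome value inside a tract's own corridor tracks the
        truth load within 0.05 on a jitter-free atlas."""
        atlas = make_tract_atlas(2, specs[:2], jitter_mm=0.0, seed=0,
                                 n_streamlines=3, template=template)
        lesions = make_lesion_cohort(4, seed=11, tract_specs=specs[:2],
                                     template=template)
        loads, tract_ids = streamline_lesion_loads(lesions, atlas)
        norm = NormativeSet(atlas, template)
        # jitter-free: each tract occupies exactly its centerline corridor
        corridors = {}
        for spec in specs[:2]:
            acc = np.zeros(template.grid, bool)
            for b in atlas:
                for s, lab in zip(b.streamlines, b.labels):
                    if lab == spec.tract_id:
                        from dsdkit.disconnectome import _streamline_voxels

                        acc.reshape(-1)[
                            _streamline_voxels(s, template, 1.0)
                        ] = True
            corridors[spec.tract_id] = acc
        for p, lesion in enumerate(lesions):
            dmap = norm.map_for(lesion)
            for t, tid in enumerate(tract_ids):
                mean_in = dmap.volume.data[corridors[tid]].mean()
                assert abs(mean_in - loads[p, t]) <= 0.05
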