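"""Synthetic-study generators: determinism, planted structure, null behavior."""

import numpy as np
import pandas as pd
import pytest

from itemrsa import apm, iraf, rsm
from itemrsa import simulate as sm

from helpers import planted_truth, small_design, study_to_iraf


class TestGenFeatureNorms:
    def test_full_duplication_forces_identical_rsms(self):
        norms = sm.gen_feature_norms(4, 3, 3, cross_corr=1.0, seed=7)
        rv = rsm.build_model_rsm(norms, "visual")
        rs = rsm.build_model_rsm(norms, "semantic")
        assert np.linalg.norm(rv.values - rs.values) == pytest.approx(0.0, abs=1e-12)

    def test_determinism(self):
        a = sm.gen_feature_norms(10, 6, 5, cross_corr=0.4, seed=3)
        b = sm.gen_feature_norms(10, 6, 5, cross_corr=0.4, seed=3)
        assert np.array_equal(a.values, b.values)
        assert a.feature_ids == b.feature_ids

    def test_independent_blocks_have_near_zero_rsm_correlation(self):
        """Monte-Carlo estimate of the null RSM correlation across 200 seeds."""
        rhos = []
        for seed in range(200):
            norms = sm.gen_feature_norms(50, 30, 30, cross_corr=0.0, seed=seed)
            rv = rsm.build_model_rsm(norms, "visual")
            rs = rsm.build_model_rsm(norms, "semantic")
            rhos.append(abs(rsm.compare_rsms(rv, rs).global_rho))
        assert np.mean(rhos) < 0.15

    def test_rsm_overlap_increases_with_cross_corr(self):
        means = []
        for c in (0.0, 0.5, 1.0):
            rhos = [
                rsm.compare_rsms(
                    rsm.build_model_rsm(n, "visual"),
                    rsm.build_model_rsm(n, "semantic"),
                ).global_rho
                for n in (sm.gen_feature_norms(30, 20, 20, c, seed=s)
                          for s in range(10))
            ]
            means.append(np.mean(rhos))
        assert means[0] < means[1] < means[2]

    def test_invariants_enforced(self):
        norms = sm.gen_feature_norms(12, 8, 6, cross_corr=0.3, seed=1)
        assert (norms.values >= 0).all()
        assert ((norms.values > 0).sum(axis=0) >= 2).all()
        with pytest.raises(ValueError):
            sm.gen_feature_norms(10, 5, 5, cross_corr=1.5, seed=0)
        with pytest.raises(ValueError):
            sm.gen_feature_norms(10, 5, 5, cross_corr=np.nan, seed=0)


class TestGenBehavior:
    def test_extreme_bias_saturates(self):
        old, new = sm.gen_behavior(np.zeros(50), bias=50.0,
                                   thresholds=(-1, 0, 1), seed=0, n_new=50)
        assert (old == 4).all() and (new == 4).all()

    def test_unbiased_new_items_center_on_midscale(self):
        """Symmetric thresholds around 0 with no bias give E[response] = 2.5."""
        means = [
            sm.gen_behavior(np.zeros(0), bias=0.0, thresholds=(-1, 0, 1),
                            seed=seed, n_new=2000)[1].mean()
            for seed in range(10)
        ]
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means) - 2.5) < 2 * se

    def test_determinism_and_threshold_validation(self):
        theta = np.linspace(-1, 1, 20)
        a = sm.gen_behavior(theta, 0.2, (-1, 0, 1), seed=9, n_new=10)
        b = sm.gen_behavior(theta, 0.2, (-1, 0, 1), seed=9, n_new=10)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        with pytest.raises(ValueError):
            sm.gen_behavior(theta, 0.0, (1, 0, -1), seed=0)


class TestGenStudy:
    def test_determinism(self):
        norms = sm.gen_feature_norms(25, 10, 8, 0.3, seed=2)
        design = sm.StudyDesign(n_participants=2, n_old=12, n_catch=2, n_new=4,
                                roi_spec=[("r1", "OTC", 20)])
        truth = sm.uniform_effects(0.5, 0.5)
        a = sm.gen_study(design, truth, norms, seed=4)
        b = sm.gen_study(design, truth, norms, seed=4)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        for key in a.patterns:
            assert np.array_equal(a.patterns[key].values, b.patterns[key].values)

    def test_pattern_trial_ids_subset_of_table(self):
        norms = sm.gen_feature_norms(25, 10, 8, 0.3, seed=2)
        design = sm.StudyDesign(n_participants=2, n_old=12, n_catch=2, n_new=4,
                                roi_spec=[("r1", "OTC", 20)])
        study = sm.gen_study(design, sm.uniform_effects(0.5, 0.5), norms, seed=4)
        all_ids = set(study.trials["trial_id"])
        for betas in study.patterns.values():
            assert set(betas.trial_ids) <= all_ids

    def test_missing_weights_raise_configuration_error(self):
        norms = sm.gen_feature_norms(25, 10, 8, 0.3, seed=2)
        design = sm.StudyDesign(n_participants=1, n_old=12, n_catch=0, n_new=4,
                                roi_spec=[("r1", "other", 20)])
        truth = sm.PlantedEffects(
            {("OTC", "encoding", "remembered"): (1.0, 0.0)}, noise_sd=1.0
        )
        with pytest.raises(KeyError):
            sm.gen_study(design, truth, norms, seed=1)

    def test_visual_only_planting_yields_visual_dominant_iraf(self):
        """Near-noiseless, w_s = 0: each item's visual IRAF beats semantic."""
        norms = sm.gen_feature_norms(24, 12, 10, cross_corr=0.0, seed=6)
        design = sm.StudyDesign(n_participants=1, n_old=16, n_catch=0, n_new=4,
                                p_dont_know=0.0,
                                roi_spec=[("r1", "OTC", 200)])
        truth = sm.uniform_effects(1.0, 0.0, noise_sd=1e-6)
        study = sm.gen_study(design, truth, norms, seed=8)
        table = study_to_iraf(study)
        wide = table.pivot_table(
            index=["phase", "item"], columns="feature_type", values="iraf"
        )
        frac = (wide["visual"] > wide["semantic"]).mean()
        assert frac >= 0.95

    def test_null_success_planting_centers_contrast_on_zero(self):
        """Equal remembered/forgotten weights: the memory contrast is null."""
        diffs = []
        for seed in range(12):
            norms = sm.gen_feature_norms(30, 14, 12, 0.2, seed=seed)
            design = sm.StudyDesign(n_participants=3, n_old=20, n_catch=0,
                                    n_new=6, roi_spec=[("r1", "IPC", 40)])
            study = sm.gen_study(design, sm.uniform_effects(0.7, 0.7), norms,
                                 seed=seed + 50)
            table = study_to_iraf(study)
            means = table.groupby("memory")["iraf"].mean()
            diffs.append(means.get("remembered", 0.0) - means.get("forgotten", 0.0))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-3

    def test_planted_success_gap_recovers_sign(self):
        """Retrieval remembered > forgotten planted well above the
        3*sigma/sqrt(n_voxels) threshold recovers a positive contrast."""
        positive = 0
        n_seeds = 20
        for seed in range(n_seeds):
            norms = sm.gen_feature_norms(45, 24, 20, 0.2, seed=seed)
            study = sm.gen_study(small_design(), planted_truth(), norms,
                                 seed=seed + 1)
            table = study_to_iraf(study)
            sub = table[(table["roi_id"] == "ipc-ret")
                        & (table["phase"] == "retrieval")]
            means = sub.groupby("memory")["iraf"].mean()
            if means["remembered"] > means["forgotten"]:
                positive += 1
        assert positive >= 0.95 * n_seeds

    def test_insufficient_concepts_rejected(self):
        norms = sm.gen_feature_norms(10, 5, 5, 0.2, seed=0)
        design = sm.StudyDesign(n_participants=1, n_old=10, n_catch=2, n_new=4,
                                roi_spec=[("r1", "OTC", 10)])
        with pytest.raises(ValueError):
            sm.gen_study(design, sm.uniform_effects(1, 1), norms, seed=0)
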