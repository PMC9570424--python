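"""Synthetic TCSPC generator: parameter draws, layouts, photon statistics."""
import numpy as np
import pytest
from scipy import stats

from flimcyto import (AcquisitionConfig, CohortSpec, DEFAULT_GROUP_PROFILES,
                      GroupProfile, generate_cohort, inject_artifacts,
                      render_cell_layout, sample_cell_params,
                      simulate_tcspc_image)
from flimcyto.simulate import (A2_FLOOR, LayoutError, TM_MARGIN_PS,
                               decay_profile, expected_counts)

from conftest import biexp_expected


class TestSampleCellParams:
    def test_draws_respect_bounds_and_reconstruct_tm(self, default_config,
                                                     normal_profile):
        rng = np.random.default_rng(7)
        half = default_config.period_ps / 2
        for _ in range(200):
            a2, t2 = sample_cell_params(normal_profile, default_config, rng)
            assert A2_FLOOR <= a2 <= 1.0
            assert default_config.t1_ps <= t2 <= half
            tm = (1 - a2) * default_config.t1_ps + a2 * t2
            assert default_config.t1_ps <= tm <= half

    def test_reconstructed_tm_matches_truncated_normal_mean(
            self, default_config, normal_profile):
        # Monte-Carlo oracle: tm is drawn from a truncated normal, so the
        # mean of the reconstructed tm must match its analytic mean.
        rng = np.random.default_rng(11)
        n = 10_000
        tms = np.empty(n)
        for i in range(n):
            a2, t2 = sample_cell_params(normal_profile, default_config, rng)
            tms[i] = (1 - a2) * default_config.t1_ps + a2 * t2
        lo = default_config.t1_ps + TM_MARGIN_PS
        hi = default_config.period_ps / 2
        m, s = normal_profile.tm_mean_ps, normal_profile.tm_sd_ps
        expected = stats.truncnorm.mean((lo - m) / s, (hi - m) / s,
                                        loc=m, scale=s)
        se = tms.std() / np.sqrt(n)
        assert abs(tms.mean() - expected) < 3 * se + 1.0

    def test_invalid_profile_rejected(self, default_config):
        with pytest.raises(TypeError):
            sample_cell_params({"group": "CC"}, default_config, 0)
        with pytest.raises(ValueError):
            GroupProfile("x", tm_mean_ps=-5, tm_sd_ps=1,
                         a2_mean_pct=50, a2_sd_pct=1)


class TestRenderCellLayout:
    def test_requested_cell_count(self, small_config, normal_profile):
        phantoms, maps = render_cell_layout(5, normal_profile, small_config,
                                            seed=3)
        assert len(phantoms) == 5
        assert set(np.unique(maps["cell_label"])) == set(range(6))

    def test_zero_cells_gives_background_only(self, small_config,
                                              normal_profile):
        _, maps = render_cell_layout(0, normal_profile, small_config, seed=3)
        assert not maps["amplitude"].any()
        assert not maps["cell_label"].any()

    def test_deterministic_given_seed(self, small_config, normal_profile):
        _, a = render_cell_layout(4, normal_profile, small_config, seed=42)
        _, b = render_cell_layout(4, normal_profile, small_config, seed=42)
        for key in a:
            np.testing.assert_array_equal(a[key], b[key])

    def test_impossible_placement_raises(self, small_config, normal_profile):
        with pytest.raises(LayoutError):
            render_cell_layout(200, normal_profile, small_config, seed=1,
                               max_tries=5)


class TestSimulateImage:
    def test_zero_amplitude_zero_background_is_dark(self, small_config,
                                                    normal_profile):
        cfg = AcquisitionConfig(image_size_px=64, n_time_bins=32,
                                background_rate=0.0)
        _, maps = render_cell_layout(0, normal_profile, cfg, seed=5)
        img = simulate_tcspc_image(maps, cfg, seed=5)
        assert img.counts.sum() == 0

    def test_single_pixel_total_counts(self):
        cfg = AcquisitionConfig(image_size_px=32, n_time_bins=64,
                                background_rate=0.0)
        n = cfg.image_size_px
        maps = {"a2": np.full((n, n), 0.5), "t2": np.full((n, n), 2000.0),
                "amplitude": np.zeros((n, n))}
        maps["amplitude"][4, 4] = 10_000.0
        img = simulate_tcspc_image(maps, cfg, seed=9)
        total = img.counts[4, 4].sum()
        assert abs(total - 10_000) < 4 * np.sqrt(10_000)
        assert img.counts.sum() == total

    def test_degenerate_mixture_is_single_exponential(self, default_config):
        # a2 = 1 with t2 = t1 must give the same expected profile as a2 = 0
        p_mix = decay_profile(1.0, default_config.t1_ps, default_config)
        p_single = decay_profile(0.0, 5000.0, default_config)
        np.testing.assert_allclose(p_mix, p_single, atol=1e-12)

    def test_photon_conservation_in_expectation(self):
        cfg = AcquisitionConfig(image_size_px=32, n_time_bins=32,
                                background_rate=0.05)
        n = cfg.image_size_px
        amp = 300.0
        maps = {"a2": np.full((n, n), 0.8), "t2": np.full((n, n), 2500.0),
                "amplitude": np.full((n, n), amp)}
        img = simulate_tcspc_image(maps, cfg, seed=21)
        per_pixel = img.counts.sum(axis=2).astype(float)
        expected = amp + cfg.n_time_bins * cfg.background_rate
        se = per_pixel.std() / np.sqrt(per_pixel.size)
        assert abs(per_pixel.mean() - expected) < 3 * se

    def test_matches_dense_expectation(self, small_config, normal_profile):
        # sparse sampling path must target the same expectation surface
        _, maps = render_cell_layout(2, normal_profile, small_config, seed=8)
        dense = expected_counts(maps, small_config)
        cell = maps["cell_label"] > 0
        iy, ix = np.argwhere(cell)[0]
        a2, t2 = maps["a2"][iy, ix], maps["t2"][iy, ix]
        oracle = biexp_expected(a2, t2, maps["amplitude"][iy, ix],
                                small_config, small_config.background_rate)
        np.testing.assert_allclose(dense[iy, ix], oracle, rtol=1e-10)

    def test_non_finite_parameters_rejected(self, small_config):
        n = small_config.image_size_px
        maps = {"a2": np.full((n, n), np.nan), "t2": np.ones((n, n)),
                "amplitude": np.ones((n, n))}
        with pytest.raises(ValueError):
            simulate_tcspc_image(maps, small_config, seed=1)


class TestInjectArtifacts:
    @pytest.fixture()
    def clean(self, small_image):
        return small_image[0]

    def test_zero_severity_is_identity(self, clean):
        out = inject_artifacts(clean, "bright_debris", 0.0, seed=4)
        np.testing.assert_array_equal(out.counts, clean.counts)

    def test_bright_debris_outshines_cells(self, clean, small_image):
        _, _, maps = small_image
        out = inject_artifacts(clean, "bright_debris", 0.5, seed=4)
        cell = maps["cell_label"] > 0
        intensity = out.intensity()
        assert intensity[~cell].max() > intensity[cell].max()

    def test_neutrophil_coverage_matches_severity(self, clean, small_image):
        _, _, maps = small_image
        out = inject_artifacts(clean, "neutrophil_clutter", 0.5, seed=4)
        cell = maps["cell_label"] > 0
        diff = out.counts.sum(axis=2) - clean.counts.sum(axis=2)
        coverage = (diff[cell] > 0).sum() / cell.sum()
        assert abs(coverage - 0.5) < 0.1

    def test_unknown_kind_rejected(self, clean):
        with pytest.raises(ValueError):
            inject_artifacts(clean, "cosmic_rays", 0.5, seed=1)


class TestGenerateCohort:
    def test_training_split_structure(self, small_config):
        spec = CohortSpec(patients_per_group={"normal": 14, "CC": 5,
                                              "CINII/III": 4},
                          images_per_patient=2, seed=5)
        cohort = generate_cohort(spec, config=small_config)
        assert len(cohort.patients) == 23
        assert cohort.n_images == 46

    def test_zero_malignant_fraction_gives_all_normal(self, small_config):
        spec = CohortSpec(patients_per_group={"CC": 2},
                          malignant_image_fraction={"CC": 0.0},
                          images_per_patient=4, seed=6)
        cohort = generate_cohort(spec, config=small_config)
        labels = [r.truth_label for p in cohort.patients for r in p.images]
        assert set(labels) == {"normal"}

    def test_abnormal_count_within_binomial_interval(self, small_config):
        spec = CohortSpec(patients_per_group={"CINII/III": 4},
                          malignant_image_fraction={"CINII/III": 0.75},
                          images_per_patient=10, seed=17)
        cohort = generate_cohort(spec, config=small_config)
        n_abn = sum(r.truth_label == "abnormal"
                    for p in cohort.patients for r in p.images)
        lo, hi = stats.binom.ppf([0.005, 0.995], 40, 0.75)
        assert lo <= n_abn <= hi

    def test_mixture_consistency_on_parameter_maps(self, small_config):
        # every cell pixel's tm map must recombine from (a2, t2, t1)
        spec = CohortSpec(patients_per_group={"CC": 1},
                          images_per_patient=2, seed=3)
        cohort = generate_cohort(spec, config=small_config)
        for rec in cohort.patients[0].images:
            maps = rec.param_maps
            cell = maps["cell_label"] > 0
            recon = ((1 - maps["a2"][cell]) * small_config.t1_ps
                     + maps["a2"][cell] * maps["t2"][cell])
            np.testing.assert_allclose(recon, maps["tm"][cell], atol=1e-6)

    def test_bit_identical_given_seed(self, small_config):
        spec = CohortSpec(patients_per_group={"normal": 1, "CC": 1},
                          images_per_patient=2, seed=99)
        a = generate_cohort(spec, config=small_config)
        b = generate_cohort(spec, config=small_config)
        for pa, pb in zip(a.patients, b.patients):
            for ra, rb in zip(pa.images, pb.images):
                np.testing.assert_array_equal(ra.image.counts,
                                              rb.image.counts)
                assert ra.truth_label == rb.truth_label

    def test_group_separation_in_ground_truth(self, default_config):
        # CC vs normal drawn tm means should sit ~280 ps apart; oracle is
        # the analytic truncated-normal mean of each group's tm draw.
        rng = np.random.default_rng(23)
        lo = default_config.t1_ps + TM_MARGIN_PS
        hi = default_config.period_ps / 2
        means = {}
        for group in ("CC", "normal"):
            prof = DEFAULT_GROUP_PROFILES[group]
            tms = []
            for _ in range(2000):
                a2, t2 = sample_cell_params(prof, default_config, rng)
                tms.append((1 - a2) * default_config.t1_ps + a2 * t2)
            tms = np.asarray(tms)
            m, s = prof.tm_mean_ps, prof.tm_sd_ps
            analytic = stats.truncnorm.mean((lo - m) / s, (hi - m) / s,
                                            loc=m, scale=s)
            # clamping can only shift a small tail; 3 SE plus clamp margin
            assert abs(tms.mean() - analytic) < 3 * tms.std() / 45 + 15.0
            means[group] = tms.mean()
        assert 200.0 < means["normal"] - means["CC"] < 330.0
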