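"""Label geometry, cohort parameter sampling, Rician noise, cohort simulation."""

import numpy as np
import pytest

from cordmap import phantom
from cordmap.phantom import (
    CohortDesign,
    LesionEffectTable,
    RoiLabelScheme,
    SizingError,
    ConfigurationError,
    add_rician_noise,
    build_label_map,
    sample_cohort_parameters,
    simulate_cohort,
)


class TestLabelMap:
    def test_all_14_side_resolved_rois_present(self):
        scheme = RoiLabelScheme.default()
        labels = build_label_map((64, 64), scheme)
        assert set(np.unique(labels)) - {0} == set(scheme.labels)

    @pytest.mark.parametrize("grid", [(48, 48), (64, 64)])
    def test_every_roi_has_at_least_20_voxels(self, grid):
        scheme = RoiLabelScheme.default()
        labels = build_label_map(grid, scheme)
        for code in scheme.labels:
            assert (labels == code).sum() >= 20

    def test_dnr_lies_outside_the_cord(self):
        scheme = RoiLabelScheme.default()
        labels = build_label_map((64, 64), scheme)
        nx, ny = labels.shape
        x = np.arange(nx) - (nx - 1) / 2
        y = np.arange(ny) - (ny - 1) / 2
        xx, yy = np.meshgrid(x, y, indexing="ij")
        outside = (xx / 20) ** 2 + (yy / 16) ** 2 > 1
        for side in ("left", "right"):
            assert outside[labels == scheme.code_of("DNR", side)].all()

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(SizingError):
            build_label_map((8, 8))

    def test_scheme_must_cover_all_rois(self):
        with pytest.raises(ConfigurationError):
            RoiLabelScheme({1: ("VH", "left")})


class TestCohortSampling:
    def test_cv_zero_null_effects_reproduce_class_means(self):
        cohort = sample_cohort_parameters(
            CohortDesign(seed=0), between_subject_cv=0.0,
            effects=LesionEffectTable.null())
        means = phantom.default_class_means()
        for table in cohort.values():
            for (roi, _side), params in table.items():
                for pname in phantom.SAMPLED_PARAMS:
                    assert params[pname] == pytest.approx(means[roi][pname])

    def test_lesion_factor_applies_exactly_at_cv_zero(self):
        effects = LesionEffectTable({"DNR": {"psr": 0.646}})
        design = CohortDesign(seed=0, lesion_side="left")
        cohort = sample_cohort_parameters(design, between_subject_cv=0.0,
                                          effects=effects)
        pre = cohort[(1, 1, "pre")][("DNR", "left")]["psr"]
        post = cohort[(1, 1, "post")][("DNR", "left")]["psr"]
        contra = cohort[(1, 1, "post")][("DNR", "right")]["psr"]
        assert post == pytest.approx(0.646 * pre, rel=1e-12)
        assert contra == pytest.approx(pre, rel=1e-12)

    def test_same_seed_gives_identical_cohorts(self):
        a = sample_cohort_parameters(CohortDesign(seed=9))
        b = sample_cohort_parameters(CohortDesign(seed=9))
        assert a == b

    def test_eigenvalues_sorted_after_draw(self):
        cohort = sample_cohort_parameters(CohortDesign(seed=4),
                                          between_subject_cv=0.2)
        for table in cohort.values():
            for params in table.values():
                assert params["lambda1"] >= params["lambda2"] >= params["lambda3"] > 0

    def test_unknown_effect_key_rejected(self):
        with pytest.raises(ConfigurationError):
            LesionEffectTable({"DNR": {"psr2": 0.5}})
        with pytest.raises(ConfigurationError):
            LesionEffectTable({"XYZ": {"psr": 0.5}})


class TestRicianNoise:
    def test_zero_sigma_is_identity(self, rng):
        x = rng.uniform(0, 10, (5, 5))
        assert np.array_equal(add_rician_noise(x, 0.0, seed=0), x)

    def test_zero_signal_rayleigh_mean(self):
        noisy = add_rician_noise(np.zeros(200_000), 1.0, seed=2)
        assert noisy.mean() == pytest.approx(np.sqrt(np.pi / 2), abs=0.01)

    def test_high_snr_gaussian_limit(self):
        n, v, sigma = 100_000, 50.0, 1.0
        noisy = add_rician_noise(np.full(n, v), sigma, seed=3)
        se = sigma / np.sqrt(n)
        # Rician mean exceeds v by ~sigma^2/(2v); stays within 3 SE + bias
        assert abs(noisy.mean() - v) < 3 * se + sigma ** 2 / (2 * v)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), -1.0)


class TestSimulateCohort:
    def test_default_design_yields_16_bundles(self):
        design = CohortDesign(seed=0)
        bundles = simulate_cohort(design, noiseless=True)
        assert len(bundles) == 16
        assert set(bundles) == set(design.keys())

    def test_same_seed_bit_identical(self):
        d = CohortDesign(n_subjects=1, segments_per_subject=1, seed=5)
        b1 = simulate_cohort(d)
        b2 = simulate_cohort(d)
        for key in b1:
            for mod in ("dwi", "qmt", "zspec"):
                assert np.array_equal(getattr(b1[key], mod).data,
                                      getattr(b2[key], mod).data)

    def test_bundles_share_geometry_and_retain_truth(self):
        d = CohortDesign(n_subjects=1, segments_per_subject=1, seed=2)
        bundles = simulate_cohort(d, noiseless=True)
        labels = {id(b.labels) for b in bundles.values()}
        assert len(labels) == 1  # shared label map
        for b in bundles.values():
            assert set(b.truth) == {(n, s) for n in phantom.ROI_NAMES
                                    for s in phantom.SIDES}

    def test_null_cohort_sides_differ_only_by_noise(self):
        d = CohortDesign(n_subjects=1, segments_per_subject=1, seed=8)
        bundles = simulate_cohort(d, effects=LesionEffectTable.null(),
                                  between_subject_cv=0.0, noiseless=True)
        b = bundles[(1, 1, "post")]
        scheme = b.scheme
        for name in phantom.ROI_NAMES:
            left = b.qmt.data[b.labels == scheme.code_of(name, "left")]
            right = b.qmt.data[b.labels == scheme.code_of(name, "right")]
            assert np.allclose(left.mean(0), right.mean(0))
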