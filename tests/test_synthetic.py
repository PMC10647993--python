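"""Phantom and cohort generators: ground truth, determinism, conservation."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

from prmlung import prm, staging, synthetic
from prmlung.models import FEATURE_COLUMNS
from prmlung.synthetic import CohortConfig, PhantomConfig


class TestPhantomConfigValidation:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            PhantomConfig(class_fractions=(0.5, 0.5, 0.5, 0.0))

    def test_fractions_must_be_nonnegative(self):
        with pytest.raises(ValueError, match="non-negative"):
            PhantomConfig(class_fractions=(-0.1, 0.4, 0.7, 0.0))

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="32"):
            PhantomConfig(shape=(16, 64, 64))

    def test_per_lobe_fractions_must_cover_all_lobes(self):
        with pytest.raises(ValueError, match="lobes 1-5"):
            PhantomConfig(class_fractions={1: (0, 0, 1, 0)})


def test_lobe_geometry_five_disjoint_regions():
    lobes = synthetic.make_lobe_mask((48, 48, 48))
    present = set(np.unique(lobes))
    assert present == {0, 1, 2, 3, 4, 5}
    # each lobe has enough voxels to carry meaningful fractions
    for lobe in range(1, 6):
        assert (lobes == lobe).sum() > 500


def test_phantom_determinism_bit_identical():
    cfg = PhantomConfig(shape=(40, 40, 40), noise_sd=5.0, warp_amplitude=1.0, seed=13)
    a = synthetic.generate_phantom_pair(cfg)
    b = synthetic.generate_phantom_pair(cfg)
    assert np.array_equal(a.study.insp, b.study.insp)
    assert np.array_equal(a.study.exp, b.study.exp)
    assert np.array_equal(a.truth.labels, b.truth.labels)
    assert np.array_equal(a.applied_warp.displacement, b.applied_warp.displacement)


def test_every_in_mask_voxel_has_exactly_one_class():
    res = synthetic.generate_phantom_pair(PhantomConfig(shape=(40, 40, 40), seed=2))
    labels = res.truth.labels
    mask = res.study.lung_mask
    assert set(np.unique(labels[mask])) <= {1, 2, 3, 4}
    assert not labels[~mask].any()


def test_single_class_phantom_all_normal():
    cfg = PhantomConfig(shape=(40, 40, 40), class_fractions=(0.0, 0.0, 1.0, 0.0), seed=1)
    res = synthetic.generate_phantom_pair(cfg)
    st = res.study
    label_map = prm.compute_prm_map(st.insp, st.exp, st.lung_mask, spacing=st.spacing)
    assert np.array_equal(label_map.labels[st.lung_mask],
                          np.full(int(st.lung_mask.sum()), prm.LABEL_NORMAL))
    vec = prm.aggregate_regions(label_map, st.lobe_mask)
    assert vec["prm_whole_lung_normal_pct"] == pytest.approx(100.0)


def test_downstream_counts_equal_generator_assignment():
    """Zero noise, zero warp: classified counts match assigned counts exactly."""
    cfg = PhantomConfig(
        shape=(40, 40, 40), class_fractions=(0.25, 0.25, 0.25, 0.25), seed=7
    )
    res = synthetic.generate_phantom_pair(cfg)
    st = res.study
    label_map = prm.compute_prm_map(st.insp, st.exp, st.lung_mask, spacing=st.spacing)
    truth_counts = res.truth.class_counts(st.lung_mask)
    measured_counts = label_map.class_counts(st.lung_mask)
    assert measured_counts == truth_counts


def test_noisy_fraction_recovery_within_two_points():
    """5 HU noise against a >=1 HU guard band: recovered fractions stay close.

    The oracle is the Monte-Carlo misclassification probability computed by
    brute force from the noise-free HU samples: each voxel flips class only
    if its Gaussian noise crosses the distance to the -950/-856 threshold.
    """
    cfg = PhantomConfig(
        shape=(48, 48, 48), class_fractions=(0.1, 0.2, 0.7, 0.0), noise_sd=5.0, seed=9
    )
    res = synthetic.generate_phantom_pair(cfg)
    clean = synthetic.generate_phantom_pair(
        PhantomConfig(shape=(48, 48, 48), class_fractions=(0.1, 0.2, 0.7, 0.0),
                      noise_sd=0.0, seed=9)
    )
    st = res.study
    mask = st.lung_mask
    # brute-force oracle on the sampled HU values
    p_insp_flip = ndtr(-np.abs(clean.study.insp[mask] - prm.INSP_THRESHOLD_HU) / 5.0)
    p_exp_flip = ndtr(-np.abs(clean.study.exp[mask] - prm.EXP_THRESHOLD_HU) / 5.0)
    expected_flip = float(np.mean(1 - (1 - p_insp_flip) * (1 - p_exp_flip)))
    assert expected_flip < 0.02  # guard band keeps the error rate small

    label_map = prm.compute_prm_map(st.insp, st.exp, mask, spacing=st.spacing)
    vec = prm.aggregate_regions(label_map, st.lobe_mask)
    recovered = [vec[f"prm_whole_lung_{c}_pct"] for c in ("emph", "fsad", "normal", "uncat")]
    assert recovered == pytest.approx([10.0, 20.0, 70.0, 0.0], abs=2.0)


class TestCohortGenerator:
    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            CohortConfig(n_subjects=0)

    def test_determinism(self):
        cfg = CohortConfig(n_subjects=50, seed=5)
        a = synthetic.generate_cohort(cfg)
        b = synthetic.generate_cohort(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_column_order_fixed(self, cohort_noisy):
        assert list(cohort_noisy.columns) == synthetic.COHORT_COLUMNS
        assert list(cohort_noisy.columns[:72]) == prm.feature_names()

    def test_degenerate_cohort_all_intercept(self):
        cfg = CohortConfig(
            n_subjects=5, fsad_scale=0.0, emph_scale=0.0, uncat_scale=0.0,
            fvc_noise_sd=0.0, pct_noise_sd=0.0, seed=0,
        )
        df = synthetic.generate_cohort(cfg)
        assert np.allclose(df["fev1_pct"], cfg.pct_intercept)
        assert np.allclose(df["fev1_fvc"], cfg.fvc_intercept)
        assert df["group"].nunique() == 1
        assert np.allclose(df["prm_whole_lung_normal_pct"], 100.0)

    def test_percentages_sum_to_100_every_region(self, cohort_noisy):
        for region in prm.REGIONS:
            total = sum(
                cohort_noisy[f"prm_{region}_{c}_pct"]
                for c in ("emph", "fsad", "normal", "uncat")
            )
            assert np.allclose(total, 100.0, atol=1e-6)

    def test_regional_volumes_aggregate_consistently(self, cohort_noisy):
        lobes = ("right_upper", "right_middle", "right_lower", "left_upper", "left_lower")
        lobe_sum = sum(cohort_noisy[f"prm_{r}_lv_ml"] for r in lobes)
        assert np.allclose(lobe_sum, cohort_noisy["prm_whole_lung_lv_ml"])
        lr = cohort_noisy["prm_left_lung_lv_ml"] + cohort_noisy["prm_right_lung_lv_ml"]
        assert np.allclose(lr, cohort_noisy["prm_whole_lung_lv_ml"])
        for c in ("emph", "fsad", "normal", "uncat"):
            assert np.allclose(
                sum(cohort_noisy[f"prm_{r}_{c}_ml"] for r in lobes),
                cohort_noisy[f"prm_whole_lung_{c}_ml"],
            )

    def test_prm_percent_features_in_range(self, cohort_noisy):
        pct_cols = [c for c in prm.feature_names() if c.endswith("_pct")]
        vals = cohort_noisy[pct_cols].to_numpy()
        assert (vals >= 0).all() and (vals <= 100).all()

    def test_pft_values_clipped_to_domain(self, cohort_noisy):
        assert ((cohort_noisy["fev1_fvc"] > 0) & (cohort_noisy["fev1_fvc"] <= 1.2)).all()
        assert ((cohort_noisy["fev1_pct"] > 0) & (cohort_noisy["fev1_pct"] <= 1.6)).all()

    def test_labels_match_rules_on_noiseless_values(self, cohort_noiseless):
        expected = staging.classify_table(
            cohort_noiseless["fev1_fvc"], cohort_noiseless["fev1_pct"]
        )["group"]
        assert (cohort_noiseless["group"] == expected).all()

    def test_ols_recovers_generative_slopes(self, cohort_noisy):
        """OLS of FEV1% on whole-lung fSAD% and Emph% recovers the true slopes."""
        cfg = CohortConfig()  # the fixture's coefficients
        df = cohort_noisy
        inside = (df["fev1_pct"] > 0.02) & (df["fev1_pct"] < 1.58)  # drop clipped rows
        X = np.column_stack([
            np.ones(int(inside.sum())),
            df.loc[inside, "prm_whole_lung_fsad_pct"],
            df.loc[inside, "prm_whole_lung_emph_pct"],
        ])
        y = df.loc[inside, "fev1_pct"].to_numpy()
        beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = X.shape[0] - X.shape[1]
        sigma2 = float(res_ss[0]) / dof
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        truth = np.array([cfg.pct_intercept, cfg.pct_fsad_slope, cfg.pct_emph_slope])
        assert np.all(np.abs(beta - truth) < 3 * se)

    def test_feature_table_has_all_76_inputs(self, cohort_noisy):
        assert all(c in cohort_noisy.columns for c in FEATURE_COLUMNS)
        assert len(FEATURE_COLUMNS) == 76
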