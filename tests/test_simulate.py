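"""Synthetic cohort generator: lesions, staircase, noise structure."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.ndimage import label

from perilesion.lesions import distances_to_ga
from perilesion.model import SegmentedModelParams, mean_function
from perilesion.simulate import (
    DEFAULT_TRUE_PARAMS,
    LesionFieldConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_lesions,
    staircase_4_2,
)

SMALL_LESIONS = LesionFieldConfig(raster_size=160, sqrt_area_mean_deg=6.0, sqrt_area_sd_deg=1.0)


def small_config(**over):
    defaults = dict(
        n_participants=3,
        visit_months=(0.0, 3.0, 9.0),
        dropout_prob=0.0,
        lesions=SMALL_LESIONS,
        rng_seed=7,
    )
    defaults.update(over)
    return SimulationConfig(**defaults)


class TestStaircase:
    def test_threshold_at_start_is_measured_exactly(self):
        assert staircase_4_2(10.0) == (10.0, False)

    def test_absolute_scotoma_below_range(self):
        value, scotoma = staircase_4_2(-1.0)
        assert value == 0.0
        assert scotoma

    @pytest.mark.parametrize("threshold", range(0, 21))
    def test_integer_thresholds_within_two_db(self, threshold):
        value, scotoma = staircase_4_2(float(threshold))
        assert not scotoma
        assert abs(value - threshold) <= 2.0
        assert 0.0 <= value <= 20.0

    @given(st.floats(min_value=0.0, max_value=20.0, allow_nan=False))
    def test_any_threshold_within_two_db(self, threshold):
        value, scotoma = staircase_4_2(threshold)
        assert not scotoma
        assert abs(value - threshold) <= 2.0


class TestLesions:
    def test_zero_growth_keeps_masks_identical(self):
        cfg = small_config(
            lesions=dataclasses.replace(SMALL_LESIONS, growth_rate_deg_per_month=0.0)
        )
        masks = simulate_lesions(cfg)
        for pid in {k[0] for k in masks}:
            months = sorted(m for p, m in masks if p == pid)
            first = masks[(pid, months[0])].pixels
            for m in months[1:]:
                assert np.array_equal(masks[(pid, m)].pixels, first)

    def test_sqrt_area_grows_linearly(self):
        rate = 0.1
        lesions = dataclasses.replace(
            SMALL_LESIONS,
            n_foci_range=(1, 1),
            sqrt_area_mean_deg=3.0,
            sqrt_area_sd_deg=0.0,
            sqrt_area_min_deg=1.0,
            growth_rate_deg_per_month=rate,
        )
        cfg = small_config(n_participants=1, visit_months=(0.0, 6.0, 12.0), lesions=lesions)
        masks = simulate_lesions(cfg)
        for (pid, month), mask in masks.items():
            target_sqrt = 3.0 + rate * month
            # rasterization tolerance: one pixel-row of area around the contour
            perimeter_deg = 2 * np.pi * target_sqrt / np.sqrt(np.pi)
            area_tol = perimeter_deg * mask.deg_per_pixel
            assert mask.area_deg2 == pytest.approx(target_sqrt**2, abs=area_tol)

    def test_two_focus_config_gives_two_components(self):
        lesions = dataclasses.replace(
            SMALL_LESIONS,
            n_foci_range=(2, 2),
            sqrt_area_mean_deg=2.0,
            sqrt_area_sd_deg=0.0,
            center_offset_max_deg=8.0,
        )
        cfg = small_config(n_participants=2, visit_months=(0.0,), lesions=lesions)
        for mask in simulate_lesions(cfg).values():
            _, n = label(mask.pixels)
            assert n == 2

    def test_masks_deterministic_for_seed(self):
        a = simulate_lesions(small_config())
        b = simulate_lesions(small_config())
        assert a.keys() == b.keys()
        for k in a:
            assert np.array_equal(a[k].pixels, b[k].pixels)


class TestCohort:
    def test_bit_identical_for_fixed_seed(self):
        a = simulate_cohort(small_config())
        b = simulate_cohort(small_config())
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_noise_free_rounded_mode_equals_rounded_mean(self):
        cfg = small_config(sigma_u=0.0, sigma_e=0.0, measurement_mode="gaussian_rounded")
        cohort = simulate_cohort(cfg)
        loci = {l.locus_id: l for l in cohort.grid}
        for row in cohort.records.itertuples():
            mask = cohort.masks[(row.participant_id, row.visit_month)]
            d, inside = distances_to_ga([loci[row.locus_id]], mask)
            if inside[0]:
                assert row.scotoma and row.sensitivity_db == 0.0
            else:
                mu = mean_function(d[0], row.visit_month, cfg.true_params)
                assert row.sensitivity_db == np.clip(round(mu), 0, 20)

    def test_rounded_mode_values_are_integers_in_range(self):
        cohort = simulate_cohort(small_config(measurement_mode="gaussian_rounded"))
        vals = cohort.records["sensitivity_db"]
        assert ((vals >= 0) & (vals <= 20)).all()
        assert (vals == vals.round()).all()
        scot = cohort.records["scotoma"]
        assert (vals[scot] == 0).all()

    def test_staircase_mode_values_in_range(self):
        cohort = simulate_cohort(small_config(measurement_mode="staircase_4_2"))
        vals = cohort.records["sensitivity_db"]
        assert ((vals >= 0) & (vals <= 20)).all()

    def test_records_bounded_by_grid_times_visits(self):
        cfg = small_config(dropout_prob=0.3, rng_seed=11)
        cohort = simulate_cohort(cfg)
        per = cohort.records.groupby("participant_id").agg(
            n=("locus_id", "size"), visits=("visit_month", "nunique")
        )
        assert (per["n"] <= 40 * per["visits"]).all()
        # monotone dropout: attended visits are a prefix of the schedule
        for pid, months in cohort.records.groupby("participant_id")["visit_month"]:
            seen = sorted(months.unique())
            assert seen == list(cfg.visit_months[: len(seen)])

    def test_far_loci_more_sensitive_than_border_loci(self):
        from perilesion.lesions import annotate_dataset

        cfg = SimulationConfig(rng_seed=3, lesions=LesionFieldConfig(raster_size=256))
        cohort = simulate_cohort(cfg)
        ann = annotate_dataset(cohort.records, cohort.masks, cohort.grid)
        base = ann[(ann.visit_month == 0) & ~ann.inside_ga]
        far = base[base.ga_distance_deg >= 4.0]["sensitivity_db"].mean()
        near = base[base.ga_distance_deg < 1.0]["sensitivity_db"].mean()
        assert far > near

    def test_compound_symmetry_of_cluster_noise(self):
        # many single-visit clusters, continuous mode, then ANOVA-style
        # variance decomposition of residuals about the known mean surface
        cfg = SimulationConfig(
            n_participants=60,
            visit_months=(0.0,),
            dropout_prob=0.0,
            sigma_u=2.0,
            sigma_e=3.0,
            lesions=dataclasses.replace(SMALL_LESIONS, raster_size=128),
            measurement_mode="gaussian",
            rng_seed=21,
        )
        cohort = simulate_cohort(cfg)
        from perilesion.lesions import annotate_dataset

        ann = annotate_dataset(cohort.records, cohort.masks, cohort.grid)
        ext = ann[~ann.inside_ga].copy()
        mu = mean_function(
            ext.ga_distance_deg.to_numpy(), ext.visit_month.to_numpy(), cfg.true_params
        )
        ext["resid"] = ext.sensitivity_db.to_numpy() - mu
        groups = ext.groupby("participant_id")["resid"]
        within_var = groups.apply(lambda r: r.var(ddof=1)).mean()
        n_bar = groups.size().mean()
        between_var = groups.mean().var(ddof=1) - within_var / n_bar
        assert within_var == pytest.approx(cfg.sigma_e**2, rel=0.25)
        assert between_var == pytest.approx(cfg.sigma_u**2, rel=0.45)

    def test_empty_cohort_allowed(self):
        cohort = simulate_cohort(small_config(n_participants=0))
        assert len(cohort.records) == 0
        assert len(cohort.masks) == 0


def test_latent_sensitivity_is_single_source_of_truth():
    from perilesion.simulate import latent_sensitivity

    p = DEFAULT_TRUE_PARAMS
    d = np.linspace(0, 8, 30)
    assert np.allclose(latent_sensitivity(d, 12.0, p), mean_function(d, 12.0, p))
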