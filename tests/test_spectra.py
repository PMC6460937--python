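"""Spectral metrics and the neural/artefact sorting rule."""

import numpy as np
import pytest

from netmosaic.config import SimulationConfig
from netmosaic.cohort import generate_cohort
from netmosaic.exceptions import ValidationError
from netmosaic.ica import zscore_rows
from netmosaic.spectra import (
    classify_components,
    component_metrics,
    compute_dynamic_range,
    compute_falff_ratio,
    compute_gm_overlap,
    power_spectrum,
)


class TestPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(128) * 3.0
        x = np.sin(2 * np.pi * 0.05 * t)
        freqs, power, flagged = power_spectrum(x, 3.0)
        assert not flagged
        assert abs(freqs[np.argmax(power)] - 0.05) <= freqs[1] - freqs[0]

    def test_parseval_normalization_exact(self, rng):
        x = rng.normal(size=200)
        freqs, power, _ = power_spectrum(x, 3.0)
        integral = power.sum() * (freqs[1] - freqs[0])
        assert integral == pytest.approx(x.var(), rel=1e-6)

    def test_constant_series_zero_spectrum_flagged(self):
        freqs, power, flagged = power_spectrum(np.full(64, 3.0), 3.0)
        assert flagged
        assert (power == 0).all()

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            power_spectrum(np.ones(5), 3.0)


class TestFalff:
    def test_flat_spectrum_gives_exactly_one(self):
        freqs = np.linspace(0, 0.25, 501)
        ratio = compute_falff_ratio(freqs, np.full_like(freqs, 2.7))
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_tone_plus_floor_analytic(self):
        # constructed PSD: constant floor c plus a triangular tone at 0.05 Hz
        c = 0.4
        freqs = np.linspace(0, 0.25, 2501)
        power = np.full_like(freqs, c)
        df = freqs[1] - freqs[0]
        tone_area = 1.8
        i = np.argmin(np.abs(freqs - 0.05))
        power[i] += tone_area / df  # delta-like spike, trapezoid area ~ tone_area
        expected = (tone_area + 0.10 * c) / (0.10 * c)
        assert compute_falff_ratio(freqs, power) == pytest.approx(expected, rel=1e-3)

    def test_high_frequency_dominated_ratio_below_one(self):
        freqs = np.linspace(0, 0.25, 101)
        power = np.where(freqs >= 0.15, 5.0, 0.01)
        assert compute_falff_ratio(freqs, power) < 1

    def test_scalar_invariance(self, rng):
        x = rng.normal(size=120)
        f1, p1, _ = power_spectrum(x, 3.0)
        f2, p2, _ = power_spectrum(7.5 * x, 3.0)
        assert compute_falff_ratio(f1, p1) == pytest.approx(
            compute_falff_ratio(f2, p2), rel=1e-9
        )

    def test_nyquist_below_band_rejected(self):
        freqs = np.linspace(0, 0.05, 30)
        with pytest.raises(ValidationError, match="Nyquist"):
            compute_falff_ratio(freqs, np.ones_like(freqs))


class TestDynamicRange:
    def test_flat_spectrum_is_zero(self):
        freqs = np.linspace(0, 0.16, 30)
        rng_val, flagged = compute_dynamic_range(freqs, np.full_like(freqs, 1.0))
        assert rng_val == 0.0

    def test_constructed_peak_and_minimum(self):
        freqs = np.linspace(0, 0.25, 26)
        power = np.full_like(freqs, 1.0)
        power[3] = 10.0    # peak at 0.03 Hz
        power[20] = 0.5    # minimum at 0.20 Hz
        rng_val, flagged = compute_dynamic_range(freqs, power)
        assert rng_val == pytest.approx(9.5)
        assert not flagged

    def test_monotone_decreasing_spectrum(self):
        freqs = np.linspace(0, 0.16, 40)
        power = np.exp(-freqs * 20)
        rng_val, _ = compute_dynamic_range(freqs, power)
        assert rng_val == pytest.approx(power[0] - power[-1])

    def test_peak_at_last_bin_flagged(self):
        rng_val, flagged = compute_dynamic_range(np.array([0.0, 0.1]), np.array([1.0, 2.0]))
        assert rng_val == 0.0
        assert flagged


class TestGmOverlap:
    def test_entirely_inside_and_outside(self):
        gm = np.zeros(100, dtype=bool)
        gm[:50] = True
        comp = np.zeros(100)
        comp[:10] = 5.0
        assert compute_gm_overlap(comp, gm)[0] == 1.0
        comp2 = np.zeros(100)
        comp2[60:70] = 5.0
        assert compute_gm_overlap(comp2, gm)[0] == 0.0

    def test_half_in_half_out(self):
        gm = np.zeros(100, dtype=bool)
        gm[:50] = True
        comp = np.zeros(100)
        comp[45:55] = -4.0  # negative side counts too (|z| rule)
        assert compute_gm_overlap(comp, gm)[0] == pytest.approx(0.5)

    def test_no_suprathreshold_flagged(self):
        frac, flagged = compute_gm_overlap(np.zeros(50), np.ones(50, dtype=bool))
        assert frac == 0.0
        assert flagged


class TestClassification:
    @pytest.mark.parametrize("seed", range(10))
    def test_ground_truth_partition_recovered_every_seed(self, seed):
        """Planted network sources classify as neural and planted artefact
        sources as artefact, using generator ground truth components."""
        cfg = SimulationConfig(
            n_subjects_per_sex=10, n_timepoints=120, rng_seed=seed
        )
        cohort = generate_cohort(cfg)
        truth = cohort.truth
        mask_idx = np.flatnonzero(truth.mask.ravel())
        gm_flat = truth.gm_mask.ravel()[mask_idx]
        zmaps, _ = zscore_rows(truth.source_maps[:, mask_idx])
        metrics = [
            component_metrics(
                zmaps[c], truth.subject_timecourses[:, c, :], cfg.tr_seconds, gm_flat
            )
            for c in range(cfg.n_sources)
        ]
        labels = classify_components(metrics)
        for c in range(cfg.n_sources):
            expected = "neural" if c in truth.neural_indices else "artefact"
            assert labels[c].decision == expected, (seed, c, metrics[c])

    def test_thresholds_inclusive_at_boundary(self):
        from netmosaic.spectra import SpectralMetrics

        m = SpectralMetrics(falff_ratio=2.0, dynamic_range=1.0, gm_overlap=0.5)
        labels = classify_components([m], dynamic_range_min=1.0)
        assert labels[0].decision == "neural"
        assert labels[0].reasons == []

    def test_all_fail_lists_three_reasons(self):
        from netmosaic.spectra import SpectralMetrics

        m = SpectralMetrics(falff_ratio=0.1, dynamic_range=0.0, gm_overlap=0.0)
        labels = classify_components([m], dynamic_range_min=1.0)
        assert labels[0].decision == "artefact"
        assert len(labels[0].reasons) == 3

    def test_single_near_miss_marked_mixed_but_discarded(self):
        from netmosaic.spectra import SpectralMetrics

        m = SpectralMetrics(falff_ratio=1.9, dynamic_range=5.0, gm_overlap=0.9)
        labels = classify_components([m], dynamic_range_min=1.0)
        assert labels[0].decision == "artefact"
        assert labels[0].mixed

    def test_retention_ratio_with_balanced_noise_sources(self):
        """Cohorts built with ~40-50% artefact sources discard a fraction
        of components in [0.3, 0.6]."""
        for seed in (0, 1, 2):
            cfg = SimulationConfig(
                n_subjects_per_sex=8,
                n_timepoints=120,
                n_neural_sources=5,
                n_noise_sources=4,
                rng_seed=seed,
            )
            cohort = generate_cohort(cfg)
            truth = cohort.truth
            mask_idx = np.flatnonzero(truth.mask.ravel())
            gm_flat = truth.gm_mask.ravel()[mask_idx]
            zmaps, _ = zscore_rows(truth.source_maps[:, mask_idx])
            metrics = [
                component_metrics(
                    zmaps[c], truth.subject_timecourses[:, c, :], 3.0, gm_flat
                )
                for c in range(cfg.n_sources)
            ]
            labels = classify_components(metrics)
            discarded = sum(l.decision == "artefact" for l in labels) / len(labels)
            assert 0.3 <= discarded <= 0.6
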