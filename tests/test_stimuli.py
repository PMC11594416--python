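"""Stimulus generation: rendering conventions, labeling, sampling ranges,
determinism, and the energy-condition tables."""

import numpy as np
import pytest

from sdtnet import stimuli
from sdtnet.stimuli import (
    ENERGY_CONDITIONS, LEVELS, TRAINING_RANGES, EnergyCondition,
    StimulusParams, make_color_array, make_gabor_array, make_single_gabor,
    make_superimposed, make_test_set, make_training_set, render_gabor,
)


class TestRenderGabor:
    def test_zero_contrast_zero_noise_is_uniform_gray(self):
        patch = render_gabor(30.0, 0.0, size=30, noise_sd=0.0)
        assert np.allclose(patch, 0.5)

    def test_orientation_period_180_up_to_phase_sign(self):
        a = render_gabor(20.0, 0.8, size=30, noise_sd=0.0)
        b = render_gabor(200.0, 0.8, size=30, noise_sd=0.0)
        # odd carrier phase: rotating by 180 deg negates the pattern
        assert np.allclose(a - 0.5, -(b - 0.5), atol=1e-10)

    @pytest.mark.parametrize("orientation", [0.0, 17.0, 45.0, 90.0, 133.0])
    def test_noise_free_mean_is_half(self, orientation):
        patch = render_gabor(orientation, 1.0, size=30, noise_sd=0.0)
        assert abs(patch.mean() - 0.5) < 0.01

    def test_peak_to_trough_equals_contrast(self):
        for contrast in (0.3, 1.0):
            patch = render_gabor(135.0, contrast, size=100, noise_sd=0.0)
            assert abs(np.ptp(patch) - contrast) < 0.01

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            render_gabor(np.nan, 0.5)
        with pytest.raises(ValueError):
            render_gabor(0.0, 1.5)
        with pytest.raises(ValueError):
            render_gabor(0.0, 0.5, size=4)
        with pytest.raises(ValueError):
            render_gabor(0.0, 0.5, noise_sd=-1)


class TestGaborArray:
    def test_zero_orientation_sd_gives_identical_patches(self):
        s = make_gabor_array(5.0, 0.0, 0.8, noise_sd=0.0, seed=3)
        cells = [s.pixels[r * 30:(r + 1) * 30, c * 30:(c + 1) * 30]
                 for r in range(3) for c in range(3) if (r, c) != (1, 1)]
        for cell in cells[1:]:
            assert np.allclose(cell, cells[0])

    def test_center_cell_is_empty_gray(self):
        s = make_gabor_array(5.0, 3.0, 0.9, noise_sd=0.0, seed=4)
        assert np.allclose(s.pixels[30:60, 30:60], 0.5)

    def test_realized_orientation_mean_matches_generative_mean(self):
        vals = []
        for i in range(3000):
            s = make_gabor_array(5.0, 10.0, 0.05, noise_sd=0.0, seed=i)
            vals.extend(s.params.realized)
        assert abs(np.mean(vals) - 5.0) < 0.2

    def test_label_follows_sign_of_mean_tilt(self):
        assert make_gabor_array(-3.0, 1.0, 0.5, seed=0).label == 0
        assert make_gabor_array(3.0, 1.0, 0.5, seed=0).label == 1

    def test_canvas_size(self):
        assert make_gabor_array(2.0, 1.0, 0.5, seed=0).pixels.shape == (90, 90)


class TestSuperimposed:
    def test_limit_case_single_clean_grating(self):
        s = make_superimposed(0.6, 0.0, 1, noise_sd=0.0, seed=0)
        ref = 0.5 + 0.5 * 0.6 * stimuli._grating_pattern(90.0 + 45.0, 100)
        assert np.allclose(s.pixels, np.clip(ref, 0, 1), atol=1e-12)

    def test_image_is_superposition_of_components(self):
        s = make_superimposed(0.5, 0.3, 0, noise_sd=0.0, seed=0)
        dom = make_superimposed(0.5, 0.0, 0, noise_sd=0.0, seed=0).pixels - 0.5
        nond = make_superimposed(0.3, 0.0, 1, noise_sd=0.0, seed=0).pixels - 0.5
        # components rendered alone, recombined about the gray background
        assert np.allclose(s.pixels, np.clip(0.5 + dom + nond, 0, 1), atol=1e-12)

    def test_swapping_contrasts_flips_label(self):
        a = make_superimposed(0.5, 0.3, 1, noise_sd=0.0, seed=0)
        b = make_superimposed(0.5, 0.3, 0, noise_sd=0.0, seed=0)
        assert a.label == 1 and b.label == 0
        # the dominant grating carries the label either way
        assert not np.allclose(a.pixels, b.pixels)

    def test_dominance_violation_rejected(self):
        with pytest.raises(ValueError):
            make_superimposed(0.3, 0.5, 1)
        with pytest.raises(ValueError):
            make_superimposed(0.3, 0.3, 1)


class TestSingleGabor:
    def test_label_orientation_convention(self):
        cw = make_single_gabor(1.0, 0.0, 1, seed=0)
        ccw = make_single_gabor(1.0, 0.0, 0, seed=0)
        assert cw.pixels.shape == (100, 100)
        assert not np.allclose(cw.pixels, ccw.pixels)
        # CW and CCW are mirror images about the vertical axis, up to the
        # sign of the odd carrier phase
        assert np.allclose(cw.pixels - 0.5, -(ccw.pixels[:, ::-1] - 0.5),
                           atol=1e-10)

    def test_noise_field_sd(self):
        rng = np.random.default_rng(0)
        sds = []
        for i in range(30):
            s = make_single_gabor(0.0, 0.5, 0, seed=i)
            # contrast 0: the pre-clip image is 0.5 + noise; estimate the
            # noise SD from the unclipped central mass via the IQR
            flat = s.pixels.ravel()
            iqr = np.percentile(flat, 75) - np.percentile(flat, 25)
            sds.append(iqr / 1.3489795)
        assert abs(np.mean(sds) - 0.5) < 0.02


class TestColorArray:
    def test_pure_red_when_c0_v0(self):
        s = make_color_array(0.0, 0.0, seed=0)
        assert s.label == 0
        cell = s.pixels[0:30, 0:30]
        mask = stimuli._CIRCLE
        assert np.allclose(cell[mask], [1.0, 0.0, 0.0])

    def test_c1_is_blue_labelled(self):
        s = make_color_array(1.0, 0.0, seed=0)
        assert s.label == 1
        assert np.allclose(s.pixels[0:30, 0:30][stimuli._CIRCLE], [0, 0, 1])

    def test_realized_intensity_spread_matches_uniform_sd(self):
        vals = []
        for i in range(4000):
            s = make_color_array(0.5, 0.6, seed=i)
            vals.extend(s.params.realized)
        assert abs(np.std(vals) - 0.6 / np.sqrt(12)) < 0.01

    def test_negative_spread_rejected(self):
        with pytest.raises(ValueError):
            make_color_array(0.5, -0.1)


class TestSets:
    def test_training_set_is_deterministic(self):
        a = make_training_set("single_gabor", n=5, seed=9)
        b = make_training_set("single_gabor", n=5, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.pixels, sb.pixels)
            assert sa.label == sb.label

    @pytest.mark.parametrize("experiment", stimuli.EXPERIMENTS)
    def test_training_set_ranges_balance_clipping(self, experiment):
        n = 600
        samples = make_training_set(experiment, n=n, seed=1)
        assert len(samples) == n
        labels = np.array([s.label for s in samples])
        se = 0.5 / np.sqrt(n)
        assert abs(labels.mean() - 0.5) < 3 * se
        for s in samples[:50]:
            assert s.pixels.min() >= 0.0 and s.pixels.max() <= 1.0
        if experiment == "single_gabor":
            c = np.array([s.params.contrast for s in samples])
            lo, hi = TRAINING_RANGES["single_gabor"]["contrast"]
            assert c.min() >= lo and c.max() <= hi
            assert (c.max() - c.min()) >= 0.95 * (hi - lo)

    def test_test_set_uses_printed_condition_parameters(self):
        high = make_test_set("single_gabor", "high", n=8, seed=2)
        for s in high:
            assert s.params.contrast == 0.15 and s.params.noise_sd == 1.21
        low = make_test_set("superimposed", "low", n=4, seed=2)
        for s in low:
            assert s.params.contrast == 0.2
            assert s.params.nondominant_contrast == 0.168

    def test_empty_test_set_and_bad_condition(self):
        assert make_test_set("single_gabor", "low", n=0, seed=0) == []
        with pytest.raises(ValueError):
            make_test_set("single_gabor", EnergyCondition("gabor_array", "low"))
        with pytest.raises(ValueError):
            make_test_set("single_gabor", "ultra")

    def test_energy_tables_jointly_increase(self):
        for exp, table in ENERGY_CONDITIONS.items():
            rows = [table[lvl] for lvl in LEVELS]
            for key in rows[0]:
                vals = [r[key] for r in rows]
                if exp == "color_array" and key == "color_intensity":
                    vals = [abs(v - 0.5) for v in vals]
                assert vals[0] < vals[1] < vals[2], (exp, key)


def test_params_validation():
    with pytest.raises(ValueError):
        StimulusParams(experiment="nope", label=0)
    with pytest.raises(ValueError):
        StimulusParams(experiment="single_gabor", label=0, contrast=2.0)
    with pytest.raises(ValueError):
        StimulusParams(experiment="superimposed", label=0, contrast=0.2,
                       nondominant_contrast=0.5)


def test_save_set_roundtrip(tmp_path):
    from PIL import Image
    import csv

    samples = make_training_set("color_array", n=3, seed=0)
    manifest = stimuli.save_set(samples, tmp_path / "set")
    rows = list(csv.DictReader(open(manifest)))
    assert len(rows) == 3
    img = np.asarray(Image.open(tmp_path / "set" / rows[0]["filename"]))
    assert img.shape == (90, 90, 3)
    assert np.allclose(img / 255.0, samples[0].pixels, atol=1 / 255.0)
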