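"""Synthetic scene generator: click waveforms, trains, scenes, labelled bins."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from clicktypes import synth
from clicktypes.detection import GRID_KHZ, click_spectrum, detect_clicks
from clicktypes.features import spectral_peaks
from clicktypes.templates import builtin_templates, template


class TestClickWaveform:
    def test_kogia_peak_recovered(self):
        """Kogia clicks put their median spectral argmax on the 93.5 kHz peak."""
        t = template("kogia")
        argmaxes = []
        for seed in range(15):
            wave = synth.synth_click_waveform(t, t.preferred_duration_us(),
                                              200_000, seed=seed)
            spec = click_spectrum(wave, 200_000)
            argmaxes.append(GRID_KHZ[np.argmax(spec)])
        assert 92.5 <= np.median(argmaxes) <= 94.5

    def test_length_matches_duration(self):
        t = template("kogia")
        wave = synth.synth_click_waveform(t, 30, 200_000, seed=0)
        assert len(wave) == 6
        assert np.all(np.isfinite(wave))

    def test_determinism_and_seed_sensitivity(self):
        t = template("cuvier_beaked_whale")
        a = synth.synth_click_waveform(t, 400, 200_000, seed=7)
        b = synth.synth_click_waveform(t, 400, 200_000, seed=7)
        c = synth.synth_click_waveform(t, 400, 200_000, seed=8)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("duration_us", [10, 29.9, 1201, 5000])
    def test_duration_out_of_range_rejected(self, duration_us):
        with pytest.raises(ValueError):
            synth.synth_click_waveform(template("kogia"), duration_us, 200_000)

    @pytest.mark.parametrize("name", [t.name for t in builtin_templates()])
    def test_peaks_and_band_energy(self, name):
        """Median realized peaks sit within ±1 kHz of the template; < 5% of
        energy leaks outside the 10–100 kHz band; the dominant peak's −3 dB
        bandwidth is realized within ±30%.

        Peak location of a random-phase transient is estimated as the median
        over phase realizations — the same statistic the descriptor pipeline
        reports — because single realizations near the Nyquist edge (the
        Kogia peak) wobble with the phase of the folded spectral tail.
        """
        t = template(name)
        fs = 200_000
        n_fft = 8192
        freqs = np.fft.rfftfreq(n_fft, 1 / fs) / 1e3
        peak_sets, bws = [], []
        for seed in range(15):
            wave = synth.synth_click_waveform(t, t.preferred_duration_us(), fs,
                                              seed=seed)
            power = np.abs(np.fft.rfft(wave, n_fft)) ** 2
            in_band = power[(freqs >= 10) & (freqs <= 100)].sum()
            assert in_band / power.sum() > 0.95
            spec_db = 10 * np.log10(power + power.max() * 1e-12)
            found = spectral_peaks(spec_db, max_peaks=len(t.spectral_peaks),
                                   grid_khz=freqs)
            peak_sets.append(found)
            main = t.main_peak
            best = min(found, key=lambda p: abs(p[0] - main.freq_khz))
            bws.append(best[1])
        for want in t.spectral_peaks:
            nearest = [min(found, key=lambda p: abs(p[0] - want.freq_khz))[0]
                       for found in peak_sets]
            assert abs(np.median(nearest) - want.freq_khz) <= 1.0, (name, want)
        main = t.main_peak
        assert abs(np.median(bws) - main.bandwidth_khz) <= 0.3 * main.bandwidth_khz + 1.0


class TestClickTrain:
    def test_cuvier_gap_mean(self):
        """Mean of 5000 Cuvier gaps matches the Gaussian ICI model.

        Monte-Carlo oracle: gaps ~ N(0.433, 0.059) truncated at 5 ms, whose
        truncation effect on the mean is < 1e-9 s at this mode/sd.
        """
        times = synth.synth_click_train(template("cuvier_beaked_whale"), 5001, seed=2)
        gaps = np.diff(times)
        assert 0.427 <= gaps.mean() <= 0.439

    def test_two_clicks_one_positive_gap(self):
        times = synth.synth_click_train(template("kogia"), 2, seed=0)
        assert len(times) == 2 and times[1] > times[0]

    def test_strictly_increasing_and_truncated(self):
        times = synth.synth_click_train(template("stenellid_1"), 2000, seed=4)
        gaps = np.diff(times)
        assert np.all(gaps > 0.005 - 1e-12)

    def test_rejects_single_click(self):
        with pytest.raises(ValueError):
            synth.synth_click_train(template("kogia"), 1)

    def test_false_killer_whale_bimodal(self):
        """The false-killer-whale gap histogram shows both ICI modes.

        The 166 ms mode is broad (sd 109 ms), so the inter-mode dip is only
        a few percent of its height; a large sample keeps the check several
        sigma above counting noise.
        """
        times = synth.synth_click_train(template("false_killer_whale"), 400_001,
                                        seed=9)
        gaps = np.diff(times)
        gaps = gaps[gaps <= 0.6]
        hist, edges = np.histogram(gaps, bins=60, range=(0, 0.6))
        centers = (edges[:-1] + edges[1:]) / 2
        w_first = (centers > 0.005) & (centers < 0.08)
        w_second = (centers > 0.13) & (centers < 0.25)
        w_trough = (centers >= 0.09) & (centers <= 0.13)
        trough = hist[w_trough].min()
        assert hist[w_first].max() > trough
        assert hist[w_second].max() > trough
        assert abs(centers[w_first][np.argmax(hist[w_first])] - 0.0284) < 0.02
        assert abs(centers[w_second][np.argmax(hist[w_second])] - 0.166) < 0.04

    def test_truncated_gaussian_against_scipy_oracle(self, rng):
        """Gap quantiles match scipy's truncated normal at matched parameters."""
        t = template("kogia")
        gaps = np.diff(synth.synth_click_train(t, 20_001, seed=13))
        a = (0.005 - t.modal_ici_s) / t.ici_sd_s
        ref = truncnorm.rvs(a, np.inf, loc=t.modal_ici_s, scale=t.ici_sd_s,
                            size=20_000, random_state=rng)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            assert abs(np.quantile(gaps, q) - np.quantile(ref, q)) < 0.003


class TestRenderScene:
    def _config(self, trains=(), seed=0, duration_s=5.0):
        return synth.SceneConfig(fs_hz=200_000, duration_s=duration_s,
                                 trains=trains, seed=seed)

    def test_empty_scene_has_empty_truth(self):
        audio, truth = synth.render_scene(self._config())
        assert len(truth) == 0
        assert len(audio) == 5 * 200_000

    def test_determinism(self):
        cfg = self._config(
            trains=(synth.TrainSpec(template("kogia"), 0.2, 10, (125, 135)),), seed=5
        )
        a1, t1 = synth.render_scene(cfg)
        a2, t2 = synth.render_scene(cfg)
        np.testing.assert_array_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_high_snr_clicks_are_recoverable(self):
        """An end-to-end oracle: ≥95% of well-separated 130 dB clicks detected."""
        cfg = synth.SceneConfig(
            fs_hz=200_000, duration_s=30.0,
            trains=(synth.TrainSpec(template("cuvier_beaked_whale"), 0.5, 60,
                                    (129.0, 131.0)),),
            noise=synth.NoiseSpec(background_rms=1.0), seed=21,
        )
        audio, truth = synth.render_scene(cfg)
        dets = detect_clicks(audio, cfg.fs_hz, calibration_db=cfg.calibration_db)
        det_times = np.array([d.time_s for d in dets])
        matched = sum(np.min(np.abs(det_times - t)) < 5e-4 for t in truth["time_s"])
        assert matched >= 0.95 * len(truth)

    def test_rl_scaling_matches_calibration(self):
        """Injected peak-to-peak amplitude follows the stated dB convention."""
        cfg = synth.SceneConfig(
            fs_hz=200_000, duration_s=3.0,
            trains=(synth.TrainSpec(template("kogia"), 1.0, 2, (130.0, 130.0)),),
            noise=synth.NoiseSpec(background_rms=0.0), seed=1,
        )
        audio, truth = synth.render_scene(cfg)
        p2p = audio.max() - audio.min()
        rl = 20 * np.log10(p2p) + cfg.calibration_db
        assert abs(rl - 130.0) < 0.5

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synth.SceneConfig(fs_hz=44_100, duration_s=1.0)
        with pytest.raises(ValueError):
            synth.SceneConfig(
                fs_hz=200_000, duration_s=1.0,
                trains=(synth.TrainSpec(template("kogia"), 0, 5, (90.0, 140.0)),),
            )


class TestLabelledBins:
    def test_shape_and_labels(self):
        templates = [template("kogia"), template("cuvier_beaked_whale")]
        frame = synth.synth_labelled_bins(templates, 10, seed=0, include_junk=False)
        assert len(frame) == 20
        assert set(frame["label"]) == {"kogia", "cuvier_beaked_whale"}
        assert frame.shape[1] == 1 + 181 + 60 + 100

    def test_junk_energy_below_20_khz(self):
        frame = synth.synth_labelled_bins([template("kogia")], 8, seed=3)
        junk = frame[frame["label"] == synth.JUNK_CLASS]
        spec_cols = [c for c in frame.columns if c.startswith("spec_")]
        spec = junk[spec_cols].to_numpy(dtype=float)
        low = spec[:, GRID_KHZ < 20].mean(axis=1)
        high = spec[:, GRID_KHZ >= 20].mean(axis=1)
        assert np.all(low > high)
        assert np.all(GRID_KHZ[np.argmax(spec, axis=1)] < 20)

    def test_determinism(self):
        templates = [template("kogia")]
        a = synth.synth_labelled_bins(templates, 5, seed=7)
        b = synth.synth_labelled_bins(templates, 5, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            synth.synth_labelled_bins([template("kogia")], 0)
        with pytest.raises(ValueError):
            synth.synth_labelled_bins([template("kogia"), template("kogia")], 5)

    def test_ici_segment_is_probability_vector(self):
        frame = synth.synth_labelled_bins([template("stenellid_1")], 6, seed=1,
                                          include_junk=False)
        ici_cols = [c for c in frame.columns if c.startswith("ici_")]
        sums = frame[ici_cols].to_numpy(dtype=float).sum(axis=1)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))
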