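"""Synthetic click-scene generator.

Emulates long-term hydrophone recordings at desk scale: impulsive
echolocation clicks (30–1200 µs) whose spectra carry type-specific peaks and
−3 dB bandwidths, click trains with Gaussian (optionally bimodal) inter-click
intervals, received levels expressed in dB peak-to-peak re 1 µPa through a
flat calibration constant, and interfering noise — Gaussian background,
band-limited low-frequency ship-like energy, and periodic narrowband
echosounder pings.

Click waveforms are sums of exponentially damped sinusoids, one per spectral
peak, with a symmetric (rise-and-decay) envelope: the component's power
spectrum is then a squared Lorentzian whose −3 dB full width is controlled
analytically, and spectral leakage outside the 10–100 kHz analysis band is
negligible.  A Tukey taper confines each click to its requested duration.

Two fast paths bypass audio rendering for clustering and classifier tests:
:func:`synth_bin_detections` emits detection-level rows for one 5-minute bin
and :func:`synth_labelled_bins` emits labelled bin-feature vectors directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile
from scipy.signal.windows import tukey
from scipy.stats import truncnorm

from clicktypes.detection import (
    ENVELOPE_POINTS,
    ENVELOPE_SPAN_S,
    GRID_KHZ,
    bandpass,
    click_spectrum,
    waveform_envelope,
)
from clicktypes.templates import _BW_SHAPE, ClickTypeTemplate

__all__ = [
    "SceneConfig",
    "TrainSpec",
    "NoiseSpec",
    "synth_click_waveform",
    "synth_click_train",
    "render_scene",
    "synth_bin_detections",
    "synth_labelled_bins",
    "write_scene_wav",
    "JUNK_CLASS",
]

#: label used for the ship/echosounder "junk" class in labelled datasets
JUNK_CLASS = "junk"

#: smallest physical gap between successive clicks of one animal, seconds
MIN_ICI_S = 0.005


@dataclass(frozen=True)
class TrainSpec:
    """One click train to inject into a scene."""

    template: ClickTypeTemplate
    start_s: float
    n_clicks: int
    rl_range_dbpp: tuple[float, float] = (120.0, 140.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Interfering-noise configuration for a scene.

    ``background_rms`` is the white Gaussian floor in counts.  Ship noise is
    low-pass-limited energy below ``ship_cutoff_hz``; echosounder pings are
    narrowband pulses repeated every ``echosounder_interval_s``.
    """

    background_rms: float = 1.0
    ship_band_level: float = 0.0
    ship_cutoff_hz: float = 5_000.0
    echosounder_interval_s: Optional[float] = None
    echosounder_freq_khz: float = 12.0
    echosounder_level: float = 0.0


@dataclass(frozen=True)
class SceneConfig:
    """Full description of one synthetic recording."""

    fs_hz: int
    duration_s: float
    trains: tuple[TrainSpec, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    calibration_db: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz not in (200_000, 320_000):
            raise ValueError("fs_hz must be 200000 or 320000")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for tr in self.trains:
            lo, hi = tr.rl_range_dbpp
            if not (100.0 <= lo <= hi <= 160.0):
                raise ValueError("received-level range must lie within [100, 160] dBpp")


def synth_click_waveform(template: ClickTypeTemplate, duration_us: float,
                         fs_hz: float, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Synthesize one click as a sum of damped sinusoids.

    Each spectral peak contributes a sinusoid at its centre frequency with a
    symmetric exponential envelope whose decay rate realizes the requested
    −3 dB bandwidth; component amplitudes are scaled so spectral peak heights
    follow the template's relative amplitudes.  The click is Tukey-tapered to
    ``duration_us`` and high-pass filtered at 10 kHz (the recording band),
    then peak-normalized.  Deterministic for a fixed seed (randomness enters
    only through the component phases).
    """
    if not (30.0 <= duration_us <= 1200.0):
        raise ValueError("duration_us must be within [30, 1200]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = max(6, int(round(duration_us * 1e-6 * fs_hz)))
    t = (np.arange(n) - (n - 1) / 2) / fs_hz
    x = np.zeros(n)
    for p in template.spectral_peaks:
        alpha = np.pi * p.bandwidth_khz * 1e3 / _BW_SHAPE
        phase = rng.uniform(0.0, 2 * np.pi)
        # peak spectral magnitude of the component is ~A/alpha: scale A by
        # alpha so realized peak heights follow the relative amplitudes
        x += p.rel_amplitude * alpha * np.exp(-alpha * np.abs(t)) * np.sin(
            2 * np.pi * p.freq_khz * 1e3 * t + phase
        )
    x *= tukey(n, 0.25)
    pad = int(round(2e-3 * fs_hz))
    x = bandpass(np.pad(x, pad), fs_hz, 10_000.0, min(100_000.0, fs_hz / 2))[pad:pad + n]
    peak = np.abs(x).max()
    return x / peak if peak > 0 else x


def _draw_gaps(template: ClickTypeTemplate, n_gaps: int,
               rng: np.random.Generator) -> np.ndarray:
    """Gaps from the template's (possibly bimodal) truncated Gaussian ICI model."""

    def trunc(mode: float, sd: float, size: int) -> np.ndarray:
        a = (MIN_ICI_S - mode) / sd
        return truncnorm.rvs(a, np.inf, loc=mode, scale=sd, size=size, random_state=rng)

    if template.ici_bimodal is None:
        return trunc(template.modal_ici_s, template.ici_sd_s, n_gaps)
    mode2, sd2, w1 = template.ici_bimodal
    pick1 = rng.random(n_gaps) < w1
    gaps = np.empty(n_gaps)
    gaps[pick1] = trunc(template.modal_ici_s, template.ici_sd_s, int(pick1.sum()))
    gaps[~pick1] = trunc(mode2, sd2, int((~pick1).sum()))
    return gaps


def synth_click_train(template: ClickTypeTemplate, n_clicks: int,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Strictly increasing click onset times (s) with Gaussian-modal gaps.

    Successive gaps are drawn from the template's Gaussian ICI model
    truncated to positive values (bimodal types use the two-Gaussian
    mixture); the first onset is at 0.
    """
    if n_clicks < 2:
        raise ValueError("n_clicks must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gaps = _draw_gaps(template, n_clicks - 1, rng)
    return np.concatenate([[0.0], np.cumsum(gaps)])


def _ship_noise(n: int, fs_hz: float, cutoff_hz: float, level: float,
                rng: np.random.Generator) -> np.ndarray:
    sos = signal.butter(4, cutoff_hz, btype="lowpass", fs=fs_hz, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x * (level / rms) if rms > 0 else x


def _echosounder(n: int, fs_hz: float, interval_s: float, freq_khz: float,
                 level: float) -> np.ndarray:
    out = np.zeros(n)
    ping_n = int(round(2e-3 * fs_hz))  # 2 ms pings
    t = np.arange(ping_n) / fs_hz
    ping = level * np.sin(2 * np.pi * freq_khz * 1e3 * t) * tukey(ping_n, 0.5)
    step = int(round(interval_s * fs_hz))
    for start in range(0, n - ping_n, step):
        out[start:start + ping_n] += ping
    return out


def render_scene(config: SceneConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a scene to audio (counts) plus a ground-truth click table.

    Each injected click is scaled so its peak-to-peak pressure equals its
    drawn received level under the flat calibration constant
    (``p2p_counts = 10**((rl_dbpp - calibration_db) / 20)``).  Ground truth
    lists every injected click: ``time_s`` (envelope peak), ``type``,
    ``rl_dbpp`` and ``duration_us``.  Bit-identical for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    audio = rng.standard_normal(n) * config.noise.background_rms
    if config.noise.ship_band_level > 0:
        audio += _ship_noise(n, config.fs_hz, config.noise.ship_cutoff_hz,
                             config.noise.ship_band_level, rng)
    if config.noise.echosounder_interval_s:
        audio += _echosounder(n, config.fs_hz, config.noise.echosounder_interval_s,
                              config.noise.echosounder_freq_khz,
                              config.noise.echosounder_level)

    truth_rows = []
    for tr in config.trains:
        times = tr.start_s + synth_click_train(tr.template, tr.n_clicks, rng)
        # one encounter-level template draw per train, small jitter per click
        encounter = tr.template.perturbed(rng)
        for t0 in times:
            jittered = encounter.perturbed(rng, scale=0.2)
            dur = jittered.preferred_duration_us() * rng.uniform(0.8, 1.2)
            dur = float(np.clip(dur, 30.0, 1200.0))
            click = synth_click_waveform(jittered, dur, config.fs_hz, rng)
            rl = rng.uniform(*tr.rl_range_dbpp)
            p2p_counts = 10 ** ((rl - config.calibration_db) / 20.0)
            click = click * p2p_counts / (click.max() - click.min())
            start = int(round(t0 * config.fs_hz))
            if start < 0 or start + len(click) > n:
                continue
            audio[start:start + len(click)] += click
            peak_off = int(np.argmax(np.abs(click)))
            truth_rows.append(
                {
                    "time_s": (start + peak_off) / config.fs_hz,
                    "type": tr.template.name,
                    "rl_dbpp": rl,
                    "duration_us": dur,
                }
            )
    truth = pd.DataFrame(truth_rows, columns=["time_s", "type", "rl_dbpp", "duration_us"])
    return audio, truth.sort_values("time_s", ignore_index=True)


def write_scene_wav(path, audio: np.ndarray, fs_hz: int) -> None:
    """Write scene audio as 16-bit PCM WAV (counts clipped to int16 range)."""
    wavfile.write(path, int(fs_hz), np.clip(audio, -32768, 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# fast detection-level and feature-level generators (no audio rendering)
# ---------------------------------------------------------------------------

def _junk_spectrum(rng: np.random.Generator) -> np.ndarray:
    """Ship-like or echosounder-like spectrum (dB) concentrating energy < 20 kHz."""
    slope = rng.uniform(1.0, 2.5)  # dB per kHz decay away from 10 kHz
    spec = -slope * (GRID_KHZ - GRID_KHZ[0])
    if rng.random() < 0.5:  # echosounder line somewhere in 10–18 kHz
        f0 = rng.uniform(10.5, 18.0)
        spec += 25.0 * np.exp(-0.5 * ((GRID_KHZ - f0) / 0.4) ** 2)
    return spec + rng.normal(0.0, 1.0, len(GRID_KHZ))


def _junk_envelope(rng: np.random.Generator) -> np.ndarray:
    """Slowly decaying, noisy envelope typical of non-click transients."""
    t = np.linspace(0.0, 1.0, ENVELOPE_POINTS)
    env = np.exp(-t / rng.uniform(0.5, 2.0)) + 0.2 * rng.random(ENVELOPE_POINTS)
    return env / env.max()


def _with_noise_floor(spec_db: np.ndarray, floor_below_peak_db: float) -> np.ndarray:
    """Blend an ambient-noise floor into a dB spectrum (power-domain sum)."""
    floor = spec_db.max() - floor_below_peak_db
    return 10.0 * np.log10(10 ** (spec_db / 10) + 10 ** (floor / 10))


def _click_spectrum_for(template: ClickTypeTemplate, fs_hz: int,
                        rng: np.random.Generator,
                        floor_below_peak_db: float = 25.0) -> np.ndarray:
    """Measured spectrum of one freshly synthesized click above a noise floor."""
    dur = float(np.clip(template.preferred_duration_us() * rng.uniform(0.8, 1.2),
                        30.0, 1200.0))
    wave = synth_click_waveform(template, dur, fs_hz, rng)
    return _with_noise_floor(click_spectrum(wave, fs_hz), floor_below_peak_db)


def _envelope_for(template: ClickTypeTemplate, fs_hz: int,
                  rng: np.random.Generator) -> np.ndarray:
    dur = float(np.clip(template.preferred_duration_us() * rng.uniform(0.8, 1.2),
                        30.0, 1200.0))
    wave = synth_click_waveform(template, dur, fs_hz, rng)
    half = int(round(ENVELOPE_SPAN_S / 2 * fs_hz))
    pad = max(0, half * 2 - len(wave))
    snip = np.pad(wave, (pad // 2, pad - pad // 2))
    return waveform_envelope(snip, fs_hz)


def synth_bin_detections(template: ClickTypeTemplate, n_clicks: int,
                         seed: int | np.random.Generator = 0,
                         fs_hz: int = 200_000,
                         rl_range_dbpp: tuple[float, float] = (121.0, 140.0),
                         spectral_noise_db: float = 1.5,
                         bin_start_s: float = 0.0,
                         encounter_scale: float = 0.6) -> pd.DataFrame:
    """Detection-level rows for one 5-minute bin of a single click type.

    Produces the same columns as the detector's output table (time, received
    level, duration, 181 spectrum columns, envelope columns) without audio
    rendering, for fast clustering tests.  Variability is hierarchical: one
    encounter-level template draw per bin (``encounter_scale`` of the pooled
    population spread — a single deployment sees less spread than the pooled
    multi-site band), then small click-to-click jitter, spectral noise, and
    an ambient-noise floor.
    """
    if n_clicks < 1:
        raise ValueError("n_clicks must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = bin_start_s + synth_click_train(template, max(n_clicks, 2), rng)[:n_clicks]
    # hierarchical variability: one encounter-level draw for the whole bin,
    # small click-to-click jitter on top
    encounter = template.perturbed(rng, scale=encounter_scale)
    base_env = _envelope_for(encounter, fs_hz, rng)
    rows = []
    for t0 in times:
        click_tmpl = encounter.perturbed(rng, scale=0.2)
        spec = _click_spectrum_for(click_tmpl, fs_hz, rng)
        spec = spec + rng.normal(0.0, spectral_noise_db, len(spec))
        env = np.clip(base_env + rng.normal(0.0, 0.03, len(base_env)), 0.0, None)
        env = env / env.max()
        rows.append((t0, rng.uniform(*rl_range_dbpp),
                     float(np.clip(template.preferred_duration_us(), 30, 1200)),
                     spec, env))
    frame = pd.DataFrame(
        {
            "time_s": [r[0] for r in rows],
            "rl_dbpp": [r[1] for r in rows],
            "duration_us": [r[2] for r in rows],
            "source_file": "synthetic",
        }
    )
    spec_df = pd.DataFrame(np.vstack([r[3] for r in rows]),
                           columns=[f"spec_{f:.1f}" for f in GRID_KHZ])
    env_df = pd.DataFrame(np.vstack([r[4] for r in rows]),
                          columns=[f"env_{i:03d}" for i in range(ENVELOPE_POINTS)])
    return pd.concat([frame, spec_df, env_df], axis=1)


def _normalize01(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def synth_labelled_bins(templates: Sequence[ClickTypeTemplate],
                        n_bins_per_class: int,
                        seed: int = 0,
                        fs_hz: int = 200_000,
                        include_junk: bool = True,
                        clicks_per_bin: tuple[int, int] = (40, 150),
                        ici_bin_width_s: float = 0.01,
                        max_ici_s: float = 0.6,
                        encounter_scale: float = 0.6) -> pd.DataFrame:
    """Labelled bin-feature rows for classifier training/testing.

    Each row is one 5-minute bin cluster of a single class: a mean
    min-max-normalized spectrum (181 columns), an ICI probability histogram
    (60 columns over 0–0.6 s) and a mean max-normalized envelope (100
    columns), plus a ``label`` column.  A ship/echosounder ``junk`` class is
    appended when ``include_junk``.  Deterministic for a fixed seed.
    """
    if n_bins_per_class < 1:
        raise ValueError("n_bins_per_class must be >= 1")
    names = [t.name for t in templates]
    if len(set(names)) != len(names):
        raise ValueError("templates must be distinct")
    from clicktypes.features import ici_distribution  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    n_ici = int(round(max_ici_s / ici_bin_width_s))
    rows, labels = [], []
    for tmpl in templates:
        for _ in range(n_bins_per_class):
            n_clicks = int(rng.integers(*clicks_per_bin))
            # one encounter per bin; clicks jitter mildly around it
            encounter = tmpl.perturbed(rng, scale=encounter_scale)
            env = _envelope_for(encounter, fs_hz, rng)
            specs = []
            for _ in range(min(n_clicks, 12)):  # spectra vary slowly within a bin
                spec = encounter.perturbed(rng, scale=0.2).power_spectrum()
                spec = _with_noise_floor(spec, 25.0) + rng.normal(0.0, 1.5, len(spec))
                specs.append(_normalize01(spec))
            times = synth_click_train(tmpl, n_clicks, rng)
            hist = ici_distribution(times, max_ici_s=max_ici_s,
                                    bin_width_s=ici_bin_width_s)
            rows.append(np.concatenate([np.mean(specs, axis=0), hist, env]))
            labels.append(tmpl.name)
    if include_junk:
        for _ in range(n_bins_per_class):
            spec = _normalize01(_junk_spectrum(rng))
            # sporadic impulsive noise: broad, un-patterned gap distribution
            gaps = rng.uniform(MIN_ICI_S, 1.2, size=int(rng.integers(10, 60)))
            times = np.cumsum(gaps)
            hist = ici_distribution(times, max_ici_s=max_ici_s,
                                    bin_width_s=ici_bin_width_s)
            env = _junk_envelope(rng)
            rows.append(np.concatenate([spec, hist, env]))
            labels.append(JUNK_CLASS)
    spec_cols = [f"spec_{f:.1f}" for f in GRID_KHZ]
    ici_cols = [f"ici_{i:02d}" for i in range(n_ici)]
    env_cols = [f"env_{i:03d}" for i in range(ENVELOPE_POINTS)]
    out = pd.DataFrame(np.vstack(rows), columns=spec_cols + ici_cols + env_cols)
    out.insert(0, "label", labels)
    return out
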