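"""Energy-based impulse detector for odontocete echolocation clicks.

The detector follows the classic two-stage logic used on long-term
hydrophone recordings: first find periods in which band energy (10–100 kHz)
exceeds a running noise floor, then measure each impulsive event found in
those periods.  Retained detections must be 30–1200 µs long, at or above
115 dB peak-to-peak re 1 µPa, and at least 100 µs apart (closer candidates
are merged, keeping the earliest onset and the largest peak-to-peak
amplitude).

Click spectra are computed with a 400-point (fs = 200 kHz) or 640-point
(fs = 320 kHz) FFT of Hann-windowed data centred on the click's peak, so the
frequency resolution is 0.5 kHz at either rate; spectra are stored on the
common 10–100 kHz grid (181 bins) regardless of sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import signal

from clicktypes.templates import GRID_KHZ

__all__ = [
    "GRID_KHZ",
    "ENVELOPE_POINTS",
    "DetectorParams",
    "ClickDetection",
    "bandpass",
    "detect_clicks",
    "click_spectrum",
    "waveform_envelope",
    "detections_to_frame",
    "frame_to_detections",
]

#: number of samples in the stored, max-normalized waveform-envelope feature
ENVELOPE_POINTS = 100
#: span of the envelope feature window, seconds (centred on the click peak)
ENVELOPE_SPAN_S = 1.5e-3

_FFT_LEN = {200_000: 400, 320_000: 640}


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the click detector (defaults are the standard ones)."""

    highpass_hz: float = 10_000.0
    lowpass_hz: float = 100_000.0
    rl_threshold_dbpp: float = 115.0
    min_dur_us: float = 30.0
    max_dur_us: float = 1200.0
    merge_gap_us: float = 100.0
    #: trigger margin above the running median noise floor, dB
    energy_threshold_db: float = 6.0
    #: short-time energy window, seconds
    energy_window_s: float = 1e-3
    #: block length for the running median noise-floor estimate, seconds
    noise_block_s: float = 1.0

    def __post_init__(self) -> None:
        if self.min_dur_us >= self.max_dur_us:
            raise ValueError("min_dur_us must be < max_dur_us")


@dataclass
class ClickDetection:
    """One detected impulse."""

    time_s: float
    rl_dbpp: float
    duration_us: float
    spectrum_db: np.ndarray  # on GRID_KHZ, raw dB (not yet min-max normalized)
    envelope: np.ndarray  # ENVELOPE_POINTS values in [0, 1], max = 1
    source_file: str = ""


def fft_len_for(fs_hz: float) -> int:
    try:
        return _FFT_LEN[int(fs_hz)]
    except KeyError:
        raise ValueError(f"unsupported sampling rate {fs_hz}; expected 200 or 320 kHz") from None


def bandpass(waveform: np.ndarray, fs_hz: float, lo_hz: float = 10_000.0,
             hi_hz: float = 100_000.0, order: int = 8) -> np.ndarray:
    """Zero-phase Butterworth band-limiting to [lo_hz, hi_hz].

    When ``hi_hz`` equals the Nyquist frequency (the fs = 200 kHz case with
    the standard 100 kHz upper edge) only the high-pass branch is applied —
    the data cannot contain energy above Nyquist.  ``hi_hz`` beyond Nyquist
    is rejected.
    """
    x = np.asarray(waveform, dtype=float)
    nyq = fs_hz / 2.0
    if not (0 < lo_hz < hi_hz):
        raise ValueError("need 0 < lo_hz < hi_hz")
    if hi_hz > nyq:
        raise ValueError(f"hi_hz={hi_hz} exceeds Nyquist ({nyq})")
    sos = signal.butter(order, lo_hz, btype="highpass", fs=fs_hz, output="sos")
    y = signal.sosfiltfilt(sos, x)
    if hi_hz < nyq * 0.999:
        sos_lp = signal.butter(order, hi_hz, btype="lowpass", fs=fs_hz, output="sos")
        y = signal.sosfiltfilt(sos_lp, y)
    return y


def click_spectrum(snippet: np.ndarray, fs_hz: float) -> np.ndarray:
    """Click amplitude spectrum (dB) on the common 10–100 kHz, 0.5 kHz grid.

    ``snippet`` should contain the click with its peak near the centre; it is
    zero-padded or cropped symmetrically to the rate-specific FFT length
    (2 ms of data) before Hann windowing.
    """
    n = fft_len_for(fs_hz)
    x = np.asarray(snippet, dtype=float)
    if len(x) < n:
        pad = n - len(x)
        x = np.pad(x, (pad // 2, pad - pad // 2))
    elif len(x) > n:
        start = (len(x) - n) // 2
        x = x[start:start + n]
    spec = np.fft.rfft(x * np.hanning(n))
    freqs_khz = np.fft.rfftfreq(n, 1.0 / fs_hz) / 1e3
    mag_db = 20.0 * np.log10(np.abs(spec) + 1e-12)
    lo = int(np.searchsorted(freqs_khz, GRID_KHZ[0] - 1e-9))
    return mag_db[lo:lo + len(GRID_KHZ)].copy()


def waveform_envelope(snippet: np.ndarray, fs_hz: float,
                      n_points: int = ENVELOPE_POINTS) -> np.ndarray:
    """Max-normalized analytic-signal envelope resampled to ``n_points``."""
    env = np.abs(signal.hilbert(np.asarray(snippet, dtype=float)))
    src = np.linspace(0.0, 1.0, len(env))
    dst = np.linspace(0.0, 1.0, n_points)
    out = np.interp(dst, src, env)
    peak = out.max()
    return out / peak if peak > 0 else out


def _snippet(x: np.ndarray, center: int, half: int) -> np.ndarray:
    """Symmetric window around ``center``, zero-padded at the edges."""
    lo, hi = center - half, center + half
    pad_lo, pad_hi = max(0, -lo), max(0, hi - len(x))
    return np.pad(x[max(0, lo):min(len(x), hi)], (pad_lo, pad_hi))


def _duration_us(env: np.ndarray, peak_idx: int, fs_hz: float) -> float:
    """Span (µs) around the peak where the envelope stays above −10 dB of its max."""
    thresh = env[peak_idx] * 10 ** (-10 / 20)
    lo = peak_idx
    while lo > 0 and env[lo - 1] >= thresh:
        lo -= 1
    hi = peak_idx
    while hi < len(env) - 1 and env[hi + 1] >= thresh:
        hi += 1
    return (hi - lo + 1) / fs_hz * 1e6


def _noise_floor(energy: np.ndarray, block: int) -> np.ndarray:
    """Blockwise running-median noise floor, one value per sample."""
    n_blocks = max(1, int(np.ceil(len(energy) / block)))
    med = np.empty(n_blocks)
    for i in range(n_blocks):
        med[i] = np.median(energy[i * block:(i + 1) * block])
    return np.repeat(med, block)[:len(energy)]


def detect_clicks(waveform: np.ndarray, fs_hz: float,
                  params: DetectorParams = DetectorParams(),
                  calibration_db: float = 60.0,
                  source_file: str = "") -> list[ClickDetection]:
    """Detect echolocation clicks in a single-channel recording.

    Received level is ``20*log10(peak-to-peak counts) + calibration_db``
    (flat count→µPa conversion).  Returned detections are time-sorted and
    satisfy the duration, amplitude and merge constraints by construction.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("waveform must be non-empty and finite")
    fft_len_for(fs_hz)  # validate rate early

    y = bandpass(x, fs_hz, params.highpass_hz, min(params.lowpass_hz, fs_hz / 2))

    # stage 1: band-energy trigger against a running median noise floor
    win = max(1, int(round(params.energy_window_s * fs_hz)))
    energy = signal.convolve(y * y, np.ones(win) / win, mode="same")
    floor = _noise_floor(energy, max(win, int(round(params.noise_block_s * fs_hz))))
    floor = np.maximum(floor, energy.max() * 1e-12 + 1e-30)
    mask = energy > floor * 10 ** (params.energy_threshold_db / 10)

    # stage 2: one candidate impulse per triggered region
    trig = np.flatnonzero(mask)
    regions = (
        np.split(trig, np.flatnonzero(np.diff(trig) > 1) + 1) if trig.size else []
    )
    margin = win
    candidates = []  # (peak_idx, p2p)
    half_env = max(2, int(round(ENVELOPE_SPAN_S / 2 * fs_hz)))
    for reg in regions:
        s, e = int(reg[0]), int(reg[-1]) + 1
        lo, hi = max(0, s - margin), min(len(y), e + margin)
        seg = y[lo:hi]
        if seg.size == 0:
            continue
        peak = lo + int(np.argmax(np.abs(seg)))
        snip = _snippet(y, peak, half_env)
        candidates.append((peak, float(snip.max() - snip.min())))

    # merge candidates separated by less than merge_gap_us: earliest onset,
    # largest peak-to-peak amplitude
    gap = params.merge_gap_us * 1e-6 * fs_hz
    merged: list[tuple[int, float]] = []
    for peak, p2p in sorted(candidates):
        if merged and peak - merged[-1][0] < gap:
            prev_peak, prev_p2p = merged[-1]
            merged[-1] = (prev_peak, max(prev_p2p, p2p))
        else:
            merged.append((peak, p2p))

    out: list[ClickDetection] = []
    for peak, p2p in merged:
        rl = 20.0 * np.log10(max(p2p, 1e-12)) + calibration_db
        if rl < params.rl_threshold_dbpp:
            continue
        # duration is measured on a window longer than the longest admissible
        # click so over-long events cannot be clipped into the passing band
        half_dur = max(half_env, int(round(1.5 * params.max_dur_us * 1e-6 * fs_hz)))
        env_long = np.abs(signal.hilbert(_snippet(y, peak, half_dur)))
        dur = _duration_us(env_long, int(np.argmax(env_long)), fs_hz)
        if not (params.min_dur_us <= dur <= params.max_dur_us):
            continue
        snip = _snippet(y, peak, half_env)
        spec_half = fft_len_for(fs_hz) // 2
        out.append(
            ClickDetection(
                time_s=peak / fs_hz,
                rl_dbpp=float(rl),
                duration_us=float(dur),
                spectrum_db=click_spectrum(_snippet(y, peak, spec_half), fs_hz),
                envelope=waveform_envelope(snip, fs_hz),
                source_file=source_file,
            )
        )
    out.sort(key=lambda d: d.time_s)
    return out


_SPEC_COLS = [f"spec_{f:.1f}" for f in GRID_KHZ]
_ENV_COLS = [f"env_{i:03d}" for i in range(ENVELOPE_POINTS)]


def detections_to_frame(detections: Iterable[ClickDetection]) -> pd.DataFrame:
    """Flatten detections into a self-describing table (one row per click)."""
    rows = list(detections)
    meta = pd.DataFrame(
        {
            "time_s": [d.time_s for d in rows],
            "rl_dbpp": [d.rl_dbpp for d in rows],
            "duration_us": [d.duration_us for d in rows],
            "source_file": [d.source_file for d in rows],
        }
    )
    if not rows:
        return pd.concat(
            [meta, pd.DataFrame(columns=_SPEC_COLS + _ENV_COLS, dtype=float)], axis=1
        )
    spec = pd.DataFrame(np.vstack([d.spectrum_db for d in rows]), columns=_SPEC_COLS)
    env = pd.DataFrame(np.vstack([d.envelope for d in rows]), columns=_ENV_COLS)
    return pd.concat([meta, spec, env], axis=1)


def frame_to_detections(frame: pd.DataFrame) -> list[ClickDetection]:
    """Inverse of :func:`detections_to_frame`."""
    spec = frame[_SPEC_COLS].to_numpy(dtype=float)
    env = frame[_ENV_COLS].to_numpy(dtype=float)
    return [
        ClickDetection(
            time_s=float(r.time_s),
            rl_dbpp=float(r.rl_dbpp),
            duration_us=float(r.duration_us),
            spectrum_db=spec[i],
            envelope=env[i],
            source_file=str(r.source_file),
        )
        for i, r in enumerate(frame.itertuples(index=False))
    ]
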