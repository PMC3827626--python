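"""Trial segmentation, Morlet wavelet induced power, topographic alpha
statistics and short-time FFT band power.

Morlet convention: a wavelet is parametrized by its centre frequency f0 and
the ratio c = f0 / sigma_f, so sigma_f = f0 / c and sigma_t = 1 / (2 pi
sigma_f). At the default c = 4.2 and f0 = 10.5 Hz the spectral half-width is
2.5 Hz. The wavelet is amplitude-normalized so that a unit-amplitude
sinusoid at f0 yields plateau power 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal
import scipy.stats

from .io_core import Marker, Recording, TrialRecord

__all__ = [
    "WaveletSpec",
    "TFRArray",
    "StfftSpec",
    "SegmentSet",
    "segment_trials",
    "morlet_wavelet",
    "morlet_tfr",
    "baseline_correct",
    "alpha_topography",
    "stfft_power",
]


@dataclass
class WaveletSpec:
    """Complex Morlet wavelet: centre frequency and c = f0/sigma_f."""

    f0_hz: float
    c: float = 4.2

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        if self.c <= 0:
            raise ValueError("c must be positive")

    @property
    def sigma_f_hz(self) -> float:
        return self.f0_hz / self.c

    @property
    def sigma_t_s(self) -> float:
        return 1.0 / (2.0 * np.pi * self.sigma_f_hz)


@dataclass
class StfftSpec:
    """Short-time FFT configuration (window/hop in ms, analysis band in Hz)."""

    window_ms: float = 500.0
    hop_ms: float = 100.0
    taper: str = "hann"
    band_hz: tuple[float, float] = (8.0, 13.0)

    def __post_init__(self) -> None:
        if self.hop_ms > self.window_ms:
            raise ValueError("hop must not exceed the window length")
        if self.taper not in {"hann", "boxcar"}:
            raise ValueError(f"unsupported taper {self.taper!r}")

    @property
    def overlap(self) -> float:
        return 1.0 - self.hop_ms / self.window_ms

    @property
    def overlap_percent(self) -> float:
        return 100.0 * self.overlap


@dataclass
class SegmentSet:
    """Stimulus-locked segments: trials x channels x time."""

    data: np.ndarray
    times_ms: np.ndarray
    sampling_rate_hz: float
    channel_labels: list[str]
    trials: list[TrialRecord]
    markers: list[Marker]

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    def mean_segment(self) -> np.ndarray:
        return self.data.mean(axis=0)


def segment_trials(
    rec: Recording,
    markers: list[Marker],
    trials: list[TrialRecord],
    window_ms: tuple[float, float] = (-2000.0, 1000.0),
    amp_thresh_uv: float = 125.0,
    exclude_channels: tuple[str, ...] = ("ECG",),
) -> tuple[SegmentSet, dict[int, str]]:
    """Cut one segment per surviving stimulus marker; log exclusions by reason.

    Exclusion rules (first matching reason is recorded): segment exceeds the
    recording bounds ("edge"), no response ("no_response"), incorrect
    response on a unisensory/CON trial ("error"), presentation uncertainty
    above 10 ms ("uncertainty"), any sample beyond ``+-amp_thresh_uv``
    ("amplitude"). Responded INC trials are never excluded for correctness.
    """
    stim = [m for m in markers if m.kind == "stimulus"]
    if len(stim) != len(trials):
        raise ValueError(
            f"{len(stim)} stimulus markers but {len(trials)} trial records"
        )
    fs = rec.sampling_rate_hz
    i0 = int(round(window_ms[0] * fs / 1000.0))
    i1 = int(round(window_ms[1] * fs / 1000.0))
    n_times = i1 - i0
    chan_idx = [
        i for i, l in enumerate(rec.channel_labels) if l not in exclude_channels
    ]
    labels = [rec.channel_labels[i] for i in chan_idx]

    kept_data, kept_trials, kept_markers = [], [], []
    exclusions: dict[int, str] = {}
    for m, t in zip(stim, trials):
        lo, hi = m.onset_sample + i0, m.onset_sample + i1
        if lo < 0 or hi > rec.n_samples:
            exclusions[t.trial_id] = "edge"
            continue
        if t.correctness == "omitted" or t.response_code is None:
            exclusions[t.trial_id] = "no_response"
            continue
        if t.correctness == "incorrect" and t.congruence != "INC":
            exclusions[t.trial_id] = "error"
            continue
        if m.uncertainty_excluded:
            exclusions[t.trial_id] = "uncertainty"
            continue
        seg = rec.data[np.ix_(chan_idx, range(lo, hi))]
        if np.any(np.abs(seg) > amp_thresh_uv):
            exclusions[t.trial_id] = "amplitude"
            continue
        kept_data.append(seg)
        kept_trials.append(t)
        kept_markers.append(m)

    data = (
        np.stack(kept_data)
        if kept_data
        else np.empty((0, len(chan_idx), n_times))
    )
    times_ms = (np.arange(i0, i1) / fs) * 1000.0
    return (
        SegmentSet(data, times_ms, fs, labels, kept_trials, kept_markers),
        exclusions,
    )


def morlet_wavelet(
    f0_hz: float, c: float, sampling_rate_hz: float, n_sigmas: float = 5.0
) -> np.ndarray:
    """Sampled complex Morlet wavelet, amplitude-normalized (see module doc)."""
    spec = WaveletSpec(f0_hz=f0_hz, c=c)
    sigma_t = spec.sigma_t_s
    half = int(np.ceil(n_sigmas * sigma_t * sampling_rate_hz))
    t = np.arange(-half, half + 1) / sampling_rate_hz
    envelope = np.exp(-(t**2) / (2.0 * sigma_t**2))
    w = envelope * np.exp(2j * np.pi * f0_hz * t)
    # plateau response of a unit sinusoid at f0 is (1/2) * sum(envelope) * gain
    return w * (2.0 / envelope.sum())


@dataclass
class TFRArray:
    """Per-trial time-frequency power: trials x locations x freqs x times."""

    power: np.ndarray
    times_ms: np.ndarray
    freqs_hz: np.ndarray
    locations: list[str]
    sampling_rate_hz: float
    valid_time: np.ndarray
    baseline_ms: tuple[float, float] | None = None
    corrected: bool = False
    kind: str = "induced"
    trials: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.power.shape[1] != len(self.locations):
            raise ValueError("location axis mismatch")
        if self.power.shape[2] != len(self.freqs_hz):
            raise ValueError("frequency axis mismatch")
        if self.power.shape[3] != len(self.times_ms):
            raise ValueError("time axis mismatch")
        if not self.corrected and np.any(self.power < 0):
            raise ValueError("uncorrected power must be non-negative")

    def induced(self) -> np.ndarray:
        """Trial-mean of per-trial power (locations x freqs x times)."""
        return self.power.mean(axis=0)


def morlet_tfr(
    segments: SegmentSet,
    freqs_hz,
    c: float = 4.2,
    n_sigmas: float = 5.0,
) -> TFRArray:
    """Continuous wavelet transform power per trial, channel and frequency."""
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    fs = segments.sampling_rate_hz
    n_times = segments.data.shape[2]
    power = np.empty(segments.data.shape[:2] + (len(freqs), n_times))
    valid = np.ones((len(freqs), n_times), dtype=bool)
    for k, f0 in enumerate(freqs):
        w = morlet_wavelet(f0, c, fs, n_sigmas)
        if len(w) > n_times:
            raise ValueError(
                f"segment ({n_times} samples) shorter than wavelet support ({len(w)})"
            )
        conv = scipy.signal.fftconvolve(
            segments.data, w[None, None, :], mode="same", axes=2
        )
        power[:, :, k, :] = np.abs(conv) ** 2
        half = (len(w) - 1) // 2
        valid[k, :half] = False
        if half > 0:
            valid[k, -half:] = False
    return TFRArray(
        power=power,
        times_ms=segments.times_ms.copy(),
        freqs_hz=freqs,
        locations=list(segments.channel_labels),
        sampling_rate_hz=fs,
        valid_time=valid.all(axis=0),
        trials=list(segments.trials),
    )


def baseline_correct(
    tfr: TFRArray,
    window_ms: tuple[float, float] = (-1500.0, -500.0),
    mode: str = "subtract",
) -> TFRArray:
    """Per trial/location/frequency baseline correction of power."""
    if mode not in {"subtract", "percent"}:
        raise ValueError(f"unknown baseline mode {mode!r}")
    t = tfr.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    if not np.any(sel):
        raise ValueError(f"baseline window {window_ms} ms lies outside the segment")
    base = tfr.power[:, :, :, sel].mean(axis=3, keepdims=True)
    if mode == "subtract":
        corrected = tfr.power - base
    else:
        corrected = 100.0 * (tfr.power - base) / np.maximum(base, np.finfo(float).tiny)
    return TFRArray(
        power=corrected,
        times_ms=tfr.times_ms,
        freqs_hz=tfr.freqs_hz,
        locations=tfr.locations,
        sampling_rate_hz=tfr.sampling_rate_hz,
        valid_time=tfr.valid_time,
        baseline_ms=tuple(window_ms),
        corrected=True,
        kind=tfr.kind,
        trials=tfr.trials,
    )


def alpha_topography(
    tfr: TFRArray,
    band_hz: tuple[float, float] = (8.0, 13.0),
    window_ms: tuple[float, float] = (200.0, 400.0),
    contrast: str = "mean_vs_0",
) -> dict[str, np.ndarray]:
    """Per-channel statistic map of band power in a post-stimulus window.

    ``contrast='mean_vs_0'`` is a one-sample t across all trials;
    ``'con_minus_inc'`` compares audiovisual CON against INC trials.
    Returns per-channel ``mean``, ``t`` and ``p`` arrays.
    """
    f_sel = (tfr.freqs_hz >= band_hz[0]) & (tfr.freqs_hz <= band_hz[1])
    t_sel = (tfr.times_ms >= window_ms[0]) & (tfr.times_ms <= window_ms[1])
    t_sel &= tfr.valid_time
    if not np.any(f_sel) or not np.any(t_sel):
        raise ValueError("band/window selects no valid time-frequency bins")
    vals = tfr.power[:, :, f_sel, :][:, :, :, t_sel].mean(axis=(2, 3))  # trials x chan

    if contrast == "mean_vs_0":
        if vals.shape[0] < 2:
            raise ValueError("contrast needs at least 2 trials")
        tstat, p = scipy.stats.ttest_1samp(vals, 0.0, axis=0)
        mean = vals.mean(axis=0)
    elif contrast == "con_minus_inc":
        cong = np.array([tr.congruence for tr in tfr.trials])
        a, b = vals[cong == "CON"], vals[cong == "INC"]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("contrast needs at least 2 trials per condition")
        tstat, p = scipy.stats.ttest_ind(a, b, axis=0)
        mean = a.mean(axis=0) - b.mean(axis=0)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return {
        "labels": np.array(tfr.locations),
        "mean": np.asarray(mean),
        "t": np.asarray(tstat),
        "p": np.asarray(p),
    }


def stfft_power(
    data: np.ndarray,
    sampling_rate_hz: float,
    t0_ms: float,
    spec: StfftSpec | None = None,
    baseline_ms: tuple[float, float] | None = (-2000.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Band power per sliding window (tapered FFT).

    ``data`` is ``(..., n_times)`` starting at ``t0_ms``. Returns
    ``(power, window_centers_ms)`` where power has shape
    ``(..., n_windows)``: the mean of ``|X_k|^2 * 2 / sum(taper)^2`` over
    FFT bins inside the analysis band. When ``baseline_ms`` is given, the
    mean over windows fully inside that interval is subtracted.
    """
    spec = spec or StfftSpec()
    data = np.asarray(data, dtype=float)
    fs = sampling_rate_hz
    n_win = int(round(spec.window_ms * fs / 1000.0))
    hop = int(round(spec.hop_ms * fs / 1000.0))
    n_times = data.shape[-1]
    if n_win > n_times:
        raise ValueError("window longer than the data")
    starts = np.arange(0, n_times - n_win + 1, hop)
    taper = scipy.signal.get_window(spec.taper, n_win, fftbins=True)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    band_sel = (freqs >= spec.band_hz[0]) & (freqs <= spec.band_hz[1])
    if not np.any(band_sel):
        raise ValueError(f"band {spec.band_hz} Hz selects no FFT bins")
    scale = 2.0 / taper.sum() ** 2

    windows = np.stack(
        [data[..., s : s + n_win] * taper for s in starts], axis=-2
    )  # (..., n_windows, n_win)
    spectra = np.fft.rfft(windows, axis=-1)
    power = (np.abs(spectra[..., band_sel]) ** 2 * scale).mean(axis=-1)

    centers_ms = t0_ms + (starts + (n_win - 1) / 2.0) / fs * 1000.0
    if baseline_ms is not None:
        start_ms = t0_ms + starts / fs * 1000.0
        end_ms = t0_ms + (starts + n_win) / fs * 1000.0
        base_sel = (start_ms >= baseline_ms[0]) & (end_ms <= baseline_ms[1])
        if not np.any(base_sel):
            raise ValueError(
                f"no STFFT window lies fully inside baseline {baseline_ms} ms"
            )
        power = power - power[..., base_sel].mean(axis=-1, keepdims=True)
    return power, centers_ms
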