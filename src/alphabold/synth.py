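"""Synthetic multimodal session generator.

Emits a blocked audiovisual paradigm, ground-truth cortical alpha sources
(occipital suppression, congruence-dependent frontal increase), artifact-
laden in-scanner EEG (gradient, ballistocardiogram, blinks, movement
spikes) with an ECG channel, behavioural responses, and a BOLD series whose
coupled voxels follow the HRF-convolved trial-alpha regressor — so every
downstream stage can be checked against known truth.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import Marker, Recording, TrialRecord, VolumeSeries
from .inverse import LeadField, SourceSpace

__all__ = [
    "ParadigmSpec",
    "SourceSimSpec",
    "ArtifactSimSpec",
    "CouplingSimSpec",
    "SourceActivity",
    "build_paradigm",
    "simulate_sources",
    "project_to_sensors",
    "add_gradient_artifact",
    "add_bcg_and_ecg",
    "add_blinks",
    "add_movement_spikes",
    "simulate_behavior",
    "simulate_bold",
    "simulate_session",
    "DEFAULT_ACCURACY",
]

_EMOTIONS = ("angry", "happy", "neutral")
_GENDERS = ("female", "male")

#: Session-mean recognition rates reported for the paradigm.
DEFAULT_ACCURACY = {"auditory": 0.708, "visual": 0.938, "CON": 0.929}
DEFAULT_INC_PROPORTIONS = (0.50, 0.28, 0.22)  # face, voice, neither


@dataclass
class ParadigmSpec:
    """Blocked audiovisual paradigm layout (defaults: full design)."""

    n_auditory_blocks: int = 8
    n_visual_blocks: int = 8
    n_audiovisual_blocks: int = 16
    trials_per_block: int = 12
    pause_jitter_s: tuple[float, float] = (19.0, 21.0)
    stim_dur_s: tuple[float, float] = (1.0, 1.2)
    decision_dur_s: float = 1.0
    response_dur_s: float = 1.0
    lead_in_s: float = 4.0
    lead_out_s: float = 6.0
    seed: int = 0

    @property
    def n_blocks(self) -> int:
        return self.n_auditory_blocks + self.n_visual_blocks + self.n_audiovisual_blocks

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class SourceSimSpec:
    """Ground-truth cortical alpha activity."""

    source_space: SourceSpace
    occipital_patch: np.ndarray
    frontal_patch: np.ndarray
    alpha_f0_hz: float = 10.5
    suppression_depth: float = 0.5
    effect_window_s: tuple[float, float] = (0.2, 0.4)
    con_frontal_gain: float = 0.5
    alpha_amp: float = 1.0
    background_amp: float = 0.0
    n_background: int = 20
    ramp_s: float = 0.02
    phase_jitter: float = 0.1
    # phase random-walk diffusion (rad^2/s): real alpha is not phase-locked
    # over tens of seconds; without drift a 10.5 Hz carrier is exactly
    # TR-periodic (21 cycles / 2 s) and template subtraction would eat it
    phase_diffusion_rad2_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.occipital_patch = np.asarray(self.occipital_patch, dtype=int)
        self.frontal_patch = np.asarray(self.frontal_patch, dtype=int)
        if self.occipital_patch.size == 0 or self.frontal_patch.size == 0:
            raise ValueError("patches must be non-empty")
        if np.intersect1d(self.occipital_patch, self.frontal_patch).size:
            raise ValueError("occipital and frontal patches must be disjoint")
        if not 0.0 <= self.suppression_depth <= 1.0:
            raise ValueError("suppression_depth must lie in [0, 1]")


@dataclass
class ArtifactSimSpec:
    """MR-environment artifact levels (defaults give pre-cleaning SNR << 1
    for the gradient and BCG at roughly 3x EEG RMS)."""

    tr_s: float = 2.0
    n_slices: int = 34
    gradient_amp_uv: float = 2000.0
    heart_rate_bpm: float = 60.0
    rr_jitter_sd_s: float = 0.03
    bcg_amp_uv: float = 30.0
    bcg_lag_s: float = 0.21
    bcg_amp_jitter: float = 0.02
    ecg_amp_uv: float = 800.0
    blink_rate_per_min: float = 4.0
    blink_amp_uv: float = 150.0
    spike_rate_per_min: float = 1.0
    spike_amp_uv: float = 450.0
    seed: int = 0


@dataclass
class CouplingSimSpec:
    """Alpha-BOLD coupling ground truth."""

    coupled_mask: np.ndarray
    gain: float = -2.0
    noise_sd: float = 0.5
    drift_amp: float = 1.0
    drift_period_s: float = 120.0
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.coupled_mask = np.asarray(self.coupled_mask, dtype=bool)


@dataclass
class SourceActivity:
    """Sparse vertex activity: only ``vertex_ids`` carry signal."""

    vertex_ids: np.ndarray
    time_courses: np.ndarray  # (n_active, n_samples)
    n_vertices: int
    sampling_rate_hz: float
    occipital_envelope: np.ndarray | None = None
    frontal_envelope: np.ndarray | None = None


# --------------------------------------------------------------------------
# Paradigm
# --------------------------------------------------------------------------

def _balanced_conditions(n: int, rng: np.random.Generator) -> list[tuple[str, str]]:
    """Balanced (emotion, gender) assignment for ``n`` trials."""
    cells = [(e, g) for e in _EMOTIONS for g in _GENDERS]
    if n % len(cells) != 0:
        raise ValueError(
            f"{n} trials cannot be balanced over {len(cells)} emotion x gender cells"
        )
    out = cells * (n // len(cells))
    rng.shuffle(out)
    return out


def build_paradigm(
    spec: ParadigmSpec, sampling_rate_hz: float = 250.0
) -> tuple[list[Marker], list[TrialRecord], dict]:
    """Pseudo-randomized block/trial sequence with jittered pauses.

    Returns stimulus markers, trial-record skeletons (responses unfilled)
    and a metadata dict with block boundaries, pause durations and the
    exact total duration.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = (
        ["auditory"] * spec.n_auditory_blocks
        + ["visual"] * spec.n_visual_blocks
        + ["audiovisual"] * spec.n_audiovisual_blocks
    )
    rng.shuffle(blocks)

    per_modality: dict[str, list[tuple[str, str]]] = {}
    for mod in ("auditory", "visual", "audiovisual"):
        n = blocks.count(mod) * spec.trials_per_block
        if n:
            per_modality[mod] = _balanced_conditions(n, rng)

    markers: list[Marker] = []
    trials: list[TrialRecord] = []
    pauses: list[float] = []
    block_onsets: list[float] = []
    t = spec.lead_in_s
    trial_id = 0
    for b, mod in enumerate(blocks):
        block_onsets.append(t)
        for _ in range(spec.trials_per_block):
            emotion, gender = per_modality[mod].pop()
            vemo = emotion if mod in ("visual", "audiovisual") else "none"
            aemo = emotion if mod in ("auditory", "audiovisual") else "none"
            congruence = "n/a"
            if mod == "audiovisual":
                if rng.random() < 0.5:  # INC: replace the auditory emotion
                    aemo = rng.choice([e for e in _EMOTIONS if e != vemo])
                    congruence = "INC"
                else:
                    congruence = "CON"
            stim_dur = rng.uniform(*spec.stim_dur_s)
            markers.append(
                Marker(
                    onset_sample=int(round(t * sampling_rate_hz)),
                    kind="stimulus",
                    modality=mod,
                    visual_emotion=vemo,
                    auditory_emotion=aemo,
                    congruence=congruence,
                    uncertainty_ms=float(rng.uniform(0.0, 3.0)),
                )
            )
            trials.append(
                TrialRecord(
                    trial_id=trial_id,
                    marker_index=len(markers) - 1,
                    modality=mod,
                    visual_emotion=vemo,
                    auditory_emotion=aemo,
                    congruence=congruence,
                    gender=gender,
                )
            )
            trial_id += 1
            t += stim_dur + spec.decision_dur_s + spec.response_dur_s
        if b < len(blocks) - 1:
            pause = rng.uniform(*spec.pause_jitter_s)
            pauses.append(pause)
            t += pause
    total = t + spec.lead_out_s
    meta = {
        "blocks": blocks,
        "block_onsets_s": block_onsets,
        "pauses_s": pauses,
        "total_duration_s": total,
        "sampling_rate_hz": sampling_rate_hz,
    }
    return markers, trials, meta


# --------------------------------------------------------------------------
# Sources and sensors
# --------------------------------------------------------------------------

def _one_over_f_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    shaped = np.fft.irfft(spec / np.sqrt(f), n=n)
    return shaped / max(shaped.std(), 1e-300)


def _event_envelope(
    n_samples: int,
    fs: float,
    onsets_s: np.ndarray,
    window_s: tuple[float, float],
    gain: float,
    ramp_s: float,
) -> np.ndarray:
    """1 + gain inside each event window, with short cosine ramps."""
    env = np.zeros(n_samples)
    box_n = int(round((window_s[1] - window_s[0]) * fs))
    ramp_n = max(1, int(round(ramp_s * fs)))
    shape = np.ones(box_n)
    edge = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    shape[:ramp_n] = edge
    shape[-ramp_n:] = edge[::-1]
    for onset in onsets_s:
        lo = int(round((onset + window_s[0]) * fs))
        hi = lo + box_n
        if lo < 0 or hi > n_samples:
            continue
        env[lo:hi] += shape
    return 1.0 + gain * np.clip(env, 0.0, 1.0)


def simulate_sources(
    spec: SourceSimSpec,
    markers: list[Marker],
    sampling_rate_hz: float,
    n_samples: int,
) -> SourceActivity:
    """Ground-truth vertex time courses.

    Occipital vertices carry an alpha oscillation whose envelope drops by
    ``suppression_depth`` inside the post-stimulus effect window of every
    stimulus; the frontal patch envelope rises by ``con_frontal_gain`` for
    congruent audiovisual stimuli only. A 1/f background can be added on a
    random vertex subset.
    """
    rng = np.random.default_rng(spec.seed)
    fs = sampling_rate_hz
    t = np.arange(n_samples) / fs
    stim = [m for m in markers if m.kind == "stimulus"]
    onsets = np.array([m.onset_sample / fs for m in stim])
    con_onsets = np.array(
        [m.onset_sample / fs for m in stim if m.congruence == "CON"]
    )

    occ_env = _event_envelope(
        n_samples, fs, onsets, spec.effect_window_s, -spec.suppression_depth, spec.ramp_s
    )
    fr_env = (
        _event_envelope(
            n_samples, fs, con_onsets, spec.effect_window_s, spec.con_frontal_gain,
            spec.ramp_s,
        )
        if con_onsets.size
        else np.ones(n_samples)
    )

    ids = [spec.occipital_patch, spec.frontal_patch]
    tcs = []
    sigma_step = np.sqrt(spec.phase_diffusion_rad2_s / fs)
    for patch, env in zip(ids, (occ_env, fr_env)):
        phases = spec.phase_jitter * rng.standard_normal(len(patch))
        drift = np.cumsum(sigma_step * rng.standard_normal(n_samples))
        carrier = np.sin(
            2 * np.pi * spec.alpha_f0_hz * t[None, :]
            + drift[None, :]
            + phases[:, None]
        )
        tcs.append(spec.alpha_amp * env[None, :] * carrier)

    all_ids = np.concatenate(ids)
    all_tcs = np.vstack(tcs)
    if spec.background_amp > 0 and spec.n_background > 0:
        pool = np.setdiff1d(
            np.arange(spec.source_space.n_vertices), all_ids
        )
        bg_ids = rng.choice(pool, size=min(spec.n_background, pool.size), replace=False)
        bg = np.stack(
            [spec.background_amp * _one_over_f_noise(n_samples, rng) for _ in bg_ids]
        )
        all_ids = np.concatenate([all_ids, bg_ids])
        all_tcs = np.vstack([all_tcs, bg])

    return SourceActivity(
        vertex_ids=all_ids,
        time_courses=all_tcs,
        n_vertices=spec.source_space.n_vertices,
        sampling_rate_hz=fs,
        occipital_envelope=occ_env,
        frontal_envelope=fr_env,
    )


def project_to_sensors(
    leadfield: LeadField,
    sources: SourceActivity | np.ndarray,
    sensor_noise_sd: float = 0.0,
    markers: list[Marker] | None = None,
    seed: int = 0,
    sampling_rate_hz: float = 250.0,
) -> Recording:
    """Forward-project source activity: data = L s + white noise (uV)."""
    rng = np.random.default_rng(seed)
    if isinstance(sources, SourceActivity):
        if sources.n_vertices != leadfield.n_sources:
            raise ValueError(
                f"lead field has {leadfield.n_sources} sources but activity spans "
                f"{sources.n_vertices}"
            )
        data = leadfield.matrix[:, sources.vertex_ids] @ sources.time_courses
        fs = sources.sampling_rate_hz
    else:
        s = np.asarray(sources, dtype=float)
        if s.shape[0] != leadfield.matrix.shape[1]:
            raise ValueError(
                f"source array has {s.shape[0]} rows; lead field expects "
                f"{leadfield.matrix.shape[1]}"
            )
        data = leadfield.matrix @ s
        fs = sampling_rate_hz
    if sensor_noise_sd > 0:
        data = data + sensor_noise_sd * rng.standard_normal(data.shape)
    return Recording(
        channel_labels=list(leadfield.channel_labels),
        sampling_rate_hz=fs,
        data=data,
        markers=list(markers) if markers else [],
    )


# --------------------------------------------------------------------------
# Artifacts
# --------------------------------------------------------------------------

def _gradient_template(
    n_channels: int, period_n: int, n_slices: int, amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-channel TR template: ``n_slices`` slice-locked sawtooth bursts."""
    template = np.zeros((n_channels, period_n))
    slice_n = period_n // n_slices
    burst_n = max(4, int(0.6 * slice_n))
    ramp = np.linspace(-1.0, 1.0, burst_n)
    gains = rng.uniform(0.5, 1.5, size=n_channels) * np.sign(
        rng.standard_normal(n_channels)
    )
    for s in range(n_slices):
        lo = s * slice_n
        template[:, lo : lo + burst_n] += gains[:, None] * ramp[None, :]
    return amp * template


def add_gradient_artifact(
    rec: Recording, spec: ArtifactSimSpec
) -> Recording:
    """Add an exactly TR-periodic gradient artifact plus volume_sync markers.

    The artifact covers ``floor(duration / TR)`` whole volumes starting at
    sample 0; a trailing partial volume stays clean.
    """
    fs = rec.sampling_rate_hz
    period_n = int(round(spec.tr_s * fs))
    if abs(period_n - spec.tr_s * fs) > 1e-6:
        raise ValueError("TR must be an integer number of samples")
    n_volumes = rec.n_samples // period_n
    rng = np.random.default_rng(spec.seed)
    out = rec.copy()
    if spec.gradient_amp_uv != 0 and n_volumes > 0:
        template = _gradient_template(
            rec.n_channels, period_n, spec.n_slices, spec.gradient_amp_uv, rng
        )
        tiled = np.tile(template, (1, n_volumes))
        out.data[:, : n_volumes * period_n] += tiled
    for v in range(n_volumes):
        out.markers.append(Marker(onset_sample=v * period_n, kind="volume_sync"))
    out.markers.sort(key=lambda m: m.onset_sample)
    return out


def _ecg_waveform(fs: float) -> np.ndarray:
    """One normalized heartbeat complex (symmetric R wave at the centre)."""
    t = np.arange(int(0.8 * fs)) / fs - 0.4
    r = np.exp(-((t / 0.012) ** 2))
    q = -0.15 * np.exp(-(((t + 0.035) / 0.02) ** 2))
    s = -0.2 * np.exp(-(((t - 0.035) / 0.02) ** 2))
    p = 0.15 * np.exp(-(((t + 0.18) / 0.04) ** 2))
    tw = 0.3 * np.exp(-(((t - 0.25) / 0.06) ** 2))
    return r + q + s + p + tw


def add_bcg_and_ecg(
    rec: Recording, spec: ArtifactSimSpec
) -> tuple[Recording, list[Marker]]:
    """Append a synthetic ECG channel and add R-peak-locked BCG artifacts.

    Returns the augmented recording and the ground-truth R-peak markers
    (also appended to the recording's marker list).
    """
    rng = np.random.default_rng(spec.seed + 1)
    fs = rec.sampling_rate_hz
    n = rec.n_samples
    rr_mean = 60.0 / spec.heart_rate_bpm

    peaks = []
    t = 0.5 * rr_mean
    while t < n / fs - 0.5:
        peaks.append(int(round(t * fs)))
        t += max(0.3, rr_mean + spec.rr_jitter_sd_s * rng.standard_normal())

    ecg = np.zeros(n)
    beat = spec.ecg_amp_uv * _ecg_waveform(fs)
    half = len(beat) // 2
    for p in peaks:
        lo, hi = p - half, p - half + len(beat)
        blo, bhi = max(0, -lo), len(beat) - max(0, hi - n)
        ecg[max(0, lo) : min(n, hi)] += beat[blo:bhi]

    # fixed per-channel BCG waveform: a few smoothed oscillation cycles
    dur_n = int(0.4 * fs)
    tb = np.arange(dur_n) / fs
    window = np.hanning(dur_n)
    base = window * np.sin(2 * np.pi * 5.0 * tb)
    gains = spec.bcg_amp_uv * rng.uniform(0.4, 1.0, size=rec.n_channels) * np.sign(
        rng.standard_normal(rec.n_channels)
    )
    lag_n = int(round(spec.bcg_lag_s * fs))

    out = rec.copy()
    if spec.bcg_amp_uv != 0:
        for p in peaks:
            lo = p + lag_n
            hi = lo + dur_n
            if lo < 0 or hi > n:
                continue
            jitter = 1.0 + spec.bcg_amp_jitter * rng.standard_normal()
            out.data[:, lo:hi] += jitter * gains[:, None] * base[None, :]

    out.channel_labels = list(out.channel_labels) + ["ECG"]
    out.data = np.vstack([out.data, ecg[None, :]])
    r_markers = [Marker(onset_sample=p, kind="r_peak") for p in peaks]
    out.markers = sorted(out.markers + r_markers, key=lambda m: m.onset_sample)
    return out, r_markers


def add_blinks(
    rec: Recording, spec: ArtifactSimSpec, frontal_labels: tuple[str, ...]
) -> tuple[Recording, np.ndarray]:
    """Add eye blinks with a frontally weighted topography.

    Returns the recording plus the ground-truth blink time course (uV at
    the most frontal site).
    """
    rng = np.random.default_rng(spec.seed + 2)
    fs = rec.sampling_rate_hz
    n = rec.n_samples
    n_blinks = rng.poisson(spec.blink_rate_per_min * n / fs / 60.0)
    blink_tc = np.zeros(n)
    dur_n = int(0.3 * fs)
    shape = np.hanning(dur_n) ** 2
    for _ in range(n_blinks):
        lo = rng.integers(0, max(1, n - dur_n))
        blink_tc[lo : lo + dur_n] += spec.blink_amp_uv * shape

    # exponential fall-off with distance from the frontal pole
    weights = np.zeros(rec.n_channels)
    for i, label in enumerate(rec.channel_labels):
        if label in frontal_labels:
            weights[i] = 1.0
        elif label.startswith("F") and label != "FCz":
            weights[i] = 0.3
        elif label.startswith(("C", "T")):
            weights[i] = 0.05
    out = rec.copy()
    out.data += weights[:, None] * blink_tc[None, :]
    return out, blink_tc


def add_movement_spikes(
    rec: Recording, spec: ArtifactSimSpec
) -> tuple[Recording, list[int]]:
    """Occasional large transient bursts on random channel subsets."""
    rng = np.random.default_rng(spec.seed + 3)
    fs = rec.sampling_rate_hz
    n = rec.n_samples
    n_spikes = rng.poisson(spec.spike_rate_per_min * n / fs / 60.0)
    dur_n = max(2, int(0.3 * fs))
    shape = np.hanning(dur_n)
    out = rec.copy()
    onsets = []
    for _ in range(n_spikes):
        lo = int(rng.integers(0, max(1, n - dur_n)))
        chans = rng.choice(
            rec.n_channels, size=max(1, rec.n_channels // 8), replace=False
        )
        polarity = rng.choice([-1.0, 1.0])
        out.data[np.ix_(chans, range(lo, lo + dur_n))] += (
            polarity * spec.spike_amp_uv * shape[None, :]
        )
        onsets.append(lo)
    return out, onsets


# --------------------------------------------------------------------------
# Behaviour
# --------------------------------------------------------------------------

def simulate_behavior(
    trials: list[TrialRecord],
    accuracy: dict[str, float] | None = None,
    inc_proportions: tuple[float, float, float] = DEFAULT_INC_PROPORTIONS,
    omission_rate: float = 0.02,
    seed: int = 0,
) -> list[TrialRecord]:
    """Fill correctness / responses per condition (Bernoulli draws).

    ``accuracy`` maps ``auditory``/``visual``/``CON`` to hit rates. INC
    trials are assigned a face/voice/neither decision with the configured
    proportions (renormalized); "neither" counts as incorrect.
    """
    rng = np.random.default_rng(seed)
    acc = dict(DEFAULT_ACCURACY)
    if accuracy:
        acc.update(accuracy)
    props = np.asarray(inc_proportions, dtype=float)
    props = props / props.sum()

    out = []
    for t in trials:
        if rng.random() < omission_rate:
            out.append(
                replace(
                    t,
                    response_code=None,
                    correctness="omitted",
                    inc_decision="n/a",
                    included=False,
                )
            )
            continue
        if t.congruence == "INC":
            decision = ("face", "voice", "neither")[
                rng.choice(3, p=props)
            ]
            correct = decision != "neither"
            out.append(
                replace(
                    t,
                    response_code=int(rng.integers(1, 4)),
                    correctness="correct" if correct else "incorrect",
                    inc_decision=decision,
                    included=True,
                )
            )
        else:
            key = "CON" if t.congruence == "CON" else t.modality
            correct = rng.random() < acc[key]
            out.append(
                replace(
                    t,
                    response_code=int(rng.integers(1, 4)),
                    correctness="correct" if correct else "incorrect",
                    inc_decision="n/a",
                    included=True,
                )
            )
    return out


# --------------------------------------------------------------------------
# BOLD
# --------------------------------------------------------------------------

def simulate_bold(
    markers: list[Marker],
    trial_alpha: np.ndarray,
    spec: CouplingSimSpec,
    grid_shape: tuple[int, int, int] = (20, 20, 10),
    tr_s: float = 2.0,
    n_volumes: int | None = None,
    sampling_rate_hz: float = 250.0,
    t0_s: float = 0.0,
    voxel_size_mm: float = 3.0,
) -> VolumeSeries:
    """BOLD series with voxels coupled to the HRF-convolved trial-alpha
    regressor (gain ``spec.gain``) plus drift and Gaussian noise."""
    from .coupling import build_alpha_regressor

    if spec.coupled_mask.shape != tuple(grid_shape):
        raise ValueError("coupled mask shape must match the volume grid")
    stim = [m for m in markers if m.kind == "stimulus"]
    onsets_s = np.array([m.onset_sample / sampling_rate_hz for m in stim])
    if n_volumes is None:
        n_volumes = int(np.ceil((onsets_s.max() + 30.0 - t0_s) / tr_s))
    reg = build_alpha_regressor(
        np.asarray(trial_alpha, dtype=float), onsets_s, tr_s, n_volumes, t0_s=t0_s
    )

    rng = np.random.default_rng(spec.seed)
    t = t0_s + np.arange(n_volumes) * tr_s
    drift = spec.drift_amp * np.sin(2 * np.pi * t / spec.drift_period_s) + (
        spec.drift_amp * 0.5 / max(t[-1] - t[0], 1.0)
    ) * (t - t[0])

    data = np.empty(tuple(grid_shape) + (n_volumes,), dtype=np.float64)
    data[...] = spec.baseline + drift
    if spec.noise_sd > 0:
        data += spec.noise_sd * rng.standard_normal(data.shape)
    data[spec.coupled_mask] += spec.gain * reg

    affine = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return VolumeSeries(data=data, tr_s=tr_s, affine=affine)


# --------------------------------------------------------------------------
# Full session
# --------------------------------------------------------------------------

def simulate_session(
    seed: int = 0,
    paradigm: ParadigmSpec | None = None,
    artifact: ArtifactSimSpec | None = None,
    sampling_rate_hz: float = 1000.0,
    n_sources_per_hemi: int = 400,
    sensor_alpha_rms_uv: float = 8.0,
    sensor_noise_sd_uv: float = 3.0,
    suppression_depth: float = 0.5,
    con_frontal_gain: float = 0.5,
    grid_shape: tuple[int, int, int] = (20, 20, 10),
    with_bold: bool = True,
) -> dict:
    """End-to-end synthetic session (desk-scale defaults).

    Default paradigm is a reduced 4-block layout (1 auditory, 1 visual, 2
    audiovisual); pass ``ParadigmSpec()`` for the full 32-block design.
    Returns a dict with the artifact-laden recording, electrode set, lead
    field, markers/trials and ground truth for every stage.
    """
    from .inverse import (
        HeadModel,
        build_source_space,
        compute_leadfield,
        coregister_electrodes,
        geodesic_patch,
    )
    from .io_core import standard_montage

    paradigm = paradigm or ParadigmSpec(
        n_auditory_blocks=1,
        n_visual_blocks=1,
        n_audiovisual_blocks=2,
        seed=seed,
    )
    artifact = artifact or ArtifactSimSpec(seed=seed)

    markers, trials, meta = build_paradigm(paradigm, sampling_rate_hz)
    n_samples = int(round(meta["total_duration_s"] * sampling_rate_hz))

    head = HeadModel()
    montage = standard_montage(radius_mm=head.scalp_radius_mm)
    electrodes, _ = coregister_electrodes(montage, head)
    recorded = electrodes.subset(
        [l for l in electrodes.labels if l not in ("AFz", "FCz")]
    )
    src = build_source_space(n_sources_per_hemi, head=head)
    occ = np.concatenate(
        [
            geodesic_patch(src, [0.0, -1.0, -0.3], 18.0, hemi=h)
            for h in ("lh", "rh")
        ]
    )
    fro = np.concatenate(
        [
            geodesic_patch(src, [0.0, 1.0, 0.4], 15.0, hemi=h)
            for h in ("lh", "rh")
        ]
    )
    L = compute_leadfield(head, src, recorded)

    src_spec = SourceSimSpec(
        source_space=src,
        occipital_patch=occ,
        frontal_patch=fro,
        suppression_depth=suppression_depth,
        con_frontal_gain=con_frontal_gain,
        seed=seed,
    )
    activity = simulate_sources(src_spec, markers, sampling_rate_hz, n_samples)

    # calibrate source amplitude so projected alpha has the requested RMS
    proj = L.matrix[:, activity.vertex_ids] @ activity.time_courses[:, : int(5 * sampling_rate_hz)]
    scale = sensor_alpha_rms_uv / max(np.sqrt(np.mean(proj**2)), 1e-30)
    activity.time_courses *= scale

    rec = project_to_sensors(
        L, activity, sensor_noise_sd=sensor_noise_sd_uv, markers=markers, seed=seed
    )
    rec.sampling_rate_hz = sampling_rate_hz
    rec = add_gradient_artifact(rec, artifact)
    rec, blink_tc = add_blinks(rec, artifact, frontal_labels=("Fp1", "Fpz", "Fp2"))
    rec, spikes = add_movement_spikes(rec, artifact)
    rec, r_peaks = add_bcg_and_ecg(rec, artifact)

    trials = simulate_behavior(trials, seed=seed)

    result = {
        "recording": rec,
        "markers": markers,
        "trials": trials,
        "meta": meta,
        "electrodes": electrodes,
        "head": head,
        "source_space": src,
        "leadfield": L,
        "occipital_patch": occ,
        "frontal_patch": fro,
        "activity": activity,
        "r_peaks": r_peaks,
        "blink_tc": blink_tc,
        "spike_onsets": spikes,
    }

    if with_bold:
        # ground-truth trial alpha: negative deviation during suppression
        trial_alpha = np.full(len(trials), -suppression_depth)
        mask = np.zeros(grid_shape, dtype=bool)
        gx, gy, gz = grid_shape
        mask[gx // 4 : gx // 2, gy // 4 : gy // 2, gz // 4 : 3 * gz // 4] = True
        cspec = CouplingSimSpec(coupled_mask=mask, seed=seed)
        bold = simulate_bold(
            markers,
            trial_alpha,
            cspec,
            grid_shape=grid_shape,
            tr_s=artifact.tr_s,
            sampling_rate_hz=sampling_rate_hz,
            t0_s=-2 * artifact.tr_s,
        )
        result.update(
            {"bold": bold, "coupled_mask": mask, "trial_alpha_truth": trial_alpha,
             "coupling_spec": cspec}
        )
    return result
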