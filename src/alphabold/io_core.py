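"""Core data model, standard-format I/O and signal primitives.

Everything downstream (simulation, cleaning, time-frequency, inverse
modelling, EEG-informed fMRI coupling) operates on the container types
defined here: :class:`Recording`, :class:`Marker`, :class:`ElectrodeSet`,
:class:`VolumeSeries` and :class:`TrialRecord`.

File formats
------------
* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``) in a fixed dialect:
  binary IEEE float32, multiplexed channel order, one marker line per event.
  Vectorized or ASCII variants are rejected with a clear message.
* NIfTI-1 4D BOLD series via :mod:`nibabel` (TR carried in the time zoom).
* Stimulus/response timing logs as TSV with a documented column set
  (see :func:`parse_stimulus_log`).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.signal

__all__ = [
    "Marker",
    "Recording",
    "ElectrodeSet",
    "VolumeSeries",
    "TrialRecord",
    "MARKER_KINDS",
    "MODALITIES",
    "EMOTIONS",
    "CONGRUENCE_LEVELS",
    "read_brainvision",
    "write_brainvision",
    "read_volume",
    "write_volume",
    "parse_stimulus_log",
    "write_stimulus_log",
    "resample",
    "iir_lowpass",
    "standard_montage",
    "read_electrodes_tsv",
    "write_electrodes_tsv",
    "PipelineOrderError",
]

MARKER_KINDS = frozenset({"volume_sync", "slice_sync", "stimulus", "response", "r_peak"})
MODALITIES = frozenset({"auditory", "visual", "audiovisual", "none"})
EMOTIONS = frozenset({"angry", "happy", "neutral", "none"})
CONGRUENCE_LEVELS = frozenset({"CON", "INC", "n/a"})

#: Threshold above which a stimulus presentation is flagged for exclusion.
MAX_PRESENTATION_UNCERTAINTY_MS = 10.0


class PipelineOrderError(RuntimeError):
    """Raised when cleaning stages are applied out of the enforced order."""


@dataclass
class Marker:
    """A time-stamped event on a :class:`Recording`.

    ``congruence`` is constrained: a stimulus marker is ``"CON"`` iff the
    modality is audiovisual and the two emotions agree, ``"INC"`` iff
    audiovisual and they differ, and ``"n/a"`` otherwise.
    """

    onset_sample: int
    kind: str
    modality: str = "none"
    visual_emotion: str = "none"
    auditory_emotion: str = "none"
    congruence: str = "n/a"
    response_code: int | None = None
    uncertainty_ms: float = 0.0

    def __post_init__(self) -> None:
        self.onset_sample = int(self.onset_sample)
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        for emo in (self.visual_emotion, self.auditory_emotion):
            if emo not in EMOTIONS:
                raise ValueError(f"unknown emotion {emo!r}")
        if self.congruence not in CONGRUENCE_LEVELS:
            raise ValueError(f"unknown congruence {self.congruence!r}")
        if self.uncertainty_ms < 0:
            raise ValueError("uncertainty_ms must be >= 0")
        if self.kind == "stimulus" and self.modality == "audiovisual":
            expected = "CON" if self.visual_emotion == self.auditory_emotion else "INC"
            if self.congruence != expected:
                raise ValueError(
                    f"audiovisual stimulus with emotions "
                    f"({self.visual_emotion}, {self.auditory_emotion}) must have "
                    f"congruence {expected!r}, got {self.congruence!r}"
                )
        elif self.congruence != "n/a":
            raise ValueError("congruence applies only to audiovisual stimuli")

    @property
    def uncertainty_excluded(self) -> bool:
        """Flagged (not dropped) when presentation uncertainty exceeds 10 ms."""
        return self.uncertainty_ms > MAX_PRESENTATION_UNCERTAINTY_MS


@dataclass
class Recording:
    """Multichannel EEG time series in microvolts.

    ``data`` has shape ``(n_channels, n_samples)``; ``history`` tracks the
    cleaning stages already applied so that the enforced pipeline order can
    be checked.
    """

    channel_labels: list[str]
    sampling_rate_hz: float
    data: np.ndarray
    markers: list[Marker] = field(default_factory=list)
    reference: str = "AFz"
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        for m in self.markers:
            if not 0 <= m.onset_sample < self.n_samples:
                raise ValueError(
                    f"marker onset {m.onset_sample} outside [0, {self.n_samples})"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r} in recording") from None

    def markers_of_kind(self, kind: str) -> list[Marker]:
        return [m for m in self.markers if m.kind == kind]

    def copy(self) -> "Recording":
        return Recording(
            channel_labels=list(self.channel_labels),
            sampling_rate_hz=self.sampling_rate_hz,
            data=self.data.copy(),
            markers=list(self.markers),
            reference=self.reference,
            history=list(self.history),
        )


@dataclass
class ElectrodeSet:
    """Digitized electrode positions plus fiducials.

    ``frame`` is one of ``digitizer`` (raw), ``head`` (fiducial-aligned) or
    ``sphere`` (projected onto the scalp shell of a head model).
    """

    labels: list[str]
    positions_mm: np.ndarray
    fiducials: dict[str, np.ndarray]
    frame: str = "digitizer"

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        if self.positions_mm.shape != (len(self.labels), 3):
            raise ValueError("positions_mm must be (n_labels, 3)")
        if self.frame not in {"digitizer", "head", "sphere"}:
            raise ValueError(f"unknown frame {self.frame!r}")
        required = {"nasion", "lpa", "rpa"}
        if set(self.fiducials) != required:
            raise ValueError(f"fiducials must be exactly {sorted(required)}")
        self.fiducials = {k: np.asarray(v, dtype=float) for k, v in self.fiducials.items()}
        nas, lpa, rpa = (self.fiducials[k] for k in ("nasion", "lpa", "rpa"))
        cross = np.cross(rpa - lpa, nas - lpa)
        if np.linalg.norm(cross) < 1e-9 * max(np.linalg.norm(rpa - lpa), 1e-12):
            raise ValueError("fiducials are collinear")

    def position_of(self, label: str) -> np.ndarray:
        return self.positions_mm[self.labels.index(label)]

    def subset(self, labels: list[str]) -> "ElectrodeSet":
        pos = np.stack([self.position_of(l) for l in labels])
        return ElectrodeSet(list(labels), pos, dict(self.fiducials), self.frame)


@dataclass
class VolumeSeries:
    """4-D BOLD array with repetition time and voxel-to-world affine."""

    data: np.ndarray
    tr_s: float
    affine: np.ndarray
    n_discarded_leading: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("VolumeSeries data must be 4-D (x, y, z, t)")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class TrialRecord:
    """Per-trial behavioural/condition record used for inclusion decisions."""

    trial_id: int
    marker_index: int
    modality: str
    visual_emotion: str = "none"
    auditory_emotion: str = "none"
    congruence: str = "n/a"
    gender: str = "none"
    response_code: int | None = None
    correctness: str = "correct"
    inc_decision: str = "n/a"
    included: bool = True

    def __post_init__(self) -> None:
        if self.correctness not in {"correct", "incorrect", "omitted"}:
            raise ValueError(f"bad correctness {self.correctness!r}")
        if self.inc_decision not in {"face", "voice", "neither", "n/a"}:
            raise ValueError(f"bad inc_decision {self.inc_decision!r}")
        if self.correctness == "omitted" and self.included:
            raise ValueError("omitted trials cannot be included")


# --------------------------------------------------------------------------
# BrainVision triplet I/O (fixed dialect: IEEE float32, multiplexed)
# --------------------------------------------------------------------------

_BV_RESOLUTION_UV = 0.1  # stored value x resolution = microvolts

_MARKER_FIELD_KEYS = (
    ("modality", "mod"),
    ("visual_emotion", "ve"),
    ("auditory_emotion", "ae"),
    ("congruence", "c"),
    ("response_code", "r"),
    ("uncertainty_ms", "u"),
)


def _marker_description(m: Marker) -> str:
    parts = []
    for attr, key in _MARKER_FIELD_KEYS:
        val = getattr(m, attr)
        if val is None:
            continue
        parts.append(f"{key}={val}")
    return ";".join(parts)


def _marker_from_vmrk(kind: str, desc: str, position_1based: int) -> Marker:
    kwargs: dict[str, object] = {}
    if desc:
        for part in desc.split(";"):
            key, _, val = part.partition("=")
            for attr, k in _MARKER_FIELD_KEYS:
                if k == key:
                    if attr == "response_code":
                        kwargs[attr] = int(val)
                    elif attr == "uncertainty_ms":
                        kwargs[attr] = float(val)
                    else:
                        kwargs[attr] = val
    return Marker(onset_sample=position_1based - 1, kind=kind, **kwargs)  # type: ignore[arg-type]


def write_brainvision(rec: Recording, stem: str | Path) -> tuple[Path, Path, Path]:
    """Write ``rec`` as a BrainVision triplet ``stem.vhdr/.vmrk/.eeg``.

    Data are stored as IEEE float32 in units of 0.1 uV (the header
    resolution), multiplexed (sample-major).
    """
    stem = Path(stem)
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    stem.parent.mkdir(parents=True, exist_ok=True)

    sampling_interval_us = 1e6 / rec.sampling_rate_hz
    lines = [
        "BrainVision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us!r}",
        f"Reference={rec.reference}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, label in enumerate(rec.channel_labels, start=1):
        lines.append(f"Ch{i}={label},,{_BV_RESOLUTION_UV},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
    ]
    for i, m in enumerate(rec.markers, start=1):
        mlines.append(
            f"Mk{i}={m.kind},{_marker_description(m)},{m.onset_sample + 1},1,0"
        )
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    scaled = (rec.data / _BV_RESOLUTION_UV).astype("<f4")
    scaled.T.tofile(eeg)  # multiplexed: sample-major
    return vhdr, vmrk, eeg


def _parse_bv_ini(text: str) -> tuple[dict[str, str], dict[str, str]]:
    """Parse the simple key=value sections of a .vhdr/.vmrk file."""
    flat: dict[str, str] = {}
    channels: dict[str, str] = {}
    section = ""
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";") or line.startswith("BrainVision"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            continue
        key, _, val = line.partition("=")
        if section == "Channel Infos" or key.startswith("Mk"):
            channels[key] = val
        else:
            flat[key] = val
    return flat, channels


def read_brainvision(header_path: str | Path) -> Recording:
    """Read a BrainVision triplet into a :class:`Recording` (units uV).

    Only the dialect written by :func:`write_brainvision` is supported:
    binary, IEEE float32, multiplexed. Missing companion files and
    channel-count mismatches raise descriptive errors.
    """
    vhdr = Path(header_path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    info, chans = _parse_bv_ini(vhdr.read_text(encoding="utf-8"))

    if info.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError(f"unsupported DataFormat {info.get('DataFormat')!r}; only BINARY")
    if info.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError(
            f"unsupported DataOrientation {info.get('DataOrientation')!r}; only MULTIPLEXED"
        )
    if info.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError(
            f"unsupported BinaryFormat {info.get('BinaryFormat')!r}; only IEEE_FLOAT_32"
        )

    n_channels = int(info["NumberOfChannels"])
    sfreq = 1e6 / float(info["SamplingInterval"])

    labels: list[str] = []
    resolutions: list[float] = []
    for i in range(1, n_channels + 1):
        key = f"Ch{i}"
        if key not in chans:
            raise ValueError(f"header declares {n_channels} channels but {key} is missing")
        fields = chans[key].split(",")
        labels.append(fields[0])
        resolutions.append(float(fields[2]) if len(fields) > 2 and fields[2] else 1.0)

    eeg = vhdr.parent / info["DataFile"]
    if not eeg.exists():
        raise FileNotFoundError(f"data file referenced by header not found: {eeg}")
    raw = np.fromfile(eeg, dtype="<f4")
    if raw.size % n_channels != 0:
        raise ValueError(
            f"data file size ({raw.size} values) is not a multiple of the "
            f"channel count ({n_channels})"
        )
    data = raw.reshape(-1, n_channels).T.astype(np.float64)
    data *= np.asarray(resolutions)[:, None]

    markers: list[Marker] = []
    vmrk = vhdr.parent / info["MarkerFile"] if "MarkerFile" in info else None
    if vmrk is not None:
        if not vmrk.exists():
            raise FileNotFoundError(f"marker file referenced by header not found: {vmrk}")
        _, mk = _parse_bv_ini(vmrk.read_text(encoding="utf-8"))
        for key in sorted(mk, key=lambda k: int(k[2:])):
            fields = mk[key].split(",")
            kind, desc, pos = fields[0], fields[1], int(fields[2])
            if kind == "New Segment":
                continue
            markers.append(_marker_from_vmrk(kind, desc, pos))

    return Recording(
        channel_labels=labels,
        sampling_rate_hz=sfreq,
        data=data,
        markers=markers,
        reference=info.get("Reference", "AFz"),
    )


# --------------------------------------------------------------------------
# NIfTI volume I/O
# --------------------------------------------------------------------------

def write_volume(vs: VolumeSeries, path: str | Path) -> Path:
    """Write a :class:`VolumeSeries` to NIfTI-1 (TR stored in the time zoom)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vs.data, dtype=np.float32), vs.affine)
    zooms = tuple(vs.voxel_size_mm) + (vs.tr_s,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> VolumeSeries:
    """Read a 4-D NIfTI file. Non-4D input is rejected."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected a 4-D BOLD series, got {data.ndim}-D data in {path}")
    tr = float(img.header.get_zooms()[3])
    return VolumeSeries(data=data, tr_s=tr, affine=np.asarray(img.affine))


# --------------------------------------------------------------------------
# Stimulus log (documented TSV schema)
# --------------------------------------------------------------------------

LOG_COLUMNS = [
    "onset_s",
    "kind",
    "modality",
    "visual_emotion",
    "auditory_emotion",
    "response_code",
    "uncertainty_ms",
]


def write_stimulus_log(markers: list[Marker], path: str | Path, sampling_rate_hz: float) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LOG_COLUMNS)
        for m in markers:
            writer.writerow(
                [
                    f"{m.onset_sample / sampling_rate_hz:.6f}",
                    m.kind,
                    m.modality,
                    m.visual_emotion,
                    m.auditory_emotion,
                    "" if m.response_code is None else m.response_code,
                    f"{m.uncertainty_ms:.3f}",
                ]
            )
    return path


def parse_stimulus_log(log: str | Path, sampling_rate_hz: float) -> list[Marker]:
    """Parse a TSV timing log into markers.

    Rows with presentation uncertainty above 10 ms are *flagged* via
    :attr:`Marker.uncertainty_excluded`, not dropped, so that downstream
    exclusion is explicit. Malformed rows raise with the offending line
    number.
    """
    path = Path(log)
    markers: list[Marker] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != LOG_COLUMNS:
            raise ValueError(
                f"{path}: line 1: expected header {LOG_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(LOG_COLUMNS):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(LOG_COLUMNS)} fields, got {len(row)}"
                )
            try:
                onset_s = float(row[0])
                kind, modality, vemo, aemo = row[1], row[2], row[3], row[4]
                resp = int(row[5]) if row[5].strip() else None
                unc = float(row[6])
                if modality == "audiovisual":
                    congruence = "CON" if vemo == aemo else "INC"
                else:
                    congruence = "n/a"
                markers.append(
                    Marker(
                        onset_sample=int(round(onset_s * sampling_rate_hz)),
                        kind=kind,
                        modality=modality,
                        visual_emotion=vemo,
                        auditory_emotion=aemo,
                        congruence=congruence,
                        response_code=resp,
                        uncertainty_ms=unc,
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return markers


# --------------------------------------------------------------------------
# Resampling and filtering
# --------------------------------------------------------------------------

def resample(rec: Recording, target_hz: float) -> Recording:
    """Anti-aliased (Fourier) downsampling to ``target_hz``.

    The current rate must be an integer multiple of the target; upsampling
    is rejected. Marker onsets are rescaled with round-half-even; a trailing
    remainder of fewer than one decimation factor of samples is trimmed.
    """
    fs = rec.sampling_rate_hz
    if target_hz >= fs:
        raise ValueError(f"upsampling not supported ({fs} Hz -> {target_hz} Hz)")
    factor = fs / target_hz
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {fs} Hz is not an integer multiple of target {target_hz} Hz"
        )
    q = int(round(factor))
    n_keep = (rec.n_samples // q) * q
    data = rec.data[:, :n_keep]
    n_new = n_keep // q
    out = scipy.signal.resample(data, n_new, axis=1)

    markers = []
    for m in rec.markers:
        onset = int(np.round(m.onset_sample / q))  # numpy round: half-to-even
        if onset >= n_new:
            onset = n_new - 1
        markers.append(
            Marker(
                onset_sample=onset,
                kind=m.kind,
                modality=m.modality,
                visual_emotion=m.visual_emotion,
                auditory_emotion=m.auditory_emotion,
                congruence=m.congruence,
                response_code=m.response_code,
                uncertainty_ms=m.uncertainty_ms,
            )
        )
    return Recording(
        channel_labels=list(rec.channel_labels),
        sampling_rate_hz=target_hz,
        data=out,
        markers=markers,
        reference=rec.reference,
        history=rec.history + [f"resample:{target_hz:g}"],
    )


def iir_lowpass(rec: Recording, cutoff_hz: float = 70.0, slope_db_oct: float = 48.0) -> Recording:
    """Zero-phase IIR low-pass (Butterworth, order = slope/6 dB per octave).

    The default 70 Hz / 48 dB-per-octave setting corresponds to an order-8
    Butterworth applied forward-backward (``sosfiltfilt``), preserving DC
    gain and latencies.
    """
    nyq = rec.sampling_rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    order = max(1, int(round(slope_db_oct / 6.0)))
    sos = scipy.signal.butter(order, cutoff_hz, btype="low", fs=rec.sampling_rate_hz, output="sos")
    out = rec.copy()
    out.data = scipy.signal.sosfiltfilt(sos, rec.data, axis=1)
    out.history.append(f"lowpass:{cutoff_hz:g}")
    return out


# --------------------------------------------------------------------------
# Idealized spherical montage (63 recorded channels + AFz/FCz targets)
# --------------------------------------------------------------------------

# (anterior-posterior angle, lateral angle) in degrees on an azimuthal-
# equidistant layout; positive a = anterior, positive b = right.
_MONTAGE_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (72, -18), "Fpz": (72, 0), "Fp2": (72, 18),
    "AF7": (54, -54), "AF3": (54, -27), "AF4": (54, 27), "AF8": (54, 54),
    "F7": (36, -72), "F5": (36, -54), "F3": (36, -36), "F1": (36, -18),
    "Fz": (36, 0),
    "F2": (36, 18), "F4": (36, 36), "F6": (36, 54), "F8": (36, 72),
    "FT9": (18, -90), "FT7": (18, -72), "FC5": (18, -54), "FC3": (18, -36),
    "FC1": (18, -18),
    "FC2": (18, 18), "FC4": (18, 36), "FC6": (18, 54), "FT8": (18, 72),
    "FT10": (18, 90),
    "T7": (0, -72), "C5": (0, -54), "C3": (0, -36), "C1": (0, -18),
    "Cz": (0, 0),
    "C2": (0, 18), "C4": (0, 36), "C6": (0, 54), "T8": (0, 72),
    "TP9": (-18, -90), "TP7": (-18, -72), "CP5": (-18, -54), "CP3": (-18, -36),
    "CP1": (-18, -18), "CPz": (-18, 0),
    "CP2": (-18, 18), "CP4": (-18, 36), "CP6": (-18, 54), "TP8": (-18, 72),
    "TP10": (-18, 90),
    "P7": (-36, -72), "P5": (-36, -54), "P3": (-36, -36), "P1": (-36, -18),
    "Pz": (-36, 0),
    "P2": (-36, 18), "P4": (-36, 36), "P6": (-36, 54), "P8": (-36, 72),
    "PO7": (-54, -54), "PO3": (-54, -27), "POz": (-54, 0), "PO4": (-54, 27),
    "PO8": (-54, 54),
    "O1": (-72, -18), "Oz": (-72, 0), "O2": (-72, 18),
    # interpolation targets (recording reference/ground in the paradigm)
    "AFz": (54, 0), "FCz": (18, 0),
}

#: Labels recorded by the 63-channel scalp montage (AFz/FCz are synthesized).
SCALP_LABELS_63: list[str] = [l for l in _MONTAGE_ANGLES if l not in ("AFz", "FCz")]
INTERP_TARGETS: tuple[str, str] = ("AFz", "FCz")
FRONTAL_LABELS: tuple[str, ...] = ("Fp1", "Fpz", "Fp2", "AF7", "AF3", "AF4", "AF8")


def _angles_to_xyz(a_deg: float, b_deg: float, radius: float) -> np.ndarray:
    rho = math.hypot(a_deg, b_deg)
    if rho == 0:
        return np.array([0.0, 0.0, radius])
    rho_rad = math.radians(rho)
    return radius * np.array(
        [
            math.sin(rho_rad) * b_deg / rho,
            math.sin(rho_rad) * a_deg / rho,
            math.cos(rho_rad),
        ]
    )


def standard_montage(radius_mm: float = 92.0, include_targets: bool = True) -> ElectrodeSet:
    """Idealized spherical 10-10 montage (63 scalp channels, optional AFz/FCz).

    Coordinates: +x right, +y anterior, +z superior; sphere centred at the
    origin with the given scalp radius. Fiducials are placed on canonical
    axes so that fiducial-based co-registration of this montage is the
    identity.
    """
    labels = list(SCALP_LABELS_63) + (list(INTERP_TARGETS) if include_targets else [])
    pos = np.stack([_angles_to_xyz(*_MONTAGE_ANGLES[l], radius_mm) for l in labels])
    fiducials = {
        "nasion": np.array([0.0, radius_mm + 3.0, 0.0]),
        "lpa": np.array([-(radius_mm + 3.0), 0.0, 0.0]),
        "rpa": np.array([radius_mm + 3.0, 0.0, 0.0]),
    }
    return ElectrodeSet(labels, pos, fiducials, frame="head")


def write_electrodes_tsv(eset: ElectrodeSet, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["label", "x_mm", "y_mm", "z_mm"])
        for name, p in eset.fiducials.items():
            writer.writerow([f"fid:{name}", *(f"{v:.4f}" for v in p)])
        for label, p in zip(eset.labels, eset.positions_mm):
            writer.writerow([label, *(f"{v:.4f}" for v in p)])
    return path


def read_electrodes_tsv(path: str | Path, frame: str = "digitizer") -> ElectrodeSet:
    path = Path(path)
    labels: list[str] = []
    positions: list[list[float]] = []
    fiducials: dict[str, np.ndarray] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:4] != ["label", "x_mm", "y_mm", "z_mm"]:
            raise ValueError(f"{path}: unexpected electrode TSV header {header}")
        for row in reader:
            if not row:
                continue
            label, xyz = row[0], np.array([float(v) for v in row[1:4]])
            if label.startswith("fid:"):
                fiducials[label[4:]] = xyz
            else:
                labels.append(label)
                positions.append(list(xyz))
    return ElectrodeSet(labels, np.asarray(positions), fiducials, frame=frame)


def check_stage_order(history: list[str], stage: str, order: list[str]) -> None:
    """Raise :class:`PipelineOrderError` if ``stage`` would run after a later stage."""
    if stage not in order:
        return
    idx = order.index(stage)
    later = set(order[idx + 1:])
    for h in history:
        base = h.split(":")[0]
        if base in later:
            raise PipelineOrderError(
                f"stage {stage!r} must run before {base!r}, but {base!r} is already applied "
                f"(history: {history})"
            )
    if stage in {h.split(":")[0] for h in history}:
        warnings.warn(f"stage {stage!r} applied more than once", stacklevel=3)
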