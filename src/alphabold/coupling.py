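"""EEG-informed fMRI stage: POI definition, single-trial POI alpha values,
trial scoring, HRF regressors, minimal BOLD preprocessing, per-voxel GLM
and Monte-Carlo cluster-extent thresholding."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.ndimage
import scipy.sparse.csgraph
import scipy.stats

from .io_core import TrialRecord, VolumeSeries
from .inverse import InverseOperator, SourceSpace, SourceStatMap, apply_inverse

__all__ = [
    "Poi",
    "DesignMatrix",
    "StatVolume",
    "ClusterThreshold",
    "hrf_double_gamma",
    "define_poi",
    "poi_alpha_timecourse",
    "score_trials",
    "build_alpha_regressor",
    "preprocess_bold_minimal",
    "fit_glm",
    "cluster_threshold_mc",
    "couple",
]


@dataclass
class Poi:
    """Patch of interest: vertex ids with normalized non-negative weights."""

    vertex_ids: np.ndarray
    weights: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.vertex_ids = np.asarray(self.vertex_ids, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.vertex_ids.size == 0:
            raise ValueError("POI must be non-empty")
        if np.any(self.weights < 0):
            raise ValueError("POI weights must be non-negative")
        s = self.weights.sum()
        if s <= 0:
            raise ValueError("POI weights must not all be zero")
        self.weights = self.weights / s


@dataclass
class DesignMatrix:
    """TR-gridded GLM design: columns stacked as (n_volumes, n_regressors)."""

    matrix: np.ndarray
    names: list[str]
    tr_s: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix columns must match names")
        zero = np.all(self.matrix == 0, axis=0)
        if np.any(zero):
            bad = [n for n, z in zip(self.names, zero) if z]
            raise ValueError(f"all-zero design columns not allowed: {bad}")


@dataclass
class StatVolume:
    """Per-voxel GLM output for one contrast."""

    beta: np.ndarray
    t: np.ndarray
    r: np.ndarray
    df: int
    contrast: str


@dataclass
class ClusterThreshold:
    voxelwise_p: float
    min_cluster_size: int
    n_iterations: int
    fwhm_mm: float
    max_sizes: np.ndarray

    def __post_init__(self) -> None:
        if self.min_cluster_size < 1:
            raise ValueError("min cluster size must be >= 1")


def hrf_double_gamma(
    t_s: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma HRF, peak-normalized to 1.

    Built from gamma pdfs with modes at ``peak_s`` and ``undershoot_s``
    (unit scale), combined as positive lobe minus ``ratio`` x undershoot.
    """
    t = np.asarray(t_s, dtype=float)
    h = scipy.stats.gamma.pdf(t, peak_s + 1.0) - ratio * scipy.stats.gamma.pdf(
        t, undershoot_s + 1.0
    )
    h = np.where(t >= 0, h, 0.0)
    fine = np.arange(0.0, 40.0, 0.001)
    peak_val = (
        scipy.stats.gamma.pdf(fine, peak_s + 1.0)
        - ratio * scipy.stats.gamma.pdf(fine, undershoot_s + 1.0)
    ).max()
    return h / peak_val


def define_poi(
    stat_map: SourceStatMap,
    src: SourceSpace,
    p_thresh: float = 0.05,
    min_extent: int = 1,
    sign: str | None = None,
) -> list[Poi]:
    """Contiguous supra-threshold vertex clusters as patches of interest.

    Vertices with ``p < p_thresh`` (optionally restricted to positive or
    negative statistics) are grouped into connected components on the
    source-space neighbour graph; the largest cluster per hemisphere is
    returned with weights proportional to |statistic|, labelled by its
    centroid region (posterior -> "occipital", anterior -> "prefrontal").
    """
    mask = stat_map.p < p_thresh
    if sign == "negative":
        mask &= stat_map.stat < 0
    elif sign == "positive":
        mask &= stat_map.stat > 0
    elif sign is not None:
        raise ValueError("sign must be None, 'positive' or 'negative'")
    ids = np.nonzero(mask)[0]
    if ids.size == 0:
        raise ValueError(
            "no supra-threshold vertex; relax p_thresh or check the contrast"
        )
    sub = src.adjacency[np.ix_(ids, ids)]
    n_comp, labels = scipy.sparse.csgraph.connected_components(sub, directed=False)

    pois: list[Poi] = []
    for hemi in ("lh", "rh"):
        hemi_mask = src.hemis[ids] == hemi
        best, best_size = None, 0
        for c in range(n_comp):
            members = ids[(labels == c) & hemi_mask]
            if members.size >= max(min_extent, 1) and members.size > best_size:
                best, best_size = members, members.size
        if best is None:
            continue
        centroid = src.vertices_mm[best].mean(axis=0)
        label = "occipital" if centroid[1] < 0 else "prefrontal"
        pois.append(
            Poi(
                vertex_ids=best,
                weights=np.abs(stat_map.stat[best]),
                label=f"{label}-{hemi}",
            )
        )
    if not pois:
        raise ValueError(
            f"no cluster reached min_extent={min_extent}; relax the threshold"
        )
    return pois


def poi_alpha_timecourse(
    inv: InverseOperator,
    segments,
    poi: Poi,
    window_ms: tuple[float, float] = (200.0, 400.0),
    band_hz: tuple[float, float] = (8.0, 13.0),
    baseline_ms: tuple[float, float] = (-2000.0, 0.0),
    stfft_window_ms: float = 500.0,
    stfft_hop_ms: float = 100.0,
) -> np.ndarray:
    """Per-trial POI alpha value.

    Each trial's sensor segment is projected through the noise-normalized
    inverse kernel restricted to the POI vertices (so all electrodes are
    weighted by the inverse solution), baseline-corrected STFFT band power
    is averaged inside ``window_ms``, and the POI weights collapse vertices
    to a scalar.
    """
    from .timefreq import StfftSpec, stfft_power

    kernel = inv.kernel[poi.vertex_ids]
    nn = inv.noise_norm[poi.vertex_ids]
    spec = StfftSpec(window_ms=stfft_window_ms, hop_ms=stfft_hop_ms, band_hz=band_hz)
    values = np.empty(segments.n_segments)
    for i in range(segments.n_segments):
        z = (kernel @ segments.data[i]) / nn[:, None]
        power, centers = stfft_power(
            z,
            segments.sampling_rate_hz,
            t0_ms=segments.times_ms[0],
            spec=spec,
            baseline_ms=baseline_ms,
        )
        sel = (centers >= window_ms[0]) & (centers <= window_ms[1])
        if not np.any(sel):
            raise ValueError(f"no STFFT window centres inside {window_ms} ms")
        values[i] = poi.weights @ power[:, sel].mean(axis=1)
    return values


def score_trials(
    trials: list[TrialRecord],
) -> tuple[list[TrialRecord], dict]:
    """Inclusion/confound assignment plus a behaviour summary.

    Unisensory and congruent-audiovisual trials require a correct response;
    incongruent trials require any response; omitted and incorrect
    non-INC trials form the confound set. The summary mirrors the
    per-condition accuracy table (auditory / visual / congruent %, INC
    decision-for-face / voice / neither %).
    """
    out: list[TrialRecord] = []
    confound_ids: list[int] = []
    for t in trials:
        responded = t.correctness != "omitted" and t.response_code is not None
        if not responded:
            out.append(replace(t, included=False, correctness="omitted",
                               response_code=None))
            confound_ids.append(t.trial_id)
            continue
        if t.congruence == "INC":
            out.append(replace(t, included=True))
        elif t.correctness == "correct":
            out.append(replace(t, included=True))
        else:
            out.append(replace(t, included=False))
            confound_ids.append(t.trial_id)

    def pct(sel: list[TrialRecord], pred) -> float:
        responded = [t for t in sel if t.correctness != "omitted"]
        if not responded:
            return float("nan")
        return 100.0 * sum(pred(t) for t in responded) / len(responded)

    aud = [t for t in out if t.modality == "auditory"]
    vis = [t for t in out if t.modality == "visual"]
    con = [t for t in out if t.congruence == "CON"]
    inc = [t for t in out if t.congruence == "INC"]
    summary = {
        "auditory_pct": pct(aud, lambda t: t.correctness == "correct"),
        "visual_pct": pct(vis, lambda t: t.correctness == "correct"),
        "congruent_pct": pct(con, lambda t: t.correctness == "correct"),
        "inc_face_pct": pct(inc, lambda t: t.inc_decision == "face"),
        "inc_voice_pct": pct(inc, lambda t: t.inc_decision == "voice"),
        "inc_neither_pct": pct(inc, lambda t: t.inc_decision == "neither"),
        "n_confound": len(confound_ids),
        "confound_trial_ids": confound_ids,
    }
    return out, summary


def build_alpha_regressor(
    trial_values: np.ndarray,
    onsets_s: np.ndarray,
    tr_s: float,
    n_volumes: int,
    t0_s: float = 0.0,
    fine_dt_s: float = 0.01,
    hrf_duration_s: float = 60.0,
) -> np.ndarray:
    """HRF-convolved single-trial alpha stick function on the TR grid.

    Sticks at the stimulus onsets are scaled by the trial alpha values and
    zero elsewhere; convolution happens on a fine grid (10 ms default) and
    is then sampled at the volume times ``t0_s + k * tr_s``.
    """
    values = np.asarray(trial_values, dtype=float)
    onsets = np.asarray(onsets_s, dtype=float)
    if values.shape != onsets.shape:
        raise ValueError("one alpha value per onset required")
    t_end = t0_s + n_volumes * tr_s + hrf_duration_s
    n_fine = int(np.ceil((t_end - t0_s) / fine_dt_s)) + 1
    sticks = np.zeros(n_fine)
    for v, o in zip(values, onsets):
        idx = int(round((o - t0_s) / fine_dt_s))
        if 0 <= idx < n_fine:
            sticks[idx] += v
    h = hrf_double_gamma(np.arange(0.0, hrf_duration_s, fine_dt_s))
    conv = np.convolve(sticks, h)[:n_fine]
    vol_idx = np.round(np.arange(n_volumes) * tr_s / fine_dt_s).astype(int)
    return conv[vol_idx]


def _dct_basis(n: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine high-pass basis: components with period > cutoff."""
    order = int(np.floor(2.0 * n * tr_s / cutoff_s))
    k = np.arange(1, max(order, 0) + 1)
    t = np.arange(n)
    if k.size == 0:
        return np.empty((n, 0))
    return np.cos(np.pi * np.outer(t + 0.5, k) / n)


def preprocess_bold_minimal(
    vol: VolumeSeries,
    fwhm_mm: float = 4.0,
    highpass_cutoff_s: float = 128.0,
    n_discard: int = 2,
) -> VolumeSeries:
    """Discard leading volumes, smooth spatially, remove drift per voxel.

    Spatial smoothing is a per-volume 3-D Gaussian at the stated FWHM
    (nearest-edge padding, so spatially constant volumes are untouched).
    Drift removal regresses out an intercept, a linear trend and a
    discrete-cosine high-pass basis.
    """
    data = np.asarray(vol.data, dtype=float)[..., n_discard:]
    if data.shape[-1] < 3:
        raise ValueError("too few volumes after discarding leading images")
    if fwhm_mm > 0:
        sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vol.voxel_size_mm
        out = np.empty_like(data)
        for k in range(data.shape[-1]):
            out[..., k] = scipy.ndimage.gaussian_filter(
                data[..., k], sigma=tuple(sigma_vox), mode="nearest"
            )
        data = out

    n_t = data.shape[-1]
    t = np.arange(n_t)
    X = np.column_stack(
        [np.ones(n_t), t - t.mean(), _dct_basis(n_t, vol.tr_s, highpass_cutoff_s)]
    )
    flat = data.reshape(-1, n_t).T  # time x voxels
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = flat - X @ beta
    # keep the voxel mean so the series stays interpretable
    resid += flat.mean(axis=0, keepdims=True)
    data = resid.T.reshape(data.shape)

    return VolumeSeries(
        data=data,
        tr_s=vol.tr_s,
        affine=vol.affine.copy(),
        n_discarded_leading=vol.n_discarded_leading + n_discard,
    )


def fit_glm(
    vol: VolumeSeries,
    X: DesignMatrix,
    contrasts: dict[str, np.ndarray] | None = None,
) -> dict[str, StatVolume]:
    """Per-voxel OLS with t and r maps for each named contrast.

    An intercept column is appended automatically if absent. ``r`` is the
    partial correlation implied by the t statistic,
    ``t / sqrt(t^2 + df)``.
    """
    mat = X.matrix
    names = list(X.names)
    if not any(np.allclose(c, c[0]) and c[0] != 0 for c in mat.T):
        mat = np.column_stack([mat, np.ones(mat.shape[0])])
        names.append("intercept")
    n_t, p = mat.shape
    if vol.n_volumes != n_t:
        raise ValueError(
            f"design has {n_t} rows but the series has {vol.n_volumes} volumes"
        )
    if contrasts is None:
        contrasts = {}
        for j, name in enumerate(X.names):
            c = np.zeros(p)
            c[j] = 1.0
            contrasts[name] = c

    Y = np.asarray(vol.data, dtype=float).reshape(-1, n_t).T  # time x voxels
    pinv = np.linalg.pinv(mat)
    beta = pinv @ Y  # p x voxels
    resid = Y - mat @ beta
    df = n_t - np.linalg.matrix_rank(mat)
    sigma2 = (resid**2).sum(axis=0) / max(df, 1)
    xtx_inv = np.linalg.pinv(mat.T @ mat)

    shape = vol.data.shape[:3]
    out: dict[str, StatVolume] = {}
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.size == p - 1:  # user contrast without the implicit intercept
            c = np.concatenate([c, [0.0]])
        eff = c @ beta
        var = sigma2 * float(c @ xtx_inv @ c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, eff / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        r = t / np.sqrt(t**2 + df)
        out[name] = StatVolume(
            beta=eff.reshape(shape),
            t=t.reshape(shape),
            r=r.reshape(shape),
            df=df,
            contrast=name,
        )
    return out


def cluster_threshold_mc(
    grid_shape: tuple[int, int, int],
    voxel_p: float = 0.05,
    fwhm_mm: float = 0.0,
    voxel_size_mm: float = 3.0,
    n_iter: int = 10000,
    seed: int = 0,
    connectivity: int = 6,
) -> ClusterThreshold:
    """Monte-Carlo cluster-extent threshold for smoothed Gaussian noise.

    Each iteration draws a Gaussian noise volume, optionally smooths it to
    the given FWHM (re-standardized to unit variance), thresholds one-sided
    at ``voxel_p``, and records the maximum cluster size under the chosen
    connectivity. The minimum cluster size is the 95th percentile of that
    null distribution plus one.
    """
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must lie strictly between 0 and 1")
    if connectivity == 6:
        structure = scipy.ndimage.generate_binary_structure(3, 1)
    elif connectivity == 18:
        structure = scipy.ndimage.generate_binary_structure(3, 2)
    elif connectivity == 26:
        structure = scipy.ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6, 18 or 26")
    rng = np.random.default_rng(seed)
    z_thresh = scipy.stats.norm.isf(voxel_p)
    sigma_vox = (
        fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
        if fwhm_mm > 0
        else 0.0
    )
    max_sizes = np.zeros(n_iter, dtype=int)
    for i in range(n_iter):
        noise = rng.standard_normal(grid_shape)
        if sigma_vox > 0:
            noise = scipy.ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
            noise = noise / noise.std()
        labels, n_lab = scipy.ndimage.label(noise > z_thresh, structure=structure)
        if n_lab:
            max_sizes[i] = np.bincount(labels.ravel())[1:].max()
    min_size = int(np.percentile(max_sizes, 95.0, method="higher")) + 1
    return ClusterThreshold(
        voxelwise_p=voxel_p,
        min_cluster_size=min_size,
        n_iterations=n_iter,
        fwhm_mm=fwhm_mm,
        max_sizes=max_sizes,
    )


def couple(
    vol: VolumeSeries,
    alpha_regressor: np.ndarray,
    confounds: np.ndarray | None = None,
    voxel_p: float = 0.05,
    threshold: ClusterThreshold | None = None,
    connectivity: int = 6,
) -> tuple[StatVolume, np.ndarray | None]:
    """GLM of BOLD on the POI alpha regressor (plus confounds).

    Returns the alpha-regressor :class:`StatVolume` (beta/t/r) and, when a
    cluster threshold is supplied, the boolean map of voxels in clusters
    that survive it (either sign; one-sided ``voxel_p`` per tail).
    """
    cols = [np.asarray(alpha_regressor, dtype=float)]
    names = ["alpha"]
    if confounds is not None:
        conf = np.atleast_2d(np.asarray(confounds, dtype=float))
        if conf.shape[0] == len(alpha_regressor):
            conf = conf.T
        for i, c in enumerate(conf):
            cols.append(c)
            names.append(f"confound_{i}")
    X = DesignMatrix(np.column_stack(cols), names, vol.tr_s)
    stats = fit_glm(vol, X)["alpha"]

    if threshold is None:
        return stats, None
    t_crit = scipy.stats.t.isf(voxel_p, stats.df)
    if connectivity == 6:
        structure = scipy.ndimage.generate_binary_structure(3, 1)
    else:
        structure = scipy.ndimage.generate_binary_structure(3, 3)
    surviving = np.zeros(stats.t.shape, dtype=bool)
    for sign in (1.0, -1.0):
        labels, n_lab = scipy.ndimage.label(sign * stats.t > t_crit, structure=structure)
        for lab in range(1, n_lab + 1):
            members = labels == lab
            if members.sum() >= threshold.min_cluster_size:
                surviving |= members
    return stats, surviving
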