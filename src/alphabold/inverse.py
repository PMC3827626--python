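"""Four-shell spherical forward model and weighted minimum-norm inverse.

The forward solution expands the dipole potential in Legendre series and
matches boundary conditions across four concentric shells (brain, CSF,
skull, scalp). The inverse is a depth-weighted minimum-norm kernel with
noise-based normalization: sources are divided by their predicted noise
standard deviation under the pre-stimulus sensor covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats
from scipy.spatial import cKDTree

from .io_core import ElectrodeSet

__all__ = [
    "HeadModel",
    "SourceSpace",
    "LeadField",
    "NoiseCov",
    "InverseOperator",
    "SourceStatMap",
    "build_source_space",
    "geodesic_patch",
    "coregister_electrodes",
    "shell_potential",
    "homogeneous_potential",
    "compute_leadfield",
    "estimate_noise_cov",
    "build_inverse",
    "apply_inverse",
    "source_contrast_map",
]


@dataclass
class HeadModel:
    """Concentric four-shell conductor (radii strictly increasing, in mm)."""

    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radii_mm: np.ndarray = field(
        default_factory=lambda: 92.0 * np.array([0.87, 0.92, 0.96, 1.00])
    )
    conductivities: np.ndarray = field(
        default_factory=lambda: np.array([0.33, 1.0, 0.0042, 0.33])
    )

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.conductivities = np.asarray(self.conductivities, dtype=float)
        if len(self.radii_mm) != len(self.conductivities):
            raise ValueError("need one conductivity per shell")
        if not np.all(np.diff(self.radii_mm) > 0):
            raise ValueError("shell radii must be strictly increasing")
        if not np.all(self.conductivities > 0):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius_mm(self) -> float:
        return float(self.radii_mm[0])

    @property
    def scalp_radius_mm(self) -> float:
        return float(self.radii_mm[-1])


@dataclass
class SourceSpace:
    """Cortical source locations with orientations and a neighbour graph."""

    vertices_mm: np.ndarray
    orientations: np.ndarray
    hemis: np.ndarray  # array of "lh"/"rh" per vertex
    adjacency: scipy.sparse.csr_matrix
    edge_length_mm: float

    def __post_init__(self) -> None:
        self.vertices_mm = np.asarray(self.vertices_mm, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientations must be unit-norm")

    @property
    def n_vertices(self) -> int:
        return self.vertices_mm.shape[0]

    def n_per_hemisphere(self) -> dict[str, int]:
        return {h: int(np.sum(self.hemis == h)) for h in ("lh", "rh")}


def build_source_space(
    n_per_hemisphere: int = 2500,
    head: HeadModel | None = None,
    rel_radius: float = 0.8,
    n_neighbors: int = 6,
) -> SourceSpace:
    """Sphere-mapped cortex surrogate with exactly ``n_per_hemisphere`` vertices.

    Each hemisphere is a Fibonacci lattice on a half-sphere of radius
    ``rel_radius`` x brain radius (axis +-x), with radial (cortex-normal)
    orientations and a symmetrized k-nearest-neighbour adjacency graph.
    """
    head = head or HeadModel()
    radius = rel_radius * head.brain_radius_mm
    golden = np.pi * (3.0 - np.sqrt(5.0))

    verts, hemis = [], []
    for hemi, axis in (("lh", np.array([-1.0, 0, 0])), ("rh", np.array([1.0, 0, 0]))):
        i = np.arange(n_per_hemisphere)
        cos_t = (i + 0.5) / n_per_hemisphere  # in (0, 1): half-sphere around axis
        sin_t = np.sqrt(1.0 - cos_t**2)
        phi = golden * i
        e1, e2 = np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])
        dirs = (
            cos_t[:, None] * axis
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        verts.append(radius * dirs)
        hemis.extend([hemi] * n_per_hemisphere)

    vertices = np.vstack(verts) + head.center_mm
    rel = vertices - head.center_mm
    orientations = rel / np.linalg.norm(rel, axis=1, keepdims=True)

    tree = cKDTree(vertices)
    dists, idx = tree.query(vertices, k=n_neighbors + 1)
    rows = np.repeat(np.arange(vertices.shape[0]), n_neighbors)
    cols = idx[:, 1:].ravel()
    adj = scipy.sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(vertices.shape[0],) * 2
    ).tocsr()
    adj = ((adj + adj.T) > 0).astype(np.int8).tocsr()
    edge_length = float(np.median(dists[:, 1:]))

    return SourceSpace(vertices, orientations, np.array(hemis), adj, edge_length)


def geodesic_patch(
    src: SourceSpace,
    direction: np.ndarray,
    angular_radius_deg: float,
    hemi: str | None = None,
    center_mm: np.ndarray | None = None,
) -> np.ndarray:
    """Vertex ids within an angular radius of ``direction`` (seen from centre)."""
    center = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = src.vertices_mm - center
    rel = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    ang = np.degrees(np.arccos(np.clip(rel @ d, -1.0, 1.0)))
    mask = ang <= angular_radius_deg
    if hemi is not None:
        mask &= src.hemis == hemi
    ids = np.nonzero(mask)[0]
    if ids.size == 0:
        raise ValueError("geodesic patch is empty; widen the angular radius")
    return ids


# --------------------------------------------------------------------------
# Electrode co-registration
# --------------------------------------------------------------------------

def coregister_electrodes(
    digitized: ElectrodeSet, head: HeadModel
) -> tuple[ElectrodeSet, float]:
    """Fiducial-based rigid alignment plus radial projection onto the scalp.

    The head frame is built from the digitized fiducials (origin at the
    midpoint of LPA/RPA, +x toward RPA, +y toward nasion); positions are
    expressed in that frame, translated to the head-model centre, and
    projected radially onto the scalp shell. Returns the sphere-frame
    electrode set and the RMS radial projection distance in mm.
    """
    nas = digitized.fiducials["nasion"]
    lpa = digitized.fiducials["lpa"]
    rpa = digitized.fiducials["rpa"]
    origin = (lpa + rpa) / 2.0
    x = rpa - lpa
    nx = np.linalg.norm(x)
    y = nas - origin
    y = y - (y @ x) * x / nx**2
    if nx < 1e-9 or np.linalg.norm(y) < 1e-9 * max(nx, 1.0):
        raise ValueError("fiducials are collinear; cannot build a head frame")
    x = x / nx
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    R = np.stack([x, y, z])  # rows: head-frame axes in digitizer coords

    head_coords = (digitized.positions_mm - origin) @ R.T + head.center_mm
    rel = head_coords - head.center_mm
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii < 1e-9):
        raise ValueError("electrode coincides with head centre")
    projected = head.center_mm + rel * (head.scalp_radius_mm / radii)[:, None]
    rms = float(np.sqrt(np.mean((radii - head.scalp_radius_mm) ** 2)))

    fids = {
        k: (v - origin) @ R.T + head.center_mm for k, v in digitized.fiducials.items()
    }
    return (
        ElectrodeSet(list(digitized.labels), projected, fids, frame="sphere"),
        rms,
    )


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------

def _shell_coefficients(head: HeadModel, n_terms: int) -> np.ndarray:
    """Dimensionless radial transfer coefficients g_n, n = 1..n_terms.

    In each shell the n-th radial factor is A rho^n + B rho^-(n+1) with
    rho = r / scalp_radius; the innermost shell carries the source term
    rho^-(n+1) with unit coefficient. Continuity of potential and of radial
    current at the three interfaces plus zero radial current at the scalp
    give a 7x7 linear system per degree n; g_n is the resulting potential
    factor at the scalp surface.
    """
    rho = head.radii_mm / head.scalp_radius_mm
    sig = head.conductivities
    g = np.empty(n_terms)
    for n in range(1, n_terms + 1):
        # unknowns: [A1, A2, B2, A3, B3, A4, B4]
        A = np.zeros((7, 7))
        b = np.zeros(7)

        def pw(r: float) -> tuple[float, float, float, float]:
            # value/derivative factors for rho^n and rho^-(n+1)
            return (r**n, r ** -(n + 1), n * r ** (n - 1), -(n + 1) * r ** -(n + 2))

        rows = 0
        for k in range(3):  # interfaces between shells k and k+1
            r = rho[k]
            vp, vm, dp, dm = pw(r)
            # potential continuity
            if k == 0:
                A[rows, 0] = vp
                b[rows] = -vm
            else:
                A[rows, 2 * k - 1] = vp
                A[rows, 2 * k] = vm
            A[rows, 2 * k + 1] = -vp
            A[rows, 2 * k + 2] = -vm
            rows += 1
            # radial current continuity
            if k == 0:
                A[rows, 0] = sig[0] * dp
                b[rows] = -sig[0] * dm
            else:
                A[rows, 2 * k - 1] = sig[k] * dp
                A[rows, 2 * k] = sig[k] * dm
            A[rows, 2 * k + 1] = -sig[k + 1] * dp
            A[rows, 2 * k + 2] = -sig[k + 1] * dm
            rows += 1
        # outer boundary: zero radial current at scalp (rho = 1)
        _, _, dp, dm = pw(1.0)
        A[rows, 5] = dp
        A[rows, 6] = dm
        sol = np.linalg.solve(A, b)
        g[n - 1] = sol[5] + sol[6]  # A4 * 1^n + B4 * 1^-(n+1)
    return g


def _legendre_terms(x: np.ndarray, n_terms: int) -> tuple[np.ndarray, np.ndarray]:
    """P_n(x) and sin(theta) * P_n'(x) for n = 1..n_terms via recurrences.

    ``x = cos(theta)``. Shapes: input (...,), outputs (n_terms, ...).
    """
    x = np.asarray(x)
    P = np.empty((n_terms + 1,) + x.shape)
    P[0] = 1.0
    P[1] = x
    for n in range(1, n_terms):
        P[n + 1] = ((2 * n + 1) * x * P[n] - n * P[n - 1]) / (n + 1)
    sin_t = np.sqrt(np.clip(1.0 - x**2, 0.0, None))
    # (1 - x^2) P_n'(x) = n (P_{n-1} - x P_n)  =>  sin*P' = n (P_{n-1} - x P_n)/sin
    sPd = np.zeros((n_terms,) + x.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for n in range(1, n_terms + 1):
            val = n * (P[n - 1] - x * P[n]) / sin_t
            sPd[n - 1] = np.where(sin_t > 1e-12, val, 0.0)
    return P[1:], sPd


def shell_potential(
    head: HeadModel,
    dip_pos_mm: np.ndarray,
    dip_moment: np.ndarray,
    elec_pos_mm: np.ndarray,
    n_terms: int = 60,
) -> np.ndarray:
    """Scalp potential of a current dipole inside a four-shell sphere.

    ``elec_pos_mm`` (n_elec, 3) are assumed on (or are radially projected to)
    the scalp shell. Output potentials are *not* average-referenced. Units
    are arbitrary-but-consistent (moment units / (S/m x mm^2)).
    """
    g = _shell_coefficients(head, n_terms)
    return _series_potential(
        head.center_mm,
        head.scalp_radius_mm,
        head.conductivities[0],
        head.brain_radius_mm,
        g,
        dip_pos_mm,
        dip_moment,
        elec_pos_mm,
        n_terms,
    )


def _series_potential(
    center: np.ndarray,
    scalp_r: float,
    sigma1: float,
    brain_r: float,
    g: np.ndarray,
    dip_pos_mm: np.ndarray,
    dip_moment: np.ndarray,
    elec_pos_mm: np.ndarray,
    n_terms: int,
) -> np.ndarray:
    b_vec = np.asarray(dip_pos_mm, dtype=float) - center
    q = np.asarray(dip_moment, dtype=float)
    e = np.asarray(elec_pos_mm, dtype=float) - center
    e_hat = e / np.linalg.norm(e, axis=1, keepdims=True)

    b = np.linalg.norm(b_vec)
    if b >= brain_r:
        raise ValueError(
            f"dipole at radius {b:.1f} mm is outside the brain shell ({brain_r:.1f} mm)"
        )
    beta = b / scalp_r

    if b < 1e-9:
        # dipole at the centre: pick the moment direction as the axis
        qn = np.linalg.norm(q)
        b_hat = q / qn if qn > 0 else np.array([0.0, 0.0, 1.0])
    else:
        b_hat = b_vec / b

    q_r = q @ b_hat
    q_t_vec = q - q_r * b_hat

    cos_g = np.clip(e_hat @ b_hat, -1.0, 1.0)
    t_e = e_hat - cos_g[:, None] * b_hat
    t_norm = np.linalg.norm(t_e, axis=1, keepdims=True)
    t_e = np.where(t_norm > 1e-12, t_e / np.maximum(t_norm, 1e-300), 0.0)
    q_t_proj = t_e @ q_t_vec

    P, sPd = _legendre_terms(cos_g, n_terms)  # (n_terms, n_elec)
    n = np.arange(1, n_terms + 1)
    beta_pow = beta ** (n - 1)
    coeff = g * beta_pow  # (n_terms,)

    radial = (coeff * n) @ P * q_r
    tangential = coeff @ sPd * q_t_proj
    return (radial + tangential) / (4.0 * np.pi * sigma1 * scalp_r**2)


def homogeneous_potential(
    sigma: float,
    dip_pos_mm: np.ndarray,
    dip_moment: np.ndarray,
    points_mm: np.ndarray,
) -> np.ndarray:
    """Closed-form infinite-medium dipole potential (oracle for the series)."""
    d = np.asarray(points_mm, float) - np.asarray(dip_pos_mm, float)
    r3 = np.linalg.norm(d, axis=1) ** 3
    return (d @ np.asarray(dip_moment, float)) / (4.0 * np.pi * sigma * r3)


def single_sphere_potential(
    radius_mm: float,
    sigma: float,
    dip_pos_mm: np.ndarray,
    dip_moment: np.ndarray,
    elec_pos_mm: np.ndarray,
    n_terms: int = 100,
) -> np.ndarray:
    """Homogeneous single-sphere surface potential, series g_n = (2n+1)/n.

    Independent oracle path: uses :func:`scipy.special.lpmv` rather than the
    recurrence implementation in the general solver.
    """
    import scipy.special

    b_vec = np.asarray(dip_pos_mm, dtype=float)
    q = np.asarray(dip_moment, dtype=float)
    e = np.asarray(elec_pos_mm, dtype=float)
    e_hat = e / np.linalg.norm(e, axis=1, keepdims=True)
    b = np.linalg.norm(b_vec)
    b_hat = b_vec / b if b > 0 else np.array([0.0, 0.0, 1.0])
    q_r = q @ b_hat
    q_t_vec = q - q_r * b_hat
    cos_g = np.clip(e_hat @ b_hat, -1.0, 1.0)
    t_e = e_hat - cos_g[:, None] * b_hat
    t_norm = np.linalg.norm(t_e, axis=1, keepdims=True)
    t_e = np.where(t_norm > 1e-12, t_e / np.maximum(t_norm, 1e-300), 0.0)
    q_t_proj = t_e @ q_t_vec

    out = np.zeros(e.shape[0])
    sin_g = np.sqrt(np.clip(1 - cos_g**2, 0, None))
    for n in range(1, n_terms + 1):
        gn = (2 * n + 1) / n
        Pn = scipy.special.lpmv(0, n, cos_g)
        # lpmv includes the Condon-Shortley phase: P_n^1 = -sin * P_n'
        sPd = -scipy.special.lpmv(1, n, cos_g)
        sPd = np.where(sin_g > 1e-12, sPd, 0.0)
        out += gn * (b / radius_mm) ** (n - 1) * (n * q_r * Pn + q_t_proj * sPd)
    return out / (4.0 * np.pi * sigma * radius_mm**2)


@dataclass
class LeadField:
    """Channels x sources gain matrix bound to an electrode set."""

    matrix: np.ndarray
    channel_labels: list[str]
    oriented: bool

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[1] if self.oriented else self.matrix.shape[1] // 3


def compute_leadfield(
    head: HeadModel,
    src: SourceSpace,
    electrodes: ElectrodeSet,
    orientation: str = "normal",
    n_terms: int = 60,
) -> LeadField:
    """Average-referenced four-shell lead field for every source vertex.

    ``orientation='normal'`` constrains dipoles to the source-space
    orientations (one column per vertex); ``'free'`` emits three columns
    (x, y, z moments) per vertex.
    """
    if orientation not in {"normal", "free"}:
        raise ValueError("orientation must be 'normal' or 'free'")
    rel = src.vertices_mm - head.center_mm
    if np.any(np.linalg.norm(rel, axis=1) >= head.brain_radius_mm):
        raise ValueError("all sources must lie strictly inside the brain shell")

    g = _shell_coefficients(head, n_terms)
    elec = electrodes.positions_mm
    cols = []
    moments: list[np.ndarray]
    for i in range(src.n_vertices):
        if orientation == "normal":
            moments = [src.orientations[i]]
        else:
            moments = [np.eye(3)[k] for k in range(3)]
        for q in moments:
            cols.append(
                _series_potential(
                    head.center_mm,
                    head.scalp_radius_mm,
                    head.conductivities[0],
                    head.brain_radius_mm,
                    g,
                    src.vertices_mm[i],
                    q,
                    elec,
                    n_terms,
                )
            )
    L = np.column_stack(cols)
    L = L - L.mean(axis=0, keepdims=True)  # average reference
    return LeadField(L, list(electrodes.labels), oriented=(orientation == "normal"))


# --------------------------------------------------------------------------
# Noise covariance and inverse operator
# --------------------------------------------------------------------------

@dataclass
class NoiseCov:
    matrix: np.ndarray
    window_ms: tuple[float, float]
    n_samples: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("noise covariance must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("noise covariance must be symmetric")


def estimate_noise_cov(
    segments,
    window_ms: tuple[float, float] = (-2000.0, 0.0),
    diag_load: float = 1e-6,
) -> NoiseCov:
    """Sample covariance over concatenated pre-stimulus samples.

    ``segments`` is a :class:`~alphabold.timefreq.SegmentSet`. A small
    diagonal loading (``diag_load`` x mean diagonal) keeps the matrix well
    conditioned.
    """
    t = segments.times_ms
    sel = (t >= window_ms[0]) & (t < window_ms[1])
    if not np.any(sel):
        raise ValueError(f"window {window_ms} ms not covered by segments")
    X = segments.data[:, :, sel]  # trials x channels x time
    X = np.concatenate([X[i] for i in range(X.shape[0])], axis=1)
    X = X - X.mean(axis=1, keepdims=True)
    n = X.shape[1]
    C = (X @ X.T) / max(n - 1, 1)
    C = C + diag_load * np.mean(np.diag(C)) * np.eye(C.shape[0])
    return NoiseCov(C, tuple(window_ms), n)


@dataclass
class InverseOperator:
    """Kernel sources x channels with noise normalization."""

    kernel: np.ndarray
    lambda2: float
    snr: float
    noise_norm: np.ndarray
    source_weights: np.ndarray
    trace_fraction: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("inverse kernel contains non-finite entries")
        if not np.all(self.noise_norm > 0):
            raise ValueError("noise normalization must be positive")


def build_inverse(
    L: LeadField,
    C: NoiseCov,
    snr: float = 5.0,
    depth_weight: float = 0.5,
    lambda2: float | None = None,
) -> InverseOperator:
    """Depth-weighted minimum-norm kernel with noise-based normalization.

    M = R L' (L R L' + lambda^2 C)^-1 with
    lambda^2 = trace(L R L') / (trace(C) snr^2) unless given explicitly;
    R is diagonal with entries ||l_i||^(-2*depth_weight). The per-source
    noise normalization is sqrt(diag(M C M')).
    """
    A = L.matrix
    col_norms = np.linalg.norm(A, axis=0)
    if np.any(col_norms == 0):
        raise ValueError("lead field has an all-zero column")
    w = col_norms ** (-2.0 * depth_weight)
    ARA = (A * w) @ A.T  # L R L'
    trC = np.trace(C.matrix)
    if lambda2 is None:
        if trC <= 0:
            raise ValueError("noise covariance has non-positive trace")
        lambda2 = float(np.trace(ARA) / (trC * snr**2))
    G = ARA + lambda2 * C.matrix
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            "sensor Gram matrix is singular; use lambda2 > 0 (regularization)"
        )
    M = (A * w).T @ np.linalg.inv(G)
    noise_norm = np.sqrt(np.einsum("ij,jk,ik->i", M, C.matrix, M))
    noise_norm = np.maximum(noise_norm, np.finfo(float).tiny)
    trace_fraction = lambda2 * trC / (np.trace(ARA) + lambda2 * trC)
    return InverseOperator(
        kernel=M,
        lambda2=lambda2,
        snr=snr,
        noise_norm=noise_norm,
        source_weights=w,
        trace_fraction=trace_fraction,
        channel_labels=list(L.channel_labels),
    )


def apply_inverse(
    inv: InverseOperator, sensor_data: np.ndarray, normalized: bool = True
) -> np.ndarray:
    """Project sensor data (channels x time) to sources; optionally divide by
    the per-source predicted noise standard deviation."""
    est = inv.kernel @ sensor_data
    if normalized:
        est = est / inv.noise_norm[:, None]
    return est


@dataclass
class SourceStatMap:
    stat: np.ndarray
    p: np.ndarray
    contrast: str
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p values must lie in [0, 1]")


def source_contrast_map(
    inv: InverseOperator,
    segments,
    contrast: str,
    band_hz: tuple[float, float] = (8.0, 13.0),
    window_ms: tuple[float, float] = (200.0, 400.0),
    stfft_window_ms: float = 500.0,
    stfft_hop_ms: float = 100.0,
    baseline_ms: tuple[float, float] = (-2000.0, 0.0),
) -> SourceStatMap:
    """Across-trial t-map of source-level induced alpha power.

    Per trial, sensor segments are projected through the noise-normalized
    kernel, band power is computed per vertex with the short-time FFT, and
    baseline-corrected power is averaged inside ``window_ms``. Contrasts:
    ``"av_vs_baseline"`` (one-sample t of all audiovisual trials against 0)
    and ``"con_gt_inc"`` (two-sample t, CON minus INC).
    """
    from .timefreq import StfftSpec, stfft_power

    spec = StfftSpec(window_ms=stfft_window_ms, hop_ms=stfft_hop_ms, band_hz=band_hz)
    n_trials = segments.n_segments
    values = np.empty((n_trials, inv.kernel.shape[0]))
    for i in range(n_trials):
        z = apply_inverse(inv, segments.data[i])
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
        values[i] = power[:, sel].mean(axis=1)

    cong = np.array([t.congruence for t in segments.trials])
    if contrast == "av_vs_baseline":
        sel_trials = np.isin(cong, ["CON", "INC"])
        if sel_trials.sum() < 2:
            raise ValueError("need at least 2 audiovisual trials")
        t, p = scipy.stats.ttest_1samp(values[sel_trials], 0.0, axis=0)
    elif contrast == "con_gt_inc":
        a, b = values[cong == "CON"], values[cong == "INC"]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 trials per condition for CON > INC")
        t, p = scipy.stats.ttest_ind(a, b, axis=0)
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    return SourceStatMap(
        stat=np.asarray(t),
        p=np.asarray(p),
        contrast=contrast,
        band_hz=tuple(band_hz),
        window_ms=tuple(window_ms),
    )
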