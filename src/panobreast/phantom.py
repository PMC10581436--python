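"""Synthetic supine torso/breast phantom, conformal coil array and noise model.

The phantom stands in for volunteer anatomy: an elliptic-cylinder torso (long
axis head-foot, with a gentle anterior "chest bow" along HF so the sternum
line is genuinely curved in the sagittal plane) and two hemispherical breasts
protruding anteriorly from the chest wall, each with a fibroglandular core
inside a fat shell and optional spherical lesions.  All solids are analytic,
so curve geometry, arc lengths and tissue volumes have closed forms that the
tests use as oracles.

The receive array emulates a conformal 28-channel bra-shaped coil: 7 columns
of loops spread left-right around the chest arc times 4 rows along head-foot
(7 four-channel modules), circular loops of 8 cm diameter floating 5 mm above
the skin with their axes pointing into the body.  Per-channel complex
sensitivities come from Biot-Savart integration over the discretized loop
conductor plus a smooth channel-specific phase.

Channel noise is complex Gaussian with a specified Hermitian covariance;
the default construction reproduces the array's measured behavior of a 6-7%
mean normalized inter-channel correlation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import h5py
import numpy as np

from .core_geometry import Segmentation, Volume
from .panorama import Curve3D, fit_curve

TISSUE_LABELS = {"background": 0, "fat": 1, "fibroglandular": 2, "lesion": 3}


@dataclasses.dataclass
class Sphere:
    center: tuple[float, float, float]
    radius: float
    signal: float = 1.5


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and signal model of the synthetic supine torso.

    Distances in mm.  Defaults emulate a small-breasted subject (two 55 mm
    hemispheres, about 0.70 L total breast volume, within the 0.5-3.0 L range
    of the study population) lying supine with a 140-degree anterior chest arc.
    """

    torso_halfwidth_LR: float = 150.0
    torso_halfdepth_AP: float = 90.0
    torso_length_HF: float = 256.0
    breast_radius: float = 55.0
    breast_separation: float = 120.0
    chest_bow_mm: float = 12.0
    contour_arc_deg: float = 140.0
    fibroglandular_fraction: float = 0.6
    lesion_list: list[Sphere] = dataclasses.field(default_factory=list)
    tissue_signals: dict[str, float] = dataclasses.field(
        default_factory=lambda: {"background": 0.0, "fat": 1.0, "fibroglandular": 0.85, "lesion": 1.4}
    )
    voxel_spacing: float = 4.0
    margin_mm: float = 12.0

    def __post_init__(self) -> None:
        for name in ("torso_halfwidth_LR", "torso_halfdepth_AP", "torso_length_HF",
                     "breast_radius", "breast_separation", "voxel_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.breast_separation / 2 >= self.torso_halfwidth_LR:
            raise ValueError("breasts must sit on the torso (separation too large)")
        if not 0 < self.fibroglandular_fraction < 1:
            raise ValueError("fibroglandular_fraction must be in (0, 1)")

    # -- analytic helpers ---------------------------------------------------

    def breast_centers(self) -> np.ndarray:
        """Breast sphere centers on the chest wall at HF = 0."""
        x = self.breast_separation / 2.0
        y = self.torso_halfdepth_AP * np.sqrt(1 - (x / self.torso_halfwidth_LR) ** 2)
        return np.array([[-x, y, 0.0], [x, y, 0.0]])

    def anterior_offset(self, z) -> np.ndarray:
        """Anterior surface depression (mm) at head-foot position z."""
        return self.chest_bow_mm * (2.0 * np.asarray(z, dtype=float) / self.torso_length_HF) ** 2

    def analytic_breast_volume_ml(self) -> float:
        """Closed-form total volume of the two hemispherical breasts (mL)."""
        return 2.0 * (2.0 / 3.0) * np.pi * self.breast_radius**3 / 1000.0


@dataclasses.dataclass
class CoilLayout:
    """Circular receive loops: (center mm, unit normal into the body, radius mm)."""

    loops: list[tuple[np.ndarray, np.ndarray, float]]

    @property
    def channel_count(self) -> int:
        return len(self.loops)


@dataclasses.dataclass
class NoiseCovariance:
    """Channel noise covariance: Hermitian PSD with strictly positive diagonal."""

    matrix: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.conj().T, atol=1e-10):
            raise ValueError("covariance must be Hermitian")
        diag = np.real(np.diag(m))
        if np.any(diag <= 0):
            raise ValueError("covariance diagonal must be strictly positive")
        if np.linalg.eigvalsh(m).min() < -1e-9 * diag.max():
            raise ValueError("covariance must be positive semidefinite")
        self.matrix = m

    @property
    def channels(self) -> int:
        return self.matrix.shape[0]


@dataclasses.dataclass
class MultiCoilImage:
    """Per-channel complex image data sharing one geometry."""

    data: np.ndarray  # (channels, nx, ny, nz) complex
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("multi-coil data must be channels x 3D")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def channels(self) -> int:
        return self.data.shape[0]


@dataclasses.dataclass
class PhantomData:
    labels: dict[str, Segmentation]
    labelmap: Volume
    signal: Volume
    breast_roi: Segmentation
    sternum: Curve3D
    breast_contour: Curve3D


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec) -> PhantomData:
    """Rasterize the torso/breast phantom and its analytic reference curves.

    Returns per-tissue binary segmentations, an integer labelmap, the
    piecewise-constant signal volume, the whole-breast ROI, the sternum curve
    (midsagittal anterior surface) and the breast contour (axial plane through
    the fullest breast section, mid-tissue).
    """
    a, b = spec.torso_halfwidth_LR, spec.torso_halfdepth_AP
    half_l = spec.torso_length_HF / 2.0
    r = spec.breast_radius
    sp = spec.voxel_spacing
    m = spec.margin_mm

    lo = np.array([-a - m, -b - m, -half_l - m])
    hi = np.array([a + m, b + r + m, half_l + m])
    shape = np.ceil((hi - lo) / sp).astype(int) + 1
    affine = np.diag([sp, sp, sp, 1.0])
    affine[:3, 3] = lo

    ii = np.indices(shape, dtype=float)
    x = lo[0] + ii[0] * sp
    y = lo[1] + ii[1] * sp
    z = lo[2] + ii[2] * sp

    y_off = spec.anterior_offset(z)
    torso = ((x / a) ** 2 + ((y + y_off) / b) ** 2 <= 1.0) & (np.abs(z) <= half_l)

    labelmap = np.zeros(shape, dtype=np.uint8)
    labelmap[torso] = TISSUE_LABELS["fat"]

    breast = np.zeros(shape, dtype=bool)
    fibro = np.zeros(shape, dtype=bool)
    for cx, cy, cz in spec.breast_centers():
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        hemi = (d2 <= r**2) & (y >= cy)
        breast |= hemi
        fibro |= (d2 <= (spec.fibroglandular_fraction * r) ** 2) & (y >= cy)
    labelmap[breast] = TISSUE_LABELS["fat"]
    labelmap[fibro] = TISSUE_LABELS["fibroglandular"]

    for lesion in spec.lesion_list:
        cx, cy, cz = lesion.center
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lesion.radius**2
        if not inside.any():
            raise ValueError("lesion smaller than one voxel")
        if not breast[inside].all():
            raise ValueError("lesion extends outside breast tissue")
        labelmap[inside] = TISSUE_LABELS["lesion"]

    signal = np.zeros(shape, dtype=float)
    for name, lab in TISSUE_LABELS.items():
        signal[labelmap == lab] = spec.tissue_signals[name]
    for lesion in spec.lesion_list:
        cx, cy, cz = lesion.center
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lesion.radius**2
        signal[inside] = lesion.signal

    labels = {
        name: Segmentation(data=(labelmap == lab).astype(np.uint8), affine=affine.copy())
        for name, lab in TISSUE_LABELS.items()
        if name != "background"
    }
    roi = Segmentation(data=breast.astype(np.uint8), affine=affine.copy())

    # sternum: midsagittal anterior torso surface, curved by the chest bow
    z_line = np.linspace(-half_l, half_l, 33)
    sternum_pts = np.column_stack(
        [np.zeros_like(z_line), b - spec.anterior_offset(z_line), z_line]
    )
    sternum = fit_curve(sternum_pts)

    # breast contour: scaled-ellipse arc through mid-breast tissue at HF = 0
    centers = spec.breast_centers()
    e_norm = np.linalg.norm(centers[1][:2])
    lam = 1.0 + (r / 2.0) / e_norm
    half_arc = np.deg2rad(spec.contour_arc_deg / 2.0)
    theta = np.linspace(-half_arc, half_arc, 33)  # 0 = anterior, + = subject left
    contour_pts = np.column_stack(
        [lam * a * np.sin(theta), lam * b * np.cos(theta), np.zeros_like(theta)]
    )
    contour = fit_curve(contour_pts)

    return PhantomData(
        labels=labels,
        labelmap=Volume(data=labelmap.astype(float), affine=affine.copy()),
        signal=Volume(data=signal, affine=affine.copy()),
        breast_roi=roi,
        sternum=sternum,
        breast_contour=contour,
    )


# ---------------------------------------------------------------------------
# Coil layout and sensitivities
# ---------------------------------------------------------------------------

def build_coil_layout(
    spec: PhantomSpec,
    n_modules: int = 7,
    coils_per_module: int = 4,
    loop_radius: float = 40.0,
    standoff_mm: float = 5.0,
) -> CoilLayout:
    """Conformal loop array: `n_modules` columns around the chest arc (LR)
    times `coils_per_module` rows along HF, offset `standoff_mm` anterior of
    the skin with loop axes pointing into the body."""
    if n_modules < 1 or coils_per_module < 1:
        raise ValueError("need at least one module and one coil per module")
    if loop_radius <= 0:
        raise ValueError("loop radius must be positive")
    a, b = spec.torso_halfwidth_LR, spec.torso_halfdepth_AP
    half_arc = np.deg2rad(spec.contour_arc_deg / 2.0) * 0.9
    thetas = np.linspace(-half_arc, half_arc, n_modules) if n_modules > 1 else np.array([0.0])
    span = 0.7 * spec.torso_length_HF
    zs = (
        np.linspace(-span / 2, span / 2, coils_per_module)
        if coils_per_module > 1
        else np.array([0.0])
    )
    loops = []
    for th in thetas:
        sx, sy = a * np.sin(th), b * np.cos(th)
        n_out = np.array([sx / a**2, sy / b**2, 0.0])
        n_out /= np.linalg.norm(n_out)
        for z in zs:
            surf = np.array([sx, sy - spec.anterior_offset(z), z])
            center = surf + standoff_mm * n_out
            loops.append((center, -n_out, float(loop_radius)))
    return CoilLayout(loops=loops)


def _loop_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([0.0, 0.0, 1.0]) if abs(normal[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return u, v


def biot_savart_loop(
    center: np.ndarray,
    normal: np.ndarray,
    radius: float,
    points: np.ndarray,
    n_segments: int = 64,
    core_radius: float = 1.0,
) -> np.ndarray:
    """|B| of a circular current loop by segment-wise Biot-Savart summation.

    The loop is discretized into `n_segments` straight elements; distances are
    clamped to `core_radius` mm so the field stays finite on the wire.  Units
    are arbitrary (mu0*I/4pi = 1).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u, v = _loop_frame(np.asarray(normal, dtype=float))
    phi = np.linspace(0.0, 2 * np.pi, n_segments + 1)
    ring = center + radius * (np.cos(phi)[:, None] * u + np.sin(phi)[:, None] * v)
    mids = 0.5 * (ring[:-1] + ring[1:])
    dls = np.diff(ring, axis=0)

    bx = np.zeros(pts.shape[0])
    by = np.zeros(pts.shape[0])
    bz = np.zeros(pts.shape[0])
    px, py, pz = pts[:, 0], pts[:, 1], pts[:, 2]
    for (mx, my, mz), (dx, dy, dz) in zip(mids, dls):
        rx, ry, rz = px - mx, py - my, pz - mz
        d2 = rx * rx + ry * ry + rz * rz
        inv_d3 = np.maximum(np.sqrt(d2), core_radius) ** -3
        bx += (dy * rz - dz * ry) * inv_d3
        by += (dz * rx - dx * rz) * inv_d3
        bz += (dx * ry - dy * rx) * inv_d3
    return np.sqrt(bx * bx + by * by + bz * bz)


def loop_sensitivity(
    layout: CoilLayout,
    grid: Volume,
    n_segments: int = 64,
    phase_scale: float = 0.01,
) -> np.ndarray:
    """Complex per-channel sensitivity maps on the grid of `grid`.

    Magnitudes are Biot-Savart loop fields; a smooth channel-specific linear
    phase (phase_scale rad/mm along a per-channel direction) makes the maps
    complex and non-collinear, as real receive profiles are.
    """
    if np.any(grid.spacing <= 0):
        raise ValueError("grid spacing must be positive")
    if n_segments < 64:
        raise ValueError("need >= 64 loop segments")
    pts = grid.grid_world_points()
    nc = layout.channel_count
    sens = np.empty((nc,) + grid.data.shape, dtype=complex)
    for c, (center, normal, radius) in enumerate(layout.loops):
        mag = biot_savart_loop(center, normal, radius, pts, n_segments=n_segments)
        alpha = 2 * np.pi * c / max(nc, 1)
        direction = np.array([np.cos(alpha), np.sin(alpha), 0.3])
        direction /= np.linalg.norm(direction)
        phase = phase_scale * ((pts - center) @ direction)
        sens[c] = (mag * np.exp(1j * phase)).reshape(grid.data.shape)
    return sens


def on_axis_loop_field(radius: float, distance: float) -> float:
    """Analytic on-axis |B| of a circular loop (same units as biot_savart_loop)."""
    return 2 * np.pi * radius**2 / (radius**2 + distance**2) ** 1.5


# ---------------------------------------------------------------------------
# Noise model
# ---------------------------------------------------------------------------

def make_noise_cov(
    channels: int,
    sigma: float,
    mean_offdiag_corr: float,
    phase_jitter: float = 0.0,
    seed: int | None = None,
) -> NoiseCovariance:
    """Uniform-correlation channel covariance: diagonal sigma^2, normalized
    off-diagonal magnitudes averaging exactly `mean_offdiag_corr`.

    With `phase_jitter` > 0 the off-diagonals get random phases (seeded),
    re-projected to the PSD cone if needed; magnitudes then match the target
    mean only approximately.
    """
    if not 0 <= mean_offdiag_corr < 1:
        raise ValueError("mean off-diagonal correlation must be in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rho = mean_offdiag_corr
    cov = np.full((channels, channels), rho, dtype=complex)
    np.fill_diagonal(cov, 1.0)
    if phase_jitter > 0:
        rng = np.random.default_rng(seed)
        theta = phase_jitter * rng.standard_normal((channels, channels))
        theta = np.triu(theta, 1)
        phases = np.exp(1j * (theta - theta.T))
        cov = cov * phases
        np.fill_diagonal(cov, 1.0)
        w, v = np.linalg.eigh(cov)
        if w.min() < 0:
            cov = (v * np.clip(w, 0, None)) @ v.conj().T
            # restore the unit diagonal by congruence (keeps PSD)
            d = np.sqrt(np.real(np.diag(cov)))
            cov = cov / np.outer(d, d)
            np.fill_diagonal(cov, 1.0)
    return NoiseCovariance(matrix=sigma**2 * cov, scale=sigma**2)


def _noise_factor(cov: NoiseCovariance) -> np.ndarray:
    """Matrix square root L with L L^H = cov (Cholesky, eigh fallback)."""
    try:
        return np.linalg.cholesky(cov.matrix)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov.matrix)
        return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def draw_noise(cov: NoiseCovariance, n: int, rng: np.random.Generator) -> np.ndarray:
    """n complex channel-noise vectors with E[x x^H] = cov (columns)."""
    c = cov.channels
    white = (rng.standard_normal((c, n)) + 1j * rng.standard_normal((c, n))) / np.sqrt(2.0)
    return _noise_factor(cov) @ white


def simulate_multicoil(
    signal: Volume,
    sens: np.ndarray,
    cov: NoiseCovariance,
    seed: int,
    n_noise_samples: int = 10000,
) -> tuple[MultiCoilImage, np.ndarray]:
    """Simulate a multi-channel acquisition plus a noise-only scan.

    Channel c = sens_c * signal + correlated complex Gaussian noise with
    covariance `cov` per voxel (real and imaginary parts independent, each
    with covariance cov/2).  Deterministic for a given seed.
    """
    sens = np.asarray(sens, dtype=complex)
    if sens.shape[0] != cov.channels:
        raise ValueError("channel count mismatch between sensitivities and covariance")
    if sens.shape[1:] != signal.data.shape:
        raise ValueError("sensitivity grid does not match the signal volume")
    rng = np.random.default_rng(seed)
    nvox = int(np.prod(signal.data.shape))
    noise = draw_noise(cov, nvox, rng).reshape(sens.shape)
    data = sens * signal.data[None] + noise
    noise_only = draw_noise(cov, n_noise_samples, rng)
    return MultiCoilImage(data=data, affine=signal.affine.copy()), noise_only


# ---------------------------------------------------------------------------
# HDF5 I/O (complex stored as paired real/imag, channel-major)
# ---------------------------------------------------------------------------

def save_multicoil_h5(path: str | Path, mc: MultiCoilImage, noise_samples: np.ndarray) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data/real", data=mc.data.real)
        f.create_dataset("data/imag", data=mc.data.imag)
        f.create_dataset("affine", data=mc.affine)
        f.create_dataset("noise/real", data=np.asarray(noise_samples).real)
        f.create_dataset("noise/imag", data=np.asarray(noise_samples).imag)
    return path


def load_multicoil_h5(path: str | Path) -> tuple[MultiCoilImage, np.ndarray]:
    with h5py.File(Path(path), "r") as f:
        data = f["data/real"][()] + 1j * f["data/imag"][()]
        affine = f["affine"][()]
        noise = f["noise/real"][()] + 1j * f["noise/imag"][()]
    return MultiCoilImage(data=data, affine=affine), noise
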