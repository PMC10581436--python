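"""SENSE g-factor maps for 2D Cartesian acceleration and the max-R search.

Acceleration is modeled as ideal Cartesian SENSE: undersampling by (R1, R2)
folds voxels separated by FOV/R in each accelerated direction onto each
other, and the reconstruction unfolds them with known sensitivities S and
channel noise covariance Psi.  The geometry factor at voxel rho of an
aliasing set is the closed form

    g_rho = sqrt([(S^H Psi^-1 S)^-1]_rho,rho * [S^H Psi^-1 S]_rho,rho),

the SNR penalty of unfolding beyond the sqrt(R) sampling loss.  Aliasing
sets are restricted to the object support mask (standard practice; an
unrestricted mode exists for sensitivity analysis).  Voxels whose aliased
sensitivities are collinear are unresolvable and carry an infinity sentinel;
voxels outside the support are NaN.

The accelerated-acquisition noise model draws aliased-image noise with
covariance R * cov: acquiring 1/R of the k-space lines raises image-domain
noise variance by R under a unitary DFT convention, which is exactly what
makes SNR_R = SNR_full / (g sqrt(R)) hold.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .phantom import NoiseCovariance, draw_noise

_SINGULAR_RCOND = 1e-10


@dataclasses.dataclass
class GFactorMap:
    """Unitless g >= 1 on the support; inf = unresolvable, NaN = outside support."""

    data: np.ndarray
    acceleration: tuple[int, int]  # (R_LR, R_HF) or generally (R_axis0, R_axis1)
    method: str
    axes: tuple[str, str] = ("LR", "HF")

    def max_over(self, mask: np.ndarray) -> float:
        vals = self.data[np.asarray(mask, dtype=bool)]
        vals = vals[~np.isnan(vals)]
        return float(vals.max()) if vals.size else np.nan


def _pad_to_multiple(arr: np.ndarray, r1: int, r2: int, axes=(-2, -1)) -> np.ndarray:
    n1, n2 = arr.shape[axes[0]], arr.shape[axes[1]]
    p1 = (-n1) % r1
    p2 = (-n2) % r2
    pad = [(0, 0)] * arr.ndim
    pad[axes[0]] = (0, p1)
    pad[axes[1]] = (0, p2)
    return np.pad(arr, pad)


def _aliasing_sets(shape: tuple[int, int], r1: int, r2: int):
    """Yield (base voxel, array of aliased (i, j) index pairs) on a padded grid."""
    n1, n2 = shape
    b1, b2 = n1 // r1, n2 // r2
    for i in range(b1):
        for j in range(b2):
            rows = i + b1 * np.arange(r1)
            cols = j + b2 * np.arange(r2)
            ii, jj = np.meshgrid(rows, cols, indexing="ij")
            yield (i, j), np.column_stack([ii.ravel(), jj.ravel()])


def sense_gfactor(
    sens_slice: np.ndarray,
    cov: NoiseCovariance,
    R1: int,
    R2: int,
    support_mask: np.ndarray,
    restrict_to_support: bool = True,
) -> GFactorMap:
    """Closed-form SENSE g-factor map for a 2D slice.

    `sens_slice` is channels x N1 x N2 complex; `support_mask` marks the
    object.  R1 accelerates axis 0, R2 axis 1.
    """
    sens_slice = np.asarray(sens_slice, dtype=complex)
    if sens_slice.ndim != 3:
        raise ValueError("sens_slice must be channels x N1 x N2")
    if R1 < 1 or R2 < 1:
        raise ValueError("acceleration factors must be >= 1")
    support = np.asarray(support_mask, dtype=bool)
    if support.shape != sens_slice.shape[1:]:
        raise ValueError("support mask shape mismatch")

    sens_p = _pad_to_multiple(sens_slice, R1, R2)
    supp_p = _pad_to_multiple(
        support if restrict_to_support else np.ones_like(support), R1, R2
    ).astype(bool)

    psi_inv = np.linalg.inv(cov.matrix)
    gmap = np.full(sens_p.shape[1:], np.nan)
    for _, idx in _aliasing_sets(sens_p.shape[1:], R1, R2):
        in_supp = supp_p[idx[:, 0], idx[:, 1]]
        active = idx[in_supp]
        if active.size == 0:
            continue
        s = sens_p[:, active[:, 0], active[:, 1]]  # (C, K)
        m = s.conj().T @ psi_inv @ s               # (K, K)
        svals = np.linalg.svd(m, compute_uv=False)
        if svals[-1] <= _SINGULAR_RCOND * svals[0]:
            gmap[active[:, 0], active[:, 1]] = np.inf
            continue
        m_inv = np.linalg.inv(m)
        g = np.sqrt(np.real(np.diag(m_inv)) * np.real(np.diag(m)))
        gmap[active[:, 0], active[:, 1]] = g

    n1, n2 = sens_slice.shape[1:]
    out = gmap[:n1, :n2]
    if not restrict_to_support:
        out = np.where(support | ~np.isnan(out), out, np.nan)
    return GFactorMap(data=out, acceleration=(R1, R2), method="analytic_sense")


def _unfold_matrices(sens_p, supp_p, psi_inv, R1, R2):
    """Per aliasing set: active indices, unfold matrix U = M^-1 S^H Psi^-1."""
    for _, idx in _aliasing_sets(sens_p.shape[1:], R1, R2):
        in_supp = supp_p[idx[:, 0], idx[:, 1]]
        active = idx[in_supp]
        if active.size == 0:
            continue
        s = sens_p[:, active[:, 0], active[:, 1]]
        m = s.conj().T @ psi_inv @ s
        svals = np.linalg.svd(m, compute_uv=False)
        if svals[-1] <= _SINGULAR_RCOND * svals[0]:
            yield active, None
            continue
        yield active, np.linalg.solve(m, s.conj().T @ psi_inv)


def analytic_accelerated_snr(
    signal_slice: np.ndarray,
    sens_slice: np.ndarray,
    cov: NoiseCovariance,
    R1: int,
    R2: int,
    support_mask: np.ndarray,
) -> np.ndarray:
    """Closed-form SNR of the SENSE-unfolded image (same sigma convention as
    the full-acquisition maps): SNR_R(rho) = |m_rho| / sqrt(R [(S^H Psi^-1 S)^-1]_rho,rho / 2)."""
    sens_slice = np.asarray(sens_slice, dtype=complex)
    signal_slice = np.asarray(signal_slice, dtype=float)
    support = np.asarray(support_mask, dtype=bool)
    r_tot = R1 * R2
    sens_p = _pad_to_multiple(sens_slice, R1, R2)
    supp_p = _pad_to_multiple(support, R1, R2).astype(bool)
    sig_p = _pad_to_multiple(signal_slice, R1, R2)
    psi_inv = np.linalg.inv(cov.matrix)

    snr = np.full(sens_p.shape[1:], np.nan)
    for _, idx in _aliasing_sets(sens_p.shape[1:], R1, R2):
        in_supp = supp_p[idx[:, 0], idx[:, 1]]
        active = idx[in_supp]
        if active.size == 0:
            continue
        s = sens_p[:, active[:, 0], active[:, 1]]
        m = s.conj().T @ psi_inv @ s
        svals = np.linalg.svd(m, compute_uv=False)
        if svals[-1] <= _SINGULAR_RCOND * svals[0]:
            snr[active[:, 0], active[:, 1]] = 0.0
            continue
        m_inv = np.linalg.inv(m)
        var = r_tot * np.real(np.diag(m_inv)) / 2.0
        mag = np.abs(sig_p[active[:, 0], active[:, 1]])
        snr[active[:, 0], active[:, 1]] = mag / np.sqrt(var)
    n1, n2 = sens_slice.shape[1:]
    return snr[:n1, :n2]


def pseudo_replica_gfactor(
    mc_slice: np.ndarray,
    sens_slice: np.ndarray,
    cov: NoiseCovariance,
    R1: int,
    R2: int,
    n_replicas: int = 256,
    seed: int = 0,
) -> GFactorMap:
    """Monte-Carlo g-factor: g = SNR_full / (SNR_accel sqrt(R1 R2)) with both
    SNR maps from the pseudo-replica machinery (matched-filter combine for
    the full acquisition, SENSE unfolding for the accelerated one)."""
    if n_replicas < 32:
        raise ValueError("need at least 32 replicas")
    mc_slice = np.asarray(mc_slice, dtype=complex)
    sens_slice = np.asarray(sens_slice, dtype=complex)
    if mc_slice.shape != sens_slice.shape:
        raise ValueError("data and sensitivity slices must share a shape")
    support = np.abs(sens_slice).sum(axis=0) > 0
    n1, n2 = sens_slice.shape[1:]
    nvox = n1 * n2
    psi_inv = np.linalg.inv(cov.matrix)
    rng = np.random.default_rng(seed)
    r_tot = R1 * R2

    # --- full acquisition, matched-filter combine --------------------------
    s_flat = sens_slice.reshape(cov.channels, -1)
    cov_inv_s = psi_inv @ s_flat
    denom = np.real(np.einsum("cn,cn->n", s_flat.conj(), cov_inv_s))
    w = cov_inv_s / np.where(denom > 0, denom, 1.0)
    w[:, denom == 0] = 0.0
    full_mag = np.abs(np.einsum("cn,cn->n", w.conj(), mc_slice.reshape(cov.channels, -1)))

    sum_re2 = np.zeros(nvox); sum_re = np.zeros(nvox)
    sum_im2 = np.zeros(nvox); sum_im = np.zeros(nvox)
    for _ in range(n_replicas):
        noise = draw_noise(cov, nvox, rng)
        out = np.einsum("cn,cn->n", w.conj(), noise)
        sum_re += out.real; sum_re2 += out.real**2
        sum_im += out.imag; sum_im2 += out.imag**2
    var = ((sum_re2 - sum_re**2 / n_replicas) + (sum_im2 - sum_im**2 / n_replicas)) / (
        n_replicas - 1
    )
    sigma_full = np.sqrt(np.maximum(var, 0.0) / 2.0)
    snr_full = np.where(sigma_full > 0, full_mag / np.where(sigma_full > 0, sigma_full, 1.0), 0.0)
    snr_full = snr_full.reshape(n1, n2)

    # --- accelerated acquisition: fold, unfold, replicate -------------------
    sens_p = _pad_to_multiple(sens_slice, R1, R2)
    supp_p = _pad_to_multiple(support, R1, R2).astype(bool)
    mc_p = _pad_to_multiple(mc_slice, R1, R2)
    n1p, n2p = sens_p.shape[1:]
    b1, b2 = n1p // R1, n2p // R2

    folded = mc_p.reshape(cov.channels, R1, b1, R2, b2).sum(axis=(1, 3))  # (C, b1, b2)
    sets = list(_unfold_matrices(sens_p, supp_p, psi_inv, R1, R2))

    recon = np.full((n1p, n2p), 0.0)
    for active, u in sets:
        if u is None:
            continue
        base = (active[:, 0] % b1, active[:, 1] % b2)
        vals = u @ folded[:, base[0][0], base[1][0]]
        recon[active[:, 0], active[:, 1]] = np.abs(vals)

    cov_acc = NoiseCovariance(matrix=r_tot * cov.matrix, scale=r_tot)
    a_re = np.zeros((n1p, n2p)); a_re2 = np.zeros((n1p, n2p))
    a_im = np.zeros((n1p, n2p)); a_im2 = np.zeros((n1p, n2p))
    for _ in range(n_replicas):
        eta = draw_noise(cov_acc, b1 * b2, rng).reshape(cov.channels, b1, b2)
        for active, u in sets:
            if u is None:
                continue
            vals = u @ eta[:, active[0, 0] % b1, active[0, 1] % b2]
            a_re[active[:, 0], active[:, 1]] += vals.real
            a_re2[active[:, 0], active[:, 1]] += vals.real**2
            a_im[active[:, 0], active[:, 1]] += vals.imag
            a_im2[active[:, 0], active[:, 1]] += vals.imag**2
    var_acc = ((a_re2 - a_re**2 / n_replicas) + (a_im2 - a_im**2 / n_replicas)) / (
        n_replicas - 1
    )
    sigma_acc = np.sqrt(np.maximum(var_acc, 0.0) / 2.0)

    gmap = np.full((n1p, n2p), np.nan)
    ok = (sigma_acc > 0) & supp_p
    snr_full_p = _pad_to_multiple(snr_full, R1, R2)
    snr_acc = np.where(ok, recon / np.where(ok, sigma_acc, 1.0), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        gmap[ok] = snr_full_p[ok] / (snr_acc[ok] * np.sqrt(r_tot))
    for active, u in sets:
        if u is None:
            gmap[active[:, 0], active[:, 1]] = np.inf
    return GFactorMap(
        data=gmap[:n1, :n2], acceleration=(R1, R2), method="pseudo_replica"
    )


def max_acceleration(
    gmaps: dict[tuple[int, int], GFactorMap],
    roi_mask: np.ndarray,
    g_threshold: float = 2.0,
) -> tuple[int, int]:
    """Largest-product (R1, R2) whose max g over the ROI stays below the
    threshold; ties go to the larger R1 (the LR direction, where the array
    has more channels).  Returns (1, 1) with a warning if nothing qualifies.
    """
    if not gmaps:
        raise ValueError("empty candidate grid")
    roi = np.asarray(roi_mask, dtype=bool)
    feasible = []
    for (r1, r2), gmap in gmaps.items():
        gmax = gmap.max_over(roi)
        if np.isfinite(gmax) and gmax < g_threshold:
            feasible.append((r1 * r2, r1, r2))
    if not feasible:
        warnings.warn("no acceleration satisfies the g-factor threshold; returning (1, 1)")
        return (1, 1)
    feasible.sort()
    _, r1, r2 = feasible[-1]
    return (r1, r2)
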