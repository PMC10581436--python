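"""Noise statistics, pseudo-multiple-replica SNR maps and ROI comparisons.

Conventions (used consistently by every SNR path in the package):

* channel noise is complex Gaussian with E[n n^H] = cov, real and imaginary
  parts independent with covariance cov/2 each;
* the per-voxel noise estimate of the pseudo-replica method is
  sigma_hat = sqrt((var(Re) + var(Im)) / 2) over replica reconstructions,
  i.e. the per-quadrature noise standard deviation;
* SNR = |combined signal| / sigma_hat.  For a linear combiner with weights w
  this equals |w^H p| / sqrt(w^H cov w / 2), which the analytic oracle
  computes in closed form; for the matched filter it reduces to
  sqrt(2 p^H cov^-1 p).

Two channel combiners are provided.  ``whitened_rss`` is the root-sum-of-
squares of the prewhitened channel vector (no sensitivity estimate needed);
because the magnitude is nonlinear, its noise is propagated through the
per-voxel effective linear weights w = cov^-1 p / ||L^-1 p|| recorded at
combine time.  ``matched_filter`` uses w proportional to cov^-1 s with
|w^H s| = 1 (SNR-optimal when the sensitivities s are known).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, stats

from .core_geometry import Segmentation, Volume
from .phantom import MultiCoilImage, NoiseCovariance, draw_noise

COMBINE_MODES = ("whitened_rss", "matched_filter")


@dataclasses.dataclass
class SNRMap:
    """Non-negative per-voxel SNR with provenance of how it was produced."""

    data: np.ndarray
    affine: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if (self.data < 0).any():
            raise ValueError("SNR must be non-negative")

    def as_volume(self) -> Volume:
        return Volume(data=self.data, affine=self.affine)


@dataclasses.dataclass
class ROIStats:
    mean_snr: float
    sd_snr: float
    homogeneity: float  # sd / mean ("relative homogeneity", lower = flatter)
    voxel_count: int


@dataclasses.dataclass
class CombineResult:
    combined: np.ndarray          # complex, image shape
    weights: np.ndarray           # (channels, *image shape) effective linear weights
    affine: np.ndarray


# ---------------------------------------------------------------------------
# Noise statistics
# ---------------------------------------------------------------------------

def noise_covariance(samples: np.ndarray) -> NoiseCovariance:
    """Sample channel covariance (1/n) sum x x^H after mean removal.

    `samples` is channels x n complex; requires n >= channels.
    """
    x = np.asarray(samples, dtype=complex)
    if x.ndim != 2:
        raise ValueError("samples must be channels x n")
    c, n = x.shape
    if n < c:
        raise ValueError("insufficient samples: need at least one per channel")
    x = x - x.mean(axis=1, keepdims=True)
    cov = (x @ x.conj().T) / n
    cov = 0.5 * (cov + cov.conj().T)
    if np.all(np.abs(cov) < 1e-300):
        # degenerate but legal (e.g. constant samples): zero matrix, built
        # without the strictly-positive-diagonal validation
        nc = object.__new__(NoiseCovariance)
        nc.matrix = cov
        nc.scale = 0.0
        return nc
    return NoiseCovariance(matrix=cov, scale=float(np.real(np.diag(cov)).mean()))


def normalized_correlation(cov: NoiseCovariance) -> np.ndarray:
    """|cov_ij| / sqrt(cov_ii cov_jj): unit diagonal, off-diagonals in [0, 1]."""
    diag = np.real(np.diag(cov.matrix))
    if np.any(diag <= 0):
        raise ValueError("covariance has a non-positive diagonal entry")
    d = np.sqrt(diag)
    corr = np.abs(cov.matrix) / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def mean_offdiagonal(corr: np.ndarray) -> float:
    """Mean of the off-diagonal entries of a normalized correlation matrix."""
    n = corr.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(np.abs(corr[mask]).mean())


# ---------------------------------------------------------------------------
# Channel combination
# ---------------------------------------------------------------------------

def _whitener(cov: NoiseCovariance) -> np.ndarray:
    """L^-1 with L L^H = cov."""
    try:
        chol = np.linalg.cholesky(cov.matrix)
    except np.linalg.LinAlgError as exc:
        raise ValueError("noise covariance is singular; cannot prewhiten") from exc
    return linalg.solve_triangular(chol, np.eye(cov.channels), lower=True)


def combine_channels(
    mc: MultiCoilImage,
    cov: NoiseCovariance,
    mode: str = "whitened_rss",
    sens: np.ndarray | None = None,
) -> CombineResult:
    """Combine channel images into one complex image plus effective weights.

    The weight record is the per-voxel linear map the combined value responds
    to at first order; it is what the pseudo-replica machinery propagates
    noise through, and what the analytic oracle plugs into its closed form.
    """
    if mode not in COMBINE_MODES:
        raise ValueError(f"unknown combine mode {mode!r}")
    shape = mc.data.shape[1:]
    p = mc.data.reshape(mc.channels, -1)

    if mode == "whitened_rss":
        w_mat = _whitener(cov)
        wp = w_mat @ p
        norm = np.linalg.norm(wp, axis=0)
        combined = norm.astype(complex)
        cov_inv_p = w_mat.conj().T @ wp
        safe = np.where(norm > 0, norm, 1.0)
        weights = cov_inv_p / safe
        weights[:, norm == 0] = 0.0
    else:
        if sens is None:
            raise ValueError("matched_filter requires sensitivity maps")
        s = np.asarray(sens, dtype=complex).reshape(mc.channels, -1)
        try:
            cov_inv_s = np.linalg.solve(cov.matrix, s)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "noise covariance is singular; matched filter is ill-conditioned"
            ) from exc
        denom = np.real(np.einsum("cn,cn->n", s.conj(), cov_inv_s))
        safe = np.where(denom > 0, denom, 1.0)
        weights = cov_inv_s / safe
        weights[:, denom == 0] = 0.0
        combined = np.einsum("cn,cn->n", weights.conj(), p)

    return CombineResult(
        combined=combined.reshape(shape),
        weights=weights.reshape((mc.channels,) + shape),
        affine=mc.affine.copy(),
    )


# ---------------------------------------------------------------------------
# SNR maps
# ---------------------------------------------------------------------------

def pseudo_replica_snr(
    mc: MultiCoilImage,
    cov: NoiseCovariance,
    mode: str = "whitened_rss",
    sens: np.ndarray | None = None,
    n_replicas: int = 256,
    seed: int = 0,
) -> SNRMap:
    """Monte-Carlo SNR map: propagate synthetic correlated noise through the
    identical combine path and divide the combined magnitude by the measured
    per-voxel quadrature noise standard deviation."""
    if n_replicas < 32:
        raise ValueError("need at least 32 replicas")
    if np.all(np.abs(cov.matrix) == 0):
        raise ValueError("zero noise model: SNR undefined")
    res = combine_channels(mc, cov, mode=mode, sens=sens)
    w = res.weights.reshape(cov.channels, -1)
    nvox = w.shape[1]

    rng = np.random.default_rng(seed)
    sum_re = np.zeros(nvox)
    sum_re2 = np.zeros(nvox)
    sum_im = np.zeros(nvox)
    sum_im2 = np.zeros(nvox)
    for _ in range(n_replicas):
        noise = draw_noise(cov, nvox, rng)
        out = np.einsum("cn,cn->n", w.conj(), noise)
        sum_re += out.real
        sum_re2 += out.real**2
        sum_im += out.imag
        sum_im2 += out.imag**2
    var_re = (sum_re2 - sum_re**2 / n_replicas) / (n_replicas - 1)
    var_im = (sum_im2 - sum_im**2 / n_replicas) / (n_replicas - 1)
    sigma = np.sqrt(np.maximum(var_re + var_im, 0.0) / 2.0)

    mag = np.abs(res.combined).ravel()
    snr = np.where(sigma > 0, mag / np.where(sigma > 0, sigma, 1.0), 0.0)
    return SNRMap(
        data=snr.reshape(mc.data.shape[1:]),
        affine=mc.affine.copy(),
        provenance={"method": "pseudo_replica", "replicas": n_replicas, "seed": seed,
                    "combiner": mode},
    )


def analytic_snr(
    signal: Volume,
    sens: np.ndarray,
    cov: NoiseCovariance,
    mode: str = "whitened_rss",
) -> SNRMap:
    """Closed-form SNR oracle: |w^H p| / sqrt(w^H cov w / 2) with p the
    noiseless channel signal vector and w the combine weights."""
    sens = np.asarray(sens, dtype=complex)
    p = sens * signal.data[None]
    mc = MultiCoilImage(data=p, affine=signal.affine.copy())
    res = combine_channels(mc, cov, mode=mode, sens=sens)
    w = res.weights.reshape(cov.channels, -1)
    num = np.abs(np.einsum("cn,cn->n", w.conj(), p.reshape(cov.channels, -1)))
    var = np.real(np.einsum("cn,cd,dn->n", w.conj(), cov.matrix, w))
    sigma = np.sqrt(np.maximum(var, 0.0) / 2.0)
    snr = np.where(sigma > 0, num / np.where(sigma > 0, sigma, 1.0), 0.0)
    return SNRMap(
        data=snr.reshape(signal.data.shape),
        affine=signal.affine.copy(),
        provenance={"method": "analytic", "combiner": mode},
    )


# ---------------------------------------------------------------------------
# ROI statistics and study-level comparisons
# ---------------------------------------------------------------------------

def roi_snr_stats(snr_map: SNRMap, roi: Segmentation) -> ROIStats:
    """Mean, SD and relative homogeneity (SD/mean) of SNR over the ROI."""
    if snr_map.data.shape != roi.data.shape:
        raise ValueError("SNR map and ROI are on different grids")
    mask = roi.data.astype(bool)
    if not mask.any():
        raise ValueError("empty ROI")
    vals = snr_map.data[mask]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    homog = sd / mean if mean != 0 else np.inf
    return ROIStats(mean_snr=mean, sd_snr=sd, homogeneity=homog, voxel_count=int(mask.sum()))


def snr_gain(map_a: SNRMap, map_b: SNRMap, roi: Segmentation) -> float:
    """Ratio of ROI mean SNRs a/b (the coil-array gain factor)."""
    stats_a = roi_snr_stats(map_a, roi)
    stats_b = roi_snr_stats(map_b, roi)
    if stats_b.mean_snr == 0:
        raise ValueError("zero reference ROI mean SNR")
    return stats_a.mean_snr / stats_b.mean_snr


def paired_onesided_ttest(a, b, alternative: str = "a_greater") -> tuple[float, float]:
    """Classical paired t test on a-b, one-sided upper tail, df = n-1."""
    if alternative != "a_greater":
        raise ValueError("only the a_greater alternative is supported")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of the paired differences")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def standardized_effect_size(mean_ratio: float, sd_fraction: float) -> float:
    """Cohen's d for a relative difference: (ratio - 1) / relative SD.

    A factor-1.2 difference with a 20% standard deviation gives d = 1.
    """
    if sd_fraction <= 0:
        raise ValueError("sd_fraction must be positive")
    return (mean_ratio - 1.0) / sd_fraction


def required_sample_size(
    effect_size: float,
    alpha: float = 0.05,
    power: float = 0.8,
    dropout: float = 0.0,
    sided: str = "one",
    max_n: int = 10**6,
) -> int:
    """Smallest paired-t sample size reaching the target power, then inflated
    for dropout by dividing by (1 - dropout) and rounding up.

    Power uses the noncentral t distribution: ncp = d * sqrt(n), df = n - 1,
    rejection at the upper alpha (or alpha/2) t quantile.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValueError("alpha and power must be in (0, 1)")
    if not 0 <= dropout < 1:
        raise ValueError("dropout must be in [0, 1)")
    if effect_size <= 0:
        raise ValueError("effect size must be positive")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    tail = alpha if sided == "one" else alpha / 2.0
    for n in range(2, max_n + 1):
        df = n - 1
        tcrit = stats.t.ppf(1 - tail, df)
        achieved = stats.nct.sf(tcrit, df, effect_size * np.sqrt(n))
        if achieved >= power:
            return int(np.ceil(n / (1.0 - dropout)))
    raise ValueError(f"power {power} unreachable within n <= {max_n}")
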