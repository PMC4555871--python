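"""Detection and 2D-Gaussian quantification of spots and microclusters.

Single fluorophore-labelled molecules and receptor microclusters both appear
in TIRF images as approximately round, diffraction-limited (or slightly
larger) blobs.  Both are quantified the same way: candidate maxima are found
on a band-passed image, then each candidate is fitted with a symmetric 2D
Gaussian plus constant background,

    I(x, y) = b + A * exp(-((x - x0)^2 + (y - y0)^2) / (2 sigma^2)),

whose integrated intensity 2*pi*A*sigma^2 serves as the molecule/cluster
"volume" proxy.  Counting converged, quality-filtered fits inside a region
of known area yields the surface density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import peak_local_max

from .simulate import ImageFrame, OpticsModel

__all__ = [
    "DetectionParams",
    "SpotFit",
    "detect_candidates",
    "fit_gaussian_2d",
    "count_spots",
    "quantify_clusters",
    "robust_noise_sd",
]


@dataclass(frozen=True)
class DetectionParams:
    """Detection and fitting knobs.

    bandpass_low/high   Gaussian scales (px) of the difference-of-Gaussians
                        filter; low ~ PSF sigma, high ~ background scale
    threshold_k         candidate threshold in multiples of the robust noise SD
                        of the band-passed image
    min_separation      non-maximum-suppression radius, px (ties keep the
                        brighter candidate)
    fit_halfwidth       half-width of the square fitting window, px
    init_sigma          starting sigma for the fit, px
    max_iter            optimiser iteration cap
    tol                 optimiser convergence tolerance
    sigma_bounds        quality filter on fitted sigma, px (reject blur/noise)
    amplitude_k         quality filter: A must exceed this multiple of noise SD
    """

    bandpass_low: float = 0.7
    bandpass_high: float = 6.0
    threshold_k: float = 4.0
    min_separation: int = 2
    fit_halfwidth: int = 4
    init_sigma: float = 1.2
    max_iter: int = 200
    tol: float = 1e-10
    sigma_bounds: tuple[float, float] = (0.4, 4.0)
    amplitude_k: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold_k <= 0 or self.fit_halfwidth < 2:
            raise ValueError("invalid detection parameters")


@dataclass
class SpotFit:
    """One fitted spot.  ``ok`` gates entry into downstream counts."""

    x0: float
    y0: float
    amplitude: float
    sigma: float
    background: float
    integrated_intensity: float
    residual_norm: float
    converged: bool
    flags: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return self.converged and not self.flags


def robust_noise_sd(values: np.ndarray) -> float:
    """Noise SD from the median absolute deviation (outlier-resistant)."""
    v = np.asarray(values, dtype=float).ravel()
    return 1.4826 * float(np.median(np.abs(v - np.median(v))))


def _bandpass(data: np.ndarray, params: DetectionParams) -> np.ndarray:
    lo = ndimage.gaussian_filter(data, params.bandpass_low)
    hi = ndimage.gaussian_filter(data, params.bandpass_high)
    return lo - hi


def detect_candidates(image: ImageFrame, params: DetectionParams | None = None) -> np.ndarray:
    """Candidate spot centres as an (N, 2) array of (row, col) pixel indices.

    Local maxima of the band-passed image above ``threshold_k`` times its
    robust noise SD, non-maximum-suppressed at ``min_separation`` (the
    brighter of two merged maxima survives).  The band-pass removes any
    constant offset, so detection is invariant to background level.
    """
    params = params or DetectionParams()
    data = np.asarray(image.data, dtype=float)
    if data.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(data)):
        raise ValueError("image contains non-finite values")
    if np.ptp(data) == 0:
        return np.empty((0, 2), dtype=int)
    bp = _bandpass(data, params)
    # noise floor keeps noiseless synthetic frames detectable (MAD would be 0)
    noise = max(robust_noise_sd(bp), 1e-9 * float(np.ptp(bp)))
    coords = peak_local_max(
        bp,
        min_distance=params.min_separation,
        threshold_abs=params.threshold_k * noise,
        exclude_border=False,
    )
    return coords


def fit_gaussian_2d(
    image: ImageFrame,
    center: Sequence[float],
    params: DetectionParams | None = None,
) -> SpotFit:
    """Least-squares symmetric-Gaussian fit in a window around ``center``.

    ``center`` is (row, col).  A window clipped by the image border is not
    fitted: the result is flagged ``border`` with ``converged=False``.
    """
    params = params or DetectionParams()
    data = np.asarray(image.data, dtype=float)
    h, w = data.shape
    r, c = int(round(center[0])), int(round(center[1]))
    hw = params.fit_halfwidth
    if r - hw < 0 or c - hw < 0 or r + hw >= h or c + hw >= w:
        return SpotFit(
            x0=float(c), y0=float(r), amplitude=0.0, sigma=params.init_sigma,
            background=0.0, integrated_intensity=0.0, residual_norm=math.inf,
            converged=False, flags=("border",),
        )
    win = data[r - hw : r + hw + 1, c - hw : c + hw + 1]
    yy, xx = np.mgrid[r - hw : r + hw + 1, c - hw : c + hw + 1]

    b0 = float(np.median([win[0, :].min(), win[-1, :].min(), win[:, 0].min(), win[:, -1].min()]))
    a0 = max(float(win[hw, hw] - b0), 1e-3)

    def model(_, x0, y0, a, s, b):
        return (b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2))).ravel()

    def jac(_, x0, y0, a, s, b):
        r2 = (xx - x0) ** 2 + (yy - y0) ** 2
        e = np.exp(-r2 / (2 * s**2))
        cols = [
            (a * e * (xx - x0) / s**2).ravel(),
            (a * e * (yy - y0) / s**2).ravel(),
            e.ravel(),
            (a * e * r2 / s**3).ravel(),
            np.ones(e.size),
        ]
        return np.column_stack(cols)

    p0 = [float(c), float(r), a0, params.init_sigma, b0]
    lower = [c - hw, r - hw, 0.0, 0.05, -np.inf]
    upper = [c + hw, r + hw, np.inf, 5.0 * hw, np.inf]
    try:
        popt, _ = optimize.curve_fit(
            model, None, win.ravel(), p0=p0, bounds=(lower, upper), jac=jac,
            maxfev=params.max_iter * 10, xtol=params.tol, ftol=params.tol, gtol=params.tol,
        )
        converged = True
    except (RuntimeError, ValueError):
        popt, converged = p0, False
    x0, y0, a, s, b = (float(v) for v in popt)
    resid = float(np.linalg.norm(model(None, *popt) - win.ravel()))
    return SpotFit(
        x0=x0, y0=y0, amplitude=a, sigma=s, background=b,
        integrated_intensity=2.0 * math.pi * a * s**2,
        residual_norm=resid, converged=converged,
    )


def _quality_filter(fit: SpotFit, params: DetectionParams, noise: float,
                    psf_sigma_px: float | None = None) -> bool:
    if not fit.ok:
        return False
    lo, hi = params.sigma_bounds
    if psf_sigma_px is not None:
        lo, hi = 0.5 * psf_sigma_px, 3.0 * psf_sigma_px
    if not (lo <= fit.sigma <= hi):
        return False
    return fit.amplitude > params.amplitude_k * noise


#: Counting-efficiency curve: the fraction of molecules that survive
#: detection, non-maximum suppression and the quality filters is
#: ``r(lambda) = exp(c0 + c1*lambda + c2*lambda**2)`` with ``lambda`` the
#: molecule density per pixel².  The intercept captures the small
#: density-independent filter loss; the linear and quadratic terms capture
#: pair and higher-order merging of unresolvable neighbours.  Calibrated
#: once against generator ground truth for the default detection settings
#: at diffraction-limited optics (PSF sigma 0.15 µm, 0.16 µm pixels); valid
#: up to ~1 molecule/µm².
_EFFICIENCY_COEFS = (-0.0366, -11.46, -191.9)


def _overlap_corrected(raw: int, area_px: float) -> float:
    """Invert the counting-efficiency curve to estimate the true count.

    Solves ``raw = N * r(N / area_px)`` for N by fixed-point iteration.
    """
    if raw == 0:
        return 0.0
    c0, c1, c2 = _EFFICIENCY_COEFS
    n_est = float(raw)
    for _ in range(200):
        lam = n_est / area_px
        new = raw * math.exp(-(c0 + c1 * lam + c2 * lam**2))
        if abs(new - n_est) < 1e-9:
            return new
        n_est = new
    return n_est


def count_spots(
    image: ImageFrame,
    roi: tuple[int, int, int, int],
    optics: OpticsModel,
    params: DetectionParams | None = None,
    overlap_correction: bool = True,
) -> tuple[int, float]:
    """Count quality-filtered single molecules in ``roi`` and convert to density.

    ``roi`` is (row0, col0, height, width) in pixels.  The returned count is
    the number of converged, quality-filtered fits whose centre lies in the
    ROI; the density (molecules/µm²) additionally corrects for filter losses
    and unresolvable close pairs through the calibrated counting-efficiency
    curve (see :func:`_overlap_corrected`), which keeps counting unbiased up
    to ~1 molecule/µm².  Denser surfaces should go through the MFI calibration
    pathway instead.  For unbiased densities keep the ROI at least a fit
    window away from the frame edge, since border fits are discarded.
    """
    params = params or DetectionParams()
    r0, c0, rh, cw = roi
    if rh <= 0 or cw <= 0:
        raise ValueError("roi must have positive area")
    data = np.asarray(image.data, dtype=float)
    if r0 < 0 or c0 < 0 or r0 + rh > data.shape[0] or c0 + cw > data.shape[1]:
        raise ValueError("roi outside image")
    coords = detect_candidates(image, params)
    noise = robust_noise_sd(_bandpass(data, params))
    count = 0
    for rc in coords:
        if not (r0 <= rc[0] < r0 + rh and c0 <= rc[1] < c0 + cw):
            continue
        fit = fit_gaussian_2d(image, rc, params)
        if _quality_filter(fit, params, noise, optics.psf_sigma_px):
            count += 1
    area_px = float(rh * cw)
    estimate = _overlap_corrected(count, area_px) if overlap_correction else float(count)
    area_um2 = area_px * optics.pixel_size**2
    return count, estimate / area_um2


def quantify_clusters(
    image: ImageFrame,
    mask: np.ndarray,
    params: DetectionParams | None = None,
) -> list[SpotFit]:
    """Fit every microcluster inside a synapse mask.

    Returns all fits; clusters whose fitting window leaves the mask (or the
    image) are flagged ``mask_border``/``border`` and excluded from ``ok``.
    Integrated intensity of each ``ok`` fit is the cluster's volume proxy.
    """
    params = params or DetectionParams()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    coords = detect_candidates(image, params)
    hw = params.fit_halfwidth
    fits: list[SpotFit] = []
    for rc in coords:
        if not mask[rc[0], rc[1]]:
            continue
        fit = fit_gaussian_2d(image, rc, params)
        r, c = int(rc[0]), int(rc[1])
        r0, r1 = r - hw, r + hw + 1
        c0, c1 = c - hw, c + hw + 1
        if "border" not in fit.flags:
            window_in_mask = (
                r0 >= 0 and c0 >= 0 and r1 <= mask.shape[0] and c1 <= mask.shape[1]
                and bool(mask[r0:r1, c0:c1].all())
            )
            if not window_in_mask:
                fit.flags = fit.flags + ("mask_border",)
        fits.append(fit)
    return fits
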