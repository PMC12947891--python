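"""Raster image correlation spectroscopy (RICS) core.

Computes masked 2D spatial autocorrelation functions (ACFs) from raster-scan
image time series and fits diffusion models to them.  The theoretical ACF of
a single Brownian species observed through a 3D Gaussian PSF is

    G(dx, dy) = A * (1 + 4 D tau / w0^2)^-1 * (1 + 4 D tau / wz^2)^-1/2
                  * exp(-(dx^2 + dy^2) dr^2 / (w0^2 + 4 D tau))

with ``tau = tau_p dx + tau_l dy`` the time between the two pixels of the
shift, ``dr`` the pixel size and ``(w0, wz)`` the PSF radii.  Mixtures of
species enter as linear combinations of this kernel (each with unit
amplitude) weighted by their population fractions; the overall amplitude A
encodes the total concentration through ``A = gamma / (V_psf * c)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .core import (
    Acf2D,
    AcquisitionGeometry,
    ImageStack,
    NuclearMask,
    PsfModel,
    concentration_to_density,
    density_to_concentration,
)

__all__ = [
    "RicsFit",
    "FastAxisFit",
    "SlowAxisProfile",
    "BackgroundSubtractionError",
    "model_acf",
    "model_acf_multi",
    "compute_acf2d",
    "positive_quadrant",
    "subtract_background",
    "autofluorescence_factor",
    "segment_nuclei",
    "fit_fast_axis",
    "fit_two_component",
    "fit_three_component",
    "amplitude_to_concentration",
    "concentration_to_amplitude",
    "slow_axis_profile",
]

#: magnitude bound on the background nuisance parameter B in all ACF fits
B_BOUND = 1e-3

#: default shift grid (fast axis in pixels, slow axis in lines)
DEFAULT_MAX_DX = 64
DEFAULT_MAX_DY = 32


class BackgroundSubtractionError(RuntimeError):
    """No resolvable low-intensity mode in the intensity histogram."""


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _single_species_values(
    dx: np.ndarray,
    dy: np.ndarray,
    diffusivity: float,
    geometry: AcquisitionGeometry,
    psf: PsfModel,
) -> np.ndarray:
    """Unit-amplitude ACF kernel of one Brownian species on a shift grid.

    Evaluated at nonnegative effective lags: the kernel is symmetric under
    joint sign flip, and |dx|, |dy| are used so that the model is defined on
    a full symmetric grid for plotting against data.
    """
    if diffusivity < 0:
        raise ValueError("diffusivity must be nonnegative")
    adx = np.abs(np.asarray(dx, dtype=float))
    ady = np.abs(np.asarray(dy, dtype=float))
    tau = geometry.dwell * adx + geometry.line_time * ady
    spread = 4.0 * diffusivity * tau
    lateral = 1.0 / (1.0 + spread / psf.w0 ** 2)
    axial = 1.0 / np.sqrt(1.0 + spread / psf.wz ** 2)
    r2 = (adx ** 2 + ady ** 2) * geometry.pixel_size ** 2
    return lateral * axial * np.exp(-r2 / (psf.w0 ** 2 + spread))


def _default_shifts(max_dx: int, max_dy: int) -> tuple[np.ndarray, np.ndarray]:
    return np.arange(max_dx + 1), np.arange(max_dy + 1)


def model_acf(
    amplitude: float,
    diffusivity: float,
    geometry: AcquisitionGeometry,
    psf: PsfModel,
    background: float = 0.0,
    dx_shifts: np.ndarray | None = None,
    dy_shifts: np.ndarray | None = None,
) -> Acf2D:
    """Theoretical single-species 2D RICS ACF on a shift grid.

    With ``diffusivity = 0`` this reduces to the pure spatial Gaussian
    ``A * exp(-(dx^2+dy^2) dr^2 / w0^2)``.
    """
    return model_acf_multi(
        amplitude, [1.0], [diffusivity], geometry, psf, background,
        dx_shifts, dy_shifts,
    )


def model_acf_multi(
    amplitude: float,
    fractions,
    diffusivities,
    geometry: AcquisitionGeometry,
    psf: PsfModel,
    background: float = 0.0,
    dx_shifts: np.ndarray | None = None,
    dy_shifts: np.ndarray | None = None,
) -> Acf2D:
    """Multi-species ACF: ``(A - B) * sum_i f_i g(D_i) + B``.

    ``fractions`` must sum to 1; each component kernel has unit amplitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    fractions = np.asarray(fractions, dtype=float)
    diffusivities = np.asarray(diffusivities, dtype=float)
    if fractions.shape != diffusivities.shape:
        raise ValueError("fractions and diffusivities must align")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if not np.all(np.isfinite(fractions)) or not np.all(np.isfinite(diffusivities)):
        raise ValueError("model parameters must be finite")
    if dx_shifts is None or dy_shifts is None:
        dx_shifts, dy_shifts = _default_shifts(DEFAULT_MAX_DX, DEFAULT_MAX_DY)
    dxg, dyg = np.meshgrid(dx_shifts, dy_shifts)
    values = np.zeros(dxg.shape, dtype=float)
    for f, d in zip(fractions, diffusivities):
        values += f * _single_species_values(dxg, dyg, d, geometry, psf)
    values = (amplitude - background) * values + background
    return Acf2D(values, np.asarray(dx_shifts), np.asarray(dy_shifts), geometry)


# ---------------------------------------------------------------------------
# amplitude <-> concentration
# ---------------------------------------------------------------------------

def amplitude_to_concentration(amplitude: float, psf: PsfModel) -> float:
    """Convert a fitted ACF amplitude to an absolute concentration in nM.

    ``A = gamma / (V_psf * c)`` with c in molecules/um^3.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    density = psf.gamma / (psf.volume * amplitude)
    return density_to_concentration(density)


def concentration_to_amplitude(conc_nm: float, psf: PsfModel) -> float:
    """Inverse of :func:`amplitude_to_concentration`."""
    if conc_nm <= 0:
        raise ValueError("concentration must be positive")
    return psf.gamma / (psf.volume * concentration_to_density(conc_nm))


def autofluorescence_factor(signal_mean: float, background_mean: float) -> float:
    """Concentration correction factor ``(I - I0)^2 / I^2`` for tissue
    autofluorescence measured in a label-free control."""
    if background_mean < 0:
        raise ValueError("background mean must be nonnegative")
    if signal_mean <= background_mean:
        raise ValueError("signal mean must exceed background mean")
    return float(((signal_mean - background_mean) / signal_mean) ** 2)


# ---------------------------------------------------------------------------
# background subtraction
# ---------------------------------------------------------------------------

def _gauss(x, a, mu, sd):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))


def subtract_background(
    stack: ImageStack, n_bins: int = 256
) -> tuple[ImageStack, float, float]:
    """Estimate and subtract the detector amplifier offset.

    A Gaussian is fit to the lowest-intensity mode of the first frame's
    intensity histogram (pixels outside nuclei carry only the offset); its
    mean is subtracted from every pixel of every frame.

    Returns ``(subtracted_stack, offset_mean, offset_sd)``.
    """
    if stack.offset_subtracted:
        raise ValueError("stack is already offset-subtracted")
    frame = stack.data[0].ravel()
    lo, hi = frame.min(), frame.max()
    if hi - lo <= 0:
        raise BackgroundSubtractionError("frame has no intensity spread")
    counts, edges = np.histogram(frame, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # light smoothing so single-bin spikes are not mistaken for modes
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    smooth = np.convolve(counts, kernel / kernel.sum(), mode="same")
    peaks, _ = signal.find_peaks(smooth, prominence=0.02 * smooth.max())
    if peaks.size == 0:
        raise BackgroundSubtractionError("no histogram mode found")
    peak = int(peaks[0])  # lowest-intensity mode
    # half-width at half-maximum around the peak -> fit window
    half = smooth[peak] / 2.0
    right = peak
    while right + 1 < smooth.size and smooth[right + 1] > half:
        right += 1
    width_bins = max(right - peak, 2)
    sel = slice(max(peak - 3 * width_bins, 0), min(peak + 3 * width_bins + 1, n_bins))
    bin_w = edges[1] - edges[0]
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers[sel],
            counts[sel].astype(float),
            p0=(counts[peak], centers[peak], width_bins * bin_w),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - degenerate histograms
        raise BackgroundSubtractionError("offset Gaussian fit failed") from exc
    mean, sd = float(popt[1]), float(abs(popt[2]))
    out = ImageStack(stack.data - mean, stack.geometry, stack.channel,
                     offset_subtracted=True)
    return out, mean, sd


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_nuclei(
    red_stack: ImageStack,
    smooth_sigma: float = 2.0,
    min_size: int = 64,
) -> NuclearMask:
    """Per-frame global-threshold segmentation of the histone-marker channel.

    Each frame is Gaussian-smoothed, thresholded (Otsu), opened, and
    hole-filled.  This is a simple heuristic adequate for bright nuclei on a
    dark background; it is not meant to rival dedicated segmentation tools.
    """
    from skimage import filters, morphology

    masks = []
    for frame in red_stack.data:
        sm = ndimage.gaussian_filter(frame, smooth_sigma)
        if sm.max() - sm.min() <= 0:
            raise ValueError("uniform frame: no nuclei to segment")
        thr = filters.threshold_otsu(sm)
        m = sm > thr
        m = morphology.binary_opening(m, morphology.disk(2))
        m = ndimage.binary_fill_holes(m)
        m = morphology.remove_small_objects(m, max_size=min_size - 1)
        if not m.any():
            raise ValueError("segmentation produced an empty mask")
        masks.append(m)
    return NuclearMask(np.asarray(masks))


# ---------------------------------------------------------------------------
# data ACF
# ---------------------------------------------------------------------------

def _frame_acf(
    frame: np.ndarray,
    mask: np.ndarray,
    max_dx: int,
    max_dy: int,
    min_overlap_frac: float,
) -> np.ndarray:
    """Masked linear 2D autocorrelation of one frame.

    Numerator: FFT correlation of the mean-subtracted, mask-zeroed frame.
    Denominator: (masked mean)^2 times the mask's own autocorrelation, i.e.
    the number of valid pixel pairs at each shift.  Shifts whose overlap is
    below ``min_overlap_frac`` of the mask size are NaN.
    """
    n_rows, n_cols = frame.shape
    m = mask.astype(float)
    n_mask = m.sum()
    mu = frame[mask].mean()
    if mu == 0:
        raise ValueError("masked mean intensity is zero; cannot normalize ACF")
    centered = (frame - mu) * m
    fr = max(n_rows + max_dy, 1)
    fc = max(n_cols + max_dx, 1)
    shape = (int(2 ** np.ceil(np.log2(fr))), int(2 ** np.ceil(np.log2(fc))))
    F = np.fft.rfft2(centered, s=shape)
    num = np.fft.irfft2(F * np.conj(F), s=shape)
    M = np.fft.rfft2(m, s=shape)
    cnt = np.fft.irfft2(M * np.conj(M), s=shape)

    dys = np.arange(-max_dy, max_dy + 1)
    dxs = np.arange(-max_dx, max_dx + 1)
    g = np.empty((dys.size, dxs.size), dtype=float)
    num_s = np.roll(num, (max_dy, max_dx), axis=(0, 1))
    cnt_s = np.roll(cnt, (max_dy, max_dx), axis=(0, 1))
    num_w = num_s[: 2 * max_dy + 1, : 2 * max_dx + 1]
    cnt_w = cnt_s[: 2 * max_dy + 1, : 2 * max_dx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = num_w / (cnt_w * mu ** 2)
    g[cnt_w < min_overlap_frac * n_mask] = np.nan
    return g


def compute_acf2d(
    stack: ImageStack,
    mask: NuclearMask | None = None,
    group_size: int = 12,
    max_dx: int = DEFAULT_MAX_DX,
    max_dy: int = DEFAULT_MAX_DY,
    min_overlap_frac: float = 0.25,
    other: ImageStack | None = None,
) -> list[Acf2D]:
    """Per-frame masked 2D ACFs, averaged uniformly within frame groups.

    ``G_j(dx, dy) = <I(x,y) I(x+dx, y+dy)> / <I>^2 - 1`` over masked pixels.
    When ``other`` is given the cross-correlation analog is computed, with
    the second intensity taken from ``other`` (both channels must share the
    geometry and be offset-subtracted).
    """
    if group_size < 1:
        raise ValueError("group_size must be at least 1")
    if not stack.offset_subtracted:
        raise ValueError("stack must be offset-subtracted before the ACF")
    if mask is None:
        mask = NuclearMask.full_frame(stack.geometry)
    mask.validate(stack)
    if other is not None:
        if other.data.shape != stack.data.shape:
            raise ValueError("channel shape mismatch")
        if not other.offset_subtracted:
            raise ValueError("second channel must be offset-subtracted")

    acfs = []
    n = stack.n_frames
    for start in range(0, n, group_size):
        frames = range(start, min(start + group_size, n))
        g_sum = None
        count = 0
        for j in frames:
            m = mask.for_frame(j)
            if other is None:
                g = _frame_acf(stack.data[j], m, max_dx, max_dy, min_overlap_frac)
            else:
                g = _frame_ccf(stack.data[j], other.data[j], m,
                               max_dx, max_dy, min_overlap_frac)
            g_sum = g if g_sum is None else g_sum + g
            count += 1
        dys = np.arange(-max_dy, max_dy + 1)
        dxs = np.arange(-max_dx, max_dx + 1)
        acfs.append(
            Acf2D(g_sum / count, dxs, dys, stack.geometry, n_frames_averaged=count)
        )
    return acfs


def _frame_ccf(
    green: np.ndarray,
    red: np.ndarray,
    mask: np.ndarray,
    max_dx: int,
    max_dy: int,
    min_overlap_frac: float,
) -> np.ndarray:
    """Masked linear 2D cross-correlation of two co-registered frames."""
    n_rows, n_cols = green.shape
    m = mask.astype(float)
    n_mask = m.sum()
    mu_g = green[mask].mean()
    mu_r = red[mask].mean()
    if mu_g == 0 or mu_r == 0:
        raise ValueError("masked mean intensity is zero; cannot normalize CCF")
    cg = (green - mu_g) * m
    cr = (red - mu_r) * m
    fr = max(n_rows + max_dy, 1)
    fc = max(n_cols + max_dx, 1)
    shape = (int(2 ** np.ceil(np.log2(fr))), int(2 ** np.ceil(np.log2(fc))))
    Fg = np.fft.rfft2(cg, s=shape)
    Fr = np.fft.rfft2(cr, s=shape)
    num = np.fft.irfft2(Fg * np.conj(Fr), s=shape)
    M = np.fft.rfft2(m, s=shape)
    cnt = np.fft.irfft2(M * np.conj(M), s=shape)
    num_s = np.roll(num, (max_dy, max_dx), axis=(0, 1))
    cnt_s = np.roll(cnt, (max_dy, max_dx), axis=(0, 1))
    num_w = num_s[: 2 * max_dy + 1, : 2 * max_dx + 1]
    cnt_w = cnt_s[: 2 * max_dy + 1, : 2 * max_dx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        g = num_w / (cnt_w * mu_g * mu_r)
    g[cnt_w < min_overlap_frac * n_mask] = np.nan
    return g


def positive_quadrant(acf: Acf2D) -> Acf2D:
    """Fold an ACF onto nonnegative shifts by averaging sign quadrants.

    The theoretical kernel is evaluated at nonnegative effective lags only,
    so fits operate on this folded surface.  NaN entries are ignored in the
    averaging.  An ACF already restricted to nonnegative shifts is returned
    unchanged.
    """
    if acf.dx_shifts.min() >= 0 and acf.dy_shifts.min() >= 0:
        return acf
    dxs = np.unique(np.abs(acf.dx_shifts))
    dys = np.unique(np.abs(acf.dy_shifts))
    out = np.full((dys.size, dxs.size), np.nan)
    for iy, dy in enumerate(dys):
        for_sgny = [dy] if dy == 0 else [dy, -dy]
        rows = [int(np.flatnonzero(acf.dy_shifts == s)[0]) for s in for_sgny]
        for ix, dx in enumerate(dxs):
            cols_sgn = [dx] if dx == 0 else [dx, -dx]
            cols = [int(np.flatnonzero(acf.dx_shifts == s)[0]) for s in cols_sgn]
            vals = np.array([acf.values[r, c] for r in rows for c in cols])
            if np.any(np.isfinite(vals)):
                out[iy, ix] = np.nanmean(vals)
    return Acf2D(out, dxs, dys, acf.geometry, acf.n_frames_averaged)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

@dataclass
class FastAxisFit:
    """Result of the fast-axis (PSF) amplitude fit."""

    amplitude: float
    w0: float
    background: float
    residual_norm: float
    converged: bool
    background_pinned: bool = False


@dataclass
class RicsFit:
    """Result of a two- or three-component RICS model fit."""

    amplitude: float
    background: float
    w0: float
    diffusivities: tuple
    phi: float | None = None
    phi0: float | None = None
    phi1: float | None = None
    residual_norm: float = np.nan
    converged: bool = False
    at_boundary: bool = False


def fit_fast_axis(
    acf: Acf2D,
    psf: PsfModel,
    w0_bounds_frac: float = 0.2,
    exclude_zero_lag: bool = True,
) -> FastAxisFit:
    """Fit ``(A - B) exp(-dx^2 dr^2 / w0^2) + B`` to the fast-axis cut.

    ``w0`` may vary within ``+-w0_bounds_frac`` of the configured PSF value
    and ``|B| < 1e-3``.  The zero-lag point is excluded by default: in data
    ACFs it carries the uncorrelated shot/read-noise variance, which does
    not belong to the diffusive correlation.
    """
    folded = positive_quadrant(acf)
    dx, g = folded.fast_axis_cut()
    keep = np.isfinite(g)
    if exclude_zero_lag:
        keep &= dx != 0
    dx, g = dx[keep], g[keep]
    if dx.size < 4:
        raise ValueError("too few fast-axis points to fit")
    dr = acf.geometry.pixel_size

    def residuals(p):
        a, w0, b = p
        return (a - b) * np.exp(-(dx ** 2) * dr ** 2 / w0 ** 2) + b - g

    a0 = max(float(np.interp(0, dx, g)), 1e-6)
    lo = [1e-12, psf.w0 * (1 - w0_bounds_frac), -B_BOUND]
    hi = [np.inf, psf.w0 * (1 + w0_bounds_frac), B_BOUND]
    res = optimize.least_squares(
        residuals, x0=[a0, psf.w0, 0.0], bounds=(lo, hi), xtol=1e-12, ftol=1e-12
    )
    a, w0, b = res.x
    pinned = bool(abs(abs(b) - B_BOUND) < 1e-12)
    if pinned:
        warnings.warn("background parameter pinned at its bound", stacklevel=2)
    return FastAxisFit(
        amplitude=float(a),
        w0=float(w0),
        background=float(b),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        background_pinned=pinned,
    )


def _prepare_surface(acf: Acf2D, exclude_zero_lag: bool):
    folded = positive_quadrant(acf)
    dxg, dyg = np.meshgrid(folded.dx_shifts, folded.dy_shifts)
    g = folded.values
    keep = np.isfinite(g)
    if exclude_zero_lag:
        keep &= ~((dxg == 0) & (dyg == 0))
    return dxg[keep], dyg[keep], g[keep], folded


def fit_two_component(
    acf: Acf2D,
    a_fixed: float,
    d_free: float = 3.0,
    psf: PsfModel | None = None,
    fit_background: bool = True,
    exclude_zero_lag: bool = True,
) -> RicsFit:
    """Fit the slowly-moving fraction ``phi`` of a two-component model.

    ``G = (A - B) [phi g(D=0) + (1 - phi) g(D=d_free)] + B`` with the
    amplitude held fixed at the fast-axis estimate.  A fit landing at
    ``phi = 0`` or ``phi = 1`` is flagged as a boundary solution.
    """
    psf = psf or PsfModel()
    dx, dy, g, folded = _prepare_surface(acf, exclude_zero_lag)
    g0 = _single_species_values(dx, dy, 0.0, acf.geometry, psf)
    g1 = _single_species_values(dx, dy, d_free, acf.geometry, psf)

    def model(phi, b):
        return (a_fixed - b) * (phi * g0 + (1 - phi) * g1) + b

    if fit_background:
        def residuals(p):
            return model(p[0], p[1]) - g
        res = optimize.least_squares(
            residuals, x0=[0.5, 0.0],
            bounds=([0.0, -B_BOUND], [1.0, B_BOUND]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, x_scale="jac",
        )
        phi, b = res.x
    else:
        def residuals(p):
            return model(p[0], 0.0) - g
        res = optimize.least_squares(
            residuals, x0=[0.5], bounds=([0.0], [1.0]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        phi, b = res.x[0], 0.0
    boundary = bool(phi < 1e-6 or phi > 1 - 1e-6)
    return RicsFit(
        amplitude=float(a_fixed),
        background=float(b),
        w0=psf.w0,
        diffusivities=(0.0, float(d_free)),
        phi=float(phi),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        at_boundary=boundary,
    )


def fit_three_component(
    acf: Acf2D,
    a_fixed: float,
    phi0_fixed: float,
    d_set: tuple = (0.0, 0.1, 3.0),
    psf: PsfModel | None = None,
    fit_background: bool = True,
    exclude_zero_lag: bool = True,
) -> RicsFit:
    """Fit the mobile-cluster fraction ``phi1`` of a three-component model.

    ``G = (A - B) [phi0 g(D0) + phi1 g(D1) + (1 - phi0 - phi1) g(D2)] + B``
    with ``phi0`` (the DNA-bound fraction, typically from the cross-channel
    correlated fraction) and the diffusivity set held fixed.
    """
    if not (0 <= phi0_fixed <= 1):
        raise ValueError("phi0 must lie in [0, 1]")
    psf = psf or PsfModel()
    d0, d1, d2 = d_set
    dx, dy, g, folded = _prepare_surface(acf, exclude_zero_lag)
    k0 = _single_species_values(dx, dy, d0, acf.geometry, psf)
    k1 = _single_species_values(dx, dy, d1, acf.geometry, psf)
    k2 = _single_species_values(dx, dy, d2, acf.geometry, psf)

    def model(phi1, b):
        return (a_fixed - b) * (
            phi0_fixed * k0 + phi1 * k1 + (1 - phi0_fixed - phi1) * k2
        ) + b

    phi1_max = 1.0 - phi0_fixed
    if fit_background:
        def residuals(p):
            return model(p[0], p[1]) - g
        res = optimize.least_squares(
            residuals, x0=[phi1_max / 2, 0.0],
            bounds=([0.0, -B_BOUND], [phi1_max, B_BOUND]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15, x_scale="jac",
        )
        phi1, b = res.x
    else:
        def residuals(p):
            return model(p[0], 0.0) - g
        res = optimize.least_squares(
            residuals, x0=[phi1_max / 2], bounds=([0.0], [phi1_max]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        phi1, b = res.x[0], 0.0
    boundary = bool(phi1 < 1e-6 or phi1 > phi1_max - 1e-6)
    return RicsFit(
        amplitude=float(a_fixed),
        background=float(b),
        w0=psf.w0,
        diffusivities=tuple(float(d) for d in d_set),
        phi0=float(phi0_fixed),
        phi1=float(phi1),
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        at_boundary=boundary,
    )


# ---------------------------------------------------------------------------
# slow-axis diagnostics
# ---------------------------------------------------------------------------

@dataclass
class SlowAxisProfile:
    """Slow-axis ACF cut compared against the PSF Gaussian.

    ``exceeds`` flags, per shift in the tail region, whether the profile
    rises more than three noise standard deviations above the PSF;
    ``exceeds_psf`` is True when at least two consecutive tail shifts are
    flagged — the signature of a slowly diffusing (not immobile) component.
    """

    dy_shifts: np.ndarray
    profile: np.ndarray
    psf_reference: np.ndarray
    exceeds: np.ndarray
    exceeds_psf: bool
    noise_sd: float


def slow_axis_profile(
    acf: Acf2D,
    psf: PsfModel,
    noise_sd: float | None = None,
    amplitude: float | None = None,
    tail_fraction: float = 0.1,
) -> SlowAxisProfile:
    """Compare the slow-axis ACF cut with the PSF Gaussian of width w0.

    The tail region is where the PSF reference has decayed below
    ``tail_fraction`` of the amplitude.  ``noise_sd`` defaults to a
    difference-based estimate from the outer half of the profile.
    """
    folded = positive_quadrant(acf)
    dy, prof = folded.slow_axis_cut()
    finite = np.isfinite(prof)
    dy, prof = dy[finite], prof[finite]
    if amplitude is None:
        amplitude = float(prof[dy == 0][0]) if np.any(dy == 0) else float(prof.max())
    dr = acf.geometry.pixel_size
    ref = amplitude * np.exp(-(dy ** 2) * dr ** 2 / psf.w0 ** 2)
    if noise_sd is None:
        outer = prof[dy >= dy.max() // 2]
        noise_sd = float(np.std(np.diff(outer)) / np.sqrt(2)) if outer.size > 2 else 0.0
    tail = ref < tail_fraction * amplitude
    exceeds = tail & (prof - ref > 3.0 * noise_sd)
    flagged = exceeds.astype(int)
    consecutive = np.any(flagged[1:] + flagged[:-1] == 2) if flagged.size > 1 else False
    return SlowAxisProfile(
        dy_shifts=dy,
        profile=prof,
        psf_reference=ref,
        exceeds=exceeds,
        exceeds_psf=bool(consecutive),
        noise_sd=float(noise_sd),
    )
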