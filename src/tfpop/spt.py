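"""Single-particle-tracking step-size-distribution (SSD) analysis.

Step sizes of 2D Brownian particles localized with precision ``sigma^2``
follow a Rayleigh mixture

    P(r) = sum_i f_i * r / (2 (D_i dt + sigma^2))
                 * exp(-r^2 / (4 (D_i dt + sigma^2)))

whose component scales encode the diffusivities.  Because imaging collects
a thin axial slab, faster particles preferentially defocalize between
frames; the correction factor ``Zcorr`` (the absorbing-slab survival
probability over one frame interval) reweights the faster component so the
fitted fractions refer to the true populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .core import ImageStack

__all__ = [
    "TrajectoryTable",
    "StepSet",
    "RayleighMixtureFit",
    "LocalizationCalibration",
    "MsdResult",
    "extract_steps",
    "compute_snr",
    "calibrate_localization",
    "effective_axial_range",
    "axial_survival_probability",
    "zcorr",
    "rayleigh_mixture_pdf",
    "fit_ssd",
    "msd_analysis",
]

#: localization variance (um^2) measured from immobilized beads
DEFAULT_SIGMA2 = 4.5e-4

#: axial detection slab thickness (um) of a high-NA oil objective
DEFAULT_DETECTION_RANGE = 0.7


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryTable:
    """Linked particle trajectories with a common frame interval.

    ``data`` holds columns ``particle, frame, x_um, y_um``; frames are
    strictly increasing within each particle.  Trajectories with fewer than
    ``min_steps`` steps are discarded at construction.
    """

    data: pd.DataFrame
    frame_interval: float
    min_steps: int = 3

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        required = {"particle", "frame", "x_um", "y_um"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"trajectory table must have columns {sorted(required)}")
        df = self.data.sort_values(["particle", "frame"]).reset_index(drop=True)
        diffs = df.groupby("particle")["frame"].diff().dropna()
        if (diffs <= 0).any():
            raise ValueError("frames must be strictly increasing per particle")
        lengths = df.groupby("particle")["frame"].size()
        keep = lengths[lengths >= self.min_steps + 1].index
        self.data = df[df["particle"].isin(keep)].reset_index(drop=True)

    @property
    def n_trajectories(self) -> int:
        return int(self.data["particle"].nunique())


@dataclass
class StepSet:
    """Step magnitudes between consecutive frames at a single lag."""

    steps: np.ndarray
    lag: float
    n_trajectories: int = 0

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=float)
        if self.lag <= 0:
            raise ValueError("lag must be positive")
        if np.any(self.steps < 0):
            raise ValueError("step sizes must be nonnegative")


@dataclass
class LocalizationCalibration:
    """Fit of localization variance vs signal-to-noise ratio.

    ``sigma^2(SNR) = a_bg / SNR + b_shot / SNR^2`` — the first term from
    background noise, the second from shot noise.
    """

    a_bg: float
    b_shot: float
    points: list = field(default_factory=list)

    def predict(self, snr) -> np.ndarray:
        snr = np.asarray(snr, dtype=float)
        return self.a_bg / snr + self.b_shot / snr ** 2


@dataclass
class RayleighMixtureFit:
    """A k-component Rayleigh mixture fit to step sizes.

    ``diffusivities`` are sorted descending; ``weights`` are the population
    fractions (defocalization-corrected when ``corrected`` is True, in which
    case ``observed_weights`` holds the raw mixture weights of the step
    distribution).
    """

    k: int
    diffusivities: np.ndarray
    weights: np.ndarray
    sigma2: float
    lag: float
    log_likelihood: float
    n_steps: int
    converged: bool
    corrected: bool = False
    zcorr: float = 1.0
    observed_weights: np.ndarray | None = None
    degenerate: bool = False
    pruned: bool = False


# ---------------------------------------------------------------------------
# steps and diagnostics
# ---------------------------------------------------------------------------

def extract_steps(traj: TrajectoryTable) -> StepSet:
    """Euclidean displacements between consecutive-frame localizations.

    Frame gaps (non-consecutive frame indices) contribute no step.
    """
    df = traj.data
    if df.empty:
        raise ValueError("trajectory table is empty")
    steps = []
    for _, g in df.groupby("particle", sort=False):
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        consec = np.diff(frames) == 1
        d = np.sqrt(np.sum(np.diff(xy, axis=0) ** 2, axis=1))
        steps.append(d[consec])
    return StepSet(
        np.concatenate(steps), traj.frame_interval, traj.n_trajectories
    )


def compute_snr(
    stack: ImageStack,
    detections: np.ndarray,
    mask: np.ndarray | None = None,
    exclusion_radius: int = 3,
) -> float:
    """Signal-to-noise ratio of detected puncta.

    Mean intensity at the detection coordinates divided by the standard
    deviation of the remaining (background) pixels; ``detections`` is an
    ``(n, 3)`` array of ``(frame, row, col)`` indices.
    """
    detections = np.asarray(detections, dtype=int)
    if detections.ndim != 2 or detections.shape[1] != 3:
        raise ValueError("detections must be (n, 3): frame, row, col")
    nf, nr, nc = stack.data.shape
    if (
        np.any(detections < 0)
        or np.any(detections[:, 0] >= nf)
        or np.any(detections[:, 1] >= nr)
        or np.any(detections[:, 2] >= nc)
    ):
        raise ValueError("detections fall outside the stack")
    signal_mean = stack.data[
        detections[:, 0], detections[:, 1], detections[:, 2]
    ].mean()
    bg_mask = np.ones((nf, nr, nc), dtype=bool)
    if mask is not None:
        bg_mask &= np.broadcast_to(mask, bg_mask.shape)
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    for f, r, c in detections:
        near = (np.abs(rr - r) <= exclusion_radius) & (np.abs(cc - c) <= exclusion_radius)
        bg_mask[f][near] = False
    bg = stack.data[bg_mask]
    if bg.size == 0:
        raise ValueError("no background pixels available")
    sd = bg.std()
    if sd == 0:
        raise ValueError("background SD is zero; SNR undefined")
    return float(signal_mean / sd)


def calibrate_localization(points) -> LocalizationCalibration:
    """Nonnegative least-squares fit of ``sigma^2 = a/SNR + b/SNR^2``.

    ``points`` is an iterable of ``(snr, sigma2)`` pairs spanning a range of
    SNR (at least 3 distinct values).
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (SNR, sigma2) points")
    snr, s2 = pts[:, 0], pts[:, 1]
    if np.unique(snr).size < 3:
        raise ValueError("SNR values must span a range (rank-deficient design)")
    design = np.column_stack([1.0 / snr, 1.0 / snr ** 2])
    coef, _ = optimize.nnls(design, s2)
    return LocalizationCalibration(float(coef[0]), float(coef[1]), pts.tolist())


def effective_axial_range(
    detection_range: float = DEFAULT_DETECTION_RANGE,
    d_free: float = 0.0,
    coefficient: float = 0.21,
    exponent: float = 0.5,
    reference_time: float = 1.0,
) -> float:
    """Effective absorbing-slab thickness for the defocalization correction.

    The hard absorbing boundary of the survival model overestimates losses,
    so the slab is widened beyond the optical detection range by an
    empirical diffusivity-dependent term:
    ``dz = detection_range + 0.21 * sqrt(D * 1 s)`` by default.
    """
    if detection_range < 0 or d_free < 0:
        raise ValueError("inputs must be nonnegative")
    return detection_range + coefficient * (d_free * reference_time) ** exponent


# ---------------------------------------------------------------------------
# defocalization correction
# ---------------------------------------------------------------------------

def axial_survival_probability(
    z0,
    d: float,
    dt: float,
    dz: float,
    tol: float = 1e-9,
    max_terms: int = 200,
) -> np.ndarray:
    """Probability that 1D Brownian motion starting at ``z0`` stays inside
    the absorbing slab ``[-dz/2, dz/2]`` for time ``dt`` (image series)."""
    z0 = np.asarray(z0, dtype=float)
    if d <= 0 or dt <= 0:
        return np.ones_like(z0)
    if dz <= 0:
        raise ValueError("dz must be positive")
    ell = np.sqrt(4.0 * d * dt)
    total = np.zeros_like(z0)
    for n in range(max_terms):
        arg_m = ((2 * n + 1) * dz / 2.0 - z0) / ell
        arg_p = ((2 * n + 1) * dz / 2.0 + z0) / ell
        term = special.erfc(arg_m) + special.erfc(arg_p)
        total += ((-1) ** n) * term
        if np.max(np.abs(term)) < tol:
            break
    else:
        raise RuntimeError("absorbing-slab series did not converge")
    return np.clip(1.0 - total, 0.0, 1.0)


def zcorr(
    d_free: float,
    dt: float,
    dz: float,
    tol: float = 1e-9,
    n_quad: int = 256,
) -> float:
    """Fraction of particles of diffusivity ``d_free`` remaining inside the
    detection slab after one frame interval, averaged over a uniform start
    position (composite quadrature of the survival probability)."""
    if dt < 0 or d_free < 0:
        raise ValueError("d_free and dt must be nonnegative")
    if d_free == 0 or dt == 0:
        return 1.0
    if dz <= 0:
        raise ValueError("dz must be positive")
    z = np.linspace(-dz / 2.0, dz / 2.0, n_quad + 1)
    s = axial_survival_probability(z, d_free, dt, dz, tol=tol)
    from scipy.integrate import simpson

    val = simpson(s, x=z) / dz
    return float(np.clip(val, np.finfo(float).tiny, 1.0))


# ---------------------------------------------------------------------------
# Rayleigh mixture fitting
# ---------------------------------------------------------------------------

def _scales_from_d(diffusivities, sigma2, dt):
    return 2.0 * (np.asarray(diffusivities, dtype=float) * dt + sigma2)


def rayleigh_mixture_pdf(r, weights, diffusivities, sigma2, dt) -> np.ndarray:
    """Probability density of step sizes for a Rayleigh mixture."""
    r = np.asarray(r, dtype=float)
    weights = np.asarray(weights, dtype=float)
    s2 = _scales_from_d(diffusivities, sigma2, dt)  # s2 = 2(D dt + sigma^2)
    out = np.zeros_like(r)
    for w, s in zip(weights, s2):
        out += w * r / s * np.exp(-(r ** 2) / (2.0 * s))
    return out


def _em_rayleigh(u, weights, s2, s2_floor, max_iter=500, rtol=1e-12):
    """EM for a Rayleigh mixture on squared steps ``u = r^2``.

    Rayleigh in r with scale s2 corresponds to Exponential(mean 2*s2) in u,
    so the M-step has a closed form.  Returns (weights, s2, loglik).
    """
    n = u.size
    k = weights.size
    prev = -np.inf
    for _ in range(max_iter):
        # densities in u: (1/(2 s2)) exp(-u / (2 s2))
        log_comp = (
            np.log(weights)[None, :]
            - np.log(2.0 * s2)[None, :]
            - u[:, None] / (2.0 * s2)[None, :]
        )
        m = log_comp.max(axis=1, keepdims=True)
        p = np.exp(log_comp - m)
        denom = p.sum(axis=1, keepdims=True)
        loglik = float(np.sum(m.ravel() + np.log(denom.ravel())))
        gamma = p / denom
        nk = gamma.sum(axis=0)
        weights = nk / n
        with np.errstate(invalid="ignore", divide="ignore"):
            s2_new = (gamma * u[:, None]).sum(axis=0) / (2.0 * np.maximum(nk, 1e-300))
        s2 = np.maximum(np.where(nk > 0, s2_new, s2), s2_floor)
        weights = np.maximum(weights, 1e-12)
        weights /= weights.sum()
        if loglik - prev < rtol * max(abs(loglik), 1.0) and loglik >= prev:
            break
        prev = loglik
    return weights, s2, loglik


def _loglik(u, weights, s2):
    log_comp = (
        np.log(weights)[None, :]
        - np.log(2.0 * s2)[None, :]
        - u[:, None] / (2.0 * s2)[None, :]
    )
    m = log_comp.max(axis=1, keepdims=True)
    return float(np.sum(m.ravel() + np.log(np.exp(log_comp - m).sum(axis=1))))


def fit_ssd(
    steps: StepSet,
    k: int = 2,
    sigma2: float = DEFAULT_SIGMA2,
    correction: bool = False,
    dz: float | None = None,
    max_iter: int = 500,
    parsimony: bool = True,
) -> RayleighMixtureFit:
    """Maximum-likelihood k-component Rayleigh mixture fit to step sizes.

    Fitting is by EM on the squared steps (exact M-steps).  Component
    diffusivities follow from the fitted scales via
    ``s2_i = 2 (D_i dt + sigma^2)`` with ``D_i >= 0`` enforced.  With
    ``correction`` on (two components only) the faster component's weight is
    divided by ``Zcorr`` computed at the fitted fast diffusivity, converting
    the observed step-mixture weights into true population fractions — the
    maximum-likelihood estimate of the defocalization-corrected model, since
    the reweighting is a bijection at fixed Zcorr.

    Components are reported in descending diffusivity; two components whose
    scales agree within 1% relative are flagged degenerate and merged, with
    the vacated component assigned zero weight.

    With ``parsimony`` (the default) an extra component is retained only if
    it carries statistical support: when the k-component likelihood improves
    on the (k-1)-component one by less than the BIC penalty for its two
    extra parameters (``2 ln n``), the simpler solution is reported with the
    surplus component at exactly zero weight.  Over-specifying the model on
    data with fewer populations then optimizes the surplus weight to zero
    rather than splitting a real component along a flat likelihood ridge;
    genuinely separated components exceed the penalty by orders of
    magnitude and are unaffected.
    """
    if k < 1 or k > 3:
        raise ValueError("k must be 1, 2, or 3")
    if correction and k != 2:
        raise ValueError("the defocalization correction applies to k = 2")
    if correction and (dz is None or dz <= 0):
        raise ValueError("correction requires a positive slab thickness dz")
    r = steps.steps
    if r.size < 10:
        raise ValueError("too few steps to fit")
    if np.sum(r > 0) < 10:
        raise ValueError("steps are degenerate (all zero)")
    dt = steps.lag
    u = r.astype(float) ** 2
    s2_floor = 2.0 * sigma2 if sigma2 > 0 else 1e-12
    u_sorted = np.sort(u)

    def quantile_init(kk):
        chunks = np.array_split(u_sorted, kk)
        s2 = np.array([max(c.mean() / 2.0, s2_floor * (1 + 1e-6)) for c in chunks])
        w = np.full(kk, 1.0 / kk)
        return w, s2

    best = None
    inits = [quantile_init(k)]
    prev_solution = None
    if k > 1:
        # include the (k-1)-solution padded with a broad low-weight component,
        # which guarantees the fitted likelihood is non-decreasing in k
        w_prev, s2_prev = quantile_init(k - 1)
        w_prev, s2_prev, ll_prev = _em_rayleigh(u, w_prev, s2_prev, s2_floor, max_iter)
        prev_solution = (w_prev, s2_prev, ll_prev)
        w_pad = np.concatenate([w_prev * (1 - 1e-3), [1e-3]])
        s2_pad = np.concatenate([s2_prev, [max(u_sorted[-1] / 2.0, s2_prev.max() * 5)]])
        inits.append((w_pad, s2_pad))
    for w0, s20 in inits:
        w, s2, ll = _em_rayleigh(u, w0.copy(), s20.copy(), s2_floor, max_iter)
        if best is None or ll > best[2]:
            best = (w, s2, ll)
    weights, s2, loglik = best

    pruned = False
    if parsimony and prev_solution is not None:
        w_prev, s2_prev, ll_prev = prev_solution
        if 2.0 * (loglik - ll_prev) < 2.0 * np.log(u.size):
            # surplus component unsupported: keep it at exactly zero weight
            weights = np.concatenate([w_prev, [0.0]])
            s2 = np.concatenate([s2_prev, [s2_prev.max()]])
            loglik = ll_prev
            pruned = True

    # canonicalize: merge components whose scales collapsed onto each other
    degenerate = False
    order = np.argsort(-s2)
    s2, weights = s2[order], weights[order]
    i = 0
    while i < s2.size - 1 and not pruned:
        if weights[i + 1] > 0 and abs(s2[i] - s2[i + 1]) <= 0.01 * max(s2[i], s2[i + 1]):
            degenerate = True
            wsum = weights[i] + weights[i + 1]
            s2[i] = (weights[i] * s2[i] + weights[i + 1] * s2[i + 1]) / max(wsum, 1e-300)
            weights[i] = wsum
            # vacated slot becomes a zero-weight component
            s2 = np.concatenate([np.delete(s2, i + 1), [s2[i]]])
            weights = np.concatenate([np.delete(weights, i + 1), [0.0]])
        else:
            i += 1
    order = np.argsort(-s2 + 1e-30 * -weights)
    s2, weights = s2[order], weights[order]

    diffusivities = np.maximum((s2 / 2.0 - sigma2) / dt, 0.0)
    observed = weights.copy()
    zc = 1.0
    if correction:
        zc = zcorr(float(diffusivities[0]), dt, float(dz))
        w_fast = observed[0]
        f_fast = w_fast / (w_fast + zc * (1.0 - w_fast))
        weights = np.array([f_fast, 1.0 - f_fast])
    return RayleighMixtureFit(
        k=k,
        diffusivities=diffusivities,
        weights=weights,
        sigma2=float(sigma2),
        lag=float(dt),
        log_likelihood=loglik,
        n_steps=int(r.size),
        converged=True,
        corrected=bool(correction),
        zcorr=float(zc),
        observed_weights=observed,
        degenerate=degenerate,
        pruned=pruned,
    )


# ---------------------------------------------------------------------------
# MSD diagnostics
# ---------------------------------------------------------------------------

@dataclass
class MsdResult:
    """Time-and-ensemble-averaged MSD with regime diagnostics.

    ``loglog_slope`` below 1 indicates subdiffusion; a negative slope of
    ``MSD/dt`` versus ``dt`` is the complementary signature of confinement.
    """

    lags: np.ndarray
    msd: np.ndarray
    loglog_slope: float
    msd_over_t_slope_sign: int


def msd_analysis(traj: TrajectoryTable, max_lag: int = 10) -> MsdResult:
    """Ensemble- and time-averaged mean squared displacement per lag."""
    if traj.n_trajectories < 10:
        raise ValueError("need at least 10 trajectories for MSD analysis")
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag, dtype=int)
    for _, g in traj.data.groupby("particle", sort=False):
        frames = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        for i in range(len(frames)):
            dlag = frames[i + 1:] - frames[i]
            ok = dlag <= max_lag
            if not ok.any():
                continue
            disp2 = np.sum((xy[i + 1:][ok] - xy[i]) ** 2, axis=1)
            np.add.at(sums, dlag[ok] - 1, disp2)
            np.add.at(counts, dlag[ok] - 1, 1)
    valid = counts > 0
    if valid.sum() < 3:
        raise ValueError("insufficient lags with data")
    lags = (np.arange(1, max_lag + 1) * traj.frame_interval)[valid]
    msd = (sums[valid] / counts[valid])
    n_fit = min(5, msd.size)
    loglog = np.polyfit(np.log(lags[:n_fit]), np.log(msd[:n_fit]), 1)[0]
    ratio_slope = np.polyfit(lags, msd / lags, 1)[0]
    return MsdResult(
        lags=lags,
        msd=msd,
        loglog_slope=float(loglog),
        msd_over_t_slope_sign=int(np.sign(ratio_slope)),
    )
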