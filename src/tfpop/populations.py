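"""Population maps: LLPS threshold allocation, binning and dose/response fits.

Under a liquid-liquid phase-separation picture, the dispersed (free) phase
holds a fixed concentration ``C0`` while condensed phases grow in volume:
measured nucleus-averaged pool concentrations then obey

    c_free  = min(c_total, C0)
    c_cond  = c_total - C0        (for c_total > C0, split between pools)

so each condensed pool is linear in ``c_total - C0`` and extrapolates to
zero at the threshold.  This module provides that allocation model, the
equilibrium time-point filters, dorsoventral (DV) binning, Hill and linear
threshold fits, and the bookkeeping from fitted correlation amplitudes to
per-pool concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import PsfModel
from .rics import amplitude_to_concentration

__all__ = [
    "PopulationRecord",
    "LlpsModel",
    "GaussianGradient",
    "DoseResponseFit",
    "llps_allocate",
    "filter_equilibrium_timepoints",
    "hill_fit",
    "dv_bin",
    "linear_threshold_fit",
    "gradient_gaussian_fit",
    "population_decompose",
    "records_to_frame",
]

#: number of early (pre-equilibrium) time points dropped per nuclear cycle
EQUILIBRATION_SKIP = {10: None, 11: 2, 12: 3, 13: 4, 14: 5}


@dataclass
class PopulationRecord:
    """Per-timepoint or per-DV-position concentrations of the Dl pools (nM).

    ``conc_total = conc_free + conc_slow`` and
    ``conc_slow = conc_correlated + conc_uncorrelated`` (after clipping).
    """

    conc_total: float
    conc_free: float
    conc_slow: float
    conc_correlated: float = 0.0
    conc_uncorrelated: float = 0.0
    nc: int | None = None
    time: float | None = None
    dv: float | None = None
    embryo: str | int | None = None

    def __post_init__(self) -> None:
        pools = (self.conc_total, self.conc_free, self.conc_slow,
                 self.conc_correlated, self.conc_uncorrelated)
        if any(c < 0 for c in pools):
            raise ValueError("concentrations must be nonnegative")
        scale = max(self.conc_total, 1e-12)
        if abs(self.conc_total - (self.conc_free + self.conc_slow)) > 1e-6 * scale:
            raise ValueError("conc_total must equal conc_free + conc_slow")
        split = self.conc_correlated + self.conc_uncorrelated
        if split > 0 and abs(self.conc_slow - split) > 1e-6 * scale:
            raise ValueError(
                "conc_slow must equal conc_correlated + conc_uncorrelated"
            )


def records_to_frame(records) -> pd.DataFrame:
    """List of :class:`PopulationRecord` -> tidy DataFrame."""
    return pd.DataFrame([vars(r) for r in records])


@dataclass(frozen=True)
class LlpsModel:
    """Fixed-phase-concentration threshold model.

    ``dispersed`` is the saturation concentration of the dilute phase (the
    threshold, nM); ``condensed1``/``condensed2`` are the fixed dense-phase
    concentrations of the two condensed pools (DNA-bound and mobile
    clusters) — they set phase volumes but drop out of the measured,
    volume-averaged pool concentrations; ``split_ratio`` is the fraction of
    above-threshold material allocated to pool 1.
    """

    dispersed: float = 30.0
    condensed1: float = 1000.0
    condensed2: float = 1000.0
    split_ratio: float = 1.0 / 3.0
    v_tot: float = 1.0

    def __post_init__(self) -> None:
        if not (self.condensed1 > self.dispersed > 0):
            raise ValueError("require condensed1 > dispersed > 0")
        if not (self.condensed2 > self.dispersed):
            raise ValueError("require condensed2 > dispersed")
        if not (0 <= self.split_ratio <= 1):
            raise ValueError("split_ratio must lie in [0, 1]")
        if self.v_tot <= 0:
            raise ValueError("v_tot must be positive")


def llps_allocate(c_total, model: LlpsModel):
    """Allocate a total concentration to (free, condensed-1, condensed-2).

    Below the threshold everything is free; above it the free pool is
    pinned at the threshold and the excess is split between the condensed
    pools by ``split_ratio``.  Mass is conserved exactly and the output is
    continuous, piecewise linear in ``c_total`` with its only kink at the
    threshold.  Accepts scalars or arrays.
    """
    c = np.asarray(c_total, dtype=float)
    if np.any(c < 0):
        raise ValueError("total concentration must be nonnegative")
    excess = np.maximum(c - model.dispersed, 0.0)
    free = c - excess
    cond1 = model.split_ratio * excess
    cond2 = (1.0 - model.split_ratio) * excess
    if np.isscalar(c_total):
        return float(free), float(cond1), float(cond2)
    return free, cond1, cond2


# ---------------------------------------------------------------------------
# filtering and binning
# ---------------------------------------------------------------------------

def filter_equilibrium_timepoints(records: pd.DataFrame) -> pd.DataFrame:
    """Drop pre-equilibrium time points from a per-nuclear-cycle series.

    Nuclear cycle 10 is removed entirely (too short to equilibrate); the
    first 2, 3, 4 and 5 time points of ncs 11-14 are removed.  Records are
    grouped per embryo (when an ``embryo`` column exists) and ordered by
    time within each cycle.
    """
    if records.empty:
        return records.copy()
    if not {"nc", "time"}.issubset(records.columns):
        raise ValueError("records must have 'nc' and 'time' columns")
    unknown = set(records["nc"].unique()) - set(EQUILIBRATION_SKIP)
    if unknown:
        raise ValueError(f"unknown nuclear cycle labels: {sorted(unknown)}")
    group_cols = ["nc"] + (["embryo"] if "embryo" in records.columns else [])
    out = []
    for keys, g in records.groupby(group_cols, sort=False):
        nc = keys[0] if isinstance(keys, tuple) else keys
        skip = EQUILIBRATION_SKIP[int(nc)]
        if skip is None:
            continue
        out.append(g.sort_values("time").iloc[skip:])
    if not out:
        return records.iloc[0:0].copy()
    return pd.concat(out).reset_index(drop=True)


def dv_bin(
    records: pd.DataFrame,
    value_columns=None,
    width: float = 0.05,
    min_embryos: int = 2,
) -> pd.DataFrame:
    """Bin per-embryo records along the DV coordinate.

    Bins are half-open, lower-inclusive ``[i*width, (i+1)*width)`` starting
    at DV = 0 (ventral midline); bins with fewer than ``min_embryos``
    distinct embryos are dropped.  Returns per-bin mean and SEM of each
    value column, computed over embryo means within the bin.
    """
    if records.empty:
        raise ValueError("no records to bin")
    if "dv" not in records.columns:
        raise ValueError("records must have a 'dv' column")
    if value_columns is None:
        value_columns = [
            c for c in records.columns
            if c.startswith("conc_") and records[c].notna().any()
        ]
    df = records.copy()
    df["_bin"] = np.floor(df["dv"] / width).astype(int)
    rows = []
    for b, g in df.groupby("_bin"):
        if "embryo" in g.columns:
            per_embryo = g.groupby("embryo")[value_columns].mean()
        else:
            per_embryo = g[value_columns]
        n = len(per_embryo)
        if n < min_embryos:
            continue
        row = {"dv_center": (b + 0.5) * width, "n_embryos": n}
        for c in value_columns:
            row[f"{c}_mean"] = per_embryo[c].mean()
            row[f"{c}_sem"] = per_embryo[c].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows).sort_values("dv_center").reset_index(drop=True)


# ---------------------------------------------------------------------------
# dose/response fits
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """Hill or linear dose/response fit result."""

    kind: str
    ymax: float | None = None
    k_half: float | None = None
    order: int | None = None
    slope: float | None = None
    intercept: float | None = None
    x_intercept: float | None = None
    x_intercept_se: float | None = None
    residual_norm: float = np.nan
    flagged: bool = False


def hill_fit(x, y, order: int = 4) -> DoseResponseFit:
    """Least-squares fit of ``y = ymax * x^n / (K^n + x^n)`` with fixed n.

    A fit with the half-saturation constant K weakly identified (relative
    standard error above 1, e.g. when all x lie far above K) is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points for a Hill fit")

    def model(xx, ymax, k):
        return ymax * xx ** order / (k ** order + xx ** order)

    ymax0 = max(y.max(), 1e-9)
    k0 = max(np.median(x), 1e-9)
    flagged = False
    if np.allclose(y, 0):
        return DoseResponseFit(kind=f"hill-{order}", ymax=0.0, k_half=k0,
                               order=order, residual_norm=0.0, flagged=True)
    try:
        popt, pcov = optimize.curve_fit(
            model, x, y, p0=(ymax0, k0),
            bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        return DoseResponseFit(kind=f"hill-{order}", flagged=True, order=order)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(2, np.inf)
    if not np.isfinite(perr[1]) or perr[1] > abs(popt[1]):
        flagged = True
    if popt[1] < x.min() or popt[1] > x.max():
        # half-saturation outside the sampled range: K is unconstrained
        flagged = True
    resid = model(x, *popt) - y
    return DoseResponseFit(
        kind=f"hill-{order}",
        ymax=float(popt[0]),
        k_half=float(popt[1]),
        order=order,
        residual_norm=float(np.linalg.norm(resid)),
        flagged=flagged,
    )


def linear_threshold_fit(x, y) -> DoseResponseFit:
    """Ordinary least squares of a pool concentration against total
    concentration; the x-intercept ``-intercept/slope`` estimates the
    formation threshold.  A non-positive slope leaves the threshold
    undefined and flags the fit."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points for a threshold fit")
    res = stats.linregress(x, y)
    slope, intercept = res.slope, res.intercept
    flagged = slope <= 0
    x_int = np.nan
    x_int_se = np.nan
    if not flagged:
        x_int = -intercept / slope
        # first-order error propagation, covariance term neglected
        x_int_se = float(
            np.sqrt(
                (res.intercept_stderr / slope) ** 2
                + (intercept * res.stderr / slope ** 2) ** 2
            )
        )
    resid = slope * x + intercept - y
    return DoseResponseFit(
        kind="linear",
        slope=float(slope),
        intercept=float(intercept),
        x_intercept=float(x_int),
        x_intercept_se=x_int_se,
        residual_norm=float(np.linalg.norm(resid)),
        flagged=bool(flagged),
    )


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianGradient:
    """DV concentration (or intensity) gradient centered at the ventral
    midline: ``amplitude * exp(-dv^2 / (2 width^2)) + baseline``."""

    amplitude: float
    width: float
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.width <= 0:
            raise ValueError("amplitude and width must be positive")

    def __call__(self, dv) -> np.ndarray:
        dv = np.asarray(dv, dtype=float)
        return self.amplitude * np.exp(-(dv ** 2) / (2.0 * self.width ** 2)) + self.baseline


def gradient_gaussian_fit(
    intensities: pd.DataFrame,
    window: tuple = (-26.0, -20.0),
) -> tuple[GaussianGradient, bool]:
    """Fit a ventral-centered Gaussian to time-averaged DV intensities.

    ``intensities`` has columns ``embryo, time_min, dv, intensity`` with
    time in minutes relative to gastrulation.  Intensities are averaged per
    embryo within the window, then across embryos per DV position, and a
    Gaussian centered at DV = 0 is fit.  Returns ``(gradient, flagged)``
    where ``flagged`` marks an unbounded width (flat profile).
    """
    required = {"embryo", "time_min", "dv", "intensity"}
    if not required.issubset(intensities.columns):
        raise ValueError(f"need columns {sorted(required)}")
    sel = intensities[
        (intensities["time_min"] >= window[0]) & (intensities["time_min"] <= window[1])
    ]
    if sel.empty:
        raise ValueError("no data inside the averaging window")
    per_embryo = sel.groupby(["embryo", "dv"], as_index=False)["intensity"].mean()
    avg = per_embryo.groupby("dv", as_index=False)["intensity"].mean()
    dv = avg["dv"].to_numpy()
    yv = avg["intensity"].to_numpy()

    def model(xx, a, w, b):
        return a * np.exp(-(xx ** 2) / (2.0 * w ** 2)) + b

    span = max(dv.max() - dv.min(), 1e-6)
    try:
        popt, pcov = optimize.curve_fit(
            model, dv, yv,
            p0=(max(yv.max() - yv.min(), 1e-9), span / 3.0, yv.min()),
            bounds=([1e-12, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        warnings.warn("gradient Gaussian fit did not converge", stacklevel=2)
        return GaussianGradient(max(yv.max(), 1e-9), span * 100), True
    a, w, b = popt
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else np.full(3, np.inf)
    spacing = float(np.median(np.diff(np.unique(dv)))) if dv.size > 1 else span
    flagged = bool(
        w > 10 * span          # flat profile: width unbounded above
        or w < spacing / 2     # narrower than the sampling: unidentifiable
        or a < 0.05 * max(abs(b), float(np.ptp(yv)))  # no gradient over baseline
        or not np.isfinite(perr[1])
        or perr[1] > w
    )
    return GaussianGradient(float(max(a, 1e-12)), float(w), float(b)), flagged


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def population_decompose(
    a_total: float,
    phi: float,
    correlated_fraction: float,
    psf: PsfModel,
    clip_tolerance: float = 0.05,
    **labels,
) -> PopulationRecord:
    """Compose per-pool concentrations from fitted correlation quantities.

    ``a_total`` is the fitted ACF amplitude (total concentration), ``phi``
    the slowly-moving fraction from the two-component fit, and
    ``correlated_fraction`` the DNA-correlated fraction from the
    cross-correlation.  The uncorrelated pool is the difference
    ``phi - correlated_fraction`` of the total, clipped at zero (with a
    warning) when measurement noise makes the correlated pool exceed the
    slow pool.
    """
    if not (0 <= phi <= 1):
        raise ValueError("phi must lie in [0, 1]")
    if correlated_fraction < 0:
        raise ValueError("correlated fraction must be nonnegative")
    total = amplitude_to_concentration(a_total, psf)
    free = (1.0 - phi) * total
    slow = phi * total
    corr = correlated_fraction * total
    if corr > slow:
        if correlated_fraction - phi > clip_tolerance:
            warnings.warn(
                "correlated fraction exceeds slow fraction beyond tolerance; "
                "clipping correlated pool to the slow pool",
                stacklevel=2,
            )
        corr = slow
    uncorr = max(slow - corr, 0.0)
    return PopulationRecord(
        conc_total=total,
        conc_free=free,
        conc_slow=slow,
        conc_correlated=corr,
        conc_uncorrelated=uncorr,
        **labels,
    )
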