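"""Synthetic-data generators with known ground truth.

Every input class the analysis pipeline consumes can be generated here:

* analytic two-/three-component ACFs with the jitter-and-noise replication
  protocol used for the line-time simulation study;
* raster-scanned image stacks of Brownian species observed through a 3D
  Gaussian PSF, with detector offset and shot noise, optionally confined
  to a nuclear disk and paired with a chromatin-marker channel;
* 2D particle trajectories with localization noise and continuous-time
  axial escape from a finite detection slab (the Monte-Carlo counterpart
  of the Zcorr defocalization model);
* i.i.d. Rayleigh-mixture step samples, with or without defocalization
  thinning;
* per-embryo DV concentration profiles allocated by the LLPS threshold
  model along a Gaussian gradient.

Defaults reproduce the acquisition constants of the study the pipeline
models: 31.95 nm pixels, 2.06 us dwell, 5 ms (case-1) or 17 ms (case-2)
line times, amplifier offset 100 +- 10 AU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Acf2D,
    AcquisitionGeometry,
    ImageStack,
    NuclearMask,
    PsfModel,
    concentration_to_density,
)
from .populations import GaussianGradient, LlpsModel, PopulationRecord, llps_allocate
from .rics import concentration_to_amplitude, model_acf_multi
from .spt import StepSet, TrajectoryTable, axial_survival_probability

__all__ = [
    "SpeciesSpec",
    "StepMixtureSpec",
    "NoiseProtocol",
    "AcfBaseline",
    "SimulatedAcfStudy",
    "RasterSimulation",
    "case_geometry",
    "two_component_baseline",
    "three_component_baseline",
    "mixture_90ms",
    "mixture_500ms",
    "simulate_acf_study",
    "simulate_raster_stack",
    "simulate_trajectories",
    "sample_steps_rayleigh",
    "sample_steps_defocalized",
    "simulate_dv_profile",
]

PIXEL_SIZE_UM = 0.03195
DWELL_S = 2.06e-6
LINE_TIME_CASE1_S = 5e-3
LINE_TIME_CASE2_S = 17e-3


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """One Brownian species in a raster-scan simulation."""

    diffusivity: float  # um^2/s
    concentration: float  # nM
    brightness: float = 10.0  # photons per molecule per dwell at beam center
    colocalized_with_red: bool = False

    def __post_init__(self) -> None:
        if self.diffusivity < 0 or self.concentration < 0:
            raise ValueError("diffusivity and concentration must be nonnegative")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")


@dataclass(frozen=True)
class StepMixtureSpec:
    """Ground truth for a step-size mixture: (diffusivity, weight) pairs,
    localization variance, frame interval, and optional detection-slab
    thickness for defocalization."""

    components: tuple  # ((D_i, f_i), ...)
    localization_variance: float = 4.5e-4  # um^2
    frame_interval: float = 0.09  # s
    axial_range: float | None = None  # um

    def __post_init__(self) -> None:
        comps = tuple((float(d), float(f)) for d, f in self.components)
        object.__setattr__(self, "components", comps)
        weights = np.array([f for _, f in comps])
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        if any(d < 0 for d, _ in comps):
            raise ValueError("diffusivities must be nonnegative")
        if self.localization_variance < 0:
            raise ValueError("localization variance must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def diffusivities(self) -> np.ndarray:
        return np.array([d for d, _ in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([f for _, f in self.components])


@dataclass(frozen=True)
class NoiseProtocol:
    """Replication protocol for the analytic ACF study: number of
    simulations, uniform parameter jitter (fraction), additive ACF noise
    (fraction of the amplitude), and seed."""

    n_sims: int = 20
    param_jitter: float = 0.10
    acf_noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be at least 1")
        if not (0 <= self.param_jitter < 1) or not (0 <= self.acf_noise < 1):
            raise ValueError("jitter and noise fractions must lie in [0, 1)")


@dataclass(frozen=True)
class AcfBaseline:
    """Baseline parameters of the analytic ACF study.

    For a two-component system ``fractions = (phi,)`` is the slowly moving
    fraction; for a three-component system ``fractions = (phi0, phi1)`` are
    the DNA-bound and mobile-cluster fractions.  The remainder is the free
    population at ``d_free``.
    """

    amplitude: float
    fractions: tuple
    diffusivities_slow: tuple  # diffusivities of the non-free components
    d_free: float = 3.0

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.diffusivities_slow):
            raise ValueError("fractions and slow diffusivities must align")
        if len(self.fractions) not in (1, 2):
            raise ValueError("baseline must have one or two slow components")
        if sum(self.fractions) > 1:
            raise ValueError("slow fractions must sum to at most 1")
        if not np.isfinite(self.amplitude) or self.amplitude <= 0:
            raise ValueError("amplitude must be positive and finite")

    @property
    def n_components(self) -> int:
        return len(self.fractions) + 1

    def all_fractions(self) -> np.ndarray:
        return np.array([*self.fractions, 1.0 - sum(self.fractions)])

    def all_diffusivities(self) -> np.ndarray:
        return np.array([*self.diffusivities_slow, self.d_free])


def two_component_baseline(
    psf: PsfModel | None = None, total_conc_nm: float = 120.0
) -> AcfBaseline:
    """Free + immobile system: slowly moving fraction 0.75, D_free 3 um^2/s."""
    psf = psf or PsfModel()
    return AcfBaseline(
        amplitude=concentration_to_amplitude(total_conc_nm, psf),
        fractions=(0.75,),
        diffusivities_slow=(0.0,),
        d_free=3.0,
    )


def three_component_baseline(
    psf: PsfModel | None = None, total_conc_nm: float = 120.0
) -> AcfBaseline:
    """Free + mobile clusters + DNA-bound: phi0 = 0.25 (bound, D = 0),
    phi1 = 0.50 (clusters, D = 0.1 um^2/s), remainder free at 3 um^2/s."""
    psf = psf or PsfModel()
    return AcfBaseline(
        amplitude=concentration_to_amplitude(total_conc_nm, psf),
        fractions=(0.25, 0.50),
        diffusivities_slow=(0.0, 0.1),
        d_free=3.0,
    )


def mixture_90ms(axial_range: float | None = None) -> StepMixtureSpec:
    """Step mixture observed at the 90 ms frame rate: mobile clusters at
    0.1 um^2/s (34%) and DNA-bound at 0.01 um^2/s (66%)."""
    return StepMixtureSpec(
        components=((0.1, 0.34), (0.01, 0.66)),
        frame_interval=0.09,
        axial_range=axial_range,
    )


def mixture_500ms() -> StepMixtureSpec:
    """Step mixture at the 500 ms frame rate: only bound populations remain
    visible, 0.01 um^2/s (66%) and 0.004 um^2/s (34%)."""
    return StepMixtureSpec(
        components=((0.01, 0.66), (0.004, 0.34)),
        frame_interval=0.5,
    )


def case_geometry(case: str = "case-1") -> AcquisitionGeometry:
    """Acquisition geometry of the two line-time orientations.

    Case 1 scans 1024-pixel lines (5 ms line time); case 2 scans the same
    field rotated by 90 degrees in 4096-pixel lines (17 ms line time).
    """
    if case in ("case-1", "1", "case1"):
        n_cols, n_rows, line = 1024, 4096, LINE_TIME_CASE1_S
        tag = "case-1"
    elif case in ("case-2", "2", "case2"):
        n_cols, n_rows, line = 4096, 1024, LINE_TIME_CASE2_S
        tag = "case-2"
    else:
        raise ValueError(f"unknown case {case!r}")
    return AcquisitionGeometry(
        pixel_size=PIXEL_SIZE_UM,
        dwell=DWELL_S,
        line_time=line,
        frame_time=n_rows * line,
        n_rows=n_rows,
        n_cols=n_cols,
        orientation=tag,
    )


# ---------------------------------------------------------------------------
# analytic ACF study
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAcfStudy:
    """Replicate analytic ACFs plus the jittered truth of each replicate."""

    acfs: list
    params: list  # per-replicate dicts of the jittered baseline


def simulate_acf_study(
    system_kind: str,
    geometry: AcquisitionGeometry,
    baseline: AcfBaseline,
    protocol: NoiseProtocol,
    psf: PsfModel | None = None,
    dx_shifts: np.ndarray | None = None,
    dy_shifts: np.ndarray | None = None,
) -> SimulatedAcfStudy:
    """Replicate noisy analytic ACFs of a two- or three-component system.

    Each replicate multiplies every baseline parameter (amplitude,
    fractions, nonzero diffusivities) independently by ``1 + jitter * u``
    with u uniform in [-1, 1], evaluates the mixture ACF, and adds Gaussian
    noise with SD equal to ``acf_noise`` times the replicate's amplitude.
    Zero jitter and zero noise reproduce the analytic model exactly.
    """
    psf = psf or PsfModel()
    expected = {"two": 2, "three": 3}
    if system_kind not in expected:
        raise ValueError("system_kind must be 'two' or 'three'")
    if baseline.n_components != expected[system_kind]:
        raise ValueError(
            f"{system_kind}-component system needs a baseline with "
            f"{expected[system_kind]} components, got {baseline.n_components}"
        )
    rng = np.random.default_rng(protocol.seed)
    acfs, params = [], []
    for _ in range(protocol.n_sims):
        def jit(value):
            if value == 0:
                return 0.0
            return value * (1.0 + protocol.param_jitter * rng.uniform(-1, 1))

        amp = jit(baseline.amplitude)
        fracs = [jit(f) for f in baseline.fractions]
        slow_ds = [jit(d) for d in baseline.diffusivities_slow]
        d_free = jit(baseline.d_free)
        all_f = np.array([*fracs, 1.0 - sum(fracs)])
        if np.any(all_f < 0):
            all_f = np.clip(all_f, 0, None)
        all_f = all_f / all_f.sum()
        all_d = np.array([*slow_ds, d_free])
        acf = model_acf_multi(
            amp, all_f, all_d, geometry, psf,
            dx_shifts=dx_shifts, dy_shifts=dy_shifts,
        )
        if protocol.acf_noise > 0:
            noise = rng.normal(0.0, protocol.acf_noise * amp, size=acf.values.shape)
            acf = acf.copy_with(acf.values + noise)
        acfs.append(acf)
        params.append(
            {"amplitude": amp, "fractions": all_f.tolist(),
             "diffusivities": all_d.tolist()}
        )
    return SimulatedAcfStudy(acfs=acfs, params=params)


# ---------------------------------------------------------------------------
# raster-scan image simulation
# ---------------------------------------------------------------------------

@dataclass
class RasterSimulation:
    """Output of the raster-scan simulator: image stacks, masks, truth."""

    green: ImageStack
    red: ImageStack | None
    mask: NuclearMask
    analysis_mask: NuclearMask
    truth: dict


def simulate_raster_stack(
    species,
    geometry: AcquisitionGeometry,
    psf: PsfModel | None = None,
    offset_mean: float = 100.0,
    offset_sd: float = 10.0,
    n_frames: int = 12,
    nucleus_radius_um: float | None = None,
    seed: int = 0,
    gain: float = 2.0,
    axial_halfwidth_factor: float = 3.0,
    red_brightness: float = 10.0,
) -> RasterSimulation:
    """Simulate a raster-scanned confocal acquisition of Brownian species.

    Particles move in a 3D box spanning the field of view laterally
    (periodic boundaries, or confined to a reflecting nuclear disk of
    radius ``nucleus_radius_um``) and reflecting axial walls well outside
    the detection volume.  Particle positions are advanced once per scan
    line (within-line motion is negligible against ``w0`` for the
    diffusivities and dwell times of interest); each pixel's expected
    photon count is the sum over nearby particles of
    ``brightness * exp(-2((x-xp)^2+(y-yp)^2)/w0^2 - 2 zp^2/wz_det^2)``,
    drawn as a Poisson count, scaled to AU by ``gain`` and summed with
    Gaussian amplifier offset ``(offset_mean, offset_sd)``.

    The axial detection radius is rendered as ``wz_det = wz / gamma``:
    the illumination factor gamma expresses that the instrument's
    effective observation volume exceeds the nominal ``pi^3/2 w0^2 wz``,
    and widening the axial profile by ``1/gamma`` reproduces exactly the
    amplitude calibration ``A = gamma / (V_psf c)`` that the analysis
    applies, while leaving the lateral correlation shape (which sets the
    fitted w0) untouched.

    Species marked ``colocalized_with_red`` are rendered into a second
    (red) channel at the same positions, emulating an immobile chromatin
    marker for segmentation and cross-correlation.

    The returned ``analysis_mask`` is the nuclear disk eroded by ``2 w0``
    so that pixels near the confinement boundary (where the particle
    neighborhood is truncated) are excluded from correlation analysis; in
    full-field mode it equals the full frame.
    """
    psf = psf or PsfModel()
    species = list(species)
    if not species:
        raise ValueError("species list must be non-empty")
    if offset_sd < 0:
        raise ValueError("offset_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    dr = geometry.pixel_size
    n_rows, n_cols = geometry.n_rows, geometry.n_cols
    lx, ly = geometry.width_um, geometry.height_um
    wz_det = psf.wz / psf.gamma
    zh = axial_halfwidth_factor * wz_det
    if zh <= 0 or lx <= 0 or ly <= 0:
        raise ValueError("simulation box has zero volume")

    cx, cy = lx / 2.0, ly / 2.0
    if nucleus_radius_um is not None:
        radius = float(nucleus_radius_um)
        if radius <= 0 or 2 * radius > min(lx, ly):
            raise ValueError("nuclear disk must fit inside the field of view")
        volume = np.pi * radius ** 2 * 2 * zh
    else:
        radius = None
        volume = lx * ly * 2 * zh

    # particle populations
    pos, spec_of = [], []
    for si, sp in enumerate(species):
        n = int(rng.poisson(concentration_to_density(sp.concentration) * volume))
        if n == 0:
            continue
        if radius is None:
            xy = rng.uniform([0, 0], [lx, ly], size=(n, 2))
        else:
            rr = radius * np.sqrt(rng.uniform(0, 1, n))
            th = rng.uniform(0, 2 * np.pi, n)
            xy = np.column_stack([cx + rr * np.cos(th), cy + rr * np.sin(th)])
        z = rng.uniform(-zh, zh, n)
        pos.append(np.column_stack([xy, z]))
        spec_of.append(np.full(n, si))
    if pos:
        pos = np.vstack(pos)
        spec_of = np.concatenate(spec_of)
    else:
        pos = np.zeros((0, 3))
        spec_of = np.zeros(0, dtype=int)

    diff = np.array([sp.diffusivity for sp in species])
    bright = np.array([sp.brightness for sp in species])
    coloc = np.array([sp.colocalized_with_red for sp in species])
    moving = diff[spec_of] > 0 if pos.size else np.zeros(0, dtype=bool)
    step_sd = np.sqrt(2.0 * diff[spec_of] * geometry.line_time) if pos.size else None
    any_red = bool(coloc.any())

    # pixel grid
    x_centers = (np.arange(n_cols) + 0.5) * dr
    cutoff = 3.0 * psf.w0
    kx = int(np.ceil(cutoff / dr))
    win = np.arange(-kx, kx + 1)
    z_cut = 2.0 * wz_det

    green = np.empty((n_frames, n_rows, n_cols))
    red = np.empty_like(green) if any_red else None

    def render_row(idx, y_row, channel_bright):
        """Expected photon count per column from particles ``idx``."""
        lam = np.zeros(n_cols)
        if idx.size == 0:
            return lam
        p = pos[idx]
        wz_w = np.exp(-2.0 * p[:, 2] ** 2 / wz_det ** 2)
        wy = np.exp(-2.0 * (p[:, 1] - y_row) ** 2 / psf.w0 ** 2)
        amp = channel_bright[spec_of[idx]] * wz_w * wy
        c0 = np.round(p[:, 0] / dr - 0.5).astype(int)
        cols = c0[:, None] + win[None, :]
        xw = x_centers[np.clip(cols, 0, n_cols - 1)]
        wx = np.exp(-2.0 * (xw - p[:, 0][:, None]) ** 2 / psf.w0 ** 2)
        contrib = amp[:, None] * wx
        valid = (cols >= 0) & (cols < n_cols)
        np.add.at(lam, cols[valid], contrib[valid])
        return lam

    for fr in range(n_frames):
        for j in range(n_rows):
            if moving.any():
                steps = rng.normal(0.0, 1.0, (int(moving.sum()), 3))
                pos[moving] += steps * step_sd[moving][:, None]
                # boundaries: reflect z, wrap or reflect xy
                zp = pos[moving, 2]
                zp = np.where(zp > zh, 2 * zh - zp, zp)
                zp = np.where(zp < -zh, -2 * zh - zp, zp)
                pos[moving, 2] = np.clip(zp, -zh, zh)
                if radius is None:
                    pos[moving, 0] %= lx
                    pos[moving, 1] %= ly
                else:
                    dx = pos[moving, 0] - cx
                    dy = pos[moving, 1] - cy
                    r = np.hypot(dx, dy)
                    out = r > radius
                    if out.any():
                        scale = np.where(out, np.maximum(2 * radius - r, 0.0) / np.maximum(r, 1e-12), 1.0)
                        midx = np.flatnonzero(moving)
                        pos[midx, 0] = cx + dx * scale
                        pos[midx, 1] = cy + dy * scale
            y_row = (j + 0.5) * dr
            if pos.size:
                near = (np.abs(pos[:, 1] - y_row) < cutoff) & (np.abs(pos[:, 2]) < z_cut)
                idx = np.flatnonzero(near)
            else:
                idx = np.zeros(0, dtype=int)
            lam_g = render_row(idx, y_row, bright)
            counts = rng.poisson(lam_g)
            offset = rng.normal(offset_mean, offset_sd, n_cols)
            green[fr, j] = gain * counts + offset
            if any_red:
                ridx = idx[coloc[spec_of[idx]]]
                lam_r = render_row(
                    ridx, y_row, np.full(len(species), red_brightness)
                )
                red[fr, j] = gain * rng.poisson(lam_r) + rng.normal(
                    offset_mean, offset_sd, n_cols
                )

    if radius is not None:
        yy, xx = np.meshgrid(
            (np.arange(n_rows) + 0.5) * dr, x_centers, indexing="ij"
        )
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mask = NuclearMask(r2 <= radius ** 2)
        analysis = NuclearMask(r2 <= max(radius - 2 * psf.w0, dr) ** 2)
    else:
        mask = NuclearMask.full_frame(geometry)
        analysis = NuclearMask.full_frame(geometry)

    counts_per_species = np.bincount(spec_of, minlength=len(species))
    actual_conc = counts_per_species / volume / 0.6022
    truth = {
        "n_particles": counts_per_species.tolist(),
        "concentrations_nM": actual_conc.tolist(),
        "total_concentration_nM": float(actual_conc.sum()),
        "phi_slow": float(
            actual_conc[diff == 0].sum() / max(actual_conc.sum(), 1e-300)
        ),
        "volume_um3": float(volume),
        "gain": gain,
        "offset_mean": offset_mean,
        "offset_sd": offset_sd,
    }
    g_stack = ImageStack(green, geometry, channel="green")
    r_stack = ImageStack(red, geometry, channel="red") if any_red else None
    return RasterSimulation(g_stack, r_stack, mask, analysis, truth)


# ---------------------------------------------------------------------------
# trajectories and steps
# ---------------------------------------------------------------------------

def simulate_trajectories(
    mixture: StepMixtureSpec,
    n_particles: int,
    n_frames: int,
    seed: int = 0,
    min_steps: int = 3,
    substeps: int = 16,
) -> TrajectoryTable:
    """Simulate 2D-localized trajectories of a diffusivity mixture.

    Each particle draws its component by weight and performs 3D Brownian
    motion.  When the mixture declares an ``axial_range``, the axial
    coordinate starts uniformly inside the slab and the particle is lost
    the moment it touches either boundary (continuous-time absorption,
    realized with Brownian substeps plus a bridge crossing test per
    substep); the trajectory is truncated at the last frame before the
    loss.  Recorded lateral positions carry Gaussian localization noise of
    variance ``sigma^2`` per axis per localization, so an immobile
    particle's mean squared step is ``4 sigma^2`` — the D = 0 limit of the
    Rayleigh mixture the fits assume.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be positive")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    dt = mixture.frame_interval
    comp = rng.choice(len(mixture.components), size=n_particles, p=mixture.weights)
    d_of = mixture.diffusivities[comp]
    sigma_loc = np.sqrt(mixture.localization_variance)

    # lateral true positions: cumulative Brownian steps from the origin
    lateral_sd = np.sqrt(2.0 * d_of * dt)
    steps_xy = rng.normal(0.0, 1.0, (n_particles, n_frames - 1, 2)) * lateral_sd[:, None, None]
    xy = np.concatenate(
        [np.zeros((n_particles, 1, 2)), np.cumsum(steps_xy, axis=1)], axis=1
    )
    xy_rec = xy + rng.normal(0.0, sigma_loc, xy.shape)

    # axial survival: last frame index at which the particle is still inside
    last_frame = np.full(n_particles, n_frames - 1)
    if mixture.axial_range is not None:
        dz = float(mixture.axial_range)
        half = dz / 2.0
        z = rng.uniform(-half, half, n_particles)
        alive = np.ones(n_particles, dtype=bool)
        dt_sub = dt / substeps
        sd_sub = np.sqrt(2.0 * d_of * dt_sub)
        for f in range(1, n_frames):
            for _ in range(substeps):
                z_new = z + rng.normal(0.0, 1.0, n_particles) * sd_sub
                esc = np.abs(z_new) >= half
                # Brownian-bridge crossing probability for in-to-in moves
                inside = alive & ~esc
                var = 2.0 * d_of * dt_sub
                with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                    p_up = np.exp(-2.0 * (half - z) * (half - z_new) / np.maximum(var, 1e-300))
                    p_dn = np.exp(-2.0 * (half + z) * (half + z_new) / np.maximum(var, 1e-300))
                cross = rng.uniform(0, 1, n_particles) < np.clip(p_up + p_dn - p_up * p_dn, 0, 1)
                died = alive & (esc | (inside & cross))
                last_frame[died] = np.minimum(last_frame[died], f - 1)
                alive &= ~died
                z = np.where(alive, z_new, z)
            if not alive.any():
                break

    rows = []
    for p in range(n_particles):
        lf = int(last_frame[p])
        if lf < 1:
            continue
        frames = np.arange(lf + 1)
        rows.append(
            pd.DataFrame(
                {
                    "particle": p,
                    "frame": frames,
                    "x_um": xy_rec[p, : lf + 1, 0],
                    "y_um": xy_rec[p, : lf + 1, 1],
                }
            )
        )
    if not rows:
        raise ValueError("no trajectories survived")
    df = pd.concat(rows, ignore_index=True)
    return TrajectoryTable(df, frame_interval=dt, min_steps=min_steps)


def sample_steps_rayleigh(
    mixture: StepMixtureSpec, n_steps: int, seed: int = 0
) -> StepSet:
    """I.i.d. draws from the Rayleigh-mixture step-size density.

    Component scales are ``sqrt(2 (D_i dt + sigma^2))``; the mean squared
    step is ``4 sum_i f_i (D_i dt + sigma^2)``.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(mixture.components), size=n_steps, p=mixture.weights)
    scale2 = 2.0 * (
        mixture.diffusivities[comp] * mixture.frame_interval
        + mixture.localization_variance
    )
    r = rng.rayleigh(np.sqrt(scale2))
    return StepSet(r, mixture.frame_interval, n_trajectories=0)


def sample_steps_defocalized(
    mixture: StepMixtureSpec, n_steps: int, seed: int = 0
) -> StepSet:
    """I.i.d. single-frame steps thinned by axial escape from the slab.

    Each candidate step draws a component, a uniform axial start inside the
    detection slab, and is retained with the absorbing-slab survival
    probability of its component over one frame interval.  This is the
    exact generative counterpart of the defocalization-corrected mixture
    model: the observed component weights are each component's true weight
    rescaled by its own survival fraction.
    """
    if n_steps <= 0:
        raise ValueError("n_steps must be positive")
    if mixture.axial_range is None:
        raise ValueError("mixture must declare an axial_range for defocalization")
    rng = np.random.default_rng(seed)
    dz = float(mixture.axial_range)
    dt = mixture.frame_interval
    out = []
    remaining = n_steps
    while remaining > 0:
        batch = max(int(remaining * 1.8) + 16, 64)
        comp = rng.choice(len(mixture.components), size=batch, p=mixture.weights)
        z0 = rng.uniform(-dz / 2.0, dz / 2.0, batch)
        keep = np.zeros(batch, dtype=bool)
        for i, (d, _) in enumerate(mixture.components):
            sel = comp == i
            if not sel.any():
                continue
            surv = axial_survival_probability(z0[sel], d, dt, dz)
            keep[sel] = rng.uniform(0, 1, int(sel.sum())) < surv
        kept = comp[keep]
        scale2 = 2.0 * (
            mixture.diffusivities[kept] * dt + mixture.localization_variance
        )
        out.append(rng.rayleigh(np.sqrt(scale2)))
        remaining -= kept.size
    r = np.concatenate(out)[:n_steps]
    return StepSet(r, dt, n_trajectories=0)


# ---------------------------------------------------------------------------
# DV profiles
# ---------------------------------------------------------------------------

def simulate_dv_profile(
    llps: LlpsModel,
    gradient: GaussianGradient,
    dv_coords,
    noise_cv: float = 0.05,
    seed: int = 0,
    n_embryos: int = 3,
) -> list[PopulationRecord]:
    """Per-embryo DV concentration records from the threshold model.

    The total concentration follows the Gaussian gradient of DV position;
    pools are allocated by the LLPS threshold model; each measured pool of
    each record receives independent multiplicative lognormal noise with
    coefficient of variation ``noise_cv`` (keeping concentrations positive)
    and the total is recomputed as the sum of the noisy pools so that mass
    stays conserved record by record.
    """
    dv_coords = np.asarray(dv_coords, dtype=float)
    if np.any((dv_coords < 0) | (dv_coords > 0.5)):
        raise ValueError("DV coordinates must lie in [0, 0.5]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    rng = np.random.default_rng(seed)
    log_sd = np.sqrt(np.log(1.0 + noise_cv ** 2)) if noise_cv > 0 else 0.0

    def noisy(value):
        if value == 0 or log_sd == 0:
            return float(value)
        return float(value * rng.lognormal(-0.5 * log_sd ** 2, log_sd))

    records = []
    for e in range(n_embryos):
        for dv in dv_coords:
            total = float(gradient(dv))
            free, cond1, cond2 = llps_allocate(total, llps)
            free_n = noisy(free)
            corr_n = noisy(cond1)
            uncorr_n = noisy(cond2)
            slow_n = corr_n + uncorr_n
            records.append(
                PopulationRecord(
                    conc_total=free_n + slow_n,
                    conc_free=free_n,
                    conc_slow=slow_n,
                    conc_correlated=corr_n,
                    conc_uncorrelated=uncorr_n,
                    dv=float(dv),
                    embryo=e,
                )
            )
    return records
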