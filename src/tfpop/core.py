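"""Core data containers shared across the RICS/SPT analysis pipeline.

Units convention throughout the package: lengths in micrometers, times in
seconds, diffusivities in um^2/s, concentrations in nanomolar (nM),
raw detector intensities in arbitrary units (AU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: molecules per um^3 for a 1 nM solution (Avogadro * 1e-9 mol/L * 1e-15 L/um^3)
MOLECULES_PER_UM3_PER_NM = 0.6022


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scan timing and spacing of a raster confocal acquisition.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel spacing ``dr`` in um.
    dwell : float
        Pixel dwell time ``tau_p`` in seconds.
    line_time : float
        Line period ``tau_l`` in seconds (includes retrace overhead, so it
        is supplied as measured rather than derived from ``n_cols * dwell``).
    frame_time : float
        Frame period in seconds.
    n_rows, n_cols : int
        Image dimensions; rows advance along the slow axis, columns along
        the fast axis.
    orientation : str
        Free-form tag for the scan orientation (e.g. ``"case-1"`` for the
        short-line-time orientation, ``"case-2"`` for the long one).
    """

    pixel_size: float
    dwell: float
    line_time: float
    frame_time: float
    n_rows: int = 256
    n_cols: int = 256
    orientation: str = "case-1"

    def __post_init__(self) -> None:
        for name in ("pixel_size", "dwell", "line_time", "frame_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("image dimensions must be at least 1 pixel")
        if self.line_time < self.n_cols * self.dwell * (1 - 1e-9):
            raise ValueError(
                "line_time must be at least n_cols * dwell "
                f"({self.line_time:g} < {self.n_cols * self.dwell:g})"
            )
        # 20% slack for hardware overhead not captured by the line period
        if self.frame_time < self.n_rows * self.line_time * 0.8:
            raise ValueError("frame_time inconsistent with n_rows * line_time")

    @property
    def width_um(self) -> float:
        return self.n_cols * self.pixel_size

    @property
    def height_um(self) -> float:
        return self.n_rows * self.pixel_size


@dataclass(frozen=True)
class PsfModel:
    """3D Gaussian observation volume of a confocal microscope.

    ``w0`` and ``wz`` are the lateral and axial 1/e^2 radii of the detected
    intensity profile ``exp(-2(x^2+y^2)/w0^2 - 2 z^2/wz^2)``. ``gamma`` is
    the illumination-profile factor entering the amplitude relation
    ``A = gamma / (V_psf * c)``; for a 3D Gaussian it is 2^(-3/2).
    """

    w0: float = 0.25
    wz: float = 0.75
    gamma: float = 2.0 ** (-1.5)

    def __post_init__(self) -> None:
        if not (0 < self.w0 <= self.wz):
            raise ValueError("require 0 < w0 <= wz")
        if not (0 < self.gamma <= 1):
            raise ValueError("gamma must lie in (0, 1]")

    @property
    def volume(self) -> float:
        """Effective PSF volume ``pi^(3/2) w0^2 wz`` in um^3."""
        return float(np.pi ** 1.5 * self.w0 ** 2 * self.wz)


@dataclass
class ImageStack:
    """A single-channel raster time series with its acquisition geometry.

    ``data`` has shape ``(n_frames, n_rows, n_cols)`` in AU.
    """

    data: np.ndarray
    geometry: AcquisitionGeometry
    channel: str = "green"
    offset_subtracted: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (n_frames, n_rows, n_cols)")
        if self.data.shape[1:] != (self.geometry.n_rows, self.geometry.n_cols):
            raise ValueError(
                f"stack shape {self.data.shape[1:]} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def scaled(self, gain: float) -> "ImageStack":
        return ImageStack(self.data * gain, self.geometry, self.channel,
                          self.offset_subtracted)


@dataclass
class NuclearMask:
    """Boolean pixel-inclusion mask, either per frame or shared by all frames.

    ``mask`` has shape ``(n_rows, n_cols)`` or ``(n_frames, n_rows, n_cols)``.
    """

    mask: np.ndarray
    min_pixels: int = 1000

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise ValueError("mask must be 2D or 3D")

    def for_frame(self, j: int) -> np.ndarray:
        return self.mask if self.mask.ndim == 2 else self.mask[j]

    def validate(self, stack: ImageStack) -> None:
        shape = (stack.geometry.n_rows, stack.geometry.n_cols)
        per_frame = self.mask if self.mask.ndim == 3 else self.mask[None]
        if per_frame.shape[-2:] != shape:
            raise ValueError("mask shape does not match stack")
        counts = per_frame.reshape(per_frame.shape[0], -1).sum(axis=1)
        if np.any(counts < self.min_pixels):
            raise ValueError(
                f"mask has fewer than {self.min_pixels} pixels in some frame"
            )

    @classmethod
    def full_frame(cls, geometry: AcquisitionGeometry) -> "NuclearMask":
        return cls(np.ones((geometry.n_rows, geometry.n_cols), dtype=bool))


@dataclass
class Acf2D:
    """A 2D spatial (cross-)correlation surface over pixel shifts.

    ``values[iy, ix]`` holds ``G(dx_shifts[ix], dy_shifts[iy])``; entries may
    be NaN where the masked overlap was too small to estimate. ``dx`` runs
    along the fast scan axis (columns), ``dy`` along the slow axis (rows).
    """

    values: np.ndarray
    dx_shifts: np.ndarray
    dy_shifts: np.ndarray
    geometry: AcquisitionGeometry
    n_frames_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.dx_shifts = np.asarray(self.dx_shifts, dtype=int)
        self.dy_shifts = np.asarray(self.dy_shifts, dtype=int)
        if self.values.shape != (self.dy_shifts.size, self.dx_shifts.size):
            raise ValueError("ACF values shape must be (n_dy, n_dx)")
        if self.n_frames_averaged < 1:
            raise ValueError("ACF must average at least one frame")
        if 0 not in self.dx_shifts or 0 not in self.dy_shifts:
            raise ValueError("ACF must be defined at zero shift")

    @property
    def zero_index(self) -> tuple[int, int]:
        iy = int(np.flatnonzero(self.dy_shifts == 0)[0])
        ix = int(np.flatnonzero(self.dx_shifts == 0)[0])
        return iy, ix

    def fast_axis_cut(self) -> tuple[np.ndarray, np.ndarray]:
        """``(dx, G(dx, 0))`` for dx >= 0."""
        iy, _ = self.zero_index
        keep = self.dx_shifts >= 0
        return self.dx_shifts[keep], self.values[iy, keep]

    def slow_axis_cut(self) -> tuple[np.ndarray, np.ndarray]:
        """``(dy, G(0, dy))`` for dy >= 0."""
        _, ix = self.zero_index
        keep = self.dy_shifts >= 0
        return self.dy_shifts[keep], self.values[keep, ix]

    def copy_with(self, values: np.ndarray) -> "Acf2D":
        return replace(self, values=np.asarray(values, dtype=float))


def concentration_to_density(conc_nm: float) -> float:
    """nM -> molecules per um^3."""
    return conc_nm * MOLECULES_PER_UM3_PER_NM


def density_to_concentration(density: float) -> float:
    """molecules per um^3 -> nM."""
    return density / MOLECULES_PER_UM3_PER_NM
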