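"""Readers, writers, configuration and pipeline orchestration.

Image stacks travel as multi-page TIFF files with a YAML sidecar declaring
the acquisition geometry in physical units; trajectory tables as delimited
text with header ``particle,frame,x_um,y_um``; fit reports as JSON; run
configuration as a single YAML file whose entries CLI flags may override.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import AcquisitionGeometry, ImageStack, NuclearMask, PsfModel
from .spt import DEFAULT_SIGMA2, TrajectoryTable

logger = logging.getLogger("tfpop")

SIDECAR_KEYS = ("pixel_size_um", "dwell_s", "line_time_s", "frame_time_s", "channels")


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def write_stack(
    path,
    stacks,
    sidecar=None,
) -> Path:
    """Write one or more co-registered channels as a multi-page TIFF.

    Pages are ordered frame-major, channel-minor; the sidecar YAML records
    geometry and channel names so the file is self-describing.
    """
    path = Path(path)
    if isinstance(stacks, ImageStack):
        stacks = [stacks]
    geom = stacks[0].geometry
    for s in stacks[1:]:
        if s.geometry != geom:
            raise ValueError("channels must share a geometry")
        if s.data.shape != stacks[0].data.shape:
            raise ValueError("channels must share a shape")
    pages = np.stack([s.data for s in stacks], axis=1)  # (frames, ch, h, w)
    tifffile.imwrite(path, pages, imagej=False, metadata={"axes": "TCYX"})
    meta = {
        "pixel_size_um": geom.pixel_size,
        "dwell_s": geom.dwell,
        "line_time_s": geom.line_time,
        "frame_time_s": geom.frame_time,
        "orientation": geom.orientation,
        "channels": [s.channel for s in stacks],
        "offset_subtracted": [bool(s.offset_subtracted) for s in stacks],
    }
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yml")
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))
    return sidecar


def read_stack(path, sidecar=None) -> list[ImageStack]:
    """Read a multi-page TIFF plus sidecar into one ImageStack per channel."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".yml")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}; need keys {SIDECAR_KEYS}"
        )
    meta = yaml.safe_load(sidecar.read_text())
    missing = [k for k in SIDECAR_KEYS if k not in meta]
    if missing:
        raise KeyError(f"sidecar {sidecar} missing keys: {missing}")
    data = np.asarray(tifffile.imread(path), dtype=float)
    channels = list(meta["channels"])
    if data.ndim == 3:
        data = data[:, None] if len(channels) == 1 else data[None]
    if data.ndim != 4 or data.shape[1] != len(channels):
        raise ValueError(
            f"stack shape {data.shape} inconsistent with channels {channels}"
        )
    geom = AcquisitionGeometry(
        pixel_size=float(meta["pixel_size_um"]),
        dwell=float(meta["dwell_s"]),
        line_time=float(meta["line_time_s"]),
        frame_time=float(meta["frame_time_s"]),
        n_rows=data.shape[2],
        n_cols=data.shape[3],
        orientation=meta.get("orientation", "case-1"),
    )
    subtracted = meta.get("offset_subtracted", [False] * len(channels))
    return [
        ImageStack(data[:, i], geom, channel=ch, offset_subtracted=bool(subtracted[i]))
        for i, ch in enumerate(channels)
    ]


# ---------------------------------------------------------------------------
# trajectories and reports
# ---------------------------------------------------------------------------

def write_trajectories(path, traj: TrajectoryTable) -> Path:
    path = Path(path)
    traj.data[["particle", "frame", "x_um", "y_um"]].to_csv(path, index=False)
    side = path.with_suffix(".yml")
    side.write_text(yaml.safe_dump({"frame_interval_s": traj.frame_interval}))
    return path


def read_trajectories(path, frame_interval: float | None = None,
                      min_steps: int = 3) -> TrajectoryTable:
    path = Path(path)
    if frame_interval is None:
        side = path.with_suffix(".yml")
        if not side.exists():
            raise FileNotFoundError(
                "frame interval not given and no sidecar found"
            )
        frame_interval = float(yaml.safe_load(side.read_text())["frame_interval_s"])
    df = pd.read_csv(path)
    return TrajectoryTable(df, frame_interval=frame_interval, min_steps=min_steps)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(path, payload: dict) -> Path:
    """JSON fit report; numpy scalars and arrays are converted."""
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=2))
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline configuration: geometry, PSF and analysis constants.

    Every random operation takes an explicit seed from here; there is no
    hidden global random state.
    """

    pixel_size_um: float = 0.03195
    dwell_s: float = 2.06e-6
    line_time_s: float = 5e-3
    frame_time_s: float = 5.06
    w0_um: float = 0.25
    wz_um: float = 0.75
    gamma: float = 2.0 ** (-1.5)
    group_size: int = 12
    d_free: float = 3.0
    d_cluster: float = 0.1
    sigma2_um2: float = DEFAULT_SIGMA2
    detection_range_um: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size_um", "dwell_s", "line_time_s", "frame_time_s",
                     "w0_um", "wz_um", "gamma", "d_free", "d_cluster"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.group_size < 1:
            raise ValueError("group_size must be at least 1")

    @property
    def psf(self) -> PsfModel:
        return PsfModel(w0=self.w0_um, wz=self.wz_um, gamma=self.gamma)

    def geometry(self, n_rows: int, n_cols: int) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            pixel_size=self.pixel_size_um,
            dwell=self.dwell_s,
            line_time=self.line_time_s,
            frame_time=self.frame_time_s,
            n_rows=n_rows,
            n_cols=n_cols,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def write_provenance(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Record the configuration hash and package version beside outputs."""
    from . import __version__

    payload = {
        "config_sha256_16": config.digest(),
        "tfpop_version": __version__,
        "config": asdict(config),
    }
    if extra:
        payload.update(_jsonable(extra))
    out = Path(out_dir) / "provenance.json"
    out.write_text(json.dumps(payload, indent=2))
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, mode: str, **kwargs) -> dict:
    """Execute one analysis chain end to end, writing results and provenance.

    Modes: ``simulate`` (raster-scan simulation to TIFF + truth),
    ``rics`` (stack -> background -> masked ACFs -> amplitude and fraction
    fits -> CSV), ``ccrics`` (two channels -> CCF -> correlated fraction),
    ``ssd`` (trajectories -> step sizes -> Rayleigh mixture fit -> JSON),
    ``dosemap`` (population records -> binning and threshold/Hill fits).
    Any stage failure propagates with the stage named in the log.
    """
    from . import ccrics as cc
    from . import populations as pop
    from . import rics
    from . import spt
    from . import synthetic

    out_dir = Path(kwargs.pop("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline mode=%s out=%s seed=%d", mode, out_dir, config.seed)

    if mode == "simulate":
        n_px = int(kwargs.pop("n_pixels", 256))
        n_frames = int(kwargs.pop("n_frames", 12))
        species = kwargs.pop("species", None) or [
            synthetic.SpeciesSpec(config.d_free, 30.0),
            synthetic.SpeciesSpec(0.0, 90.0, colocalized_with_red=True),
        ]
        geom = config.geometry(n_px, n_px)
        sim = synthetic.simulate_raster_stack(
            species, geom, config.psf, n_frames=n_frames,
            nucleus_radius_um=kwargs.pop("nucleus_radius_um", None),
            seed=config.seed,
        )
        channels = [sim.green] + ([sim.red] if sim.red is not None else [])
        write_stack(out_dir / "stack.tif", channels)
        (out_dir / "truth.yml").write_text(yaml.safe_dump(_jsonable(sim.truth)))
        write_provenance(out_dir, config, {"mode": mode})
        logger.info("simulated %d-frame stack, truth total %.1f nM",
                    n_frames, sim.truth["total_concentration_nM"])
        return {"stack": str(out_dir / "stack.tif"), "truth": sim.truth}

    if mode == "rics":
        stack_path = kwargs.pop("stack")
        model = kwargs.pop("model", "2c")
        channels = read_stack(stack_path, kwargs.pop("meta", None))
        green = channels[0]
        sub, off_mean, off_sd = rics.subtract_background(green)
        logger.info("offset %.1f +- %.1f AU", off_mean, off_sd)
        if len(channels) > 1:
            mask = rics.segment_nuclei(channels[1])
        else:
            mask = NuclearMask.full_frame(green.geometry)
        acfs = rics.compute_acf2d(sub, mask, group_size=config.group_size)
        rows = []
        for i, acf in enumerate(acfs):
            fa = rics.fit_fast_axis(acf, config.psf)
            row = {
                "group_index": i,
                "A": fa.amplitude,
                "B": fa.background,
                "w0_um": fa.w0,
                "phi": np.nan,
                "phi0": np.nan,
                "phi1": np.nan,
                "conc_total_nM": rics.amplitude_to_concentration(fa.amplitude, config.psf),
                "conc_free_nM": np.nan,
                "converged": fa.converged,
            }
            if model in ("2c", "3c"):
                f2 = rics.fit_two_component(acf, fa.amplitude, config.d_free, config.psf)
                row["phi"] = f2.phi
                row["conc_free_nM"] = (1 - f2.phi) * row["conc_total_nM"]
                row["converged"] = row["converged"] and f2.converged
            if model == "3c":
                phi0 = float(kwargs.get("phi0", 0.25))
                f3 = rics.fit_three_component(
                    acf, fa.amplitude, phi0,
                    (0.0, config.d_cluster, config.d_free), config.psf,
                )
                row["phi0"], row["phi1"] = f3.phi0, f3.phi1
                row["converged"] = row["converged"] and f3.converged
            rows.append(row)
        table = pd.DataFrame(rows)
        out = out_dir / kwargs.pop("out", "results.csv")
        table.to_csv(out, index=False)
        write_provenance(out_dir, config, {"mode": mode, "model": model})
        return {"results": str(out), "table": table}

    if mode == "ccrics":
        green_path = kwargs.pop("green")
        red_path = kwargs.pop("red", None)
        if red_path is None:
            channels = read_stack(green_path, kwargs.pop("meta", None))
            if len(channels) < 2:
                raise ValueError("ccrics needs two channels")
            green, red = channels[0], channels[1]
        else:
            green = read_stack(green_path)[0]
            red = read_stack(red_path)[0]
        g_sub, *_ = rics.subtract_background(green)
        r_sub, *_ = rics.subtract_background(red)
        mask = rics.segment_nuclei(red)
        psf = config.psf
        rows = []
        ccfs = cc.compute_ccf2d(g_sub, r_sub, mask, group_size=config.group_size)
        red_acfs = rics.compute_acf2d(r_sub, mask, group_size=config.group_size)
        for i, (ccf, racf) in enumerate(zip(ccfs, red_acfs)):
            ccfit = cc.fit_ccf_zero_diffusion(ccf, psf, psf)
            ra = rics.fit_fast_axis(racf, psf)
            frac = cc.correlated_fraction(ccfit.amplitude, ra.amplitude, psf, psf)
            rows.append({
                "group_index": i,
                "Acc": ccfit.amplitude,
                "Ared": ra.amplitude,
                "correlated_fraction": frac,
            })
        table = pd.DataFrame(rows)
        out = out_dir / kwargs.pop("out", "cc.csv")
        table.to_csv(out, index=False)
        write_provenance(out_dir, config, {"mode": mode})
        return {"results": str(out), "table": table}

    if mode == "ssd":
        traj = read_trajectories(
            kwargs.pop("traj"), kwargs.pop("frame_interval", None)
        )
        k = int(kwargs.pop("k", 2))
        correct = bool(kwargs.pop("correct", False))
        steps = spt.extract_steps(traj)
        dz = None
        if correct:
            dz = spt.effective_axial_range(
                config.detection_range_um, config.d_cluster
            )
        fit = spt.fit_ssd(steps, k=k, sigma2=config.sigma2_um2,
                          correction=correct, dz=dz)
        payload = {
            "k": fit.k,
            "diffusivities_um2_s": fit.diffusivities,
            "weights": fit.weights,
            "observed_weights": fit.observed_weights,
            "sigma2_um2": fit.sigma2,
            "zcorr": fit.zcorr,
            "log_likelihood": fit.log_likelihood,
            "n_steps": fit.n_steps,
            "corrected": fit.corrected,
            "converged": fit.converged,
        }
        out = out_dir / kwargs.pop("out", "ssd_fit.json")
        write_report(out, payload)
        write_provenance(out_dir, config, {"mode": mode})
        return {"results": str(out), "fit": fit}

    if mode == "dosemap":
        records = pd.read_csv(kwargs.pop("records"))
        how = kwargs.pop("how", "dv")
        results = {}
        if how == "timecourse":
            filtered = pop.filter_equilibrium_timepoints(records)
            hf = pop.hill_fit(
                filtered["conc_free"], filtered["conc_uncorrelated"]
            )
            results["hill"] = {"ymax": hf.ymax, "k_half": hf.k_half,
                               "order": hf.order, "flagged": hf.flagged}
        else:
            binned = pop.dv_bin(records)
            for poolcol in ("conc_slow", "conc_correlated", "conc_uncorrelated"):
                mcol = f"{poolcol}_mean"
                if mcol not in binned.columns:
                    continue
                lf = pop.linear_threshold_fit(
                    binned["conc_total_mean"], binned[mcol]
                )
                results[poolcol] = {
                    "slope": lf.slope,
                    "intercept": lf.intercept,
                    "x_intercept_nM": lf.x_intercept,
                    "x_intercept_se_nM": lf.x_intercept_se,
                    "flagged": lf.flagged,
                }
        out = out_dir / kwargs.pop("out", "dosemap.json")
        write_report(out, results)
        write_provenance(out_dir, config, {"mode": mode})
        return {"results": str(out), "fits": results}

    raise ValueError(f"unknown pipeline mode {mode!r}")
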