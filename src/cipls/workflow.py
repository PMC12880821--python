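"""Run orchestration: configuration, the two thickness-sweep experiments,
and report generation.

A run is described by a :class:`RunConfig` (YAML on disk).  ``simulate``
mode generates mosaic frames for phantom samples with the polarized Monte
Carlo; ``process`` mode consumes existing frames.  The two experiments are

* **T1 sweep** -- samples 1, 4, 5, 6 (T1 = 0.0, 0.5, 1.0, 1.5 mm at fixed
  T2 = 1.0 mm): how deep the cancerous layer is buried.
* **T2 sweep** -- samples 2, 3, 4 (T2 = 0.1, 0.5, 1.0 mm at fixed
  T1 = 0.5 mm): how thick the cancerous layer is.

Each sweep writes per-sample DOCP/DeltaDOCP maps, a ``summaries.csv``, a
``trends_<sweep>.csv`` and a JSON run log carrying the config hash and
seeds, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from cipls.conventions import DEFAULT_CONVENTION
from cipls import io as cio
from cipls.mosaic import docp_image, split_mosaic, stokes_images
from cipls.phantom import (
    LayeredPhantom,
    default_spot,
    make_sample_set,
    render_synthetic_frames,
)
from cipls.pipeline import (
    ROISummary,
    TrendTable,
    build_trend,
    delta_docp,
    roi_stats,
    segment_tissue,
    sensitivity_ratio,
)

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "process_frames",
    "run_sweep",
    "run_t1_sweep",
    "run_t2_sweep",
    "report",
    "T1_SWEEP_SAMPLES",
    "T2_SWEEP_SAMPLES",
    "WAVELENGTHS",
]

#: Sample ids entering each experiment.
T1_SWEEP_SAMPLES = ("1", "4", "5", "6")
T2_SWEEP_SAMPLES = ("2", "3", "4")
WAVELENGTHS = (617.0, 850.0)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed for a named sample (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Validated run description; hashable for provenance."""

    mode: str = "simulate"
    out_dir: str = "cipls_out"
    seed: int = 0
    n_photons: int = 20_000
    gain: float = 10_000.0
    noise_model: str = "shot"
    scene_shape: tuple = (256, 256)
    total_thickness_mm: float = 3.5
    acceptance_deg: float = 20.0
    closing_radius: int = 2
    registration: str = "none"
    frames: Dict[str, Dict[str, str]] = field(default_factory=dict)
    healthy_overrides: dict = field(default_factory=dict)
    cancerous_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "process"):
            raise ConfigError(f"mode must be simulate|process, got {self.mode!r}")
        if self.n_photons < 1000:
            raise ConfigError("n_photons must be >= 1000")
        if self.gain <= 0:
            raise ConfigError("gain must be positive")
        if self.noise_model not in ("none", "shot"):
            raise ConfigError(f"unknown noise model {self.noise_model!r}")
        if self.registration not in ("none", "xcorr"):
            raise ConfigError(f"unknown registration {self.registration!r}")
        self.scene_shape = tuple(int(x) for x in self.scene_shape)
        if self.mode == "process" and not self.frames:
            raise ConfigError("process mode needs a frames mapping "
                              "{sample_id: {'617': path, '850': path}}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config: {e}") from e
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sample_seed(base_seed: int, sample_id: str, wavelength_nm: float) -> int:
    """Distinct, stable sub-seed per (sample, wavelength); < 2**31."""
    h = hashlib.sha256(
        f"{base_seed}:{sample_id}:{int(round(wavelength_nm))}".encode()
    ).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def process_frames(
    frame_617,
    frame_850,
    sample_id: str,
    t1_mm: float,
    t2_mm: float,
    closing_radius: int = 2,
    registration: str = "none",
) -> dict:
    """Run the analysis chain on one sample's pair of mosaic frames.

    Split each frame, estimate the DOCP map, segment the tissue on the
    617 nm pseudo-intensity (one mask shared by both wavelengths so the ROI
    areas agree), compute ROI statistics, and form the DeltaDOCP map where
    both wavelength maps are valid.
    """
    maps = {}
    valids = {}
    channels = {}
    for wl, frame in ((617.0, frame_617), (850.0, frame_850)):
        ch = split_mosaic(frame)
        m, v = docp_image(ch)
        channels[wl] = ch
        maps[wl] = m
        valids[wl] = v
    pseudo = stokes_images(channels[617.0]).pseudo_s0
    mask = segment_tissue(pseudo, closing_radius=closing_radius)
    summaries = []
    for wl in WAVELENGTHS:
        mean, sd, n = roi_stats(maps[wl], mask, valid=valids[wl])
        summaries.append(
            ROISummary(sample_id=sample_id, wavelength_nm=wl, t1_mm=t1_mm,
                       t2_mm=t2_mm, mean_docp=mean, sd_docp=sd, n_pixels=n)
        )
    dmap, shift = delta_docp(maps[617.0], maps[850.0],
                             registration=registration)
    dmap = np.where(valids[617.0] & valids[850.0], dmap, np.nan)
    d_mean, d_sd, d_n = roi_stats(dmap, mask)
    return {
        "summaries": summaries,
        "docp_maps": maps,
        "delta_map": dmap,
        "mask": mask,
        "pseudo_s0": pseudo,
        "registration_shift": shift,
        "delta_roi_pixelwise": (d_mean, d_sd, d_n),
    }


def _simulate_sample(phantom: LayeredPhantom, cfg: RunConfig, wl: float):
    seed = _sample_seed(cfg.seed, phantom.sample_id, wl)
    frame, truth, result = render_synthetic_frames(
        phantom,
        wl,
        spot=default_spot(wl),
        n_photons=cfg.n_photons,
        seed=seed,
        shape=cfg.scene_shape,
        gain=cfg.gain,
        noise_model=cfg.noise_model,
    )
    return frame, truth, result


def run_sweep(cfg: RunConfig, sweep: str) -> TrendTable:
    """Run one experiment end to end; returns the trend table and writes all
    artifacts under ``cfg.out_dir``."""
    if sweep not in ("T1", "T2"):
        raise ConfigError(f"sweep must be 'T1' or 'T2', got {sweep!r}")
    sample_ids = T1_SWEEP_SAMPLES if sweep == "T1" else T2_SWEEP_SAMPLES
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantoms = {
        p.sample_id: p
        for p in make_sample_set(
            cfg.total_thickness_mm,
            overrides_healthy=cfg.healthy_overrides,
            overrides_cancerous=cfg.cancerous_overrides,
        )
    }
    t_start = time.time()
    log: dict = {
        "sweep": sweep,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "samples": {},
    }
    summaries: List[ROISummary] = []
    sim_docp: Dict[str, Dict[str, float]] = {}
    for sid in sample_ids:
        ph = phantoms[sid]
        frames = {}
        try:
            for wl in WAVELENGTHS:
                if cfg.mode == "simulate":
                    frame, truth, result = _simulate_sample(ph, cfg, wl)
                    tag = f"sample{sid}_{int(wl)}nm"
                    cio.write_frame(frame, out / f"{tag}.tif",
                                    convention=DEFAULT_CONVENTION)
                    sim_docp.setdefault(sid, {})[str(int(wl))] = result.docp
                    log["samples"].setdefault(sid, {})[str(int(wl))] = {
                        "seed": frame.seed,
                        "simulated_docp": result.docp,
                        "docp_se": result.docp_se,
                        "audit": result.audit,
                    }
                else:
                    try:
                        path = cfg.frames[sid][str(int(wl))]
                    except KeyError as e:
                        raise StageError(
                            f"sample {sid}: no frame configured for "
                            f"{int(wl)} nm"
                        ) from e
                    if not Path(path).exists():
                        raise StageError(
                            f"sample {sid}: frame not found: {path}"
                        )
                    frame = cio.read_frame(path)
                frames[wl] = frame
            res = process_frames(
                frames[617.0], frames[850.0], sid, ph.t1_mm, ph.t2_mm,
                closing_radius=cfg.closing_radius,
                registration=cfg.registration,
            )
        except StageError:
            raise
        except Exception as e:
            raise StageError(f"sample {sid}: {e}") from e
        summaries.extend(res["summaries"])
        for wl in WAVELENGTHS:
            cio.write_map(res["docp_maps"][wl],
                          out / f"sample{sid}_docp_{int(wl)}nm.tif")
        cio.write_map(res["delta_map"], out / f"sample{sid}_ddocp.tif",
                      vmin=-0.5, vmax=0.5)
        entry = log["samples"].setdefault(sid, {})
        entry["roi"] = {
            str(int(s.wavelength_nm)): {"mean": s.mean_docp, "sd": s.sd_docp,
                                        "n": s.n_pixels}
            for s in res["summaries"]
        }
        entry["delta_roi_pixelwise"] = res["delta_roi_pixelwise"]

    trend = build_trend(summaries, sweep=sweep)
    trend.to_csv(out / f"trends_{sweep.lower()}.csv")
    sm = pd.DataFrame(
        [asdict(s) for s in summaries]
    ).sort_values(["sample_id", "wavelength_nm"], kind="mergesort")
    sm.to_csv(out / f"summaries_{sweep.lower()}.csv", index=False,
              float_format="%.6f")
    log["runtime_s"] = round(time.time() - t_start, 3)
    (out / f"runlog_{sweep.lower()}.json").write_text(
        json.dumps(log, indent=2, sort_keys=True, default=float) + "\n"
    )
    return trend


def run_t1_sweep(cfg: RunConfig) -> TrendTable:
    """Depth experiment: samples 1, 4, 5, 6 (T1 varies, T2 = 1.0 mm)."""
    return run_sweep(cfg, "T1")


def run_t2_sweep(cfg: RunConfig) -> TrendTable:
    """Volume experiment: samples 2, 3, 4 (T2 varies, T1 = 0.5 mm)."""
    return run_sweep(cfg, "T2")


def report(out_dir) -> Path:
    """Render trend plots and an index of the artifacts in ``out_dir``.

    Purely presentational: reads the CSV/TIFF artifacts and produces PNG
    figures plus a Markdown index.  Missing artifacts are listed as
    warnings, and regeneration is idempotent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# CiPLS run report", ""]
    warnings: List[str] = []
    for sweep in ("t1", "t2"):
        csv = out / f"trends_{sweep}.csv"
        if not csv.exists():
            warnings.append(f"missing {csv.name}")
            continue
        df = pd.read_csv(csv)
        xcol = "t1_mm" if sweep == "t1" else "t2_mm"
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.6))
        axes[0].errorbar(df[xcol], df["mean_docp_617"], yerr=df["sd_docp_617"],
                         color="red", marker="s", label="617 nm")
        axes[0].errorbar(df[xcol], df["mean_docp_850"], yerr=df["sd_docp_850"],
                         color="blue", marker="s", label="850 nm")
        axes[0].set_xlabel(f"{xcol.split('_')[0].upper()} (mm)")
        axes[0].set_ylabel("mean DOCP in tissue ROI")
        axes[0].legend()
        axes[1].plot(df[xcol], df["delta_docp"], color="black", marker="o")
        axes[1].set_xlabel(f"{xcol.split('_')[0].upper()} (mm)")
        axes[1].set_ylabel(r"$\Delta$DOCP (617 - 850)")
        fig.tight_layout()
        png = out / f"trend_{sweep}.png"
        fig.savefig(png, dpi=120)
        plt.close(fig)
        lines.append(f"## {sweep.upper()} sweep")
        lines.append("")
        lines.append(f"![{sweep} trend]({png.name})")
        lines.append("")
        lines.append(df.to_string(index=False))
        lines.append("")
    previews = sorted(out.glob("sample*_ddocp.png"))
    if previews:
        lines.append("## DeltaDOCP maps")
        lines.append("")
        for p in previews:
            lines.append(f"![{p.stem}]({p.name})")
        lines.append("")
    if warnings:
        lines.append("## Warnings")
        lines.append("")
        lines.extend(f"- {w}" for w in warnings)
        lines.append("")
    index = out / "report.md"
    index.write_text("\n".join(lines))
    return index
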