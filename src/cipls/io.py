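"""Frame and map I/O: grayscale TIFF/PNG rasters with sidecar metadata.

Raw mosaic frames travel as 16-bit single-channel grayscale TIFF (8-bit PNG
also accepted); acquisition metadata (sensor layout, wavelength, QWP flag,
gain, seed, bit depth, polarimetric convention) rides in a JSON sidecar
written next to each frame (``<stem>.meta.json``).  DOCP and DeltaDOCP maps
are exported as 32-bit float TIFF plus an 8-bit color-mapped PNG preview;
NaN (invalid) pixels are rendered black in the preview.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from cipls.conventions import DEFAULT_CONVENTION, PolarimetricConvention
from cipls.mosaic import MosaicFrame, MosaicLayout

__all__ = [
    "write_frame",
    "read_frame",
    "write_map",
    "read_map",
    "sidecar_path",
]


def sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_name(p.stem + ".meta.json")


def write_frame(
    frame: MosaicFrame,
    path,
    convention: PolarimetricConvention = DEFAULT_CONVENTION,
) -> Path:
    """Write a mosaic frame as 16-bit grayscale TIFF (or 8-bit PNG by
    extension) plus its JSON metadata sidecar.  Returns the sidecar path."""
    p = Path(path)
    data = np.asarray(frame.data)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(p, data.astype(np.uint16))
    elif p.suffix.lower() == ".png":
        if frame.bit_depth != 8:
            raise ValueError("PNG output supports only 8-bit frames")
        import imageio.v3 as iio

        iio.imwrite(p, data.astype(np.uint8))
    else:
        raise ValueError(f"unsupported frame format {p.suffix!r}")
    meta = {
        "layout": frame.layout.to_dict(),
        "wavelength_nm": frame.wavelength_nm,
        "qwp_present": frame.qwp_present,
        "bit_depth": frame.bit_depth,
        "gain": frame.gain,
        "seed": frame.seed,
        "convention": convention.to_dict(),
        **frame.meta,
    }
    sp = sidecar_path(p)
    sp.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return sp


def read_frame(path) -> MosaicFrame:
    """Read a mosaic frame and its sidecar back into a :class:`MosaicFrame`."""
    p = Path(path)
    sp = sidecar_path(p)
    if not sp.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sp}")
    meta = json.loads(sp.read_text())
    if p.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(p)
    elif p.suffix.lower() == ".png":
        import imageio.v3 as iio

        data = iio.imread(p)
    else:
        raise ValueError(f"unsupported frame format {p.suffix!r}")
    extra = {k: v for k, v in meta.items()
             if k not in ("layout", "wavelength_nm", "qwp_present",
                          "bit_depth", "gain", "seed", "convention")}
    return MosaicFrame(
        data=np.asarray(data),
        layout=MosaicLayout.from_dict(meta["layout"]),
        wavelength_nm=float(meta["wavelength_nm"]),
        qwp_present=bool(meta["qwp_present"]),
        bit_depth=int(meta["bit_depth"]),
        gain=float(meta["gain"]),
        seed=meta.get("seed"),
        meta=extra,
    )


def write_map(
    values: np.ndarray,
    path,
    preview: bool = True,
    vmin: float = -1.0,
    vmax: float = 1.0,
    cmap: str = "RdBu_r",
    meta: Optional[dict] = None,
) -> Path:
    """Write a DOCP/DeltaDOCP map as float32 TIFF, with an optional 8-bit
    color-mapped PNG preview next to it.  Returns the TIFF path."""
    p = Path(path)
    if p.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError("maps are written as float TIFF; pass a .tif path")
    arr = np.asarray(values, dtype=np.float32)
    tifffile.imwrite(p, arr)
    if meta is not None:
        sidecar_path(p).write_text(json.dumps(meta, indent=2, sort_keys=True)
                                   + "\n")
    if preview:
        import matplotlib

        matplotlib.use("Agg")
        import imageio.v3 as iio

        norm = (np.clip(arr, vmin, vmax) - vmin) / (vmax - vmin)
        rgba = matplotlib.colormaps[cmap](norm)
        rgba[~np.isfinite(arr)] = (0.0, 0.0, 0.0, 1.0)
        iio.imwrite(p.with_suffix(".png"),
                    (rgba[..., :3] * 255).astype(np.uint8))
    return p


def read_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
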