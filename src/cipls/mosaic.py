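"""Division-of-focal-plane (microgrid) polarization camera model.

The sensor carries a 2x2 mosaic of pixel-level wire-grid analyzers at
0/45/90/135 degrees.  One combined snapshot is split into four co-registered
half-resolution channel images ``I0, I45, I90, I135``; differences between
channels of the same superpixel give the Stokes images

    S1-image  = I0  - I90
    S2'-image = I45 - I135          (equal to -S3 when the QWP is present)
    pseudo-S0 = (I0 + I45 + I90 + I135) / 2

and the per-pixel degree of circular polarization is estimated as

    DOCP = -2 (I45 - I135) / (I0 + I45 + I90 + I135).

The forward direction (:func:`render_mosaic`) turns a per-pixel Stokes field
into a raw mosaic frame -- optionally through the QWP, with gain, shot noise
and quantization -- so the inverse chain can be tested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from cipls.polarimetry import analyzer_intensity, apply_mueller, qwp_mueller

__all__ = [
    "MosaicLayout",
    "MosaicFrame",
    "ChannelSet",
    "StokesImageSet",
    "DEFAULT_LAYOUT",
    "split_mosaic",
    "interleave",
    "stokes_images",
    "docp_image",
    "render_mosaic",
]

CHANNEL_ANGLES = (0, 45, 90, 135)


@dataclass(frozen=True)
class MosaicLayout:
    """2x2 grid of analyzer angles anchored at the frame's top-left pixel.

    ``angles[i][j]`` is the analyzer angle (degrees) of pixel (row i, col j)
    within each superpixel.  The four angles must be a permutation of
    {0, 45, 90, 135}; all 24 permutations are legal sensor layouts.
    """

    angles: tuple = ((90, 45), (135, 0))

    def __post_init__(self) -> None:
        a = tuple(tuple(int(x) for x in row) for row in self.angles)
        object.__setattr__(self, "angles", a)
        flat = sorted(a[0] + a[1])
        if flat != sorted(CHANNEL_ANGLES):
            raise ValueError(
                f"layout angles must be a permutation of {CHANNEL_ANGLES}, "
                f"got {self.angles}"
            )

    def position_of(self, angle: int) -> tuple:
        """(row, col) offset of the pixel carrying ``angle`` in a superpixel."""
        for i in (0, 1):
            for j in (0, 1):
                if self.angles[i][j] == angle:
                    return (i, j)
        raise KeyError(angle)  # pragma: no cover - excluded by invariant

    def to_dict(self) -> dict:
        return {"angles": [list(r) for r in self.angles]}

    @classmethod
    def from_dict(cls, d: dict) -> "MosaicLayout":
        return cls(angles=tuple(tuple(r) for r in d["angles"]))


#: Default anchor ordering, matching common four-directional wire-grid sensors.
DEFAULT_LAYOUT = MosaicLayout(((90, 45), (135, 0)))


@dataclass(frozen=True)
class MosaicFrame:
    """Raw interleaved microgrid sensor frame plus acquisition metadata."""

    data: np.ndarray
    layout: MosaicLayout = DEFAULT_LAYOUT
    wavelength_nm: float = 617.0
    qwp_present: bool = True
    bit_depth: int = 16
    gain: float = 1.0
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError(f"frame must be 2D, got shape {d.shape}")
        if d.shape[0] % 2 or d.shape[1] % 2:
            raise ValueError(f"frame dimensions must be even, got {d.shape}")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit depth must be 8, 12 or 16, got {self.bit_depth}")
        object.__setattr__(self, "data", d)

    @property
    def saturated(self) -> np.ndarray:
        """Boolean mask of pixels at full-scale (flagged invalid downstream)."""
        return np.asarray(self.data) >= (2**self.bit_depth - 1)


@dataclass(frozen=True)
class ChannelSet:
    """Four co-registered half-resolution analyzer-channel images."""

    i0: np.ndarray
    i45: np.ndarray
    i90: np.ndarray
    i135: np.ndarray
    valid: Optional[np.ndarray] = None  # per-superpixel validity

    def __post_init__(self) -> None:
        shapes = {np.shape(self.i0), np.shape(self.i45), np.shape(self.i90),
                  np.shape(self.i135)}
        if len(shapes) != 1:
            raise ValueError(f"channel images must share a shape, got {shapes}")
        if self.valid is not None and np.shape(self.valid) != np.shape(self.i0):
            raise ValueError("validity mask must match channel shape")

    @property
    def shape(self) -> tuple:
        return np.shape(self.i0)

    def channel(self, angle: int) -> np.ndarray:
        return {0: self.i0, 45: self.i45, 90: self.i90, 135: self.i135}[angle]


@dataclass(frozen=True)
class StokesImageSet:
    """Per-pixel pseudo-S0, S1 and S2' images derived from a channel set.

    When the frame was taken through the QWP at theta = 0, the S2' image is
    a ``-S3`` image (``s3 = -s2_prime``).
    """

    pseudo_s0: np.ndarray
    s1: np.ndarray
    s2_prime: np.ndarray
    qwp_present: bool = True

    @property
    def s3(self) -> np.ndarray:
        if not self.qwp_present:
            raise ValueError("S3 only available for frames taken through the QWP")
        return -self.s2_prime


def split_mosaic(frame: MosaicFrame) -> ChannelSet:
    """Separate a combined microgrid snapshot into four polarized images.

    No interpolation: channel pixel (r, c) is the single sensor pixel of
    superpixel (r, c) whose analyzer matches, so each channel has half the
    linear dimensions of the frame.  Saturated sensor pixels invalidate their
    superpixel.
    """
    d = np.asarray(frame.data, dtype=float)
    chans = {}
    for angle in CHANNEL_ANGLES:
        i, j = frame.layout.position_of(angle)
        chans[angle] = d[i::2, j::2]
    sat = frame.saturated
    valid = ~(sat[0::2, 0::2] | sat[0::2, 1::2] | sat[1::2, 0::2] | sat[1::2, 1::2])
    return ChannelSet(
        i0=chans[0], i45=chans[45], i90=chans[90], i135=chans[135], valid=valid
    )


def interleave(
    channels: ChannelSet,
    layout: MosaicLayout = DEFAULT_LAYOUT,
    **frame_kwargs,
) -> MosaicFrame:
    """Inverse of :func:`split_mosaic`: weave four channels into one frame."""
    h, w = channels.shape
    out = np.zeros((2 * h, 2 * w), dtype=float)
    for angle in CHANNEL_ANGLES:
        i, j = layout.position_of(angle)
        out[i::2, j::2] = channels.channel(angle)
    return MosaicFrame(data=out, layout=layout, **frame_kwargs)


def stokes_images(channels: ChannelSet, qwp_present: bool = True) -> StokesImageSet:
    """Stokes images by superpixel differencing.

    ``S1 = I0 - I90``; ``S2' = I45 - I135``; the pseudo total intensity is the
    halved four-channel sum (the ideal ``I0 + I90`` equals it for perfect
    pixels, but the four-channel form averages noise over all four samples).
    """
    s1 = channels.i0 - channels.i90
    s2p = channels.i45 - channels.i135
    pseudo_s0 = 0.5 * (channels.i0 + channels.i45 + channels.i90 + channels.i135)
    return StokesImageSet(pseudo_s0=pseudo_s0, s1=s1, s2_prime=s2p,
                          qwp_present=qwp_present)


def docp_image(channels: ChannelSet, qwp_present: bool = True):
    """Per-pixel DOCP map ``-2 (I45 - I135) / (I0 + I45 + I90 + I135)``.

    Valid only for frames acquired through the QWP.  Returns ``(map, valid)``
    where pixels with a zero pseudo-intensity denominator (or saturated
    superpixels) are masked invalid, not zero-filled; out-of-range values are
    preserved, never clipped.  A fully masked map triggers a warning.
    """
    if not qwp_present:
        raise ValueError("DOCP estimation requires the frame taken through the QWP")
    denom = channels.i0 + channels.i45 + channels.i90 + channels.i135
    valid = denom > 0
    if channels.valid is not None:
        valid = valid & channels.valid
    out = np.full(denom.shape, np.nan, dtype=float)
    np.divide(-2.0 * (channels.i45 - channels.i135), denom, out=out, where=valid)
    if not valid.any():
        import warnings

        warnings.warn("DOCP map is fully masked (zero-intensity frame?)",
                      stacklevel=2)
    return out, valid


def render_mosaic(
    stokes_field: np.ndarray,
    layout: MosaicLayout = DEFAULT_LAYOUT,
    qwp_present: bool = True,
    gain: float = 1.0,
    noise_model: str = "none",
    seed: Optional[int] = None,
    bit_depth: int = 16,
    quantize: bool = True,
    wavelength_nm: float = 617.0,
    qwp_theta_deg: float = 0.0,
) -> MosaicFrame:
    """Forward camera model: Stokes field -> raw mosaic frame.

    ``stokes_field`` has shape (H, W, 4) at **superpixel** resolution; the
    rendered frame is (2H, 2W), the field taken uniform within each 2x2
    superpixel (the instantaneous-field-of-view mismatch between the four
    channels is ignored).  Per pixel: optionally
    apply the QWP Mueller matrix, take the analyzer intensity at the layout
    angle, scale by ``gain`` (counts per unit S0), apply noise
    (``"none" | "shot"``), and (optionally) round half-up to integer counts
    saturating at full scale.  Deterministic for a fixed seed.
    """
    if gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    if noise_model not in ("none", "shot"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    f = np.asarray(stokes_field, dtype=float)
    if f.ndim != 3 or f.shape[-1] != 4:
        raise ValueError(f"stokes field must have shape (H, W, 4), got {f.shape}")
    if qwp_present:
        f = apply_mueller(qwp_mueller(qwp_theta_deg), f)
    full = np.repeat(np.repeat(f, 2, axis=0), 2, axis=1)
    h, w = full.shape[:2]
    ang = np.empty((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            ang[i, j] = layout.angles[i][j]
    angles = np.tile(ang, (h // 2, w // 2))
    counts = gain * analyzer_intensity(full, angles)
    if noise_model == "shot":
        rng = np.random.default_rng(seed)
        counts = rng.poisson(np.clip(counts, 0.0, None)).astype(float)
    if quantize:
        full_scale = 2**bit_depth - 1
        counts = np.clip(np.floor(counts + 0.5), 0, full_scale)
    return MosaicFrame(
        data=counts,
        layout=layout,
        wavelength_nm=wavelength_nm,
        qwp_present=qwp_present,
        bit_depth=bit_depth,
        gain=gain,
        seed=seed,
    )
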