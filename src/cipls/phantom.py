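"""Layered tissue phantoms and the synthetic imaging scene.

The buried-cancer phantom is a stack of three slabs -- healthy (thickness
T1, possibly absent), cancerous (thickness T2), healthy backing -- with
total thickness T > 3 mm, the thickness beyond which the probing light is
essentially not transmitted.  The only scatterers are cell nuclei, modelled
as homogeneous Mie spheres; cancerous nuclei are about twice the diameter of
normal ones, which is the contrast the two-wavelength DOCP measurement
reads out.  Muscle-fiber birefringence/anisotropy is omitted: it affects the
azimuth of the depolarized light but not the DOCP.

Illumination is right-handed CPL at +/-30 deg incidence with an elliptical
footprint (minor axis 25 mm; the major axis follows from the obliquity,
minor / cos 30 deg ~ 29 mm).  The circular purity of the delivered beam
falls off radially: DOCP is +1.00 at the spot center and +0.880 (617 nm) /
+0.955 (850 nm) at the farthest circumference, interpolated linearly in the
normalized elliptical radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from cipls.mie import MieTable, mie_table
from cipls.transport import TransportMedium, simulate_backscatter

__all__ = [
    "LayerSpec",
    "LayeredPhantom",
    "IlluminationSpot",
    "default_layer",
    "default_spot",
    "make_sample_set",
    "TABLE1_THICKNESSES",
    "rounded_rect_mask",
    "scene_stokes_field",
    "render_synthetic_frames",
    "scarab_scene",
    "OPTICAL_DEFAULTS",
]

# ---------------------------------------------------------------------------
# shipped optical defaults (see docs/methods.md for the calibration account)
# ---------------------------------------------------------------------------

#: Frozen default optical parameters for the two media (the outcome of the
#: calibration in scripts/calibrate_optics.py; see docs/methods.md).
#: Cancerous nuclei are exactly twice the normal diameter; each diameter
#: sits on a helicity-depolarization resonance of its medium (healthy at
#: 617 nm, cancerous at 850 nm), which is what makes the wavelength flip
#: resolvable at desk-scale photon counts.  The enlarged nuclei carry a
#: slightly lower effective index (chromatin dilution on swelling); the
#: bead-phantom-grade index contrasts keep per-event depolarization strong.
#: Number densities are of the order of one nucleus per cell volume.
OPTICAL_DEFAULTS: Dict[str, dict] = {
    "healthy": {
        "nucleus_diameter_um": 6.5,
        "number_density_mm3": 1.3e5,
        "n_particle": 1.68,
        "n_medium": 1.36,
        "mua_mm": 0.02,
    },
    "cancerous": {
        "nucleus_diameter_um": 13.0,
        "number_density_mm3": 1.6e5,
        "n_particle": 1.56,
        "n_medium": 1.36,
        "mua_mm": 0.02,
    },
}

#: Thicknesses of the six phantom samples, (T1, T2) in mm.
TABLE1_THICKNESSES: Tuple[Tuple[float, float], ...] = (
    (0.0, 1.0),
    (0.5, 0.1),
    (0.5, 0.5),
    (0.5, 1.0),
    (1.0, 1.0),
    (1.5, 1.0),
)


@dataclass(frozen=True)
class LayerSpec:
    """One slab: geometry plus the optical parameters of its medium."""

    thickness_mm: float
    nucleus_diameter_um: float
    number_density_mm3: float
    n_particle: float = 1.59
    n_medium: float = 1.36
    mua_mm: float = 0.02
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.thickness_mm > 0):
            raise ValueError(f"thickness must be > 0, got {self.thickness_mm}")
        if self.nucleus_diameter_um <= 0:
            raise ValueError("nucleus diameter must be positive")
        if self.number_density_mm3 <= 0:
            raise ValueError("number density must be positive")
        if self.mua_mm < 0:
            raise ValueError("absorption coefficient must be non-negative")

    @property
    def medium_key(self) -> tuple:
        return (
            round(self.nucleus_diameter_um, 6),
            round(self.n_particle, 6),
            round(self.n_medium, 6),
        )

    def mie(self, wavelength_nm: float) -> MieTable:
        return _cached_table(self.medium_key, wavelength_nm)

    def mus_mm(self, wavelength_nm: float) -> float:
        """Scattering coefficient mu_s = density * C_sca (mm^-1)."""
        return self.number_density_mm3 * self.mie(wavelength_nm).csca_mm2


def default_layer(kind: str, thickness_mm: float, **overrides) -> LayerSpec:
    """A healthy or cancerous slab with the shipped optical defaults."""
    if kind not in OPTICAL_DEFAULTS:
        raise ValueError(f"kind must be one of {sorted(OPTICAL_DEFAULTS)}")
    params = dict(OPTICAL_DEFAULTS[kind])
    params.update(overrides)
    return LayerSpec(thickness_mm=thickness_mm, name=kind, **params)


_TABLE_CACHE: Dict[tuple, MieTable] = {}
_MEDIUM_CACHE: Dict[tuple, TransportMedium] = {}


def _cached_table(medium_key: tuple, wavelength_nm: float) -> MieTable:
    key = medium_key + (round(wavelength_nm, 3),)
    if key not in _TABLE_CACHE:
        d, npart, nmed = medium_key
        _TABLE_CACHE[key] = mie_table(d, wavelength_nm, npart, nmed)
    return _TABLE_CACHE[key]


def _cached_medium(medium_key: tuple, wavelength_nm: float) -> TransportMedium:
    key = medium_key + (round(wavelength_nm, 3),)
    if key not in _MEDIUM_CACHE:
        _MEDIUM_CACHE[key] = TransportMedium(_cached_table(medium_key,
                                                           wavelength_nm))
    return _MEDIUM_CACHE[key]


@dataclass(frozen=True)
class LayeredPhantom:
    """Ordered slabs, top (illuminated) to bottom."""

    layers: Tuple[LayerSpec, ...]
    sample_id: str = ""
    t1_mm: float = 0.0
    t2_mm: float = 0.0
    lateral_extent_mm: float = 40.0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("phantom needs at least one layer")
        object.__setattr__(self, "layers", tuple(self.layers))
        bounds = self.z_bounds
        if not (np.diff(bounds) > 0).all():
            raise ValueError("layer boundaries must be strictly increasing")

    @property
    def z_bounds(self) -> np.ndarray:
        z = np.concatenate([[0.0],
                            np.cumsum([l.thickness_mm for l in self.layers])])
        return z

    @property
    def total_thickness_mm(self) -> float:
        return float(self.z_bounds[-1])

    def kernel_inputs(self, wavelength_nm: float) -> dict:
        """Flatten to the array form the transport kernel consumes."""
        n_medium = {l.n_medium for l in self.layers}
        if len(n_medium) != 1:
            raise ValueError(
                "internal boundaries are index-matched: all layers must share "
                f"n_medium, got {sorted(n_medium)}"
            )
        media: List[tuple] = []
        med_of_layer = np.empty(len(self.layers), dtype=np.int64)
        for i, l in enumerate(self.layers):
            if l.medium_key not in media:
                media.append(l.medium_key)
            med_of_layer[i] = media.index(l.medium_key)
        tms = [_cached_medium(k, wavelength_nm) for k in media]
        inv_cdf = np.stack([t.inv_cdf_theta for t in tms])
        r12 = np.stack([t.r12 for t in tms])
        r33 = np.stack([t.r33 for t in tms])
        r34 = np.stack([t.r34 for t in tms])
        return {
            "z_bounds": self.z_bounds,
            "mus": np.array([l.mus_mm(wavelength_nm) for l in self.layers]),
            "mua": np.array([l.mua_mm for l in self.layers]),
            "med_of_layer": med_of_layer,
            "inv_cdf_theta": inv_cdf,
            "r12": r12,
            "r33": r33,
            "r34": r34,
            "n_medium": float(self.layers[0].n_medium),
        }


@dataclass(frozen=True)
class IlluminationSpot:
    """Oblique elliptical CPL illumination with radial purity falloff."""

    incidence_deg: float = 30.0
    minor_axis_mm: float = 25.0
    center_docp: float = 1.0
    edge_docp: Dict[float, float] = field(
        default_factory=lambda: {617.0: 0.880, 850.0: 0.955}
    )
    power: float = 1.0

    def __post_init__(self) -> None:
        for v in list(self.edge_docp.values()) + [self.center_docp]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"DOCP profile values must be in [0, 1], got {v}")

    @property
    def major_axis_mm(self) -> float:
        """Footprint elongation from obliquity: minor / cos(incidence)."""
        return self.minor_axis_mm / np.cos(np.deg2rad(self.incidence_deg))

    def edge_docp_at(self, wavelength_nm: float) -> float:
        for wl, v in self.edge_docp.items():
            if abs(wl - wavelength_nm) < 1.0:
                return v
        raise KeyError(f"no edge DOCP configured for {wavelength_nm} nm")

    def docp_profile(self, rho, wavelength_nm: float):
        """Beam DOCP at normalized elliptical radius ``rho`` in [0, 1]."""
        edge = self.edge_docp_at(wavelength_nm)
        rho = np.asarray(rho, dtype=float)
        return self.center_docp + (edge - self.center_docp) * rho

    def sample_docp0(self, n: int, wavelength_nm: float, rng) -> np.ndarray:
        """Initial packet DOCP for ``n`` launch positions uniform over the
        elliptical footprint (area-uniform: rho = sqrt(u))."""
        rho = np.sqrt(rng.random(n))
        return self.docp_profile(rho, wavelength_nm)


def default_spot(wavelength_nm: Optional[float] = None) -> IlluminationSpot:
    """The shipped illumination geometry (both wavelengths configured)."""
    return IlluminationSpot()


def make_sample_set(
    total_mm: float = 3.5,
    overrides_healthy: Optional[dict] = None,
    overrides_cancerous: Optional[dict] = None,
) -> List[LayeredPhantom]:
    """The six buried-cancer phantoms: (T1, T2) pairs
    (0.0, 1.0), (0.5, 0.1), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0), (1.5, 1.0),
    each with a healthy backing filling up to ``total_mm`` (> 3 mm)."""
    if not (total_mm > 3.0):
        raise ValueError(f"total thickness must exceed 3 mm, got {total_mm}")
    oh = overrides_healthy or {}
    oc = overrides_cancerous or {}
    phantoms = []
    for i, (t1, t2) in enumerate(TABLE1_THICKNESSES, start=1):
        layers = []
        if t1 > 0:
            layers.append(default_layer("healthy", t1, **oh))
        layers.append(default_layer("cancerous", t2, **oc))
        backing = total_mm - t1 - t2
        layers.append(default_layer("healthy", backing, **oh))
        phantoms.append(
            LayeredPhantom(layers=tuple(layers), sample_id=str(i),
                           t1_mm=t1, t2_mm=t2)
        )
    return phantoms


# ---------------------------------------------------------------------------
# synthetic imaging scenes
# ---------------------------------------------------------------------------


def rounded_rect_mask(shape: tuple, fraction: float = 0.4,
                      corner_radius_frac: float = 0.2) -> np.ndarray:
    """Axis-aligned rounded rectangle centred in ``shape``, covering about
    ``fraction`` of the frame area -- the tissue slice geometry."""
    h, w = shape
    # rectangle with the frame's aspect ratio and the requested area
    scale = np.sqrt(fraction)
    rh, rw = h * scale / 2.0, w * scale / 2.0
    r = corner_radius_frac * min(rh, rw) * 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy = np.abs(yy - (h - 1) / 2.0)
    dx = np.abs(xx - (w - 1) / 2.0)
    # distance outside the radius-shrunk core rectangle
    ey = np.clip(dy - (rh - r), 0.0, None)
    ex = np.clip(dx - (rw - r), 0.0, None)
    return ey**2 + ex**2 <= r**2


def scene_stokes_field(
    tissue_stokes: np.ndarray,
    shape: tuple = (256, 256),
    tissue_fraction: float = 0.4,
    background_intensity: float = 0.05,
    background_docp: float = 0.02,
):
    """Superpixel-resolution Stokes raster for a phantom imaging scene.

    Tissue pixels carry ``tissue_stokes`` normalized to unit S0; the
    surrounding agarose background is dim and weakly polarized.  Returns
    ``(field, truth_mask)``.
    """
    s = np.asarray(tissue_stokes, dtype=float)
    if s.shape != (4,) or s[0] <= 0:
        raise ValueError("tissue_stokes must be a length-4 state with S0 > 0")
    s = s / s[0]
    mask = rounded_rect_mask(shape, tissue_fraction)
    field = np.zeros(shape + (4,), dtype=float)
    field[..., 0] = background_intensity
    field[..., 3] = background_intensity * background_docp
    field[mask] = s
    return field, mask


def scarab_scene(
    shape: tuple = (64, 64),
    reflector_fraction: float = 0.4,
    background_intensity: float = 0.3,
):
    """Synthetic stand-in for the chiral-reflector control target.

    A scene region that reflects **only left-handed** CPL under unpolarized
    illumination: Stokes (1, 0, 0, -1) inside the region, unpolarized
    background.  Its DOCP map must come out near -1 in the region and 0
    outside -- the sign check that the -S3 imaging chain resolves helicity.
    """
    mask = rounded_rect_mask(shape, reflector_fraction)
    field = np.zeros(shape + (4,), dtype=float)
    field[..., 0] = background_intensity
    field[mask, 0] = 1.0
    field[mask, 3] = -1.0
    return field, mask


def render_synthetic_frames(
    phantom: LayeredPhantom,
    wavelength_nm: float,
    spot: Optional[IlluminationSpot] = None,
    n_photons: int = 20_000,
    seed: int = 0,
    shape: tuple = (256, 256),
    gain: float = 10_000.0,
    noise_model: str = "shot",
    layout=None,
    backscatter=None,
):
    """Simulate a phantom and render it as a raw mosaic camera frame.

    Runs :func:`~cipls.transport.simulate_backscatter` (unless a precomputed
    ``backscatter`` result is passed), paints the detected Stokes state into
    a rounded-rectangle tissue region over a dim agarose background, and
    renders through the QWP + microgrid forward model with shot noise.

    Returns ``(frame, truth_mask, result)`` where ``truth_mask`` is the
    ground-truth tissue region at superpixel resolution.
    """
    from cipls.mosaic import DEFAULT_LAYOUT, render_mosaic

    if spot is None:
        spot = default_spot(wavelength_nm)
    if backscatter is None:
        backscatter = simulate_backscatter(
            phantom, wavelength_nm, spot=spot, n_photons=n_photons, seed=seed
        )
    field, mask = scene_stokes_field(backscatter.stokes, shape=shape)
    frame = render_mosaic(
        field,
        layout=DEFAULT_LAYOUT if layout is None else layout,
        qwp_present=True,
        gain=gain,
        noise_model=noise_model,
        seed=seed,
        wavelength_nm=wavelength_nm,
    )
    return frame, mask, backscatter
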