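"""Exact Stokes-Mueller algebra for the CiPLS optical chain.

The measurement chain is: sample -> quarter-wave plate (QWP, fast axis at
angle ``theta`` from vertical) -> pixel-level linear analyzers at
0/45/90/135 degrees.  A QWP at ``theta = 0`` maps (S0, S1, S2, S3) to
(S0, S1, -S3, S2), so the camera's "S2 image" taken through the QWP is a
``-S3`` image, from which the signed degree of circular polarization
DOCP = S3/S0 is recovered.

All angles at this interface are in **degrees**; conversion to radians is
internal.  Stokes vectors are plain length-4 float arrays (or arrays with a
trailing axis of length 4 for images); :class:`StokesVector` is a thin named
wrapper for scalar states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cipls.conventions import DEFAULT_CONVENTION, PolarimetricConvention

__all__ = [
    "StokesVector",
    "qwp_mueller",
    "apply_mueller",
    "analyzer_intensity",
    "docp",
    "is_physical",
]


@dataclass(frozen=True)
class StokesVector:
    """A four-element polarization state (S0, S1, S2, S3).

    S0 is total intensity (arbitrary linear units, >= 0); S1 the
    horizontal-minus-vertical linear preponderance; S2 the +45-minus--45
    linear preponderance; S3 the right-minus-left circular preponderance,
    all in the units of S0.
    """

    s0: float
    s1: float
    s2: float
    s3: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.s0, self.s1, self.s2, self.s3]).all():
            raise ValueError("Stokes components must be finite")
        if self.s0 < 0:
            raise ValueError(f"S0 must be non-negative, got {self.s0}")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.s0, self.s1, self.s2, self.s3], dtype=float)

    @classmethod
    def from_array(cls, a: np.ndarray) -> "StokesVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (4,):
            raise ValueError(f"expected shape (4,), got {a.shape}")
        return cls(*a)

    def is_physical(self, rtol: float = 1e-9) -> bool:
        """Whether S1^2 + S2^2 + S3^2 <= S0^2 (within tolerance).

        A validation flag only: unphysical states (possible under noise) are
        preserved, never silently clipped.
        """
        return is_physical(self.array, rtol=rtol)

    @property
    def dop(self) -> float:
        """Degree of polarization sqrt(S1^2+S2^2+S3^2)/S0."""
        if self.s0 <= 0:
            raise ValueError("degree of polarization undefined for S0 <= 0")
        return float(np.hypot(np.hypot(self.s1, self.s2), self.s3) / self.s0)


def is_physical(stokes: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Elementwise physicality check S1^2+S2^2+S3^2 <= S0^2 (1+rtol)."""
    s = np.asarray(stokes, dtype=float)
    pol2 = s[..., 1] ** 2 + s[..., 2] ** 2 + s[..., 3] ** 2
    return (s[..., 0] >= 0) & (pol2 <= s[..., 0] ** 2 * (1.0 + rtol) + 1e-300)


def qwp_mueller(
    theta_deg: float,
    convention: PolarimetricConvention = DEFAULT_CONVENTION,
) -> np.ndarray:
    """Mueller matrix of an ideal quarter-wave plate.

    ``theta_deg`` is the angle between the fast axis and the vertical
    (the reference recorded in ``convention.qwp_angle_reference``).  At
    ``theta = 0`` the matrix maps (S0, S1, S2, S3) -> (S0, S1, -S3, S2):
    the S2 slot of the output carries ``-S3`` of the input.

    Returns the 4x4 matrix

    .. code-block:: text

        [ 1        0               0          0       ]
        [ 0   cos^2(2t)   sin(2t)cos(2t)   sin(2t)    ]
        [ 0 sin(2t)cos(2t)   sin^2(2t)    -cos(2t)    ]
        [ 0    -sin(2t)       cos(2t)        0        ]

    which is the standard linear quarter-wave retarder with the fast-axis
    angle measured from vertical.  It is a rotation on the Poincare sphere:
    S0 and the degree of polarization are preserved exactly.
    """
    if not np.isfinite(theta_deg):
        raise ValueError("theta must be finite")
    if convention.qwp_angle_reference == "horizontal":
        # internal form is vertical-referenced
        theta_deg = theta_deg + 90.0
    t = np.deg2rad(theta_deg)
    c = np.cos(2.0 * t)
    s = np.sin(2.0 * t)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c * c, s * c, s],
            [0.0, s * c, s * s, -c],
            [0.0, -s, c, 0.0],
        ]
    )


def apply_mueller(m: np.ndarray, stokes) -> np.ndarray:
    """Apply a Mueller matrix to a Stokes vector or Stokes image.

    ``stokes`` may be a :class:`StokesVector`, a length-4 array, or an array
    whose trailing axis has length 4 (per-pixel states); the product is taken
    over that trailing axis.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"Mueller matrix must be 4x4, got {m.shape}")
    if isinstance(stokes, StokesVector):
        stokes = stokes.array
    s = np.asarray(stokes, dtype=float)
    if s.shape[-1] != 4:
        raise ValueError(f"trailing axis must have length 4, got {s.shape}")
    return s @ m.T


def analyzer_intensity(stokes, phi_deg) -> np.ndarray:
    """Intensity through an ideal linear analyzer at angle ``phi_deg``.

    Malus's law for partially polarized light:
    ``I(phi) = (S0 + S1 cos(2 phi) + S2 sin(2 phi)) / 2``,
    with ``phi`` measured from the horizontal image axis.  Broadcasts over
    Stokes images (trailing axis 4) and arrays of angles.
    """
    if isinstance(stokes, StokesVector):
        stokes = stokes.array
    s = np.asarray(stokes, dtype=float)
    if s.shape[-1] != 4:
        raise ValueError(f"trailing axis must have length 4, got {s.shape}")
    p = 2.0 * np.deg2rad(np.asarray(phi_deg, dtype=float))
    return 0.5 * (s[..., 0] + s[..., 1] * np.cos(p) + s[..., 2] * np.sin(p))


def docp(stokes) -> np.ndarray:
    """Signed degree of circular polarization S3/S0.

    The sign of S3 is meaningful (it carries the helicity of the scattered
    light), so this is **not** ``|S3|/S0``.  Scalar inputs with S0 <= 0 raise;
    for array inputs, pixels with S0 <= 0 come back NaN so the caller can
    mask them.
    """
    if isinstance(stokes, StokesVector):
        s = stokes.array
        if s[0] <= 0:
            raise ValueError("DOCP undefined for S0 <= 0")
        return float(s[3] / s[0])
    s = np.asarray(stokes, dtype=float)
    if s.shape[-1] != 4:
        raise ValueError(f"trailing axis must have length 4, got {s.shape}")
    if s.ndim == 1:
        if s[0] <= 0:
            raise ValueError("DOCP undefined for S0 <= 0")
        return float(s[3] / s[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(s[..., 0] > 0, s[..., 3] / s[..., 0], np.nan)
    return out
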