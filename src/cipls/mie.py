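"""Mie scattering tables for spherical cell-nucleus scatterers.

Computes, for a homogeneous sphere of diameter ``d`` in a non-absorbing
medium, the four independent scattering-matrix elements (m11, m12, m33, m34)
on an angle grid, plus cross-sections and the anisotropy ``g``.  For a sphere
the single-scattering Mueller matrix is

    M(theta) = [[m11, m12,   0,    0 ],
                [m12, m11,   0,    0 ],
                [ 0,   0,  m33,  m34 ],
                [ 0,   0, -m34,  m33 ]]

(m22 = m11 and m44 = m33 for homogeneous spheres), with

    m11 = (|S1|^2 + |S2|^2) / 2,    m12 = (|S2|^2 - |S1|^2) / 2,
    m33 = Re(S2 S1*),               m34 = Im(S2 S1*),

where S1(theta), S2(theta) are the complex amplitude functions built from
the Mie coefficients a_n, b_n.  The series is evaluated with the standard
stable scheme: downward recurrence for the logarithmic derivative
D_n(mx) = psi_n'(mx)/psi_n(mx), upward recurrence for the Riccati-Bessel
functions psi_n(x), chi_n(x), truncated at the Wiscombe order
N = x + 4.05 x^(1/3) + 2.

Wavelengths are given in vacuum; the size parameter uses the wavelength in
the host medium, x = pi d n_medium / lambda_vac, with relative index
m = n_particle / n_medium (real: the nucleus is taken non-absorbing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MieTable", "mie_table", "mie_coefficients", "amplitude_functions"]

#: Hard ceiling on the series order; beyond this the upward psi/chi
#: recurrences would need arbitrary precision.
_MAX_TERMS = 10_000


def _wiscombe_nmax(x: float) -> int:
    """Series truncation order (Wiscombe criterion)."""
    if x < 8:
        return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 1.0))
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


def mie_coefficients(x: float, m: float) -> tuple:
    """Mie coefficients (a_n, b_n), n = 1..N, for size parameter ``x`` and
    real relative refractive index ``m``.

    Uses downward recurrence (from 1.3x the truncation order) for the
    logarithmic derivative and upward recurrence for psi and chi.
    """
    if x <= 0:
        raise ValueError(f"size parameter must be positive, got {x}")
    if m <= 0:
        raise ValueError(f"relative index must be positive, got {m}")
    nmax = _wiscombe_nmax(x)
    if nmax > _MAX_TERMS:
        raise ValueError(
            f"size parameter x={x:g} needs {nmax} series terms "
            f"(> {_MAX_TERMS}); the series cannot be evaluated stably"
        )
    mx = m * x
    # logarithmic derivative D_n(mx), downward from well above nmax
    nstart = int(max(nmax + 16, np.ceil(1.3 * abs(mx)) + 16))
    d = 0.0
    dn = np.empty(nmax + 1)
    for n in range(nstart, 1, -1):
        # the step with index n yields D_{n-1}
        d = n / mx - 1.0 / (d + n / mx)
        if n - 1 <= nmax:
            dn[n - 1] = d
    dn[0] = 0.0  # unused

    n_arr = np.arange(1, nmax + 1, dtype=float)
    # Riccati-Bessel psi_n(x) = x j_n(x), chi_n(x) = -x y_n(x), upward
    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi_m1, psi_0 = np.cos(x), np.sin(x)  # psi_{-1}, psi_0
    chi_m1, chi_0 = -np.sin(x), np.cos(x)
    for n in range(1, nmax + 1):
        fac = (2 * n - 1) / x
        psi_m1, psi_0 = psi_0, fac * psi_0 - psi_m1
        chi_m1, chi_0 = chi_0, fac * chi_0 - chi_m1
        psi[n] = psi_0
        chi[n] = chi_0
    # need psi_{n-1}, chi_{n-1} too
    psi_prev = np.empty(nmax + 1)
    chi_prev = np.empty(nmax + 1)
    psi_prev[1], chi_prev[1] = np.sin(x), np.cos(x)
    psi_prev[2:] = psi[1:-1]
    chi_prev[2:] = chi[1:-1]

    psi_n = psi[1:]
    chi_n = chi[1:]
    psi_nm1 = psi_prev[1:]
    chi_nm1 = chi_prev[1:]
    xi_n = psi_n - 1j * chi_n
    xi_nm1 = psi_nm1 - 1j * chi_nm1
    dvec = dn[1:]

    ta = dvec / m + n_arr / x
    tb = dvec * m + n_arr / x
    a = (ta * psi_n - psi_nm1) / (ta * xi_n - xi_nm1)
    b = (tb * psi_n - psi_nm1) / (tb * xi_n - xi_nm1)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError(
            f"Mie series failed to converge for x={x:g}, m={m:g} "
            "(non-finite coefficients)"
        )
    return a, b


def amplitude_functions(
    a: np.ndarray, b: np.ndarray, mu: np.ndarray
) -> tuple:
    """Complex amplitude functions S1(theta), S2(theta) at cos(theta)=mu.

    Angular functions pi_n, tau_n by the standard upward recurrence.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    nmax = len(a)
    s1 = np.zeros(mu.shape, dtype=complex)
    s2 = np.zeros(mu.shape, dtype=complex)
    pi_nm1 = np.zeros_like(mu)  # pi_0
    pi_n = np.ones_like(mu)  # pi_1
    for n in range(1, nmax + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        s1 += f * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += f * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_nm1, pi_n = pi_n, ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
    return s1, s2


@dataclass(frozen=True)
class MieTable:
    """Tabulated single-scattering properties of a homogeneous sphere.

    Angles in radians on ``theta``; matrix elements in the amplitude-squared
    normalization (dimensionless; the phase function is m11 normalized over
    the sphere).  ``qsca``/``qext`` are efficiencies; ``csca``/``cext`` the
    cross-sections in mm^2; ``g`` the scattering anisotropy <cos theta>.
    """

    x: float
    m_rel: float
    diameter_um: float
    wavelength_nm: float
    theta: np.ndarray
    m11: np.ndarray
    m12: np.ndarray
    m33: np.ndarray
    m34: np.ndarray
    qsca: float
    qext: float
    g: float

    @property
    def csca_mm2(self) -> float:
        radius_mm = self.diameter_um * 1e-3 / 2.0
        return float(self.qsca * np.pi * radius_mm**2)

    @property
    def cext_mm2(self) -> float:
        radius_mm = self.diameter_um * 1e-3 / 2.0
        return float(self.qext * np.pi * radius_mm**2)

    def mueller(self, theta: float) -> np.ndarray:
        """4x4 single-scattering Mueller matrix at ``theta`` (interpolated)."""
        e = [np.interp(theta, self.theta, v)
             for v in (self.m11, self.m12, self.m33, self.m34)]
        m11, m12, m33, m34 = e
        return np.array(
            [
                [m11, m12, 0.0, 0.0],
                [m12, m11, 0.0, 0.0],
                [0.0, 0.0, m33, m34],
                [0.0, 0.0, -m34, m33],
            ]
        )

    def phase_function_norm(self) -> float:
        """Integral (2 pi / (k^2 Csca)) * int m11 sin(theta) dtheta.

        Equals 1 for a consistent table (k the wavenumber in the medium).
        """
        k = self.x / (self.diameter_um * 1e-3 / 2.0)  # mm^-1
        integral = np.trapezoid(self.m11 * np.sin(self.theta), self.theta)
        return float(2.0 * np.pi * integral / (k**2 * self.csca_mm2))


def mie_table(
    diameter_um: float,
    wavelength_nm: float,
    n_particle: float,
    n_medium: float,
    n_angles: int = 1801,
) -> MieTable:
    """Build a :class:`MieTable` for a sphere in a host medium.

    Parameters
    ----------
    diameter_um : sphere diameter in micrometres (> 0).
    wavelength_nm : vacuum wavelength in nanometres (> 0).
    n_particle, n_medium : real refractive indices (>= 1).
    n_angles : number of points on the uniform [0, pi] angle grid.
    """
    if diameter_um <= 0 or wavelength_nm <= 0:
        raise ValueError("diameter and wavelength must be positive")
    if n_particle < 1 or n_medium < 1:
        raise ValueError("refractive indices must be >= 1")
    lam_um = wavelength_nm * 1e-3
    x = np.pi * diameter_um * n_medium / lam_um
    m = n_particle / n_medium
    a, b = mie_coefficients(x, m)
    n = np.arange(1, len(a) + 1, dtype=float)

    qsca = float(2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2)))
    qext = float(2.0 / x**2 * np.sum((2 * n + 1) * (a + b).real))
    # anisotropy <cos theta>
    asym = (
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ).sum() + (
        (2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real
    ).sum()
    g = float(4.0 / (x**2 * qsca) * asym)

    theta = np.linspace(0.0, np.pi, n_angles)
    s1, s2 = amplitude_functions(a, b, np.cos(theta))
    m11 = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    m12 = 0.5 * (np.abs(s2) ** 2 - np.abs(s1) ** 2)
    cross = s2 * np.conj(s1)
    m33 = cross.real
    m34 = cross.imag
    return MieTable(
        x=float(x),
        m_rel=float(m),
        diameter_um=float(diameter_um),
        wavelength_nm=float(wavelength_nm),
        theta=theta,
        m11=m11,
        m12=m12,
        m33=m33,
        m34=m34,
        qsca=qsca,
        qext=qext,
        g=g,
    )
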