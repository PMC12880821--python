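"""Independent reference evaluation of the Mie series, used as the oracle.

Deliberately written by a different route than the package implementation:
Mie coefficients come straight from Riccati-Bessel functions built on
``scipy.special.spherical_jn`` / ``spherical_yn`` (no logarithmic-derivative
recurrence), and the angular functions pi_n, tau_n come from associated
Legendre polynomials via ``scipy.special.lpmn`` (no upward pi/tau
recurrence).  Slower but transparent; only used on small grids in tests.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def reference_coefficients(x: float, m: float):
    """Mie a_n, b_n from the textbook Riccati-Bessel formulas."""
    nmax = int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))
    n = np.arange(1, nmax + 1)
    jx = special.spherical_jn(n, x)
    jxp = special.spherical_jn(n, x, derivative=True)
    yx = special.spherical_yn(n, x)
    yxp = special.spherical_yn(n, x, derivative=True)
    jmx = special.spherical_jn(n, m * x)
    jmxp = special.spherical_jn(n, m * x, derivative=True)

    psi_x = x * jx
    psi_x_p = jx + x * jxp
    psi_mx = m * x * jmx
    psi_mx_p = jmx + m * x * jmxp
    xi_x = x * (jx + 1j * yx)
    xi_x_p = (jx + x * jxp) + 1j * (yx + x * yxp)

    a = (m * psi_mx * psi_x_p - psi_x * psi_mx_p) / (
        m * psi_mx * xi_x_p - xi_x * psi_mx_p
    )
    b = (psi_mx * psi_x_p - m * psi_x * psi_mx_p) / (
        psi_mx * xi_x_p - m * xi_x * psi_mx_p
    )
    return a, b


def _pi_tau_legendre(nmax: int, theta: float):
    """pi_n, tau_n at one angle from associated Legendre P_n^1.

    scipy's lpmn carries the Condon-Shortley phase, so P_1^1 = -sin(theta);
    Mie's pi_n = -P_n^1 / sin(theta) and tau_n = sin(theta) dP_n^1/dmu under
    that phase.  Endpoints use the known limits.
    """
    mu = np.cos(theta)
    sin_t = np.sin(theta)
    n = np.arange(1, nmax + 1)
    if sin_t < 1e-12:
        base = n * (n + 1) / 2.0
        if mu > 0:  # theta = 0
            return base, base
        sign = (-1.0) ** (n + 1)
        return sign * base, -sign * base
    arr = special.assoc_legendre_p_all(nmax, 1, mu, diff_n=1)
    pn1 = arr[0, 1:, 1]
    dpn1 = arr[1, 1:, 1]
    pi_n = -pn1 / sin_t
    tau_n = sin_t * dpn1
    return pi_n, tau_n


def reference_amplitudes(x: float, m: float, theta: np.ndarray):
    """S1(theta), S2(theta) via the Legendre route."""
    a, b = reference_coefficients(x, m)
    nmax = len(a)
    n = np.arange(1, nmax + 1)
    f = (2 * n + 1) / (n * (n + 1))
    s1 = np.empty(len(theta), dtype=complex)
    s2 = np.empty(len(theta), dtype=complex)
    for i, t in enumerate(np.asarray(theta, dtype=float)):
        pi_n, tau_n = _pi_tau_legendre(nmax, t)
        s1[i] = np.sum(f * (a * pi_n + b * tau_n))
        s2[i] = np.sum(f * (a * tau_n + b * pi_n))
    return s1, s2


def reference_matrix_elements(
    diameter_um: float, wavelength_nm: float, n_particle: float,
    n_medium: float, theta: np.ndarray,
):
    """m11, m12, m33, m34 on ``theta`` plus (qsca, g), all by the
    reference route."""
    x = np.pi * diameter_um * n_medium / (wavelength_nm * 1e-3)
    m = n_particle / n_medium
    s1, s2 = reference_amplitudes(x, m, theta)
    m11 = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    m12 = 0.5 * (np.abs(s2) ** 2 - np.abs(s1) ** 2)
    cross = s2 * np.conj(s1)
    a, b = reference_coefficients(x, m)
    n = np.arange(1, len(a) + 1)
    qsca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    g_num = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    ) + np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = 4.0 / (x**2 * qsca) * g_num
    return m11, m12, cross.real, cross.imag, float(qsca), float(g)
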