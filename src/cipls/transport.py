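"""Polarized photon-transport Monte Carlo in layered Mie media.

Photon packets carry a Stokes vector referenced to their **meridian plane**
(the plane containing the propagation direction and the depth axis).  At a
scattering event the Stokes vector is rotated into the scattering plane,
multiplied by the sphere's single-scattering Mueller matrix, rotated into the
new meridian, and renormalized so S0 tracks the statistical weight; the
scattering angles (theta, phi) are drawn from the polarized phase function
(theta from the m11 marginal, phi by rejection against the
m12-dependent azimuthal kernel), which makes the renormalization unbiased.

Geometry: slabs are stacked along +z (depth), laterally infinite, with the
illuminated surface at z = 0.  Internal layer boundaries are index-matched
(no Fresnel events); the top surface applies unpolarized-average Fresnel
reflection/refraction stochastically, with specular entry reflection excluded
from detection.  Detection accumulates every top-surface exit whose refracted
direction lies within an acceptance cone about the surface normal (a distant
normal-viewing camera), with the Stokes vector rotated to the fixed
laboratory meridian.  Mirror-type reflections at the top surface flip the
helicity (S3 -> -S3) as an ideal near-normal approximation.

Weight bookkeeping is exact: every unit of injected weight ends in one of
the buckets {specular, detected, escaped (top exit outside the acceptance
cone), transmitted (bottom exit), absorbed, roulette, cap}, so the audit
closes to floating-point precision.

Randomness is a counter-based splitmix64 stream keyed per photon from
``(seed, photon index)``: runs are bit-reproducible under any execution
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numba import njit

from cipls.mie import MieTable

__all__ = [
    "PhotonPacket",
    "BackscatterResult",
    "TransportMedium",
    "sample_scatter",
    "propagate",
    "simulate_backscatter",
]

# outcome codes returned by the single-photon tracer
OUT_DETECTED = 0
OUT_ESCAPED = 1
OUT_TRANSMITTED = 2
OUT_ROULETTE = 3
OUT_CAP = 4

# --------------------------------------------------------------------------
# counter-based RNG (splitmix64)
# --------------------------------------------------------------------------


@njit(cache=True, inline="always", fastmath=True)
def _rng_next(state):
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True, inline="always", fastmath=True)
def _uniform(state):
    state, z = _rng_next(state)
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _photon_state(seed, index):
    """Independent stream key for photon ``index`` under run ``seed``."""
    s = (np.uint64(seed) + np.uint64(1)) * np.uint64(0x9E3779B97F4A7C15)
    s = s ^ ((np.uint64(index) + np.uint64(1)) * np.uint64(0xBF58476D1CE4E5B9))
    # burn-in decorrelates nearby keys
    s, _ = _rng_next(s)
    s, _ = _rng_next(s)
    return s


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


@njit(cache=True, inline="always", fastmath=True)
def _meridian_parallel(ux, uy, uz):
    """Unit vector in the meridian plane, perpendicular to u (the
    'theta-hat' reference axis for the Stokes vector).  Near the poles the
    meridian is degenerate; fall back to the x-z plane."""
    # e = z_hat - (z_hat . u) u, normalized
    ex = -uz * ux
    ey = -uz * uy
    ez = 1.0 - uz * uz
    norm = np.sqrt(ex * ex + ey * ey + ez * ez)
    if norm < 1e-9:
        ex = 1.0 - ux * ux
        ey = -ux * uy
        ez = -ux * uz
        norm = np.sqrt(ex * ex + ey * ey + ez * ez)
    return ex / norm, ey / norm, ez / norm


@njit(cache=True, inline="always", fastmath=True)
def _rotate_stokes(s0, s1, s2, s3, cos2a, sin2a):
    """Rotate the Stokes reference frame by angle a about propagation."""
    return (
        s0,
        cos2a * s1 + sin2a * s2,
        -sin2a * s1 + cos2a * s2,
        s3,
    )


@njit(cache=True, fastmath=True)
def _scatter_event(
    ux, uy, uz, s1, s2, s3,
    inv_cdf_theta, r12, r33, r34, n_theta, state,
):
    """One polarized scattering event (meridian method).

    The packet Stokes vector is (1, s1, s2, s3) in the current meridian
    frame.  Returns the new direction, the new normalized Stokes components,
    and the RNG state.  Tabulated matrix-element ratios r12, r33, r34 are on
    a uniform theta grid of ``n_theta`` points over [0, pi]; ``inv_cdf_theta``
    maps uniform quantiles to theta under the m11 marginal.
    """
    # --- draw theta from the m11 marginal (inverse-CDF lookup) ---
    state, u = _uniform(state)
    k = len(inv_cdf_theta)
    pos = u * (k - 1)
    i = int(pos)
    if i >= k - 1:
        i = k - 2
    frac = pos - i
    theta = inv_cdf_theta[i] * (1.0 - frac) + inv_cdf_theta[i + 1] * frac
    cos_t = np.cos(theta)
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))

    # interpolate matrix-element ratios at theta
    tpos = theta * ((n_theta - 1) / np.pi)
    ti = int(tpos)
    if ti >= n_theta - 1:
        ti = n_theta - 2
    tf = tpos - ti
    a12 = r12[ti] * (1.0 - tf) + r12[ti + 1] * tf
    a33 = r33[ti] * (1.0 - tf) + r33[ti + 1] * tf
    a34 = r34[ti] * (1.0 - tf) + r34[ti + 1] * tf

    # --- draw phi | theta by rejection against 1 + a12 (s1 c + s2 s) ---
    lin = np.sqrt(s1 * s1 + s2 * s2)
    env = 1.0 + abs(a12) * lin
    cos_p = 1.0
    sin_p = 0.0
    cos2p = 1.0
    sin2p = 0.0
    for _ in range(10_000):
        state, u1 = _uniform(state)
        phi = 2.0 * np.pi * u1
        cos_p = np.cos(phi)
        sin_p = np.sin(phi)
        cos2p = cos_p * cos_p - sin_p * sin_p
        sin2p = 2.0 * sin_p * cos_p
        f = 1.0 + a12 * (s1 * cos2p + s2 * sin2p)
        state, u2 = _uniform(state)
        if u2 * env <= f:
            break

    # meridian basis at the current direction
    ex, ey, ez = _meridian_parallel(ux, uy, uz)
    # e_perp = u x e_par (right-handed (e_par, e_perp, u))
    px = uy * ez - uz * ey
    py = uz * ex - ux * ez
    pz = ux * ey - uy * ex

    # in-(scattering)-plane transverse vector at u
    qx = cos_p * ex + sin_p * px
    qy = cos_p * ey + sin_p * py
    qz = cos_p * ez + sin_p * pz

    # rotate Stokes reference from meridian into scattering plane: R(phi)
    t0, t1, t2, t3 = _rotate_stokes(1.0, s1, s2, s3, cos2p, sin2p)

    # apply the sphere Mueller matrix (m11-normalized)
    b0 = t0 + a12 * t1
    b1 = a12 * t0 + t1
    b2 = a33 * t2 + a34 * t3
    b3 = -a34 * t2 + a33 * t3

    # new direction
    vx = cos_t * ux + sin_t * qx
    vy = cos_t * uy + sin_t * qy
    vz = cos_t * uz + sin_t * qz
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    vx /= norm
    vy /= norm
    vz /= norm

    # scattering-plane transverse vector at the new direction
    # (in-plane, perpendicular to v): w = cos_t * q - sin_t * u
    wx = cos_t * qx - sin_t * ux
    wy = cos_t * qy - sin_t * uy
    wz = cos_t * qz - sin_t * uz

    # new meridian basis at v
    mx, my, mz = _meridian_parallel(vx, vy, vz)

    # rotation angle psi from w to m about v
    cos_psi = wx * mx + wy * my + wz * mz
    if cos_psi > 1.0:
        cos_psi = 1.0
    elif cos_psi < -1.0:
        cos_psi = -1.0
    # sin via triple product (w x m) . v
    cx = wy * mz - wz * my
    cy = wz * mx - wx * mz
    cz = wx * my - wy * mx
    sin_psi = cx * vx + cy * vy + cz * vz
    cos2q = cos_psi * cos_psi - sin_psi * sin_psi
    sin2q = 2.0 * sin_psi * cos_psi
    b0, b1, b2, b3 = _rotate_stokes(b0, b1, b2, b3, cos2q, sin2q)

    # renormalize so S0 tracks the weight (sampling was proportional to b0)
    if b0 <= 0.0:
        b0 = 1e-300
    return vx, vy, vz, b1 / b0, b2 / b0, b3 / b0, state


@njit(cache=True, inline="always")
def _fresnel_unpolarized(cos_i, n1, n2):
    """Unpolarized-average Fresnel reflectance for incidence cosine
    ``cos_i`` going from index n1 to n2.  Returns 1.0 beyond the critical
    angle."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _trace_one(
    ux, uy, uz, s1, s2, s3, w, z, layer,
    z_bounds, mus, mua, med_of_layer,
    inv_cdf_theta, r12, r33, r34,
    n_medium, sin_accept_int, w_min, p_survive, max_steps,
    state,
):
    """Trace one photon packet to termination.

    Returns ``(outcome, w_end, det_s0, det_s1, det_s2, det_s3, absorbed,
    n_steps, state)``.  ``det_*`` are the detector-frame Stokes components
    scaled by the exit weight (zero unless outcome == OUT_DETECTED);
    ``absorbed`` is the weight deposited along the whole path.
    """
    n_layers = len(mus)
    n_theta = r12.shape[1]
    absorbed = 0.0
    outcome = OUT_CAP
    det0 = det1 = det2 = det3 = 0.0
    steps = 0
    while steps < max_steps:
        steps += 1
        med = med_of_layer[layer]
        mu_s = mus[layer]
        mu_a = mua[layer]
        mu_t = mu_s + mu_a
        # path length to the layer boundary along uz
        if mu_t <= 0.0:
            step = 1e30  # ballistic: fly to a boundary
        else:
            state, u = _uniform(state)
            if u <= 0.0:
                u = 1e-300
            step = -np.log(u) / mu_t
        z_new = z + uz * step
        top = z_bounds[layer]
        bot = z_bounds[layer + 1]
        if uz < 0.0 and z_new < top:
            # move to the upper boundary; resume sampling there (memoryless)
            z = top
            if layer == 0:
                # top surface: Fresnel exit or internal reflection
                cos_i = -uz
                refl = _fresnel_unpolarized(cos_i, n_medium, 1.0)
                state, u = _uniform(state)
                if u < refl:
                    # ideal-mirror internal reflection: flip helicity
                    uz = -uz
                    s2 = -s2
                    s3 = -s3
                    continue
                sin_i = np.sqrt(max(0.0, 1.0 - cos_i * cos_i))
                if sin_i <= sin_accept_int:
                    # detected: rotate Stokes to the laboratory meridian
                    vx, vy, vz = ux, uy, uz
                    ex, ey, ez = _meridian_parallel(vx, vy, vz)
                    # detector reference: x-axis projected perpendicular to v
                    dx = 1.0 - vx * vx
                    dy = -vx * vy
                    dz = -vx * vz
                    dn = np.sqrt(dx * dx + dy * dy + dz * dz)
                    if dn > 1e-12:
                        dx /= dn
                        dy /= dn
                        dz /= dn
                        cos_g = ex * dx + ey * dy + ez * dz
                        if cos_g > 1.0:
                            cos_g = 1.0
                        elif cos_g < -1.0:
                            cos_g = -1.0
                        cx = ey * dz - ez * dy
                        cy = ez * dx - ex * dz
                        cz = ex * dy - ey * dx
                        sin_g = cx * vx + cy * vy + cz * vz
                        cos2g = cos_g * cos_g - sin_g * sin_g
                        sin2g = 2.0 * sin_g * cos_g
                        _, s1, s2, s3 = _rotate_stokes(1.0, s1, s2, s3,
                                                       cos2g, sin2g)
                    det0 = w
                    det1 = w * s1
                    det2 = w * s2
                    det3 = w * s3
                    outcome = OUT_DETECTED
                    break
                outcome = OUT_ESCAPED
                break
            layer -= 1
            continue
        if uz > 0.0 and z_new > bot:
            z = bot
            if layer == n_layers - 1:
                outcome = OUT_TRANSMITTED
                break
            layer += 1
            continue
        if mu_t <= 0.0:
            # non-scattering layer and uz == 0: nowhere to go
            outcome = OUT_CAP
            break
        # interaction
        z = z_new
        absorbed += w * (mu_a / mu_t)
        w *= mu_s / mu_t
        ux, uy, uz, s1, s2, s3, state = _scatter_event(
            ux, uy, uz, s1, s2, s3,
            inv_cdf_theta[med], r12[med], r33[med], r34[med], n_theta, state,
        )
        if w < w_min:
            state, u = _uniform(state)
            if u < p_survive:
                w /= p_survive
            else:
                outcome = OUT_ROULETTE
                break
    return outcome, w, det0, det1, det2, det3, absorbed, steps, state


@njit(cache=True)
def _run_batch(
    n_photons, seed,
    docp0, entry_ux, entry_uz, refl_entry,
    z_bounds, mus, mua, med_of_layer,
    inv_cdf_theta, r12, r33, r34,
    n_medium, sin_accept_int, w_min, p_survive, max_steps,
):
    """Trace ``n_photons`` packets; return detected sums, per-photon moment
    sums for the ratio-estimator standard error, and the weight audit."""
    sum_det = np.zeros(4)
    # moments of (a, b) = (w*s3_detected, w_detected) incl. zero contributions
    sum_a = 0.0
    sum_b = 0.0
    sum_a2 = 0.0
    sum_b2 = 0.0
    sum_ab = 0.0
    audit = np.zeros(7)  # specular, detected, escaped, transmitted,
    #                       absorbed, roulette, cap
    n_detected = 0
    total_steps = 0
    for i in range(n_photons):
        state = _photon_state(seed, i)
        state, u = _uniform(state)
        if u < refl_entry:
            audit[0] += 1.0
            continue
        outcome, w_end, d0, d1, d2, d3, absorbed, steps, state = _trace_one(
            entry_ux, 0.0, entry_uz, 0.0, 0.0, docp0[i], 1.0, 0.0, 0,
            z_bounds, mus, mua, med_of_layer,
            inv_cdf_theta, r12, r33, r34,
            n_medium, sin_accept_int, w_min, p_survive, max_steps, state,
        )
        total_steps += steps
        audit[4] += absorbed
        a = 0.0
        b = 0.0
        if outcome == OUT_DETECTED:
            sum_det[0] += d0
            sum_det[1] += d1
            sum_det[2] += d2
            sum_det[3] += d3
            audit[1] += w_end
            a = d3
            b = d0
            n_detected += 1
        elif outcome == OUT_ESCAPED:
            audit[2] += w_end
        elif outcome == OUT_TRANSMITTED:
            audit[3] += w_end
        elif outcome == OUT_ROULETTE:
            audit[5] += w_end
        else:
            audit[6] += w_end
        sum_a += a
        sum_b += b
        sum_a2 += a * a
        sum_b2 += b * b
        sum_ab += a * b
    return (sum_det, sum_a, sum_b, sum_a2, sum_b2, sum_ab, audit,
            n_detected, total_steps)


# --------------------------------------------------------------------------
# Python-facing containers and wrappers
# --------------------------------------------------------------------------


@dataclass
class PhotonPacket:
    """State of one packet during transport.

    ``stokes`` is referenced to the packet's meridian plane and kept
    normalized to S0 = 1; intensity bookkeeping lives in ``weight``.
    """

    position: np.ndarray
    direction: np.ndarray
    stokes: np.ndarray
    weight: float = 1.0
    layer: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        self.stokes = np.asarray(self.stokes, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, |u| = {n}")
        if not (0.0 < self.weight <= 1.0 + 1e-12):
            raise ValueError(f"weight must be in (0, 1], got {self.weight}")
        s = self.stokes
        dop2 = s[1] ** 2 + s[2] ** 2 + s[3] ** 2
        if dop2 > (s[0] ** 2) * (1.0 + 2e-9):
            raise ValueError("degree of polarization exceeds 1")


class TransportMedium:
    """Scattering medium prepared for the transport kernel: inverse-CDF
    lookup for theta sampling plus m11-normalized matrix-element ratios."""

    def __init__(self, table: MieTable, n_quantiles: int = 4096):
        self.table = table
        theta = table.theta
        pdf = table.m11 * np.sin(theta)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                               * np.diff(theta))])
        cdf /= cdf[-1]
        q = np.linspace(0.0, 1.0, n_quantiles)
        # strictly increasing cdf for interpolation (pdf > 0 everywhere
        # except possibly isolated zeros; nudge ties)
        cdf = np.maximum.accumulate(cdf)
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        self.inv_cdf_theta = np.interp(q, cdf[keep], theta[keep])
        with np.errstate(divide="ignore", invalid="ignore"):
            self.r12 = np.where(table.m11 > 0, table.m12 / table.m11, 0.0)
            self.r33 = np.where(table.m11 > 0, table.m33 / table.m11, 0.0)
            self.r34 = np.where(table.m11 > 0, table.m34 / table.m11, 0.0)


@dataclass(frozen=True)
class BackscatterResult:
    """Aggregate detected polarization state from a Monte Carlo run."""

    stokes: np.ndarray
    docp: float
    docp_se: float
    n_photons: int
    n_detected: int
    detected_weight: float
    audit: dict = field(repr=False)
    mean_steps: float = 0.0
    seed: Optional[int] = None
    wavelength_nm: Optional[float] = None

    @property
    def audit_residual(self) -> float:
        """|injected - sum(buckets)| / injected."""
        total = sum(self.audit.values())
        return abs(self.n_photons - total) / self.n_photons


def sample_scatter(
    packet: PhotonPacket, table, rng_seed: int = 0
) -> PhotonPacket:
    """Draw one polarized scattering event for ``packet``.

    ``table`` is a :class:`~cipls.mie.MieTable` or a prepared
    :class:`TransportMedium`.  Returns a new packet (position and weight
    unchanged; direction and meridian-frame Stokes state updated).
    """
    med = table if isinstance(table, TransportMedium) else TransportMedium(table)
    s = packet.stokes / packet.stokes[0]
    state = np.uint64(_photon_state(rng_seed, 0))
    ux, uy, uz = packet.direction
    n_theta = len(med.r12)
    vx, vy, vz, s1, s2, s3, _ = _scatter_event(
        ux, uy, uz, s[1], s[2], s[3],
        med.inv_cdf_theta, med.r12, med.r33, med.r34, n_theta, state,
    )
    return PhotonPacket(
        position=packet.position.copy(),
        direction=np.array([vx, vy, vz]),
        stokes=np.array([1.0, s1, s2, s3]),
        weight=packet.weight,
        layer=packet.layer,
    )


def propagate(packet: PhotonPacket, phantom, wavelength_nm: float,
              rng_seed: int = 0, max_steps: int = 100_000,
              acceptance_deg: float = 20.0,
              w_min: float = 1e-4, p_survive: float = 0.1) -> dict:
    """Trace a single packet through ``phantom`` to termination.

    Returns a dict with ``outcome`` in {"detected", "escaped",
    "transmitted", "roulette", "cap"}, the terminal ``weight``, the
    ``absorbed`` weight deposited en route, ``steps``, and (when detected)
    the detector-frame ``stokes`` contribution.
    """
    ker = phantom.kernel_inputs(wavelength_nm)
    state = np.uint64(_photon_state(rng_seed, 0))
    s = packet.stokes / packet.stokes[0]
    ux, uy, uz = packet.direction
    out = _trace_one(
        ux, uy, uz, s[1], s[2], s[3], packet.weight,
        float(packet.position[2]), int(packet.layer),
        ker["z_bounds"], ker["mus"], ker["mua"], ker["med_of_layer"],
        ker["inv_cdf_theta"], ker["r12"], ker["r33"], ker["r34"],
        ker["n_medium"],
        np.sin(np.deg2rad(acceptance_deg)) / ker["n_medium"],
        w_min, p_survive, max_steps, state,
    )
    outcome, w_end, d0, d1, d2, d3, absorbed, steps, _ = out
    names = {OUT_DETECTED: "detected", OUT_ESCAPED: "escaped",
             OUT_TRANSMITTED: "transmitted", OUT_ROULETTE: "roulette",
             OUT_CAP: "cap"}
    res = {"outcome": names[outcome], "weight": w_end, "absorbed": absorbed,
           "steps": steps}
    if outcome == OUT_DETECTED:
        res["stokes"] = np.array([d0, d1, d2, d3])
    return res


def simulate_backscatter(
    phantom,
    wavelength_nm: float,
    spot=None,
    n_photons: int = 100_000,
    seed: int = 0,
    acceptance_deg: float = 20.0,
    max_steps: int = 100_000,
    w_min: float = 1e-4,
    p_survive: float = 0.1,
) -> BackscatterResult:
    """Simulate oblique CPL illumination of a layered phantom and collect the
    backscattered polarization state.

    Packets launch with Stokes (1, 0, 0, DOCP0(r)), DOCP0 sampled over the
    elliptical spot profile of ``spot`` (center +1.00, per-wavelength edge
    value, linear radial interpolation) at the spot's incidence angle,
    refracted into the medium.  The aggregate DOCP is S3/S0 of the summed
    detected Stokes vectors; its standard error comes from the delta method
    for the ratio of correlated per-photon sums.  Bit-reproducible for a
    fixed ``(seed, config)``.
    """
    from cipls.phantom import default_spot

    if n_photons < 1000:
        raise ValueError("n_photons must be at least 1000")
    if spot is None:
        spot = default_spot(wavelength_nm)
    ker = phantom.kernel_inputs(wavelength_nm)
    rng = np.random.default_rng(np.uint32(seed))
    docp0 = spot.sample_docp0(n_photons, wavelength_nm, rng)

    inc = np.deg2rad(spot.incidence_deg)
    n_med = ker["n_medium"]
    refl_entry = _fresnel_unpolarized(np.cos(inc), 1.0, n_med)
    sin_t = np.sin(inc) / n_med
    entry_ux = sin_t
    entry_uz = np.sqrt(1.0 - sin_t**2)
    sin_accept_int = np.sin(np.deg2rad(acceptance_deg)) / n_med

    (sum_det, sum_a, sum_b, sum_a2, sum_b2, sum_ab, audit, n_detected,
     total_steps) = _run_batch(
        n_photons, seed, docp0, entry_ux, entry_uz, refl_entry,
        ker["z_bounds"], ker["mus"], ker["mua"], ker["med_of_layer"],
        ker["inv_cdf_theta"], ker["r12"], ker["r33"], ker["r34"],
        n_med, sin_accept_int, w_min, p_survive, max_steps,
    )
    if n_detected == 0:
        raise RuntimeError(
            "no photons detected; raise n_photons or widen the acceptance cone"
        )
    docp = sum_det[3] / sum_det[0]
    # delta-method SE of the ratio sum(a)/sum(b)
    n = n_photons
    mean_a = sum_a / n
    mean_b = sum_b / n
    var_a = sum_a2 / n - mean_a**2
    var_b = sum_b2 / n - mean_b**2
    cov_ab = sum_ab / n - mean_a * mean_b
    r = docp
    var_r = (var_a - 2.0 * r * cov_ab + r * r * var_b) / (n * mean_b**2)
    docp_se = float(np.sqrt(max(var_r, 0.0)))
    audit_dict = {
        "specular": float(audit[0]),
        "detected": float(audit[1]),
        "escaped": float(audit[2]),
        "transmitted": float(audit[3]),
        "absorbed": float(audit[4]),
        "roulette": float(audit[5]),
        "cap": float(audit[6]),
    }
    return BackscatterResult(
        stokes=sum_det.copy(),
        docp=float(docp),
        docp_se=docp_se,
        n_photons=n_photons,
        n_detected=int(n_detected),
        detected_weight=float(audit[1]),
        audit=audit_dict,
        mean_steps=total_steps / n_photons,
        seed=seed,
        wavelength_nm=wavelength_nm,
    )
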