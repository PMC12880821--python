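"""Calibration tool for the shipped phantom optical defaults.

The measurement rests on a wavelength-dependent contrast in how strongly
the two media depolarize circularly polarized light: at 617 nm the healthy
(small-nucleus) medium must scramble helicity faster than the cancerous
(large-nucleus) medium, and at 850 nm the other way round.  This script
makes that choice reproducible:

1. ``proxy``  -- scan candidate nucleus diameters and print the per-event
   helicity-decay rate sigma_c = -ln <m33/m11> (phase-function weighted)
   and Qsca at both wavelengths, to locate diameter pairs whose resonances
   realize the flip;
2. ``verify`` -- run the polarized Monte Carlo on semi-infinite slabs of
   both media at both wavelengths for a candidate parameter set and report
   the detected-DOCP contrasts with standard errors.

The shipped defaults in ``cipls.phantom.OPTICAL_DEFAULTS`` are the frozen
outcome of this procedure (see docs/methods.md).

Usage:
    python scripts/calibrate_optics.py proxy --d-min 3 --d-max 16
    python scripts/calibrate_optics.py verify --dh 6.5 --rh 1.3e5 \
        --dc 13.0 --rc 1.6e5 --n-photons 30000
"""

from __future__ import annotations

import argparse
import math

import numpy as np


def sigma_c(diameter_um: float, wavelength_nm: float, n_particle: float,
            n_medium: float):
    """Per-event helicity decay rate and Qsca for one sphere."""
    from cipls.mie import mie_table

    t = mie_table(diameter_um, wavelength_nm, n_particle, n_medium)
    w = t.m11 * np.sin(t.theta)
    p = w / np.trapezoid(w, t.theta)
    a33 = np.where(t.m11 > 0, t.m33 / t.m11, 1.0)
    mean = np.trapezoid(a33 * p, t.theta)
    return -math.log(max(mean, 1e-9)), t.qsca, t.csca_mm2


def cmd_proxy(args) -> None:
    print("d_um : sigma617 sigma850  Qsca617 Qsca850")
    for d in np.arange(args.d_min, args.d_max + 1e-9, args.d_step):
        s6, q6, _ = sigma_c(d, 617.0, args.n_particle, args.n_medium)
        s8, q8, _ = sigma_c(d, 850.0, args.n_particle, args.n_medium)
        print(f"{d:5.2f}: {s6:.4f}  {s8:.4f}   {q6:.2f}  {q8:.2f}")


def cmd_verify(args) -> None:
    from cipls.phantom import LayeredPhantom, LayerSpec
    from cipls.transport import simulate_backscatter

    def semi(d, rho, npart, wl):
        lay = LayerSpec(args.thickness, d, rho, npart,
                        args.n_medium, args.mua)
        ph = LayeredPhantom(layers=(lay,))
        return simulate_backscatter(ph, wl, n_photons=args.n_photons,
                                    seed=args.seed)

    for wl in (617.0, 850.0):
        h = semi(args.dh, args.rh, args.nh, wl)
        c = semi(args.dc, args.rc, args.nc, wl)
        gap = h.docp - c.docp
        se = math.hypot(h.docp_se, c.docp_se)
        want = "H < C" if wl == 617.0 else "H > C"
        ok = (gap < 0) if wl == 617.0 else (gap > 0)
        print(
            f"{int(wl)} nm: healthy {h.docp:+.4f}+-{h.docp_se:.4f}  "
            f"cancerous {c.docp:+.4f}+-{c.docp_se:.4f}  "
            f"gap {gap:+.4f} ({gap / se:+.1f} SE)  want {want}: "
            f"{'ok' if ok else 'NOT met'}"
        )


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    sub = ap.add_subparsers(dest="cmd", required=True)

    p = sub.add_parser("proxy", help="single-scattering depolarization scan")
    p.add_argument("--d-min", type=float, default=3.0)
    p.add_argument("--d-max", type=float, default=18.0)
    p.add_argument("--d-step", type=float, default=0.25)
    p.add_argument("--n-particle", type=float, default=1.68)
    p.add_argument("--n-medium", type=float, default=1.36)
    p.set_defaults(func=cmd_proxy)

    v = sub.add_parser("verify", help="Monte Carlo contrast check")
    v.add_argument("--dh", type=float, required=True,
                   help="healthy nucleus diameter (um)")
    v.add_argument("--rh", type=float, required=True,
                   help="healthy number density (mm^-3)")
    v.add_argument("--dc", type=float, required=True)
    v.add_argument("--rc", type=float, required=True)
    v.add_argument("--nh", type=float, default=1.68,
                   help="healthy particle index")
    v.add_argument("--nc", type=float, default=1.56,
                   help="cancerous particle index")
    v.add_argument("--n-medium", type=float, default=1.36)
    v.add_argument("--mua", type=float, default=0.02)
    v.add_argument("--thickness", type=float, default=6.0)
    v.add_argument("--n-photons", type=int, default=30_000)
    v.add_argument("--seed", type=int, default=41)
    v.set_defaults(func=cmd_verify)

    args = ap.parse_args()
    args.func(args)


if __name__ == "__main__":
    main()
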