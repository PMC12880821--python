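"""Polarized Monte Carlo transport: sampling distributions, rotations,
weight conservation, boundary behavior and determinism.

Photon counts here are kept small (10^3 - 10^5) so the suite stays fast;
statistical assertions carry seeded tolerances.
"""

import numpy as np
import pytest
from scipy import stats

from cipls.mie import mie_table
from cipls.phantom import LayeredPhantom, LayerSpec, default_layer
from cipls.transport import (
    PhotonPacket,
    TransportMedium,
    propagate,
    sample_scatter,
    simulate_backscatter,
)


@pytest.fixture(scope="module")
def healthy_table():
    return mie_table(6.5, 617.0, 1.68, 1.36)


@pytest.fixture(scope="module")
def healthy_medium(healthy_table):
    return TransportMedium(healthy_table)


def packet(direction=(0, 0, 1.0), stokes=(1.0, 0, 0, 1.0), z=1.0):
    return PhotonPacket(
        position=np.array([0.0, 0.0, z]),
        direction=np.array(direction, dtype=float),
        stokes=np.array(stokes, dtype=float),
    )


def thick_slab(kind="healthy", thickness=6.0):
    return LayeredPhantom(layers=(default_layer(kind, thickness),),
                          sample_id=kind)


class TestSampleScatter:
    def test_theta_histogram_matches_phase_function(self, healthy_table,
                                                    healthy_medium):
        """Empirical scattering angles for unpolarized input follow the
        m11-weighted phase function (chi-squared, fixed seeds)."""
        n = 30_000
        p = packet(stokes=(1.0, 0, 0, 0))
        cos_out = np.empty(n)
        for i in range(n):
            out = sample_scatter(p, healthy_medium, rng_seed=i)
            cos_out[i] = out.direction[2]
        theta_out = np.arccos(np.clip(cos_out, -1, 1))
        # expected bin probabilities from the tabulated phase function
        t = healthy_table
        pdf = t.m11 * np.sin(t.theta)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                               * np.diff(t.theta))])
        cdf /= cdf[-1]
        qs = np.linspace(0.0, 1.0, 16)
        edges = np.interp(qs, cdf, t.theta)
        counts, _ = np.histogram(theta_out, bins=edges)
        expected = np.full(15, n / 15.0)
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=14) > 0.01

    def test_rotations_preserve_intensity_and_dop(self, healthy_medium, rng):
        """S0 tracks weight (renormalized to 1) and the degree of
        polarization never exceeds 1."""
        for i in range(200):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            s3 = rng.uniform(-1, 1)
            lin = np.sqrt(1 - s3**2) * rng.uniform(0, 1)
            ang = rng.uniform(0, 2 * np.pi)
            p = packet(direction=v,
                       stokes=(1.0, lin * np.cos(ang), lin * np.sin(ang), s3))
            out = sample_scatter(p, healthy_medium, rng_seed=1000 + i)
            assert out.stokes[0] == pytest.approx(1.0)
            dop = np.linalg.norm(out.stokes[1:])
            assert dop <= 1.0 + 1e-9
            assert np.linalg.norm(out.direction) == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_single_backscatter_flips_helicity(self, healthy_table):
        """Near-180-degree scattering of pure CPL from a sphere reverses
        the sign of S3/S0 (standard helicity-flip property)."""
        m = healthy_table.mueller(np.pi - 1e-6)
        s_in = np.array([1.0, 0.0, 0.0, 1.0])
        s_out = m @ s_in
        assert s_out[3] / s_out[0] == pytest.approx(-1.0, abs=1e-3)

    def test_forward_scattering_leaves_stokes_unchanged(self, healthy_table):
        m = healthy_table.mueller(0.0)
        s_in = np.array([1.0, 0.3, 0.2, 0.5])
        s_out = m @ s_in
        np.testing.assert_allclose(s_out / s_out[0], s_in, atol=1e-9)


class TestPropagate:
    def test_ballistic_limit_transmits_everything(self):
        """mu_s = 0 everywhere: oblique packets fly straight through and
        exit the bottom; nothing is detected."""
        lay = LayerSpec(3.5, 6.5, 1.0, 1.68, 1.36, 0.0)  # density -> mus ~ 0
        ph = LayeredPhantom(layers=(lay,))
        n_transmitted = 0
        for i in range(50):
            p = packet(direction=(np.sin(0.3), 0, np.cos(0.3)),
                       stokes=(1, 0, 0, 1), z=0.0)
            out = propagate(p, ph, 617.0, rng_seed=i)
            assert out["outcome"] in ("transmitted",)
            n_transmitted += 1
        assert n_transmitted == 50

    def test_deeply_buried_layer_is_invisible(self):
        """A cancer layer below a 10 mm healthy top is beyond the
        penetration depth: detected DOCP equals the all-healthy phantom's
        within 3 combined MC standard errors."""
        deep = LayeredPhantom(layers=(default_layer("healthy", 10.0),
                                      default_layer("cancerous", 1.0),
                                      default_layer("healthy", 1.0)))
        uniform = LayeredPhantom(layers=(default_layer("healthy", 12.0),))
        r_deep = simulate_backscatter(deep, 617.0, n_photons=20_000, seed=3)
        r_uni = simulate_backscatter(uniform, 617.0, n_photons=20_000, seed=3)
        se = np.hypot(r_deep.docp_se, r_uni.docp_se)
        assert abs(r_deep.docp - r_uni.docp) < 3 * se


class TestSimulateBackscatter:
    def test_weight_audit_closes(self):
        """Injected weight = sum over termination buckets, to < 1e-3
        relative at 1e4 photons (it closes to float precision)."""
        r = simulate_backscatter(thick_slab(), 617.0, n_photons=10_000, seed=5)
        assert r.audit_residual < 1e-3
        assert r.audit_residual < 1e-9  # exact bookkeeping in practice

    def test_same_seed_bit_identical(self):
        r1 = simulate_backscatter(thick_slab(), 850.0, n_photons=5_000, seed=11)
        r2 = simulate_backscatter(thick_slab(), 850.0, n_photons=5_000, seed=11)
        assert r1.docp == r2.docp
        np.testing.assert_array_equal(r1.stokes, r2.stokes)
        assert r1.audit == r2.audit

    def test_different_seeds_differ(self):
        r1 = simulate_backscatter(thick_slab(), 850.0, n_photons=5_000, seed=11)
        r2 = simulate_backscatter(thick_slab(), 850.0, n_photons=5_000, seed=12)
        assert r1.docp != r2.docp

    def test_docp0_linearity_thin_slab(self):
        """Halving the incident S3 halves the detected S3 in the optically
        thin, single-scattering-dominated limit (Stokes transport is
        linear)."""
        from cipls.phantom import IlluminationSpot

        thin = LayeredPhantom(
            layers=(LayerSpec(0.02, 6.5, 4.0e5, 1.68, 1.36, 0.0),)
        )
        full = IlluminationSpot(edge_docp={617.0: 1.0, 850.0: 1.0})
        half = IlluminationSpot(edge_docp={617.0: 0.5, 850.0: 0.5},
                                center_docp=0.5)
        r_full = simulate_backscatter(thin, 617.0, spot=full,
                                      n_photons=200_000, seed=21,
                                      acceptance_deg=90.0)
        r_half = simulate_backscatter(thin, 617.0, spot=half,
                                      n_photons=200_000, seed=21,
                                      acceptance_deg=90.0)
        s3_ratio = (r_half.stokes[3] / r_half.stokes[0]) / (
            r_full.stokes[3] / r_full.stokes[0]
        )
        assert s3_ratio == pytest.approx(0.5, abs=0.05)

    def test_depolarization_monotone_in_scattering_depth(self):
        """More scattering depolarizes more: on a thick slab at fixed
        absorption, scaling the scatterer density up never increases the
        detected |DOCP| (3-SE tolerance, seeded)."""
        docps, ses = [], []
        for mult in (0.5, 1.0, 2.0):
            ph = LayeredPhantom(layers=(
                default_layer("healthy", 6.0,
                              number_density_mm3=1.5e5 * mult),))
            r = simulate_backscatter(ph, 617.0, n_photons=30_000, seed=31)
            docps.append(abs(r.docp))
            ses.append(r.docp_se)
        for i in range(len(docps) - 1):
            se = np.hypot(ses[i], ses[i + 1])
            assert docps[i + 1] <= docps[i] + 3 * se

    def test_too_few_photons_rejected(self):
        with pytest.raises(ValueError, match="n_photons"):
            simulate_backscatter(thick_slab(), 617.0, n_photons=10, seed=1)


class TestPhotonPacket:
    def test_direction_must_be_unit(self):
        with pytest.raises(ValueError, match="unit"):
            PhotonPacket(position=np.zeros(3), direction=np.array([0, 0, 2.0]),
                         stokes=np.array([1.0, 0, 0, 0]))

    def test_overpolarized_state_rejected(self):
        with pytest.raises(ValueError, match="polarization"):
            PhotonPacket(position=np.zeros(3), direction=np.array([0, 0, 1.0]),
                         stokes=np.array([1.0, 1.0, 1.0, 1.0]))
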