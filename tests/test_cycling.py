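"""Internal-cycling transfers: isotope preferences, conservation, Rayleigh."""

import logging

import numpy as np
import pytest

from feiso.cycling import (
    CyclingParams,
    clip_to_donor,
    colloidal_pump_transfer,
    recycle_and_bacteria,
    remineralize_transfer,
    scavenge_transfer,
    uptake_transfer,
)
from feiso.isotopes import IsotopePool, delta_of, pool_from_total_delta
from feiso.speciation import Speciation


def params(**kw):
    return CyclingParams(**kw)


def apply_pair(pool, pair, dt=1.0, sign=-1):
    return IsotopePool(pool.fe56 + sign * pair.j56 * dt, pool.fe54 + sign * pair.j54 * dt)


class TestUptake:
    def test_alpha_one_passthrough(self):
        dfe = pool_from_total_delta(1e-6, 0.3)
        pair = uptake_transfer(dfe, 1e-9, params(alpha_uptake=1.0))
        assert pair.delta() == pytest.approx(0.3, abs=1e-9)

    def test_light_preference_and_residual_drift(self):
        dfe = pool_from_total_delta(1e-6, 0.0)
        pair = uptake_transfer(dfe, 1e-8, params())
        assert pair.delta() == pytest.approx(-0.5, abs=1e-6)
        residual = apply_pair(dfe, pair, dt=10.0)
        assert delta_of(residual) > 0.0      # residual dissolved pool drifts heavy

    def test_repeated_uptake_monotone(self):
        dfe = pool_from_total_delta(1.0, 0.0)
        p = params()
        last = delta_of(dfe)
        for _ in range(20):
            pair = uptake_transfer(dfe, 0.02 * dfe.total, p)
            dfe = apply_pair(dfe, pair)
            now = delta_of(dfe)
            assert now > last
            last = now


class TestScavenging:
    def test_no_preference_when_alpha_one(self):
        dfe = pool_from_total_delta(1e-6, 0.2)
        spec = Speciation(fe_prime=1e-8, feL=1e-6 - 1e-8)
        pair = scavenge_transfer(dfe, spec, 1.0, params(alpha_complex=1.0))
        assert pair.delta() == pytest.approx(0.2, abs=1e-9)

    def test_removes_light_iron(self):
        # inverse fractionation factor: transferred delta is (1/a - 1)*1000
        dfe = pool_from_total_delta(1e-6, 0.0)
        spec = Speciation(fe_prime=1e-8, feL=1e-6 - 1e-8)
        pair = scavenge_transfer(dfe, spec, 1.0, params())
        expected = (1.0 / 1.0006 - 1.0) * 1000.0
        assert pair.delta() == pytest.approx(expected, abs=1e-10)
        assert pair.delta() == pytest.approx(-0.5997, abs=1e-3)

    def test_bulk_rate_scales_with_particles_and_feprime(self):
        dfe = pool_from_total_delta(1e-6, 0.0)
        spec = Speciation(fe_prime=2e-8, feL=1e-6 - 2e-8)
        p = params()
        pair = scavenge_transfer(dfe, spec, 3.0, p)
        assert pair.total == pytest.approx(p.k_scavenge * 3.0 * 2e-8, rel=1e-12)

    def test_rayleigh_closed_box(self):
        # pure scavenging of a closed pool follows the Rayleigh form with
        # epsilon = (1/alpha - 1) * 1000
        p = params()
        alpha = 1.0 / p.alpha_complex
        dfe = pool_from_total_delta(1.0, 0.0)
        total0 = dfe.total
        n = 3000
        frac = 1.0 - 0.1 ** (1.0 / n)
        for _ in range(n):
            spec = Speciation(fe_prime=frac * dfe.total, feL=(1 - frac) * dfe.total)
            pair = scavenge_transfer(dfe, spec, 1.0 / p.k_scavenge, p)
            dfe = apply_pair(dfe, pair)
        f = dfe.total / total0
        expected = 1000.0 * (alpha - 1.0) * np.log(f)
        assert abs(delta_of(dfe) - expected) / abs(expected) < 0.01


class TestColloidalPumping:
    def test_neutral_when_alpha_one(self):
        dfe = pool_from_total_delta(1e-6, -0.1)
        spec = Speciation(fe_prime=1e-8, feL=1e-6 - 1e-8)
        pair = colloidal_pump_transfer(dfe, spec, params(alpha_complex=1.0))
        assert pair.delta() == pytest.approx(-0.1, abs=1e-9)

    def test_removes_heavy_iron(self):
        dfe = pool_from_total_delta(1e-6, 0.0)
        spec = Speciation(fe_prime=1e-8, feL=1e-6 - 1e-8)
        pair = colloidal_pump_transfer(dfe, spec, params())
        assert pair.delta() == pytest.approx(0.6, abs=1e-6)
        assert pair.delta() > 0

    def test_acts_on_colloidal_half_of_feL(self):
        dfe = pool_from_total_delta(1e-6, 0.0)
        spec = Speciation(fe_prime=1e-8, feL=8e-7)
        p = params()
        pair = colloidal_pump_transfer(dfe, spec, p)
        assert pair.total == pytest.approx(p.k_colloidal * 0.5 * 8e-7, rel=1e-12)

    def test_symmetric_removal_cancels_to_first_order(self):
        # equal bulk scavenging (1/a) and pumping (a) fluxes leave the
        # dissolved delta unchanged to first order in (a - 1)
        dfe = pool_from_total_delta(1.0, 0.0)
        p = params()
        spec = Speciation(fe_prime=0.01, feL=0.5)
        scav = scavenge_transfer(dfe, spec, 1.0, p)
        pump = colloidal_pump_transfer(dfe, spec, p)
        bulk = 0.01
        scav = scav.scaled(bulk / scav.total)
        pump = pump.scaled(bulk / pump.total)
        after = apply_pair(apply_pair(dfe, scav), pump)
        # an uncancelled removal of 2% at +-0.6 permil would shift the pool
        # by ~0.012 permil; the symmetric pair must do far better
        assert abs(delta_of(after)) < 1e-4


class TestRemineralization:
    @pytest.mark.parametrize("delta", [-0.5, 0.3])
    def test_passthrough(self, delta):
        pfe = pool_from_total_delta(1e-8, delta)
        pair = remineralize_transfer(pfe, 1e-10)
        assert pair.delta() == pytest.approx(delta, abs=1e-9)

    def test_full_transfer_reproduces_particle_delta(self):
        pfe = pool_from_total_delta(5e-8, -0.42)
        pair = remineralize_transfer(pfe, pfe.total)   # everything, in one go
        dfe = IsotopePool(pair.j56, pair.j54)          # released into empty pool
        assert delta_of(dfe) == pytest.approx(-0.42, abs=1e-10)
        assert dfe.total == pytest.approx(pfe.total, rel=1e-14)


class TestRecycleAndBacteria:
    def test_zero_rates_identity(self):
        p = params(k_loss_phyto=0.0, k_bacteria=0.0)
        out = recycle_and_bacteria(pool_from_total_delta(1e-8, -0.2),
                                   pool_from_total_delta(1e-6, 0.1), p)
        for pair in out.values():
            assert np.all(np.asarray(pair.j56) == 0)

    def test_recycling_preserves_delta(self):
        phyto = pool_from_total_delta(1e-8, -0.2)
        out = recycle_and_bacteria(phyto, pool_from_total_delta(1e-6, 0.1), params())
        for key in ("to_dfe", "to_small", "to_large"):
            assert out[key].delta() == pytest.approx(-0.2, abs=1e-9)

    def test_closed_loop_conserves_everything(self):
        # uptake -> grazing/recycling -> remineralization with all alpha = 1
        # conserves both isotopes exactly and never moves any delta outside
        # the convex hull of the initial deltas
        p = params(alpha_uptake=1.0, alpha_complex=1.0)
        dfe = pool_from_total_delta(1.0, 0.3)
        phyto = pool_from_total_delta(0.1, -0.4)
        pfe = pool_from_total_delta(0.05, 0.0)
        tot56 = dfe.fe56 + phyto.fe56 + pfe.fe56
        tot54 = dfe.fe54 + phyto.fe54 + pfe.fe54
        for _ in range(200):
            up = uptake_transfer(dfe, 0.02 * dfe.total, p)
            loops = recycle_and_bacteria(phyto, dfe, p)
            rem = remineralize_transfer(pfe, 0.05 * pfe.total)
            dfe = IsotopePool(
                dfe.fe56 - up.j56 + loops["to_dfe"].j56 + rem.j56 - loops["bacteria_to_small"].j56,
                dfe.fe54 - up.j54 + loops["to_dfe"].j54 + rem.j54 - loops["bacteria_to_small"].j54,
            )
            out = loops["to_dfe"] + loops["to_small"] + loops["to_large"]
            phyto = IsotopePool(phyto.fe56 + up.j56 - out.j56, phyto.fe54 + up.j54 - out.j54)
            pfe = IsotopePool(
                pfe.fe56 + loops["to_small"].j56 + loops["to_large"].j56
                + loops["bacteria_to_small"].j56 - rem.j56,
                pfe.fe54 + loops["to_small"].j54 + loops["to_large"].j54
                + loops["bacteria_to_small"].j54 - rem.j54,
            )
        assert dfe.fe56 + phyto.fe56 + pfe.fe56 == pytest.approx(tot56, rel=1e-12)
        assert dfe.fe54 + phyto.fe54 + pfe.fe54 == pytest.approx(tot54, rel=1e-12)
        for pool in (dfe, phyto, pfe):
            assert -0.4 - 1e-9 <= delta_of(pool) <= 0.3 + 1e-9


class TestClipping:
    def test_clip_preserves_delta_and_logs(self, caplog):
        donor = pool_from_total_delta(1.0, 0.5)
        big = uptake_transfer(donor, 10.0, params(alpha_uptake=1.0))
        with caplog.at_level(logging.WARNING, logger="feiso.cycling"):
            clipped = clip_to_donor(big, donor, dt=1.0, label="uptake")
        assert "clipped" in caplog.text
        assert clipped.total <= donor.total * (1 + 1e-12)
        assert clipped.delta() == pytest.approx(big.delta(), abs=1e-9)

    def test_no_clip_when_small(self):
        donor = pool_from_total_delta(1.0, 0.5)
        pair = uptake_transfer(donor, 0.01, params())
        clipped = clip_to_donor(pair, donor, dt=1.0)
        assert clipped.j56 == pair.j56 and clipped.j54 == pair.j54
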