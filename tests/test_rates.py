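"""Diffusive MFPT rates: closed forms, brute-force first passage, Kramers
limit, detailed balance, and the unit helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import proofscape as ps
from proofscape.rates import (RateConfig, acceleration_factor, debye_length,
                              kBT_to_kcal, kramers_rate, mfpt_rate)
from proofscape.synthetic import destabilize_segment
from proofscape.wham import FreeEnergyProfile


def profile_of(pot, lo, hi, n=1201):
    c = np.linspace(lo, hi, n)
    F = pot(c)
    return FreeEnergyProfile(centers=c, F=F - F.min())


def first_passage_simulation(pot, start, absorb, D=1.0, n_walkers=400,
                             seed=0, dt=None):
    """Brute-force mean first-passage time of overdamped walkers (oracle)."""
    rng = np.random.default_rng(seed)
    lo, hi = pot.bounds
    grid = np.linspace(lo, hi, 8192)
    force_grid = -pot.grad(grid)
    # force scale from the basin-to-basin region; drift in the steep
    # confining walls (rarely visited) is trust-region clipped instead
    between = (grid >= min(pot.basins)) & (grid <= max(pot.basins))
    gmax = np.max(np.abs(force_grid[between])) + 1e-9
    if dt is None:
        dt = min(0.05 / gmax ** 2, 0.005)
    sig = np.sqrt(2 * D * dt)
    x = np.full(n_walkers, float(start))
    t = np.zeros(n_walkers)
    alive = np.ones(n_walkers, dtype=bool)
    fwd = absorb > start
    step = 0
    while np.any(alive):
        step += 1
        xa = x[alive]
        drift = np.clip(dt * D * np.interp(xa, grid, force_grid), -0.3, 0.3)
        xa = xa + drift + sig * rng.normal(size=xa.size)
        xa = np.where(xa < lo, 2 * lo - xa, xa)
        xa = np.where(xa > hi, 2 * hi - xa, xa)
        x[alive] = xa
        t[alive] += dt
        crossed = xa >= absorb if fwd else xa <= absorb
        idx = np.flatnonzero(alive)
        alive[idx[crossed]] = False
        if step > 5e7:
            raise RuntimeError("first-passage oracle did not absorb")
    return t.mean(), t.std() / np.sqrt(n_walkers)


class TestMfptRate:
    def test_flat_profile_closed_form(self):
        L, D = 12.0, 1.0
        prof = FreeEnergyProfile(centers=np.linspace(0, L, 200),
                                 F=np.zeros(200))
        est = mfpt_rate(prof, RateConfig(D=D))
        assert est.mfpt == pytest.approx(L ** 2 / (2 * D), rel=1e-4)
        assert est.barrier == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_first_passage(self):
        pot = ps.make_double_well(0.0, 8.0, 5.0, 0.0)
        prof = profile_of(pot, *pot.bounds)
        # reflecting boundary at the domain edge, as in the simulation
        est = mfpt_rate(prof, RateConfig(D=1.0, reflecting=pot.bounds[0],
                                         absorbing=8.0), "forward")
        tau_sim, se = first_passage_simulation(pot, 0.0, 8.0, seed=4,
                                               n_walkers=300)
        assert est.mfpt == pytest.approx(tau_sim, rel=0.10)

    def test_kramers_limit_exp_delta(self):
        """Raising the start basin by δ multiplies the rate by e^δ."""
        pot = ps.make_double_well(0.0, 20.0, 12.0, 0.0)
        c = np.linspace(-5.0, 25.0, 2401)
        F1 = pot(c) - pot(c).min()
        delta = 3.0
        F2 = destabilize_segment(c, F1, delta, split=5.0, width=1.0)
        p1 = FreeEnergyProfile(centers=c, F=F1)
        p2 = FreeEnergyProfile(centers=c, F=F2 - F2.min())
        cfg = RateConfig(D=1.0, reflecting=0.0, absorbing=20.0)
        ratio = mfpt_rate(p2, cfg).rate / mfpt_rate(p1, cfg).rate
        assert ratio == pytest.approx(np.exp(delta), rel=0.05)

    def test_kramers_approximation_tracks_mfpt_at_high_barrier(self):
        # same order of magnitude, and the barrier dependence is exponential
        cfg = RateConfig(D=1.0)
        rates_exact, rates_kramers = [], []
        for barrier in (7.0, 9.0):
            pot = ps.make_double_well(0.0, 10.0, barrier, 0.0)
            prof = profile_of(pot, -2.0, 12.0)
            rates_exact.append(mfpt_rate(prof, cfg).rate)
            rates_kramers.append(kramers_rate(prof, cfg))
        for e, k in zip(rates_exact, rates_kramers):
            assert 0.1 * e < k < 10.0 * e
        # the 2 k_BT barrier increase dominates the rate change; the
        # curvature prefactor contributes much less than the exponential
        assert np.log(rates_kramers[1] / rates_kramers[0]) == pytest.approx(
            -2.0, abs=0.7)

    def test_boundaries_outside_domain_rejected(self):
        prof = FreeEnergyProfile(centers=np.linspace(0, 10, 50), F=np.zeros(50))
        with pytest.raises(ValueError):
            mfpt_rate(prof, RateConfig(D=1.0, absorbing=25.0))

    def test_rate_scales_linearly_with_diffusion(self):
        pot = ps.make_double_well(0.0, 8.0, 6.0, 1.0)
        prof = profile_of(pot, -2.0, 10.0)
        r1 = mfpt_rate(prof, RateConfig(D=1.0)).rate
        r3 = mfpt_rate(prof, RateConfig(D=3.0)).rate
        assert r3 == pytest.approx(3.0 * r1, rel=1e-9)

    @given(b1=st.floats(3.0, 8.0), extra=st.floats(0.5, 6.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_rate_decreases_with_barrier_height(self, b1, extra):
        pot1 = ps.make_double_well(0.0, 10.0, b1, 0.0)
        pot2 = ps.make_double_well(0.0, 10.0, b1 + extra, 0.0)
        cfg = RateConfig(D=1.0, reflecting=0.0, absorbing=10.0)
        r1 = mfpt_rate(profile_of(pot1, -2, 12), cfg).rate
        r2 = mfpt_rate(profile_of(pot2, -2, 12), cfg).rate
        assert r2 < r1

    def test_detailed_balance_of_forward_reverse_rates(self):
        dF = 3.0
        pot = ps.make_double_well(0.0, 10.0, 8.0, dF)   # basin2 lower by dF
        prof = profile_of(pot, -2.0, 12.0)
        cfg = RateConfig(D=1.0)
        kf = mfpt_rate(prof, cfg, "forward").rate
        kr = mfpt_rate(prof, cfg, "reverse").rate
        # deep-basin detailed balance up to the basin-curvature prefactors
        assert np.log(kf / kr) == pytest.approx(dF, abs=0.35)


class TestAccelerationFactor:
    def test_identical_profiles_give_one(self):
        prof = profile_of(ps.make_double_well(0.0, 10.0, 8.0, 0.0), -2, 12)
        assert acceleration_factor(prof, prof, RateConfig(D=1.0)) == pytest.approx(1.0)

    def test_eight_kBT_destabilisation_exceeds_thousandfold(self):
        pot = ps.make_double_well(0.0, 20.0, 12.0, 0.0)
        c = np.linspace(-5.0, 25.0, 2401)
        F1 = pot(c) - pot(c).min()
        F2 = destabilize_segment(c, F1, 8.0, split=5.0)
        cfg = RateConfig(D=1.0, reflecting=0.0, absorbing=20.0)
        ratio = acceleration_factor(
            FreeEnergyProfile(centers=c, F=F1),
            FreeEnergyProfile(centers=c, F=F2 - F2.min()), cfg)
        assert ratio >= 1000.0

    def test_monotone_in_destabilisation(self):
        pot = ps.make_double_well(0.0, 20.0, 12.0, 0.0)
        c = np.linspace(-5.0, 25.0, 1201)
        F1 = pot(c) - pot(c).min()
        cfg = RateConfig(D=1.0, reflecting=0.0, absorbing=20.0)
        base = FreeEnergyProfile(centers=c, F=F1)
        ratios = []
        for delta in (8.0, 10.0):
            F2 = destabilize_segment(c, F1, delta, split=5.0)
            ratios.append(acceleration_factor(
                base, FreeEnergyProfile(centers=c, F=F2 - F2.min()), cfg))
        assert ratios[1] > ratios[0]


class TestHelpers:
    def test_debye_length_paper_salt(self):
        assert round(debye_length(0.05), 1) == 1.4

    def test_debye_length_quarter_at_16x_concentration(self):
        assert debye_length(0.05 * 4) == pytest.approx(debye_length(0.05) / 2,
                                                       rel=1e-9)

    def test_debye_length_physiological(self):
        assert debye_length(0.15) == pytest.approx(0.79, abs=0.02)

    def test_invalid_concentration(self):
        with pytest.raises(ValueError):
            debye_length(-0.1)

    @pytest.mark.parametrize("n,T,expected,tol", [
        (10.0, 300.0, 5.96, 0.01),
        (0.0, 300.0, 0.0, 1e-12),
        (1.0, 298.0, 0.592, 0.001),
    ])
    def test_kBT_to_kcal(self, n, T, expected, tol):
        assert kBT_to_kcal(n, T) == pytest.approx(expected, abs=tol)
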