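"""Kinetic generators, dwell times, exchange rates, and the global fit."""

import numpy as np
import pytest

from polyion.equilibria import RateSet, solve_species_concentrations
from polyion.rate_models import (
    build_K2,
    build_K3P,
    build_K4H,
    build_K4P,
    exchange_rate,
    global_fit_ternary,
    mean_dwell_times,
    observed_rates_3state,
    tau_high_3state,
)
from polyion.synthetic import simulate_ctmc


def random_rateset(rng):
    return RateSet(k_on=10 ** rng.uniform(8, 10),
                   k_off=10 ** rng.uniform(-1, 1),
                   k_on_PPH=10 ** rng.uniform(8, 10),
                   k_off_PPH=10 ** rng.uniform(2, 4),
                   k_on_PHH=10 ** rng.uniform(8, 10),
                   k_off_PHH=10 ** rng.uniform(2, 4))


class TestGenerators:
    def test_k2_absorbing_without_ligand(self, rates):
        gen = build_K2(rates, 0.0)
        assert np.allclose(gen.p_eq, [1.0, 0.0])

    def test_k2_pseudo_first_order_scaling(self, rates):
        gen = build_K2(rates, 1e-9)
        assert gen.K[1, 0] == pytest.approx(1.45, rel=1e-12)

    def test_k2_detailed_balance(self, rates):
        gen = build_K2(rates, 5e-9)
        ratio = gen.p_eq[1] / gen.p_eq[0]
        assert ratio == pytest.approx(gen.K[1, 0] / rates.k_off, rel=1e-10)

    def test_negative_concentration_rejected(self, rates):
        with pytest.raises(ValueError):
            build_K2(rates, -1e-9)

    @pytest.mark.parametrize("builder", [build_K3P, build_K4P, build_K4H])
    def test_column_sums_zero_random_inputs(self, builder, rng):
        for _ in range(50):
            r = random_rateset(rng)
            conc = solve_species_concentrations(
                10 ** rng.uniform(-8, -5), 10 ** rng.uniform(-8, -5), r,
                include_PHH=builder is not build_K3P)
            K = builder(r, conc).K
            assert np.all(np.abs(K.sum(axis=0)) < 1e-10 * np.abs(K).max())

    def test_k3_reduces_to_k2_without_competitor(self, rates):
        conc = solve_species_concentrations(0.0, 5e-9, rates,
                                            include_PHH=False)
        K3 = build_K3P(rates, conc).K
        K2 = build_K2(rates, conc.c_H).K
        assert np.allclose(K3[:2, :2], K2)
        assert np.allclose(K3[2], 0.0) or K3[2, 2] == -rates.k_off_PPH

    def test_k4p_nests_k3p_when_phh_rate_vanishes(self, rng):
        r = random_rateset(rng)
        conc = solve_species_concentrations(1e-6, 1e-7, r, include_PHH=False)
        tiny = RateSet(r.k_on, r.k_off, r.k_on_PPH, r.k_off_PPH,
                       1e-30, 1e-30 * 12e-6)
        K4 = build_K4P(tiny, conc).K
        K3 = build_K3P(r, conc).K
        assert np.allclose(K4[:3, :3], K3, rtol=1e-12, atol=1e-20)

    def test_k4_spectral_gap_positive(self, rates):
        conc = solve_species_concentrations(3e-6, 1e-6, rates)
        ev = np.linalg.eigvals(build_K4P(rates, conc).K)
        nonzero = sorted(ev.real)[:-1]
        assert all(v < -1e-6 for v in nonzero)

    def test_k4h_reduces_to_swapped_k2_without_ternary(self, rates):
        r = RateSet(rates.k_on, rates.k_off, 1e-30, 1e-30 * 3.5e-6,
                    1e-30, 1e-30 * 12e-6)
        conc = solve_species_concentrations(5e-9, 1e-12, r)
        gen = build_K4H(r, conc)
        assert gen.K[1, 0] == pytest.approx(rates.k_on * conc.c_P, rel=1e-10)
        assert gen.K[0, 1] == pytest.approx(rates.k_off, rel=1e-12)

    def test_peq_matches_equilibrium_concentrations(self, rates):
        """The generator's stationary distribution equals the equilibrium
        populations of the labeled species from the solver."""
        conc = solve_species_concentrations(3e-6, 1e-6, rates)
        p = build_K4P(rates, conc).p_eq
        # labeled-species populations: the P*PH weight carries a
        # statistical factor 2 because the labeled chain can occupy either
        # of the two equivalent P slots of the ternary complex
        w = np.array([1.0,
                      conc.c_H / rates.K_D,
                      2 * conc.c_H * conc.c_P / (rates.K_D * rates.K_D_PPH),
                      conc.c_H ** 2 / (rates.K_D * rates.K_D_PHH)])
        assert np.allclose(p, w / w.sum(), rtol=1e-8)


class TestDwellTimes:
    def test_two_state_closed_form(self, rates):
        gen = build_K2(rates, 5e-9)
        dw = mean_dwell_times(gen, ["P*"])
        assert dw.tau_low == pytest.approx(1.0 / (rates.k_on * 5e-9), rel=1e-12)
        assert dw.tau_high == pytest.approx(1.0 / rates.k_off, rel=1e-12)

    def test_tau_low_three_state_closed_form(self, rates):
        conc = solve_species_concentrations(1e-7, 1e-8, rates,
                                            include_PHH=False)
        dw = mean_dwell_times(build_K3P(rates, conc), ["P*"])
        expected = 1.0 / (rates.k_on * conc.c_H
                          + rates.k_on_PPH * conc.c_PH)
        assert dw.tau_low == pytest.approx(expected, rel=1e-12)

    def test_tau_high_matches_closed_form_random_draws(self, rng):
        """The fundamental-matrix aggregate dwell equals the closed-form
        rational expression over many random parameter draws."""
        for _ in range(300):
            r = random_rateset(rng)
            conc = solve_species_concentrations(
                10 ** rng.uniform(-8, -5), 10 ** rng.uniform(-8, -6), r,
                include_PHH=False)
            closed = tau_high_3state(r, conc)
            agg = mean_dwell_times(build_K3P(r, conc), ["P*"]).tau_high
            assert agg == pytest.approx(closed, rel=1e-10)

    def test_dwell_times_match_gillespie(self, rates):
        """Mean dwell times from long stochastic trajectories agree with
        the linear-algebra values within Monte-Carlo error."""
        conc = solve_species_concentrations(1e-7, 1e-8, rates,
                                            include_PHH=False)
        gen = build_K3P(rates, conc)
        dw = mean_dwell_times(gen, ["P*"])
        times, states = simulate_ctmc(gen, 2000.0, seed=42)
        low = (states == 0).astype(int)
        seg_dur = np.diff(np.append(times, 2000.0))
        # dwell segments of the low aggregate
        change = np.flatnonzero(np.diff(low)) + 1
        bounds = np.concatenate([[0], change, [len(low)]])
        durs = {0: [], 1: []}
        for a, b in zip(bounds[:-1], bounds[1:]):
            durs[low[a]].append(seg_dur[a:b].sum())
        tau_low_mc = np.mean(durs[1][1:-1])
        tau_high_mc = np.mean(durs[0][1:-1])
        n_low, n_high = len(durs[1]) - 2, len(durs[0]) - 2
        assert abs(tau_low_mc - dw.tau_low) < 4 * dw.tau_low / np.sqrt(n_low)
        assert abs(tau_high_mc - dw.tau_high) < 4 * dw.tau_high / np.sqrt(n_high)

    def test_fold_acceleration_at_figure_conditions(self, rates):
        """At 10 nM H1 + 100 nM competitor the bound-state dissociation is
        accelerated about 30-fold over k_off."""
        conc = solve_species_concentrations(100e-9, 10e-9, rates,
                                            include_PHH=False)
        fold = 1.0 / tau_high_3state(rates, conc) / rates.k_off
        assert 25 < fold < 35

    def test_no_competitor_limit(self, rates):
        conc = solve_species_concentrations(0.0, 1e-8, rates,
                                            include_PHH=False)
        assert tau_high_3state(rates, conc) == pytest.approx(
            1.0 / rates.k_off, rel=1e-10)


class TestExchangeRate:
    def test_two_state_closed_form(self, rates):
        conc = solve_species_concentrations(0.0, 5e-9, rates)
        kex = exchange_rate(rates, conc, "P", "2state")
        assert kex == pytest.approx(rates.k_on * conc.c_H + rates.k_off,
                                    rel=1e-12)

    def test_recurrence_conditions_match_printed_value(self, rates):
        """Four-state k_ex at 1 µM H1 + 3 µM P lies inside the measured
        864 ± 77 1/s."""
        conc = solve_species_concentrations(3e-6, 1e-6, rates)
        kex = exchange_rate(rates, conc, "P", "4state")
        assert 864 - 77 < kex < 864 + 77

    def test_monotone_in_competitor(self, rates):
        grid = np.geomspace(1e-8, 2e-6, 20)
        kex = []
        for cPt in grid:
            conc = solve_species_concentrations(cPt, 10e-9, rates,
                                                include_PHH=False)
            kex.append(exchange_rate(rates, conc, "P", "3state"))
        assert np.all(np.diff(kex) > 0)

    def test_multistate_exceeds_two_state(self, rates):
        """Ternary pathways always accelerate exchange over the two-state
        prediction at the same dimer coefficients (the central claim)."""
        for cPt in np.geomspace(1e-8, 3e-6, 10):
            conc = solve_species_concentrations(cPt, 1e-8, rates)
            k2 = exchange_rate(rates, conc, "P", "2state")
            k4 = exchange_rate(rates, conc, "P", "4state")
            assert k4 > k2


class TestGlobalFit:
    def make_data(self, rates, rng, noise=0.05):
        grid = np.linspace(0.0, 2e-6, 12)
        rows = []
        for cPt in grid:
            kon_obs, koff_obs = observed_rates_3state(rates, cPt, 10e-9)
            for name, val in (("k_on_obs", kon_obs), ("k_off_obs", koff_obs)):
                noisy = val * (1 + rng.normal(0, noise)) if noise else val
                rows.append((cPt, 10e-9, name, noisy,
                             noise * val if noise else None))
        return rows

    def test_recovery_within_3se(self, rates, rng):
        rows = self.make_data(rates, rng, noise=0.05)
        fitted, rep = global_fit_ternary(rows, k_on=rates.k_on,
                                         k_off=rates.k_off)
        assert abs(rep["k_on_PPH"] - rates.k_on_PPH) < 3 * rep["k_on_PPH_se"]
        assert abs(rep["k_off_PPH"] - rates.k_off_PPH) < 3 * rep["k_off_PPH_se"]

    def test_idempotent_on_noise_free_predictions(self, rates, rng):
        rows = self.make_data(rates, rng, noise=0.0)
        _, rep = global_fit_ternary(rows, k_on=rates.k_on, k_off=rates.k_off)
        assert rep["k_on_PPH"] == pytest.approx(rates.k_on_PPH, rel=1e-6)
        assert rep["k_off_PPH"] == pytest.approx(rates.k_off_PPH, rel=1e-6)

    def test_null_ternary_signal_flagged(self, rates, rng):
        """Two-state data drive the ternary association toward zero with a
        poorly constrained dissociation rate."""
        grid = np.linspace(0.0, 2e-6, 12)
        rows = []
        for cPt in grid:
            conc = solve_species_concentrations(cPt, 10e-9, rates,
                                                include_PHH=False)
            rows.append((cPt, 10e-9, "k_on_obs", rates.k_on * conc.c_H,
                         0.05 * max(rates.k_on * conc.c_H, 0.1)))
            rows.append((cPt, 10e-9, "k_off_obs", rates.k_off,
                         0.05 * rates.k_off))
        _, rep = global_fit_ternary(rows, k_on=rates.k_on, k_off=rates.k_off,
                                    p0=(1e8, 1e3))
        assert rep["k_on_PPH"] < 0.05 * rates.k_on_PPH
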