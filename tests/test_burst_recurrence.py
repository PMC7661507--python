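"""Burst selection, efficiency histograms, and recurrence analysis."""

import numpy as np
import pytest

from polyion.burst_recurrence import (
    _pairs_in_window,
    estimate_p_same,
    fit_histogram,
    fit_recurrence_kex,
    recurrence_histogram,
    recurrence_series,
    select_bursts,
    transfer_efficiency,
)
from polyion.equilibria import two_state_bound_fraction, fit_titration_kd
from polyion.rate_models import GeneratorMatrix
from polyion.synthetic import simulate_burst_experiment


def two_state_gen(kon, koff):
    return GeneratorMatrix(np.array([[-kon, koff], [kon, -koff]]),
                           ("U", "B"))


class TestSelectBursts:
    def test_empty_stream(self):
        out = select_bursts([], [])
        assert len(out) == 0

    def test_manual_enumeration(self):
        """Dense burst (150 photons at 0.97 µs spacing) followed after a 1 ms
        gap by a sparse 40-photon burst: only the first 100-µs slice of the
        dense burst survives (104 photons > 50); the trailing partial slice
        (46 photons, not more than 50) and the small burst (40 <= 100
        photons) are dropped."""
        t1 = np.arange(150) * 0.97e-6   # photons at 0, 0.97, 1.94, ... µs
        t2 = t1[-1] + 1e-3 + np.arange(40) * 0.97e-6
        times = np.concatenate([t1, t2])
        out = select_bursts(times, np.zeros(len(times)))
        assert len(out) == 1
        # slice [0, 100 µs) holds photons k = 0..103 (k*0.97 µs < 100 µs)
        assert out.n_D.iloc[0] + out.n_A.iloc[0] == 104
        assert out.start.iloc[0] == 0.0

    def test_thirty_microsecond_gap_not_merged(self):
        times = np.array([0.0, 30e-6, 60e-6])
        out = select_bursts(times, [0, 0, 0], min_photons=0, slice_min=0)
        assert len(out) == 3   # strict "< 30 µs": equal gaps start new bursts

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            select_bursts([1.0, 0.5], [0, 0])

    def test_slice_boundaries_half_open(self):
        # photon exactly at start+100 µs belongs to the second slice
        times = np.concatenate([np.linspace(0, 100e-6, 60, endpoint=False),
                                100e-6 + np.linspace(0, 99e-6, 60)])
        out = select_bursts(times, np.zeros(120), min_photons=100,
                            slice_min=50)
        assert len(out) == 2
        assert (out.n_D + out.n_A).tolist() == [60, 60]


class TestTransferEfficiency:
    def test_symmetric_counts(self):
        assert transfer_efficiency(10, 10) == pytest.approx(0.5)

    def test_no_acceptor(self):
        assert transfer_efficiency(25, 0) == pytest.approx(0.0)

    def test_known_correction_vector_hand_computed(self):
        # n_D=80, n_A=120, 1 s, bg 5/10 Hz, crosstalk 0.05, direct 0.02,
        # gamma 0.9  ->  worked by hand below
        n_D = 80 - 5.0
        n_A = 120 - 10.0 - 0.05 * n_D
        n_A = n_A - 0.02 * (n_A + n_D)
        expected = n_A / (n_A + 0.9 * n_D)
        got = transfer_efficiency(80, 120, duration=1.0, bg_D=5.0, bg_A=10.0,
                                  crosstalk=0.05, direct_excitation=0.02,
                                  gamma=0.9)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_total_flagged_nan(self):
        assert np.isnan(transfer_efficiency(1, 0, duration=1.0, bg_D=5.0,
                                            bg_A=0.0))


class TestHistogramFit:
    def test_single_population_mean_recovered(self, rng):
        E = rng.normal(0.7, 0.05, 4000).clip(0, 1)
        fit = fit_histogram({0: E}, model="gaussian_pair")
        # one of the two shared peaks should sit on the population
        assert min(abs(fit["mu1"] - 0.7), abs(fit["mu2"] - 0.7)) < 0.01

    def test_fractions_sum_to_one(self, rng):
        E = np.concatenate([rng.normal(0.4, 0.05, 2000),
                            rng.normal(0.8, 0.05, 1000)]).clip(0, 1)
        fit = fit_histogram({0: E}, model="gaussian_pair")
        f = fit["bound_fraction"][0]
        assert 0 <= f <= 1
        assert f == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_titration_recovers_kd(self, rng):
        """Two-population synthetic titration at the measured affinity:
        global histogram fit + the depletion isotherm recover K_D."""
        kd_true = 0.73e-9
        c_star = 50e-12
        concs = np.geomspace(0.05e-9, 20e-9, 8)
        series = {}
        for c in concs:
            theta = float(two_state_bound_fraction(c, c_star, kd_true))
            n = 3000
            nb = rng.binomial(n, theta)
            series[c] = np.concatenate([
                rng.normal(0.45, 0.06, n - nb),
                rng.normal(0.75, 0.06, nb)]).clip(0, 1)
        fit = fit_histogram(series, model="gaussian_pair",
                            p0={"mu1": 0.45, "mu2": 0.75})
        thetas = np.array([fit["bound_fraction"][c] for c in concs])
        sds = np.array([max(fit["bound_fraction_sd"][c], 1e-3)
                        for c in concs])
        kd, se = fit_titration_kd(concs, thetas, sds, model="two_state",
                                  c_Pstar_tot=c_star, p0=1e-9)
        assert abs(kd - kd_true) < 3 * max(se, 0.03e-9)


@pytest.fixture(scope="module")
def labeled_sample():
    gen = two_state_gen(500.0, 364.0)     # k_ex = 864 1/s
    return simulate_burst_experiment(
        gen, [0.55, 0.78], duration_s=400.0, burst_rate=25,
        burst_len=1e-4, photons_per_burst=80, recur_rate=1500.0,
        recur_survival=0.85, seed=7, donor_only_fraction=0.15)


class TestRecurrence:
    def test_window_excluding_all_pairs_is_empty(self, labeled_sample):
        h, edges, chosen = recurrence_histogram(labeled_sample, (0.0, 1.0),
                                                (500.0, 1.0))
        assert h.sum() == 0 and len(chosen) == 0

    def test_matches_brute_force_pair_scan(self, labeled_sample):
        sub = labeled_sample.iloc[:1000].reset_index(drop=True)
        t_lo, t_hi = 0.001, 0.004
        first, second = _pairs_in_window(sub, t_lo, t_hi)
        starts = sub["start"].to_numpy()
        brute = [(i, j) for i in range(len(sub)) for j in range(len(sub))
                 if i != j and t_lo <= starts[j] - starts[i] < t_hi]
        assert sorted(zip(first.tolist(), second.tolist())) == sorted(brute)

    def test_static_molecules_keep_initial_population(self):
        """With no exchange, short-delay recurrences reproduce the selected
        population."""
        gen = two_state_gen(1e-6, 1e-6)
        df = simulate_burst_experiment(gen, [0.3, 0.8], duration_s=400.0,
                                       burst_rate=10, recur_rate=800.0,
                                       recur_survival=0.9, seed=3)
        h, edges, chosen = recurrence_histogram(df, (0.6, 1.0),
                                                (0.003, 0.004))
        E2 = df["E"].to_numpy()[chosen]
        # most second bursts at short delay come from the same (bound)
        # molecule
        assert np.mean(E2 > 0.55) > 0.75

    def test_p_same_against_ground_truth_labels(self, labeled_sample):
        t_grid = np.array([0.001, 0.003, 0.01, 0.03, 0.1])
        est = estimate_p_same(labeled_sample, t_grid,
                              background_tail=(0.1, 0.4))
        mol = labeled_sample["molecule"].to_numpy()
        for t, e in zip(t_grid, est):
            w = max(0.5 * t, 1e-4)
            f, s = _pairs_in_window(labeled_sample, max(t - w / 2, 0),
                                    t + w / 2)
            emp = np.mean(mol[f] == mol[s])
            assert abs(e - emp) < 0.1

    def test_p_same_vanishes_at_long_delay(self, labeled_sample):
        est = estimate_p_same(labeled_sample, [1.0],
                              background_tail=(2.0, 4.0))
        assert est[0] < 0.1

    def test_kex_exact_on_noise_free_relaxation(self):
        """p_same = 1 and a clean exponential: k_ex recovered exactly."""
        import pandas as pd

        t = np.geomspace(1e-4, 2e-2, 12)
        kex_true = 250.0
        E = 0.6 + 0.15 * np.exp(-kex_true * t)
        sb = pd.DataFrame({"t": t, "E_mean": E, "E_sd": 0.001,
                           "n_pairs": 1000})
        kex, sd, _ = fit_recurrence_kex([sb], [np.ones_like(t)])
        assert kex == pytest.approx(kex_true, rel=1e-6)

    def test_kex_invariant_under_affine_E_rescaling(self):
        import pandas as pd

        t = np.geomspace(1e-4, 2e-2, 12)
        E = 0.6 + 0.15 * np.exp(-300.0 * t)
        p = np.exp(-t / 0.02)
        model_E = 0.6 + p * (E - 0.6)
        sb = pd.DataFrame({"t": t, "E_mean": model_E, "E_sd": 0.001,
                           "n_pairs": 1000})
        k1, _, _ = fit_recurrence_kex([sb], [p])
        sb2 = sb.copy()
        sb2["E_mean"] = 0.2 + 0.5 * sb["E_mean"]
        sb2["E_sd"] = 0.5 * sb["E_sd"]
        k2, _, _ = fit_recurrence_kex([sb2], [p])
        assert k1 == pytest.approx(k2, rel=1e-4)

    def test_end_to_end_kex_recovery(self, labeled_sample):
        """Bound-start and unbound-start series fit globally with one rate
        recover the generator's exchange rate."""
        t_grid = np.array([3e-4, 6e-4, 1.2e-3, 2.5e-3, 5e-3, 1e-2, 2e-2])
        est = estimate_p_same(labeled_sample, t_grid,
                              background_tail=(0.1, 0.4))
        sb = recurrence_series(labeled_sample, (0.70, 0.95), t_grid)
        su = recurrence_series(labeled_sample, (0.38, 0.62), t_grid)
        kex, sd, _ = fit_recurrence_kex([sb, su], [est, est])
        assert abs(kex - 864.0) < 3 * max(sd, 50.0)
        # both series converge to a common equilibrium value
        assert abs(sb["E_mean"].iloc[-1] - su["E_mean"].iloc[-1]) < 0.02
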