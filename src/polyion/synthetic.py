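"""Synthetic-data generators with known ground truth.

Every experimental input of the analysis pipeline can be emulated here:
continuous-time Markov state paths (exact Gillespie), photon traces with
state-dependent Poisson emission, free-diffusion burst experiments with
same-molecule recurrence labels, stopped-flow relaxations, NMR titration
projections, and Boltzmann samples from biased umbrella windows.  All
generators are deterministic given a seed and return their ground truth
alongside the data.

By default bursts last 1 ms (the typical diffusion-limited transit);
photon emission is piecewise-constant within a burst (no focal intensity
profile, no detector dead time).
"""

from __future__ import annotations

import numpy as np

from .constants import KB_KJ_MOL_K
from .rate_models import GeneratorMatrix

__all__ = [
    "simulate_ctmc",
    "simulate_photon_trace",
    "simulate_burst_experiment",
    "simulate_stopped_flow",
    "simulate_nmr_titration",
    "simulate_umbrella",
]


def simulate_ctmc(gen: GeneratorMatrix, duration, seed=0, initial_state=None):
    """Exact-stochastic (Gillespie) trajectory of a CTMC.

    Returns (switch_times, states): ``states[i]`` holds from
    ``switch_times[i]`` until ``switch_times[i+1]`` (or ``duration``).
    """
    rng = np.random.default_rng(seed)
    K = gen.K
    n = gen.n_states
    exit_rates = -np.diag(K)
    if np.any(exit_rates < 0):
        raise ValueError("not a generator: negative exit rates")
    if initial_state is None:
        state = int(rng.choice(n, p=gen.p_eq))
    else:
        state = int(initial_state)
    times, states = [0.0], [state]
    t = 0.0
    while True:
        rate = exit_rates[state]
        if rate <= 0:       # absorbing state
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        jump = K[:, state].copy()
        jump[state] = 0.0
        state = int(rng.choice(n, p=jump / jump.sum()))
        times.append(t)
        states.append(state)
    return np.array(times), np.array(states, dtype=np.int8)


def simulate_photon_trace(switch_times, states, duration, n_D, n_A, seed=0):
    """State-dependent Poisson photon emission along a state path.

    ``n_D``/``n_A`` are per-state detection rates (Hz).  Returns
    (arrival_times, colors) merged and sorted; colors are 0 (donor) /
    1 (acceptor).
    """
    rng = np.random.default_rng(seed)
    n_D = np.asarray(n_D, dtype=float)
    n_A = np.asarray(n_A, dtype=float)
    seg_starts = np.asarray(switch_times, dtype=float)
    seg_ends = np.append(seg_starts[1:], duration)
    t_all, c_all = [], []
    for t0, t1, s in zip(seg_starts, seg_ends, states):
        dt = t1 - t0
        if dt <= 0:
            continue
        for color, rate in ((0, n_D[s]), (1, n_A[s])):
            if rate <= 0:
                continue
            k = rng.poisson(rate * dt)
            if k:
                t_all.append(t0 + rng.uniform(0.0, dt, size=k))
                c_all.append(np.full(k, color, dtype=np.int8))
    if not t_all:
        return np.array([]), np.array([], dtype=np.int8)
    t = np.concatenate(t_all)
    c = np.concatenate(c_all)
    order = np.argsort(t, kind="stable")
    return t[order], c[order]


def simulate_trace_ensemble(gen: GeneratorMatrix, n_traces, duration,
                            n_D, n_A, seed=0, rate_jitter=0.1):
    """Ensemble of photon traces sharing kinetics but with per-trace
    emission rates jittered log-normally (molecules sit at slightly
    different positions in the focus).  Returns a list of
    (times, colors, true_rates, switch_times, states)."""
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_traces):
        f = np.exp(rng.normal(0.0, rate_jitter))
        nD = np.asarray(n_D, float) * f
        nA = np.asarray(n_A, float) * f
        sub = rng.integers(0, 2**31 - 1)
        st, ss = simulate_ctmc(gen, duration, seed=sub)
        t, c = simulate_photon_trace(st, ss, duration, nD, nA,
                                     seed=rng.integers(0, 2**31 - 1))
        out.append({"times": t, "colors": c, "n_D": nD, "n_A": nA,
                    "switch_times": st, "states": ss, "trace_id": f"sim{j:03d}"})
    return out


def simulate_burst_experiment(gen: GeneratorMatrix, E_states, duration_s,
                              burst_rate=20.0, burst_len=1e-3,
                              photons_per_burst=80, seed=0,
                              recur_rate=0.0, recur_survival=0.0,
                              e_noise="binomial", e_sigma=0.05,
                              donor_only_fraction=0.0, donor_only_E=0.08):
    """Free-diffusion burst experiment with ground-truth molecule labels.

    New molecules arrive as a Poisson process (``burst_rate`` per second);
    each emits a burst of ``photons_per_burst`` photons (Poisson count)
    over ``burst_len``.  With ``recur_rate`` > 0 a molecule re-enters the
    focus with exponential waiting times and survives each re-entry with
    probability ``recur_survival``, evolving its chemical state by the
    generator between visits — this produces same-molecule recurrences.

    Per burst, the transfer efficiency is E of the current state plus shot
    noise: ``e_noise='binomial'`` draws acceptor counts binomially,
    ``'gaussian'`` adds N(0, e_sigma) to the state E.

    A ``donor_only_fraction`` of molecules carries a photobleached
    acceptor and emits at a low asymmetric E around ``donor_only_E``
    regardless of chemical state (state label -1).

    Returns a pandas DataFrame (start, end, n_D, n_A, E, molecule, state).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    E_states = np.asarray(E_states, dtype=float)
    p_eq = gen.p_eq
    exit_rates = -np.diag(gen.K)

    def evolve(state, dt):
        """Jump-chain evolution over dt; returns (end state, occupancy)."""
        occ = np.zeros(len(p_eq))
        t = 0.0
        while True:
            rate = exit_rates[state]
            if rate <= 0:
                occ[state] += dt - t
                return state, occ
            w = rng.exponential(1.0 / rate)
            if t + w >= dt:
                occ[state] += dt - t
                return state, occ
            occ[state] += w
            t += w
            jump = gen.K[:, state].copy()
            jump[state] = 0.0
            state = int(rng.choice(len(p_eq), p=jump / jump.sum()))

    rows = []
    mol_id = 0
    t = 0.0
    while True:
        t += rng.exponential(1.0 / burst_rate)
        if t >= duration_s:
            break
        state = int(rng.choice(len(p_eq), p=p_eq))
        donor_only = rng.random() < donor_only_fraction
        visit_t = t
        while True:
            entry_state = state
            state, occ = evolve(state, burst_len)
            if donor_only:
                E_avg = float(np.clip(donor_only_E * np.exp(
                    rng.normal(0.0, 0.5)), 0.0, 1.0))
            else:
                E_avg = float(np.clip(occ @ E_states / burst_len, 0.0, 1.0))
            n = rng.poisson(photons_per_burst)
            if n > 0:
                if e_noise == "binomial":
                    n_A = rng.binomial(n, E_avg)
                    E = n_A / n
                else:
                    E = float(np.clip(E_avg + rng.normal(0.0, e_sigma),
                                      0.0, 1.0))
                    n_A = int(round(E * n))
                rows.append((visit_t, visit_t + burst_len, n - n_A, n_A,
                             E, mol_id, -1 if donor_only else entry_state))
            if recur_rate <= 0 or rng.random() > recur_survival:
                break
            gap = rng.exponential(1.0 / recur_rate)
            state, _ = evolve(state, gap)
            visit_t += burst_len + gap
            if visit_t >= duration_s:
                break
        mol_id += 1
    df = pd.DataFrame(rows, columns=["start", "end", "n_D", "n_A", "E",
                                     "molecule", "state"])
    return df.sort_values("start", ignore_index=True)


def simulate_stopped_flow(gen: GeneratorMatrix, p0, bound_states, t_grid,
                          noise_sd=0.01, seed=0, amplitude=1.0, offset=0.0):
    """Relaxation of the bound-population signal after a concentration jump.

    The populations relax as p(t) = expm(K t) p0; the signal is the summed
    occupancy of ``bound_states`` scaled and offset, plus Gaussian noise.
    Returns (signal array, noise-free signal).
    """
    from scipy.linalg import expm

    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    bound = np.asarray(bound_states, dtype=int)
    clean = np.empty(len(t_grid))
    for i, t in enumerate(t_grid):
        p = expm(gen.K * t) @ p0
        clean[i] = amplitude * p[bound].sum() + offset
    noisy = clean + rng.normal(0.0, noise_sd, size=len(t_grid))
    return noisy, clean


def simulate_nmr_titration(rates, omega_states, R2_states, c_P_tot,
                           c_H_tot_list, noise_sd=0.0, seed=0,
                           omega_grid=None, mode="4state"):
    """Simulated 1-D projections across an H1 titration, volume-normalized,
    with optional additive Gaussian noise.  Returns (omega_grid, spectra)."""
    from .nmr_lineshape import titration_lineshapes

    rng = np.random.default_rng(seed)
    omega_grid, spectra, _ = titration_lineshapes(
        rates, omega_states, R2_states, c_P_tot, c_H_tot_list,
        omega_grid=omega_grid, mode=mode)
    if noise_sd > 0:
        for k in spectra:
            spectra[k] = spectra[k] + rng.normal(0.0, noise_sd,
                                                 size=len(omega_grid))
    return omega_grid, spectra


def simulate_umbrella(W_func, centers, force_constant, n_per_window,
                      seed=0, temperature=300.0, r_range=(0.05, 30.0),
                      grid_points=20_000):
    """Direct Boltzmann samples from biased 1-D windows via inverse-CDF.

    Each window samples r from p_k(r) ∝ exp[-beta (W(r) + bias_k(r))] on a
    fine grid.  ``W_func`` is the potential of mean force along r (it
    already contains the radial volume entropy of the underlying 3-D
    problem, which is what umbrella sampling of a distance coordinate
    records).  Returns a list of UmbrellaWindow.
    """
    from .pmf_rates import UmbrellaWindow

    rng = np.random.default_rng(seed)
    beta = 1.0 / (KB_KJ_MOL_K * temperature)
    r = np.linspace(*r_range, grid_points)
    W = W_func(r)
    windows = []
    for r0 in np.asarray(centers, dtype=float):
        u = W + 0.5 * force_constant * (r - r0) ** 2
        u = u - u.min()
        p = np.exp(-beta * u)
        cdf = np.cumsum(p)
        cdf /= cdf[-1]
        # strictly increasing CDF for interpolation
        draws = rng.uniform(0.0, 1.0, size=n_per_window)
        samples = np.interp(draws, cdf, r)
        windows.append(UmbrellaWindow(center=r0, force_constant=force_constant,
                                      samples=samples))
    return windows
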