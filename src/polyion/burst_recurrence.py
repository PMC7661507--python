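"""Burst selection, transfer-efficiency histograms, and recurrence analysis.

Free-diffusion confocal experiments produce a photon stream in which each
molecule transiting the observation volume emits a short burst.  Bursts
are identified in two passes: consecutive photons separated by less than
``interphoton_max`` are merged into one burst; bursts with more than
``min_photons`` photons are split into fixed-length slices and only
slices with more than ``slice_min`` photons are retained (half-open slice
boundaries [start, start + slice_len)).  All thresholds are strict
inequalities.

Recurrence analysis of single particles (RASP) extracts exchange kinetics
from pairs of bursts separated by a delay t: if the second burst is
emitted by the same molecule (probability p_same(t)), its mean transfer
efficiency relaxes from the value selected by the initial E range toward
equilibrium with rate k_ex:

    <E>(t) = (1 - p_same(t)) <E>_eq
             + p_same(t) [<E>_eq + (<E>(0) - <E>_eq) exp(-k_ex t)].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "select_bursts",
    "transfer_efficiency",
    "fit_histogram",
    "recurrence_histogram",
    "recurrence_series",
    "estimate_p_same",
    "fit_recurrence_kex",
]

BURST_COLUMNS = ["start", "end", "n_D", "n_A", "E", "parent"]


def select_bursts(times, colors, interphoton_max=30e-6, min_photons=100,
                  slice_len=100e-6, slice_min=50) -> pd.DataFrame:
    """Two-pass burst selection on a sorted photon stream.

    Returns a burst table with one row per retained slice; ``parent``
    identifies the originating first-pass burst.
    """
    times = np.asarray(times, dtype=float)
    colors = np.asarray(colors)
    if colors.dtype.kind in "US":
        colors = np.where(np.char.upper(colors.astype(str)) == "A", 1, 0)
    colors = colors.astype(np.int8)
    if np.any(np.diff(times) < 0):
        raise ValueError("photon stream must be sorted in time")
    if len(times) == 0:
        return pd.DataFrame(columns=BURST_COLUMNS)

    # pass 1: merge photons separated by strictly less than the threshold
    gaps = np.diff(times)
    breaks = np.flatnonzero(gaps >= interphoton_max) + 1
    starts = np.concatenate([[0], breaks])
    ends = np.concatenate([breaks, [len(times)]])

    rows = []
    for b, (i0, i1) in enumerate(zip(starts, ends)):
        if i1 - i0 <= min_photons:      # strict: need MORE than min_photons
            continue
        t0 = times[i0]
        burst_t = times[i0:i1]
        burst_c = colors[i0:i1]
        n_slices = int(np.floor((burst_t[-1] - t0) / slice_len)) + 1
        for k in range(n_slices):
            lo, hi = t0 + k * slice_len, t0 + (k + 1) * slice_len
            sel = (burst_t >= lo) & (burst_t < hi)
            n = int(sel.sum())
            if n <= slice_min:          # strict: need MORE than slice_min
                continue
            n_A = int(burst_c[sel].sum())
            n_D = n - n_A
            rows.append((lo, hi, n_D, n_A,
                         n_A / n if n else np.nan, b))
    return pd.DataFrame(rows, columns=BURST_COLUMNS)


def transfer_efficiency(n_D, n_A, duration=None, bg_D=0.0, bg_A=0.0,
                        crosstalk=0.0, direct_excitation=0.0, gamma=1.0):
    """Corrected transfer efficiency E = n_A / (n_A + gamma n_D).

    Corrections are applied in sequence: background subtraction
    (rates x duration), donor->acceptor crosstalk (alpha n_D removed from
    the acceptor channel), acceptor direct excitation (a fraction of the
    total removed from the acceptor channel), and the detection/quantum-
    yield factor gamma.  Bursts whose corrected total is <= 0 yield NaN
    (dropped with reason by callers).
    """
    n_D = np.asarray(n_D, dtype=float)
    n_A = np.asarray(n_A, dtype=float)
    if duration is not None and (bg_D or bg_A):
        n_D = n_D - bg_D * duration
        n_A = n_A - bg_A * duration
    n_A = n_A - crosstalk * n_D
    n_A = n_A - direct_excitation * (n_A + n_D)
    total = n_A + gamma * n_D
    with np.errstate(invalid="ignore", divide="ignore"):
        E = np.where(total > 0, n_A / total, np.nan)
    return E


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _lognormal_peak(x, amp, mu, sigma):
    with np.errstate(divide="ignore", invalid="ignore"):
        lx = np.where(x > 0, np.log(x), -np.inf)
        out = amp * np.exp(-0.5 * ((lx - mu) / sigma) ** 2)
    return np.where(x > 0, out, 0.0)


def fit_histogram(E_series, model="gaussian_pair", bins=50, range=(0.0, 1.0),
                  p0=None):
    """Global fit of transfer-efficiency histograms across a titration.

    ``E_series`` is a mapping {condition: array of per-burst E}.  Peak
    positions and widths are shared across conditions; amplitudes are free
    per condition.  The bound fraction per condition is the relative area
    of the high-E peak.

    model 'gaussian_pair': two Gaussians (unbound low-E, bound high-E).
    model 'lognormal_plus_gaussian': asymmetric donor-only/low-E peak
    described by a log-normal, plus one Gaussian FRET peak.

    Returns a dict with shared peak parameters, per-condition amplitudes,
    areas and bound fractions, and the lmfit result.
    """
    import lmfit

    conditions = list(E_series)
    hists = {}
    for cond in conditions:
        h, edges = np.histogram(np.asarray(E_series[cond], float), bins=bins,
                                range=range, density=True)
        hists[cond] = h
    centers = 0.5 * (edges[:-1] + edges[1:])

    params = lmfit.Parameters()
    if model == "gaussian_pair":
        d = p0 or {}
        params.add("mu1", value=d.get("mu1", 0.35), min=range[0], max=range[1])
        params.add("mu2", value=d.get("mu2", 0.75), min=range[0], max=range[1])
        params.add("sig1", value=d.get("sig1", 0.08), min=1e-3, max=0.5)
        params.add("sig2", value=d.get("sig2", 0.08), min=1e-3, max=0.5)
    elif model == "lognormal_plus_gaussian":
        d = p0 or {}
        # donor-only population lives at low E; cap its center at E = 0.35
        params.add("lnmu1", value=d.get("lnmu1", np.log(0.1)), min=-5,
                   max=np.log(0.35))
        params.add("lnsig1", value=d.get("lnsig1", 0.5), min=1e-2, max=2.0)
        params.add("mu2", value=d.get("mu2", 0.75), min=range[0], max=range[1])
        params.add("sig2", value=d.get("sig2", 0.08), min=1e-3, max=0.5)
    else:
        raise ValueError(f"unknown model {model!r}")
    for i, cond in enumerate(conditions):
        peak = np.max(hists[cond])
        params.add(f"a1_{i}", value=0.5 * peak, min=0.0)
        params.add(f"a2_{i}", value=0.5 * peak, min=0.0)

    def residual(pars):
        v = pars.valuesdict()
        res = []
        for i, cond in enumerate(conditions):
            if model == "gaussian_pair":
                m = (_gaussian(centers, v[f"a1_{i}"], v["mu1"], v["sig1"])
                     + _gaussian(centers, v[f"a2_{i}"], v["mu2"], v["sig2"]))
            else:
                m = (_lognormal_peak(centers, v[f"a1_{i}"],
                                     v["lnmu1"], v["lnsig1"])
                     + _gaussian(centers, v[f"a2_{i}"], v["mu2"], v["sig2"]))
            res.append(m - hists[cond])
        return np.concatenate(res)

    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"histogram fit did not converge: {out.message}")

    p = out.params
    result = {"model": model, "lmfit": out, "conditions": conditions}
    if model == "gaussian_pair":
        result.update(mu1=p["mu1"].value, mu2=p["mu2"].value,
                      sig1=p["sig1"].value, sig2=p["sig2"].value)
        areas1 = np.array([p[f"a1_{i}"].value * p["sig1"].value
                           for i in np.arange(len(conditions))])
        areas2 = np.array([p[f"a2_{i}"].value * p["sig2"].value
                           for i in np.arange(len(conditions))])
        frac = areas2 / (areas1 + areas2)
        result["bound_fraction"] = dict(zip(conditions, frac))
        # delta-method s.d. of the bound fraction per condition
        sds = {}
        for i, cond in enumerate(conditions):
            a1, a2 = p[f"a1_{i}"], p[f"a2_{i}"]
            s1, s2 = p["sig1"].value, p["sig2"].value
            A1, A2 = a1.value * s1, a2.value * s2
            tot = A1 + A2
            if a1.stderr and a2.stderr and tot > 0:
                dA1 = a1.stderr * s1
                dA2 = a2.stderr * s2
                sds[cond] = float(np.sqrt((A2 * dA1) ** 2 + (A1 * dA2) ** 2) / tot ** 2)
            else:
                sds[cond] = np.nan
        result["bound_fraction_sd"] = sds
    else:
        result.update(mu2=p["mu2"].value, sig2=p["sig2"].value,
                      lnmu1=p["lnmu1"].value, lnsig1=p["lnsig1"].value)
        result["gauss_position"] = p["mu2"].value
        result["gauss_position_sd"] = p["mu2"].stderr
    return result


# ---------------------------------------------------------------------------
# recurrence analysis (RASP)

def _pairs_in_window(bursts: pd.DataFrame, t_lo, t_hi):
    """Indices (first, second) of all burst pairs whose start-to-start delay
    falls in [t_lo, t_hi).  All pairs contribute, not only adjacent ones."""
    starts = bursts["start"].to_numpy()
    if np.any(np.diff(starts) < 0):
        raise ValueError("burst table must be time-ordered")
    first, second = [], []
    lo = np.searchsorted(starts, starts + t_lo, side="left")
    hi = np.searchsorted(starts, starts + t_hi, side="left")
    for i in range(len(starts)):
        js = np.arange(lo[i], hi[i])
        js = js[js != i]
        first.append(np.full(len(js), i))
        second.append(js)
    if not first:
        return np.array([], int), np.array([], int)
    return np.concatenate(first), np.concatenate(second)


def recurrence_histogram(bursts: pd.DataFrame, initial_E_range, time_window,
                         bins=50, range=(0.0, 1.0)):
    """Histogram of second-burst E for pairs whose first burst falls in
    ``initial_E_range`` and whose delay falls in ``time_window``.

    ``time_window`` is (center, width); the window is half-open
    [center - width/2, center + width/2).  Returns (histogram counts,
    bin edges, second-burst indices).  An empty selection returns zero
    counts (flagged by the caller via the returned index array).
    """
    t_lo = time_window[0] - time_window[1] / 2.0
    t_hi = time_window[0] + time_window[1] / 2.0
    first, second = _pairs_in_window(bursts, t_lo, t_hi)
    E = bursts["E"].to_numpy()
    sel = (E[first] >= initial_E_range[0]) & (E[first] < initial_E_range[1])
    chosen = second[sel]
    h, edges = np.histogram(E[chosen], bins=bins, range=range)
    return h, edges, chosen


def estimate_p_same(bursts: pd.DataFrame, t_grid, window_width=None,
                    background_tail=(0.2, 0.5)):
    """Same-molecule probability p_same(t) from the excess of short-delay
    recurrences over the Poisson background of new molecules.

    The rate of observing a second burst at delay t is rho(t) = lambda +
    r_same(t), where lambda is the stationary burst rate of unrelated
    molecules (estimated from delays in the ``background_tail`` interval,
    in seconds, where same-molecule recurrences have decayed) and r_same
    the same-molecule return rate.  Then p_same(t) = 1 - lambda / rho(t),
    clipped to [0, 1].
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if len(bursts) < 1000:
        import warnings
        warnings.warn("fewer than 1000 bursts: p_same estimate is unreliable")
    starts = bursts["start"].to_numpy()
    n = len(starts)

    def pair_rate(t_lo, t_hi):
        lo = np.searchsorted(starts, starts + t_lo, side="left")
        hi = np.searchsorted(starts, starts + t_hi, side="left")
        counts = (hi - lo) - (1 if (t_lo <= 0 < t_hi) else 0)
        return counts.sum() / (n * (t_hi - t_lo))

    lam = pair_rate(*background_tail)
    p_same = np.empty_like(t_grid)
    for k, t in enumerate(t_grid):
        w = window_width if window_width is not None else max(0.5 * t, 1e-4)
        rho = pair_rate(max(t - w / 2, 0.0), t + w / 2)
        p_same[k] = 1.0 - lam / rho if rho > lam else 0.0
    return np.clip(p_same, 0.0, 1.0)


def recurrence_series(bursts: pd.DataFrame, initial_E_range, t_grid,
                      window_width=None, bins=50, fret_range=(0.35, 1.0),
                      model="gaussian_pair"):
    """Mean FRET efficiency of recurrence histograms versus delay time.

    Second-burst E histograms at all delays are fit globally: peak
    positions and widths are shared across delays, amplitudes are free
    (``model='gaussian_pair'``).  The reported <E>(t) is the area-weighted
    mean of the two FRET peaks, which is linear in the state populations
    and therefore relaxes exactly as the underlying bound fraction.  The
    fit is restricted to ``fret_range`` so that an asymmetric donor-only
    population at low E does not perturb the FRET peaks.  With
    ``model='lognormal_plus_gaussian'`` the position of the single
    Gaussian FRET peak is reported instead (appropriate when exchange
    averages the populations into one peak).

    Returns a DataFrame (t, E_mean, E_sd, n_pairs); delays with fewer
    than 50 pairs are flagged with NaN.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    E_all = bursts["E"].to_numpy()
    series, counts = {}, {}
    for t in t_grid:
        w = window_width if window_width is not None else max(0.5 * t, 1e-4)
        _, _, chosen = recurrence_histogram(bursts, initial_E_range, (t, w),
                                            bins=bins)
        E_t = E_all[chosen]
        E_t = E_t[(E_t >= fret_range[0]) & (E_t < fret_range[1])]
        counts[t] = len(E_t)
        if len(E_t) >= 50:
            series[t] = E_t

    rows = []
    if model == "gaussian_pair" and series:
        lo, hi = fret_range
        fit = fit_histogram(series, model="gaussian_pair", bins=bins,
                            range=fret_range,
                            p0={"mu1": lo + 0.25 * (hi - lo),
                                "mu2": lo + 0.75 * (hi - lo)})
        mu1, mu2 = fit["mu1"], fit["mu2"]
        for t in t_grid:
            if t not in series:
                rows.append((t, np.nan, np.nan, counts[t]))
                continue
            f = fit["bound_fraction"][t]
            sd = fit["bound_fraction_sd"][t]
            rows.append((t, (1 - f) * mu1 + f * mu2,
                         abs(mu2 - mu1) * sd if np.isfinite(sd) else np.nan,
                         counts[t]))
    else:
        for t in t_grid:
            if t not in series:
                rows.append((t, np.nan, np.nan, counts[t]))
                continue
            E_t = series[t]
            try:
                f = fit_histogram({0: E_t}, model=model, bins=bins)
                pos, sd = f["gauss_position"], f.get("gauss_position_sd")
            except Exception:
                pos, sd = float(np.mean(E_t)), float(np.std(E_t)
                                                     / np.sqrt(len(E_t)))
            rows.append((t, pos, sd if sd else np.nan, counts[t]))
    return pd.DataFrame(rows, columns=["t", "E_mean", "E_sd", "n_pairs"])


def fit_recurrence_kex(series_list, p_same_list, E_eq=None):
    """Global fit of <E>(t) relaxation curves sharing a single k_ex.

    ``series_list``: DataFrames from :func:`recurrence_series` (e.g. one
    starting from the bound-E range and one from the unbound range).
    ``p_same_list``: matching arrays of p_same on each series' t grid.
    Each series gets its own <E>(0); <E>_eq and k_ex are shared.
    Returns (k_ex, k_ex_sd, lmfit result).
    """
    import lmfit

    params = lmfit.Parameters()
    all_E = np.concatenate([s["E_mean"].dropna().to_numpy() for s in series_list])
    params.add("E_eq", value=float(np.mean(all_E)) if E_eq is None else E_eq,
               min=0.0, max=1.0, vary=E_eq is None)
    params.add("ln_kex", value=np.log(100.0), min=np.log(1e-2), max=np.log(1e6))
    for i, s in enumerate(series_list):
        first_valid = s["E_mean"].dropna()
        params.add(f"E0_{i}", value=float(first_valid.iloc[0]), min=0.0, max=1.0)

    def residual(pars):
        v = pars.valuesdict()
        kex = np.exp(v["ln_kex"])
        res = []
        for i, (s, ps) in enumerate(zip(series_list, p_same_list)):
            ok = s["E_mean"].notna().to_numpy()
            t = s["t"].to_numpy()[ok]
            E = s["E_mean"].to_numpy()[ok]
            sd = s["E_sd"].to_numpy()[ok]
            sd = np.where(np.isfinite(sd) & (sd > 0), sd, np.nanmedian(sd) or 1.0)
            p = np.asarray(ps)[ok]
            model = ((1 - p) * v["E_eq"]
                     + p * (v["E_eq"]
                            + (v[f"E0_{i}"] - v["E_eq"]) * np.exp(-kex * t)))
            res.append((model - E) / sd)
        return np.concatenate(res)

    out = lmfit.minimize(residual, params, method="leastsq")
    kex = float(np.exp(out.params["ln_kex"].value))
    se = out.params["ln_kex"].stderr
    kex_sd = kex * se if se is not None else np.nan
    at_bounds = (abs(out.params["ln_kex"].value - out.params["ln_kex"].min) < 1e-6
                 or abs(out.params["ln_kex"].value - out.params["ln_kex"].max) < 1e-6)
    if at_bounds:
        import warnings
        warnings.warn("k_ex hit a fit bound; result unreliable")
    return kex, kex_sd, out
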