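"""Potential-of-mean-force post-processing: 1-D WHAM, the effective
two-body potential, and equilibrium/rate constants from radial profiles.

The center-of-mass separation r of two associating chains is sampled in
harmonic umbrella windows; WHAM recombines the biased histograms into the
potential of mean force W(r).  The effective two-body potential removes
the 3-D volume entropy of the separation coordinate,

    F(r) = W(r) + 2 k_B T ln r,

and is zeroed at large separation.  From F(r):

    K_D^-1 = 4 pi N_A  ∫_0^c exp[-beta F(r)] r^2 dr           (association volume)
    N_A / k_on = ∫_b^c exp[beta F(r)] / (4 pi r^2 D) dr + 1/(4 pi D c)

the latter being the steady-state reactive flux onto an absorbing
boundary at radius b, with D the summed translational diffusion
coefficient of the two species.  The capture radius is the largest b at
which k_on(b) has become insensitive to b (the attractive funnel already
commits the pair to association).

Units: r in nm, energies in kJ/mol, D supplied in cm^2/s, K_D in molar,
k_on in M^-1 s^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ_MOL_K, LITRE_PER_NM3, N_AVOGADRO, NM2_PER_CM2

__all__ = [
    "UmbrellaWindow",
    "PmfProfile",
    "wham_1d",
    "effective_potential",
    "kd_from_pmf",
    "kon_from_pmf",
    "capture_radius",
]

#: umbrella-window centers (nm) of the reference 32-replica protocol
DEFAULT_WINDOW_CENTERS = np.array(
    [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.5, 6.5, 7.5, 8.5,
     9.5, 10.5, 11.5, 12.5, 13.5, 14.5, 15.5, 16.5, 17.5, 18.5, 19.5, 20.5,
     21.5, 22.5, 23.5, 24.5, 25.5, 26.5])

#: umbrella force constant of the reference protocol, kJ mol^-1 nm^-2
DEFAULT_FORCE_CONSTANT = 10.0


@dataclass
class UmbrellaWindow:
    """Samples of the separation r under one harmonic bias window."""

    center: float
    force_constant: float
    samples: np.ndarray

    def __post_init__(self):
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) == 0:
            raise ValueError("window needs a 1-D non-empty sample array")

    def bias(self, r):
        return 0.5 * self.force_constant * (np.asarray(r) - self.center) ** 2


@dataclass
class PmfProfile:
    """A radial free-energy profile W(r) and its effective potential F(r)."""

    r: np.ndarray
    W: np.ndarray
    temperature: float = 300.0
    F: np.ndarray = field(default=None)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if self.F is None:
            self.F = effective_potential(self.r, self.W, self.temperature)

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KJ_MOL_K * self.temperature)


def wham_1d(windows, bins=200, r_range=None, temperature=300.0,
            tol=1e-8, max_iter=50_000):
    """Self-consistent 1-D WHAM over harmonic umbrella windows.

    Iterates the standard coupled equations for the unbiased probability
    p(r) and per-window free-energy offsets f_k until the offsets change
    by less than ``tol`` (kT units).  W is anchored to zero at the largest
    sampled r.  Non-overlapping adjacent windows (no shared occupied
    bins) raise an error naming the gap.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("no umbrella windows")
    beta = 1.0 / (KB_KJ_MOL_K * temperature)
    all_samples = np.concatenate([w.samples for w in windows])
    if r_range is None:
        r_range = (all_samples.min(), all_samples.max())
    edges = np.linspace(*r_range, bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.samples, bins=edges)[0]
                       for w in windows], dtype=float)
    # overlap check between windows adjacent in center order
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise ValueError(
                f"umbrella windows at r0={windows[a].center} and "
                f"r0={windows[b].center} share no occupied bins (sampling gap)")

    N_k = counts.sum(axis=1)
    bias = np.array([np.exp(-beta * w.bias(centers)) for w in windows])
    f = np.zeros(len(windows))          # exp(beta f_k) offsets, in log form

    num = counts.sum(axis=0)
    for _ in range(max_iter):
        denom = (N_k[:, None] * np.exp(f)[:, None] * bias).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, num / denom, 0.0)
        z = (bias * p[None, :]).sum(axis=1)
        f_new = -np.log(np.where(z > 0, z, np.finfo(float).tiny))
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    else:  # pragma: no cover
        raise RuntimeError(f"WHAM did not converge in {max_iter} iterations")

    denom = (N_k[:, None] * np.exp(f)[:, None] * bias).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, num / denom, 0.0)
    occupied = p > 0
    W = np.full_like(p, np.nan)
    W[occupied] = -np.log(p[occupied]) / beta
    # anchor at the largest sampled r
    W -= W[occupied][-1]
    return PmfProfile(r=centers[occupied], W=W[occupied],
                      temperature=temperature)


def effective_potential(r, W, temperature=300.0, zero_tail_fraction=0.1):
    """F(r) = W(r) + 2 k_B T ln r, offset so the large-r tail averages zero."""
    r = np.asarray(r, dtype=float)
    W = np.asarray(W, dtype=float)
    F = W + 2.0 * KB_KJ_MOL_K * temperature * np.log(r)
    n_tail = max(int(len(r) * zero_tail_fraction), 1)
    return F - F[-n_tail:].mean()


def _refined_grid(r, F, beta, refine=8):
    """Piecewise-linear interpolation onto a locally refined grid."""
    r_fine = np.linspace(r[0], r[-1], len(r) * refine)
    F_fine = np.interp(r_fine, r, F)
    return r_fine, F_fine


def kd_from_pmf(r, F, c, temperature=300.0, flat_tol_kT=0.5):
    """Dissociation constant from the effective potential.

    K_D^-1 = 4 pi N_A ∫_0^c exp[-beta F(r)] r^2 dr, with r in nm and the
    result in molar.  Warns if F is not flat (within ``flat_tol_kT``) at
    the cutoff c, suggesting a larger cutoff.
    """
    r = np.asarray(r, dtype=float)
    F = np.asarray(F, dtype=float)
    beta = 1.0 / (KB_KJ_MOL_K * temperature)
    if c <= r[0]:
        raise ValueError("cutoff c must exceed the smallest sampled r")
    if abs(np.interp(c, r, F)) > flat_tol_kT / beta:
        import warnings
        flat = r[np.abs(F) < flat_tol_kT / beta]
        hint = f"; try c >= {flat[0]:.2f} nm" if len(flat) else ""
        warnings.warn(f"F(r) is not flat at c={c} nm{hint}")
    r_f, F_f = _refined_grid(r[r <= c + 1e-12], F[r <= c + 1e-12], beta)
    integrand = np.exp(-beta * F_f) * r_f**2
    vol_nm3 = 4.0 * np.pi * np.trapezoid(integrand, r_f)
    kd_inv = vol_nm3 * N_AVOGADRO * LITRE_PER_NM3  # M^-1
    return 1.0 / kd_inv


def kon_from_pmf(r, F, D_cm2_s, b, c, temperature=300.0):
    """Diffusion-limited association rate coefficient from the profile.

    N_A / k_on = ∫_b^c exp[beta F(r)]/(4 pi r^2 D) dr + 1/(4 pi D c),
    evaluated in nm units and converted to M^-1 s^-1.  For a flat
    potential this reduces to the Smoluchowski rate 4 pi D b N_A.
    """
    if not 0 < b < c:
        raise ValueError("need 0 < b < c")
    r = np.asarray(r, dtype=float)
    F = np.asarray(F, dtype=float)
    beta = 1.0 / (KB_KJ_MOL_K * temperature)
    D = D_cm2_s * NM2_PER_CM2  # nm^2/s
    mask = (r >= b) & (r <= c)
    r_seg = np.concatenate([[b], r[mask], [c]])
    F_seg = np.interp(r_seg, r, F)
    r_f, F_f = _refined_grid(r_seg, F_seg, beta)
    integrand = np.exp(beta * F_f) / (4.0 * np.pi * r_f**2 * D)
    inv_flux = np.trapezoid(integrand, r_f) + 1.0 / (4.0 * np.pi * D * c)
    k_on_nm3 = 1.0 / inv_flux                     # nm^3 / s
    return k_on_nm3 * N_AVOGADRO * LITRE_PER_NM3  # M^-1 s^-1


def capture_radius(r, F, D_cm2_s, c, temperature=300.0, tol=0.01,
                   n_scan=100):
    """Largest radius b* at which k_on(b) has plateaued.

    Scans b downward from c and returns the largest b where the
    logarithmic sensitivity |d ln k_on / d ln b| falls below ``tol``.  A
    purely flat potential has k_on ∝ b (sensitivity 1 everywhere), hence
    no plateau: returns None.
    """
    r = np.asarray(r, dtype=float)
    b_grid = np.linspace(r[0] + 1e-9, c * (1 - 1e-9), n_scan)[::-1]
    k = np.array([kon_from_pmf(r, F, D_cm2_s, b, c, temperature)
                  for b in b_grid])
    dlnk = np.abs(np.diff(np.log(k)) / np.diff(np.log(b_grid)))
    hits = np.flatnonzero(dlnk < tol)
    if len(hits) == 0:
        return None
    return float(b_grid[hits[0]])
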