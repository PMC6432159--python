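"""Drift-diffusion characterization of the translocation coordinate.

Mapped onto one dimension, translocation is a biased first-passage process
of the coordinate s in 1..N.  This module provides:

* the empirical drift velocity v(s) = 1/w(s) from the waiting times;
* the classical entropic drift model: free energy
  F(s) = kBT[(1-g_I) ln(N-s) + (1-g_III) ln s] with its force (equal
  exponents g = 0.69 for self-avoiding chains), the pore driving force
  e E (N_m,II - N_c,II) and a Rouse-type effective friction
  zeta (N_m,II + N_c,II), combined into a terminal velocity
  v_es = (f_entropic + f_driving) l_0 / zeta_eff;
* the variance curve <Delta s^2(t)> across runs and its local power-law
  exponent xi (ballistic xi=2, normal diffusion xi=1; the process must end
  with negative diffusion since all runs finish at s = N);
* log-normal fits of the occupancy density p(s,t) with the amplitude A_s
  pinned to w(s)/<tau>, and the derived full width W_s and mean arrival
  time <t_s> = mu_s exp(sigma_s^2/2);
* the retardation delta_s = (<t_s> - s/v_bar)/<tau> against the
  constant-speed schedule v_bar = N/<tau>;
* the waiting-time hump position s~* and the (N - s*) ~ N^beta scaling fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "drift_velocity",
    "DriftModel",
    "entropic_drift_model",
    "variance_curve",
    "diffusion_exponent",
    "occupancy_density",
    "lognormal_fit",
    "lognormal_density",
    "lognormal_fwhm",
    "lognormal_mean_time",
    "LogNormalFit",
    "retardation",
    "hump_position",
    "hump_and_scaling",
]


def drift_velocity(w) -> np.ndarray:
    """v(s) = 1/w(s), states per tau_u; infinite where w = 0 (flagged inf)."""
    w = np.asarray(w, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(w > 0, 1.0 / w, np.inf)


@dataclass
class DriftModel:
    """Parameters of the entropic drift-velocity estimate."""

    N: int
    E: float
    gamma_cis: float = 0.69
    gamma_trans: float = 0.69
    l0: float = 1.0
    zeta: float = 1.0
    kBT: float = 1.0

    def free_energy(self, s) -> np.ndarray:
        """Entropic free energy of the tug-of-war between the sub-chains."""
        s = _interior(s, self.N)
        return self.kBT * (
            (1.0 - self.gamma_cis) * np.log(self.N - s)
            + (1.0 - self.gamma_trans) * np.log(s)
        )

    def entropic_force(self, s) -> np.ndarray:
        """-dF/ds per unit length; equal-exponent closed form
        f = kBT (1-g) (2 s~ - 1) / (N l0 s~ (1 - s~))."""
        s = _interior(s, self.N)
        st = s / self.N
        g = self.gamma_cis
        if self.gamma_trans != self.gamma_cis:
            # general two-exponent form
            return (self.kBT / self.l0) * (
                (1.0 - self.gamma_cis) / (self.N - s) - (1.0 - self.gamma_trans) / s
            )
        return (self.kBT / (self.N * self.l0)) * (1.0 - g) * (2.0 * st - 1.0) / (
            st * (1.0 - st)
        )

    def driving_force(self, n_mono_pore, n_ion_pore) -> np.ndarray:
        """f_driving = e E (N_m,II - N_c,II(+1)), in kBT/sigma for unit e."""
        return self.E * (np.asarray(n_mono_pore, float) - np.asarray(n_ion_pore, float))

    def effective_friction(self, n_mono_pore, n_ion_pore) -> np.ndarray:
        """zeta_eff = zeta (N_m,II + N_c,II(+1)) (Rouse: friction adds)."""
        return self.zeta * (np.asarray(n_mono_pore, float) + np.asarray(n_ion_pore, float))


def _interior(s, N):
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0) or np.any(s >= N):
        raise ValueError(
            "entropic model diverges at s = 0 and s = N (valid only while both "
            "sub-chains are large); evaluate at interior states"
        )
    return s


def entropic_drift_model(model: DriftModel, s, n_mono_pore, n_ion_pore):
    """All pieces of the terminal-velocity estimate at states s.

    Returns a dict with F_entropic, f_entropic, f_driving, zeta_eff and
    v_es = (f_entropic + f_driving) l0 / zeta_eff.
    """
    F = model.free_energy(s)
    fe = model.entropic_force(s)
    fd = model.driving_force(n_mono_pore, n_ion_pore)
    ze = model.effective_friction(n_mono_pore, n_ion_pore)
    if np.any(ze <= 0):
        raise ValueError("effective friction must be positive (empty pore?)")
    return {
        "F_entropic": F,
        "f_entropic": fe,
        "f_driving": fd,
        "zeta_eff": ze,
        "v_es": (fe + fd) * model.l0 / ze,
    }


def variance_curve(records, n_grid: int = 200, scaled: bool = True):
    """Population variance of s across runs, on a common time grid.

    scaled=True: the grid is t~ in [0, 1], each run evaluated at t = t~ tau_k
    (all runs align; the variance is zero at t~ = 1 where every run sits at
    s = N).  scaled=False: real-time grid from 0 to max tau; runs that have
    finished contribute s = N.

    Requires at least two runs.  Returns (grid, variance).
    """
    records = [r for r in records if r.completed]
    if len(records) < 2:
        raise ValueError("variance needs at least two completed runs")
    if scaled:
        grid = np.linspace(0.0, 1.0, n_grid)
        S = np.empty((len(records), n_grid))
        for i, r in enumerate(records):
            S[i] = _eval_s(r, grid * r.tau)
        S[:, -1] = records[0].n_monomers
    else:
        t_max = max(r.tau for r in records)
        grid = np.linspace(0.0, t_max, n_grid)
        S = np.empty((len(records), n_grid))
        for i, r in enumerate(records):
            S[i] = _eval_s(r, grid)
    return grid, S.var(axis=0)


def _eval_s(record, t):
    """Right-continuous step interpolation of the s(t) series; s = N past tau."""
    idx = np.searchsorted(record.times, t, side="right") - 1
    idx = np.clip(idx, 0, len(record.s) - 1)
    s = record.s[idx].astype(float)
    return np.where(t >= record.tau, float(record.n_monomers), s)


def diffusion_exponent(t, var, window: tuple[float, float]) -> tuple[float, float]:
    """Least-squares slope xi of log<Delta s^2> vs log t on a time window.

    Returns (xi, standard error).  Raises if the window holds fewer than
    three strictly positive (t, var) samples.
    """
    t = np.asarray(t, dtype=float)
    var = np.asarray(var, dtype=float)
    sel = (t >= window[0]) & (t <= window[1]) & (t > 0) & (var > 0)
    if sel.sum() < 3:
        raise ValueError("window must contain >= 3 positive samples of the variance")
    x = np.log(t[sel])
    y = np.log(var[sel])
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    n = x.size
    if n > 2 and res.size:
        s2 = res[0] / (n - 2)
        se = float(np.sqrt(s2 / ((x - x.mean()) ** 2).sum()))
    else:
        se = 0.0
    return float(coef[0]), se


# ---------------------------------------------------------------------------
# log-normal machinery for the occupancy density p(s, t)
# ---------------------------------------------------------------------------

def lognormal_density(t, A, sigma, mu):
    """p(t) = A / (sqrt(2 pi) sigma t) exp(-(ln t - ln mu)^2 / (2 sigma^2))."""
    t = np.asarray(t, dtype=float)
    return (
        A / (np.sqrt(2.0 * np.pi) * sigma * t)
        * np.exp(-((np.log(t) - np.log(mu)) ** 2) / (2.0 * sigma**2))
    )


def lognormal_fwhm(sigma: float, mu: float) -> float:
    """Full width at half maximum: W = 2 sinh(sqrt(2 ln 2) sigma) e^{-sigma^2} mu."""
    return 2.0 * np.sinh(np.sqrt(2.0 * np.log(2.0)) * sigma) * np.exp(-sigma**2) * mu


def lognormal_mean_time(sigma: float, mu: float) -> float:
    """Mean of the (unit-normalized) log-normal: <t> = mu exp(sigma^2/2)."""
    return float(mu * np.exp(sigma**2 / 2.0))


@dataclass
class LogNormalFit:
    """Two-parameter log-normal fit of p(s, t) at one state s."""

    s: int
    A: float
    sigma: float
    mu: float
    residual: float
    converged: bool
    n_points: int
    W: float = field(init=False)
    mean_time: float = field(init=False)

    def __post_init__(self):
        self.W = lognormal_fwhm(self.sigma, self.mu)
        self.mean_time = lognormal_mean_time(self.sigma, self.mu)


def occupancy_density(records, s: int, n_bins: int = 40):
    """Empirical p(s, t): fraction of runs at state s at time t, over <tau>.

    Uses log-spaced time bins so that the double integral over (s, t) of the
    assembled densities is one.  Returns (bin centers, density values).
    """
    records = [r for r in records if r.completed]
    if not records:
        raise ValueError("empty ensemble")
    tau_mean = float(np.mean([r.tau for r in records]))
    t_lo = min(r.times[1] - r.times[0] for r in records)
    t_hi = max(r.tau for r in records)
    edges = np.geomspace(max(t_lo, 1e-12), t_hi, n_bins + 1)
    centers = np.sqrt(edges[:-1] * edges[1:])
    occ = np.zeros(n_bins)
    for b in range(n_bins):
        tm = centers[b]
        at_s = sum(1 for r in records if tm < r.tau and _eval_s(r, np.array([tm]))[0] == s)
        occ[b] = at_s / len(records)
    return centers, occ / tau_mean


def lognormal_fit(t, p, A, s: int = 0, p0=None, max_nfev: int = 2000) -> LogNormalFit:
    """Levenberg-Marquardt fit of p(s, t) over (sigma_s, mu_s), A_s fixed.

    ``A`` is supplied from the waiting-time information, A_s = w(s)/<tau>,
    as the time integral of p(s, t).  Only strictly positive times enter.
    Non-convergence is reported via ``converged=False`` with the last
    residual, never by raising.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    sel = (t > 0) & np.isfinite(p)
    t, p = t[sel], p[sel]
    if t.size < 4:
        return LogNormalFit(s, A, np.nan, np.nan, np.inf, False, int(t.size))
    if p0 is None:
        wgt = np.clip(p, 0, None)
        if wgt.sum() > 0:
            lm = float(np.average(np.log(t), weights=wgt))
            lv = float(np.average((np.log(t) - lm) ** 2, weights=wgt))
            p0 = (max(np.sqrt(lv), 1e-3), np.exp(lm))
        else:
            p0 = (0.5, float(np.median(t)))

    def resid(params):
        sig, mu = params
        return lognormal_density(t, A, abs(sig), abs(mu)) - p

    try:
        sol = optimize.least_squares(
            resid, x0=np.asarray(p0, float), method="lm", max_nfev=max_nfev
        )
        sig, mu = abs(sol.x[0]), abs(sol.x[1])
        return LogNormalFit(
            s, A, float(sig), float(mu), float(np.sqrt(2 * sol.cost)),
            bool(sol.success), int(t.size),
        )
    except Exception:
        return LogNormalFit(s, A, p0[0], p0[1], np.inf, False, int(t.size))


def retardation(mean_times, tau_mean: float, N: int, s=None):
    """delta_s = (<t_s> - s/v_bar) / <tau> with v_bar = N/<tau>.

    Returns (s, delta_s, info) where info holds the zero crossing (linear
    interpolation) and the argmin/argmax states - the states where the
    instantaneous threading speed equals the mean speed v_bar.
    """
    mean_times = np.asarray(mean_times, dtype=float)
    if s is None:
        s = np.arange(1, mean_times.size + 1)
    s = np.asarray(s, dtype=float)
    if tau_mean <= 0:
        raise ValueError("tau_mean must be positive")
    v_bar = N / tau_mean
    delta = (mean_times - s / v_bar) / tau_mean
    info = {
        "argmin_s": float(s[np.nanargmin(delta)]),
        "argmax_s": float(s[np.nanargmax(delta)]),
        "zero_crossings": _zero_crossings(s, delta),
    }
    return s, delta, info


def _zero_crossings(s, delta):
    sign = np.sign(delta)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    out = []
    for i in idx:
        d0, d1 = delta[i], delta[i + 1]
        if d1 == d0:
            out.append(float(s[i]))
        else:
            out.append(float(s[i] - d0 * (s[i + 1] - s[i]) / (d1 - d0)))
    return out


# ---------------------------------------------------------------------------
# waiting-time hump and its chain-length scaling
# ---------------------------------------------------------------------------

def hump_position(
    s_tilde,
    w_tilde,
    window: tuple[float, float] = (0.05, 0.95),
    smooth: int = 1,
) -> float:
    """s~* = argmax of w~(s~) inside an interior window.

    The window excludes the field-switch-on peak near s~ = 0 and the
    end-crowding overshoot near s~ = 1.  ``smooth`` > 1 applies a centred
    moving average of that many states before taking the argmax.
    """
    s_tilde = np.asarray(s_tilde, dtype=float)
    w_tilde = np.asarray(w_tilde, dtype=float)
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        w_tilde = np.convolve(w_tilde, kern, mode="same")
    sel = (s_tilde >= window[0]) & (s_tilde <= window[1])
    if not sel.any():
        raise ValueError("hump window excludes every state")
    sub_s = s_tilde[sel]
    sub_w = w_tilde[sel]
    return float(sub_s[np.argmax(sub_w)])


def hump_and_scaling(curves, window=(0.05, 0.95), smooth: int = 1):
    """Hump positions over (N, E) and the (N - s*) ~ N^beta scaling fit.

    ``curves`` maps (N, E) -> (s_tilde, w_tilde).  Returns a dict with the
    per-condition hump positions and, per field strength with >= 3 chain
    lengths, the log-log regression exponent of (N - s*) against N with its
    standard error.  Fewer than 3 chain lengths for every E raises.
    """
    humps = {}
    for (N, E), (st, wt) in curves.items():
        humps[(N, E)] = hump_position(st, wt, window=window, smooth=smooth)
    fields = sorted({E for (_, E) in humps})
    scaling = {}
    for E in fields:
        Ns = sorted(N for (N, e) in humps if e == E)
        if len(Ns) < 3:
            continue
        x = np.log(np.asarray(Ns, float))
        y = np.log([N - humps[(N, E)] * N for N in Ns])
        A = np.vstack([x, np.ones_like(x)]).T
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        n = len(Ns)
        se = 0.0
        if n > 2 and res.size:
            se = float(np.sqrt(res[0] / (n - 2) / ((x - x.mean()) ** 2).sum()))
        scaling[E] = {"exponent": float(coef[0]), "stderr": se, "n_lengths": n}
    if not scaling:
        raise ValueError("scaling fit needs at least 3 chain lengths for some E")
    return {"humps": humps, "scaling": scaling}
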