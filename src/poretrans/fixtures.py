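"""Synthetic fixtures with closed-form ground truth.

Every generator returns both the synthetic data and a ground-truth record
computed here from the construction parameters alone - independent of the
analysis modules - so the fixtures can serve as true oracles:

* rigid-rod translocation: a straight chain pushed through the pore at
  constant speed (exact s(t), constant waiting times, discrete-rod shape
  factor 12(n-1)/(n+1) for the n-bead sub-chain, D/Lambda = 1);
* ideal-coil ensemble: freely jointed chains (exact eta = 6N/(N+1) -> 6);
* uniform-ball ensemble: compact globules with random end beads (eta -> 2);
* log-normal passage times: i.i.d. samples from a stated log-normal;
* ramped-tension chain: prescribed bond lengths, hence prescribed tensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FixtureSpec",
    "make_fixture",
    "rigid_rod_translocation",
    "ideal_coil_ensemble",
    "uniform_ball_ensemble",
    "lognormal_passage_samples",
    "ramped_tension_chain",
    "rod_shape_factor",
    "coil_shape_factor",
]


def rod_shape_factor(n: int) -> float:
    """Exact shape factor of n collinear equally spaced beads: 12(n-1)/(n+1).

    Derived from the discrete sums Re^2 = (n-1)^2 b^2 and
    Rg^2 = (n^2-1) b^2 / 12; tends to 12 for a long rod and equals 4 for a
    two-bead segment and 6 for a three-bead rod.
    """
    if n < 2:
        raise ValueError("need at least two beads")
    return 12.0 * (n - 1) / (n + 1)


def coil_shape_factor(n: int) -> float:
    """Exact shape factor of an n-bead freely jointed chain: 6n/(n+1) -> 6."""
    return 6.0 * n / (n + 1)


@dataclass
class FixtureSpec:
    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    """Dispatch on ``spec.kind``; returns (data, ground_truth dict)."""
    kinds = {
        "rigid-rod": rigid_rod_translocation,
        "random-coil": ideal_coil_ensemble,
        "uniform-ball": uniform_ball_ensemble,
        "log-normal": lognormal_passage_samples,
        "ramped-tension": ramped_tension_chain,
    }
    if spec.kind not in kinds:
        raise ValueError(f"unknown fixture kind {spec.kind!r}; one of {sorted(kinds)}")
    return kinds[spec.kind](seed=spec.seed, **spec.params)


def rigid_rod_translocation(N: int = 16, speed: float = 1.0,
                            dt_frame: float = 0.05, wall_thickness: float = 4.5,
                            l0: float = 1.0, seed: int = 0):
    """A straight chain advancing along the pore axis at constant speed.

    Bead i sits at z_i(t) = w/2 + eps + speed*t - i*l0, so state s is entered
    at t_s = (s-1) l0/speed and every waiting time equals l0/speed.  Returns
    (frames, truth) where frames is a list of (time, positions) and truth
    holds s(t) at the frame times, the exact waiting times, tau, and the
    cis-side bead count and discrete-rod shape factor per frame.
    """
    if N < 2 or speed <= 0:
        raise ValueError("need N >= 2 and positive speed")
    eps = 1e-9
    half = wall_thickness / 2.0
    tau = (N - 1) * l0 / speed
    times = np.arange(0.0, tau + dt_frame, dt_frame)
    frames = []
    s_truth = []
    n_cis = []
    eta_cis = []
    idx = np.arange(N)
    for t in times:
        z = half + eps + speed * t - idx * l0
        pos = np.column_stack([np.zeros(N), np.zeros(N), z])
        frames.append((float(t), pos))
        s = int(np.sum(z > half))
        s_truth.append(s)
        nc = int(np.sum(z < -half))
        n_cis.append(nc)
        eta_cis.append(rod_shape_factor(nc) if nc >= 2 else np.nan)
    truth = {
        "tau": tau,
        "s": np.array(s_truth),
        "w": np.full(N - 1, l0 / speed),
        "n_cis": np.array(n_cis),
        "eta_cis": np.array(eta_cis),
        "speed": speed,
    }
    return frames, truth


def ideal_coil_ensemble(N: int = 128, n_conf: int = 500, bond: float = 1.0,
                        seed: int = 0):
    """Freely jointed chains: n_conf configurations of N beads.

    Ground truth: <Re^2> = (N-1) b^2, <Rg^2> = (N^2-1) b^2 / (6N), so the
    ensemble shape factor is exactly 6N/(N+1).
    """
    rng = np.random.default_rng(seed)
    confs = []
    for _ in range(n_conf):
        steps = rng.normal(size=(N - 1, 3))
        steps *= bond / np.linalg.norm(steps, axis=1)[:, None]
        pos = np.vstack([[0.0, 0.0, 0.0], np.cumsum(steps, axis=0)])
        confs.append(pos)
    truth = {
        "eta": coil_shape_factor(N),
        "re2": (N - 1) * bond**2,
        "rg2": (N * N - 1) * bond**2 / (6.0 * N),
    }
    return confs, truth


def uniform_ball_ensemble(n_beads: int = 200, n_conf: int = 500,
                          radius: float = 1.0, seed: int = 0):
    """Compact globules: beads uniform in a ball, chain ends at random beads.

    With independent uniform points, <Re^2> = 2 <r^2> = (6/5) R^2 and
    <Rg^2> -> (3/5) R^2, giving eta -> 2 - the compact-globule limit.
    """
    rng = np.random.default_rng(seed)
    confs = []
    for _ in range(n_conf):
        v = rng.normal(size=(n_beads, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        r = radius * rng.random(n_beads) ** (1.0 / 3.0)
        confs.append(v * r[:, None])
    truth = {"eta": 2.0, "re2": 1.2 * radius**2, "rg2": 0.6 * radius**2}
    return confs, truth


def lognormal_passage_samples(sigma: float = 0.3, mu: float = 50.0,
                              n: int = 10_000, seed: int = 0):
    """i.i.d. passage-time samples t ~ LogNormal(ln mu, sigma).

    Ground truth includes the closed-form mean mu exp(sigma^2/2) and the
    full width at half maximum of the density.
    """
    if sigma <= 0 or mu <= 0:
        raise ValueError("sigma and mu must be positive")
    rng = np.random.default_rng(seed)
    t = rng.lognormal(mean=np.log(mu), sigma=sigma, size=n)
    truth = {
        "sigma": sigma,
        "mu": mu,
        "mean": mu * np.exp(sigma**2 / 2.0),
        "fwhm": 2.0 * np.sinh(np.sqrt(2 * np.log(2)) * sigma)
        * np.exp(-(sigma**2)) * mu,
    }
    return t, truth


def ramped_tension_chain(N: int = 32, l_start: float = 1.0, l_end: float = 1.2,
                         k: float = 600.0, l0: float = 1.0, seed: int = 0):
    """A straight chain with bond lengths ramping linearly along the backbone.

    Ground truth tension per bond n is k (l_n - l0) with
    l_n = l_start + (l_end - l_start) n/(N-2).
    """
    if N < 2:
        raise ValueError("need at least two beads")
    nb = N - 1
    lengths = (np.full(nb, l_start) if nb == 1
               else l_start + (l_end - l_start) * np.arange(nb) / (nb - 1))
    z = np.concatenate([[0.0], np.cumsum(lengths)])
    pos = np.column_stack([np.zeros(N), np.zeros(N), z])
    truth = {"lengths": lengths, "tension": k * (lengths - l0)}
    return pos, truth
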