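"""Bond-tension propagation diagnostics.

The driving field acts only on monomers inside the pore channel, so the pull
is transmitted to the cis coil bond by bond.  The local tension is read off
the harmonic bonds,

    <f_n> = k (<l_n> - l_0),

averaged over runs on a (scaled time x scaled bond index) grid.  Two
geometric observables locate how far the pull has propagated:

* D_n - straight-line distance from monomer n to the pore entrance on its
  own side (the point where the pore axis meets the wall face);
* Lambda_n - contour distance along the backbone from monomer n to the
  first monomer inside the pore region.

Both vanish for monomers inside the channel, and Lambda_n >= D_n up to the
channel dimensions.  A cis section with <D_n>/<Lambda_n> above a threshold
(0.9 by default) is "straightened"; the tension front is the deepest cis
bond whose mean tension still exceeds the thermal background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import REGION_PORE, REGION_TRANS, classify_regions

__all__ = [
    "bond_tension_profile",
    "pore_distances",
    "straightened_section",
    "tension_front",
    "TensionProfile",
]


@dataclass
class TensionProfile:
    """Ensemble tension diagnostics on a scaled-time grid.

    ``tension[b, n]`` is <f_n> for bond n in scaled-time bin b; ``D`` and
    ``Lam`` are the matching per-monomer distance profiles and ``s_tilde``
    the mean scaled translocation coordinate per bin.
    """

    t_tilde: np.ndarray
    n_tilde: np.ndarray
    tension: np.ndarray
    D: np.ndarray
    Lam: np.ndarray
    s_tilde: np.ndarray
    n_frames: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Dense long-format table of the intensity map (t~ x n~ grid)."""
        tt, nn = np.meshgrid(self.t_tilde, self.n_tilde, indexing="ij")
        return pd.DataFrame(
            {"t_tilde": tt.ravel(), "n_tilde": nn.ravel(),
             "tension_kBT_per_sigma": self.tension.ravel()}
        )


def bond_tension_profile(
    trajectories,
    taus,
    k: float,
    l0: float,
    wall_thickness: float,
    n_bins: int = 20,
) -> TensionProfile:
    """Mean bond tension, pore distances and <s~> per scaled-time bin.

    Bond lengths are averaged over all frames of all runs falling in a bin
    first, then converted to tension (f is affine in <l>, so this equals the
    mean of per-frame tensions).  Scaled time uses each run's own tau_k.
    """
    first = _frames(trajectories[0])
    n_mono = first[0][1].shape[0]
    n_bond = n_mono - 1
    len_sum = np.zeros((n_bins, n_bond))
    d_sum = np.zeros((n_bins, n_mono))
    lam_sum = np.zeros((n_bins, n_mono))
    s_sum = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)

    for traj, tau in zip(trajectories, taus):
        for t, pos in _frames(traj):
            tt = t / tau
            if tt > 1.0 + 1e-12:
                continue
            b = min(int(tt * n_bins), n_bins - 1)
            bl = np.linalg.norm(np.diff(pos, axis=0), axis=1)
            len_sum[b] += bl
            D, Lam, _ = pore_distances(pos, wall_thickness)
            d_sum[b] += D
            lam_sum[b] += Lam
            labels = classify_regions(pos[:, 2], wall_thickness)
            s_sum[b] += np.count_nonzero(labels == REGION_TRANS) / n_mono
            count[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_len = len_sum / count[:, None]
        D = d_sum / count[:, None]
        Lam = lam_sum / count[:, None]
        s_tilde = s_sum / count
    return TensionProfile(
        t_tilde=(np.arange(n_bins) + 0.5) / n_bins,
        n_tilde=(np.arange(1, n_bond + 1)) / n_mono,
        tension=k * (mean_len - l0),
        D=D,
        Lam=Lam,
        s_tilde=s_tilde,
        n_frames=count,
    )


def _frames(traj):
    if hasattr(traj, "times") and hasattr(traj, "monomer_positions"):
        return [(float(t), traj.monomer_positions(i)) for i, t in enumerate(traj.times)]
    return [(float(t), np.asarray(p, dtype=float)) for t, p in traj]


def pore_distances(positions, wall_thickness: float):
    """(D_n, Lambda_n, flagged) for every monomer of one configuration.

    D_n is the Euclidean distance to the pore-axis point on the wall face of
    the monomer's own side; Lambda_n the backbone contour length, walked
    toward the pore, up to the point where the backbone crosses that wall
    face (so for a fully straight chain on the axis D_n = Lambda_n exactly,
    and a monomer whose path reaches the face after five unit bonds has
    Lambda = 5 whatever the path's shape).  Monomers inside region II get
    D = Lambda = 0 exactly.  If no monomer is in the pore (pre-release or
    post-completion) contour distances are measured to the chain bead
    nearest the pore mouth and ``flagged`` is True.
    """
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    half = wall_thickness / 2.0
    labels = classify_regions(pos[:, 2], wall_thickness)
    in_pore = np.nonzero(labels == REGION_PORE)[0]
    flagged = in_pore.size == 0

    mouth = np.where(pos[:, 2] >= 0, half, -half)
    D = np.sqrt(pos[:, 0] ** 2 + pos[:, 1] ** 2 + (pos[:, 2] - mouth) ** 2)

    bond = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(bond)])  # contour from monomer 0
    Lam = np.empty(n)
    if flagged:
        # no anchor in the channel: contour distance to the chain bead
        # nearest the pore mouth
        anchor = int(np.argmin(D))
        Lam = np.abs(cum - cum[anchor])
        return D, Lam, flagged

    lo, hi = in_pore.min(), in_pore.max()

    def walk(i, step):
        """Contour from monomer i to the wall-face crossing, stepping by
        +-1 along the backbone toward the pore."""
        face = half if pos[i, 2] > 0 else -half
        total = 0.0
        j = i
        while True:
            k = j + step
            zj, zk = pos[j, 2], pos[k, 2]
            blen = bond[min(j, k)]
            crossed = (zj - face) * (zk - face) <= 0.0
            if crossed:
                frac = abs(zj - face) / max(abs(zk - zj), 1e-12)
                return total + min(frac, 1.0) * blen
            total += blen
            j = k
            if (step < 0 and j <= lo) or (step > 0 and j >= hi):
                return total  # safety: anchor reached without crossing

    for i in range(n):
        if labels[i] == REGION_PORE:
            Lam[i] = 0.0
        elif i < lo:       # trans side (threads first)
            Lam[i] = walk(i, +1)
        elif i > hi:       # cis side
            Lam[i] = walk(i, -1)
        else:
            # between in-pore monomers but momentarily outside the slab
            below = in_pore[in_pore < i].max()
            above = in_pore[in_pore > i].min()
            Lam[i] = min(cum[i] - cum[below], cum[above] - cum[i])
    D = np.where(labels == REGION_PORE, 0.0, D)
    return D, Lam, flagged


def straightened_section(D, Lam, threshold: float = 0.9) -> int:
    """Depth (in monomers) of the straightened cis section.

    ``D`` and ``Lam`` are the ensemble profiles for the cis sub-chain,
    ordered from the pore outward.  Returns the largest depth such that all
    monomers between the pore and that depth satisfy <D>/<Lam> >= threshold
    (ratio of means); 0 if the first cis monomer already fails.
    """
    D = np.asarray(D, dtype=float)
    Lam = np.asarray(Lam, dtype=float)
    if D.shape != Lam.shape:
        raise ValueError("D and Lam must have matching shapes")
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(Lam > 0, D / Lam, 1.0)
    bad = np.nonzero(ratio < threshold)[0]
    return int(bad[0]) if bad.size else int(D.size)


def tension_front(
    profile,
    background: float | None = None,
    background_se: float = 0.0,
    n_se: float = 3.0,
    s_tilde: float | None = None,
) -> int | None:
    """Index of the tension front in a tension profile over the bond index.

    ``profile`` holds <f_n> in ascending bond order n = 1..N-1 (small
    indices threaded first, last entry = the free cis end).  The front is
    the deepest cis bond (largest index) whose tension exceeds
    ``background + n_se * background_se``, found by scanning from the free
    end toward the pore.  Returns None when no bond exceeds the threshold
    (weak-field case: the surge is buried in thermal fluctuations).

    When ``background`` is None the trans-side plateau - the bonds already
    pulled through the pore, located by the scaled coordinate ``s_tilde`` -
    estimates the plateau level and its standard error.
    """
    f = np.asarray(profile, dtype=float)
    finite = np.isfinite(f)
    if not finite.any():
        return None
    if background is None:
        if s_tilde is None:
            raise ValueError("provide either an explicit background or s_tilde "
                             "to locate the trans-side plateau")
        n_bg = int(s_tilde * (f.size + 1)) - 1
        n_bg = max(2, min(n_bg, f.size))
        bg = f[:n_bg][finite[:n_bg]]
        if bg.size < 2:
            bg = f[finite][:2]
        background = float(bg.mean())
        background_se = float(bg.std(ddof=1) / np.sqrt(bg.size))
    cut = background + n_se * background_se
    above = np.nonzero(finite & (f > cut))[0]
    if above.size == 0:
        return None
    return int(above[-1])
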