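"""Sub-chain shape and orientation descriptors.

For a set of beads C the gyration tensor is

    G_ab = (1/N_C) sum_{i in C} (r_i - r_cm)_a (r_i - r_cm)_b,

with eigenvalues l1 >= l2 >= l3 >= 0 (squared semi-axes of the equivalent
ellipsoid; their trace is Rg^2).  From them:

    shape factor   eta = <Re^2> / <Rg^2>
                        (12 for a long rod, ~6 for an ideal coil, 2 for a
                         compact globule with randomly placed ends)
    asphericity    A = [(l1-m)^2 + (l2-m)^2 + (l3-m)^2] / (6 m^2),  m = tr/3
    prolateness    P = (l1-m)(l2-m)(l3-m) / m^3

A is in [0, 1] (0 = sphere, 1 = rod); P is in [-0.25, 2] (negative = oblate,
positive = prolate; a flat disk sits at (A, P) = (0.25, -0.25)).

The principal-axis orientation is the eigenvector of l1, sign-fixed to
e1z >= 0, expressed as a polar angle theta (from +z) and azimuth phi
(from +x), in degrees.

During a translocation the descriptors are computed separately for the cis
(I) and trans (III) sub-chains and binned on the scaled time axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import REGION_CIS, REGION_TRANS, classify_regions

__all__ = [
    "shape_factor",
    "gyration_tensor",
    "asphericity_prolateness",
    "principal_angles",
    "conformation_timeseries",
    "ShapeDescriptors",
]


def shape_factor(positions) -> float:
    """eta = <Re^2>/<Rg^2> for one configuration or an ensemble of them.

    ``positions`` is an (n, 3) array (single configuration: the means reduce
    to the configuration's own Re^2 and Rg^2) or a sequence of such arrays
    (ensemble: Re^2 and Rg^2 are averaged separately before taking the
    ratio).  The chain ends are the first and last bead of each
    configuration.
    """
    confs = _as_conf_list(positions)
    re2 = np.empty(len(confs))
    rg2 = np.empty(len(confs))
    for i, pos in enumerate(confs):
        if pos.shape[0] < 2:
            raise ValueError("shape factor needs at least two beads")
        d = pos[-1] - pos[0]
        re2[i] = d @ d
        c = pos - pos.mean(axis=0)
        rg2[i] = (c * c).sum() / pos.shape[0]
    mean_rg2 = rg2.mean()
    if mean_rg2 <= 0:
        raise ValueError("all beads coincide: Rg^2 = 0, shape factor undefined")
    return float(re2.mean() / mean_rg2)


def _as_conf_list(positions) -> list[np.ndarray]:
    if isinstance(positions, np.ndarray) and positions.ndim == 2:
        return [np.asarray(positions, dtype=float)]
    return [np.asarray(p, dtype=float) for p in positions]


def gyration_tensor(positions) -> tuple[np.ndarray, np.ndarray]:
    """Gyration tensor about the center of mass and its sorted eigenvalues.

    Returns (G, eigenvalues) with eigenvalues descending, so that
    ``eigenvalues.sum() == Rg^2`` of the bead set.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    c = pos - pos.mean(axis=0)
    G = c.T @ c / pos.shape[0]
    vals = np.linalg.eigvalsh(G)[::-1]
    return G, np.clip(vals, 0.0, None)


def asphericity_prolateness(l1: float, l2: float, l3: float) -> tuple[float, float]:
    """(A, P) from sorted gyration-tensor eigenvalues l1 >= l2 >= l3 >= 0."""
    if not (l1 >= l2 >= l3 >= 0):
        raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 >= 0")
    m = (l1 + l2 + l3) / 3.0
    if m <= 0:
        raise ValueError("all eigenvalues zero: shape descriptors undefined")
    d1, d2, d3 = l1 - m, l2 - m, l3 - m
    A = (d1 * d1 + d2 * d2 + d3 * d3) / (6.0 * m * m)
    P = d1 * d2 * d3 / m**3
    return float(A), float(P)


def principal_angles(G, degeneracy_rtol: float = 1e-9) -> tuple[float, float, bool]:
    """Polar and azimuthal angles (degrees) of the largest principal axis.

    The eigenvector e1 of the largest eigenvalue is sign-fixed to e1z >= 0
    (for e1z == 0, to e1x >= 0) and converted with full quadrant resolution:

        theta = atan2(sqrt(e1x^2 + e1y^2), e1z)  in [0, 180]
        phi   = atan2(e1y, e1x)                  in (-180, 180]

    Returns (theta, phi, degenerate); when l1 == l2 within tolerance the
    axis is not unique and ``degenerate`` is True (angles still returned
    from the numerically chosen eigenvector).
    """
    G = np.asarray(G, dtype=float)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    e1 = vecs[:, order[0]]
    degenerate = bool(np.isclose(vals[0], vals[1], rtol=degeneracy_rtol, atol=1e-15))
    if e1[2] < 0 or (e1[2] == 0 and (e1[0] < 0 or (e1[0] == 0 and e1[1] < 0))):
        e1 = -e1
    theta = np.degrees(np.arctan2(np.hypot(e1[0], e1[1]), e1[2]))
    phi = np.degrees(np.arctan2(e1[1], e1[0])) if np.hypot(e1[0], e1[1]) > 0 else 0.0
    return float(theta), float(phi), degenerate


@dataclass
class ShapeDescriptors:
    """Binned descriptors of one sub-chain on the scaled time axis."""

    region: int
    t_tilde: float
    eta: float
    re2: float
    rg2: float
    eigenvalues: np.ndarray
    asphericity: float
    prolateness: float
    theta: float
    phi: float
    n_samples: int
    flagged: bool = False


def conformation_timeseries(
    trajectories,
    taus,
    region: int,
    wall_thickness: float,
    n_bins: int = 20,
    time_mode: str = "per-run",
    tau_mean: float | None = None,
) -> pd.DataFrame:
    """Per-scaled-time-bin shape descriptors of one sub-chain.

    Parameters
    ----------
    trajectories:
        Sequence of per-run frame sets; each is an iterable of
        (time, monomer_positions) pairs or an object with ``times`` and
        ``monomer_positions(i)`` (see :class:`poretrans.engine.Trajectory`).
    taus:
        Per-run translocation times tau_k.
    region:
        ``REGION_CIS`` or ``REGION_TRANS``.
    time_mode:
        'per-run' scales each run's time by its own tau_k so every run spans
        [0, 1]; 'ensemble' divides by the ensemble mean (runs then end at
        different scaled times).

    Bins whose sub-chain has fewer than 2 beads in every contributing frame
    are flagged (NaN descriptors, n_samples reported).
    """
    if region not in (REGION_CIS, REGION_TRANS):
        raise ValueError("region must be REGION_CIS or REGION_TRANS")
    if time_mode not in ("per-run", "ensemble"):
        raise ValueError("time_mode must be 'per-run' or 'ensemble'")
    if time_mode == "ensemble" and tau_mean is None:
        tau_mean = float(np.mean(taus))

    acc: list[list] = [[] for _ in range(n_bins)]
    for traj, tau in zip(trajectories, taus):
        denom = tau if time_mode == "per-run" else tau_mean
        if denom <= 0:
            raise ValueError("translocation time must be positive")
        for t, pos in _iter_frames(traj):
            tt = t / denom
            if tt > 1.0 + 1e-12:
                continue
            b = min(int(tt * n_bins), n_bins - 1)
            labels = classify_regions(pos[:, 2], wall_thickness)
            sub = pos[labels == region]
            acc[b].append(sub)

    rows = []
    for b in range(n_bins):
        tt = (b + 0.5) / n_bins
        subs = [s for s in acc[b] if s.shape[0] >= 2]
        if not subs:
            rows.append(
                dict(t_tilde=tt, region=region, eta=np.nan, asphericity=np.nan,
                     prolateness=np.nan, theta=np.nan, phi=np.nan,
                     re2=np.nan, rg2=np.nan, n_samples=len(acc[b]), flagged=True)
            )
            continue
        re2 = rg2 = 0.0
        A_l, P_l, th_l, ph_l = [], [], [], []
        for sub in subs:
            d = sub[-1] - sub[0]
            re2 += d @ d
            G, vals = gyration_tensor(sub)
            rg2 += vals.sum()
            A, P = asphericity_prolateness(*vals)
            th, ph, _ = principal_angles(G)
            A_l.append(A)
            P_l.append(P)
            th_l.append(th)
            ph_l.append(ph)
        n = len(subs)
        rows.append(
            dict(t_tilde=tt, region=region, eta=(re2 / n) / (rg2 / n),
                 asphericity=float(np.mean(A_l)), prolateness=float(np.mean(P_l)),
                 theta=float(np.mean(th_l)), phi=float(np.mean(ph_l)),
                 re2=re2 / n, rg2=rg2 / n, n_samples=n, flagged=False)
        )
    return pd.DataFrame(rows)


def _iter_frames(traj):
    if hasattr(traj, "times") and hasattr(traj, "monomer_positions"):
        for i, t in enumerate(traj.times):
            yield float(t), traj.monomer_positions(i)
    else:
        for t, pos in traj:
            yield float(t), np.asarray(pos, dtype=float)
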