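"""Region classification, translocation coordinate and waiting-time statistics.

The membrane wall is centered on z = 0 with thickness w.  Space is split into
the cis region I (z < -w/2), the pore channel II (|z| <= w/2, closed
interval) and the trans region III (z > w/2).  The translocation coordinate
``s`` counts the monomers in region III; it runs from ~1 at release to N at
completion.

For a single completed run k, the waiting time w_k(s) is the total time the
chain spends at coordinate s (revisits accumulate), for s = 1..N-1; the
terminal state N is excluded because the chain dwells there permanently.
The per-run identity sum_s w_k(s) = tau_k holds exactly.  Over an ensemble
of M runs, w(s) = mean_k w_k(s) and the normalized form
w~(s~) = N w(s) / <tau> on s~ = s/N integrates to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REGION_CIS",
    "REGION_PORE",
    "REGION_TRANS",
    "classify_regions",
    "translocation_coordinate",
    "waiting_times",
    "ensemble_waiting",
    "TranslocationRecord",
    "EnsembleRecord",
    "IncompleteRunError",
]

REGION_CIS = 1
REGION_PORE = 2
REGION_TRANS = 3


class IncompleteRunError(ValueError):
    """Raised when statistics requiring a completed run get a truncated one."""


def classify_regions(z, wall_thickness: float):
    """Region labels (1=I cis, 2=II pore, 3=III trans) for z coordinates.

    The pore interval is closed: z exactly at +-w/2 belongs to region II.
    """
    z = np.asarray(z, dtype=float)
    half = wall_thickness / 2.0
    labels = np.full(z.shape, REGION_PORE, dtype=np.int8)
    labels[z < -half] = REGION_CIS
    labels[z > half] = REGION_TRANS
    if labels.ndim == 0:
        return int(labels)
    return labels


def translocation_coordinate(monomer_z, wall_thickness: float) -> int:
    """s = number of monomers strictly beyond the trans face of the wall."""
    z = np.asarray(monomer_z, dtype=float)
    return int(np.count_nonzero(z > wall_thickness / 2.0))


@dataclass
class TranslocationRecord:
    """Per-run bookkeeping of one translocation.

    ``times``/``s`` hold the (sub-sampled) coordinate series; ``waiting`` is
    the exact per-integrator-step dwell time, indexed by state (entry 0 and
    entry N are bookkeeping only; the analysis states are 1..N-1).
    ``first_passage[s]`` is the first-arrival time at state s.
    """

    run_id: int
    seed: int
    n_monomers: int
    times: np.ndarray
    s: np.ndarray
    waiting: np.ndarray
    first_passage: np.ndarray
    tau: float
    completed: bool
    pre_release_s: int = 1
    max_step_jump: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def states(self) -> np.ndarray:
        """The analysis states 1..N-1."""
        return np.arange(1, self.n_monomers)

    @property
    def w(self) -> np.ndarray:
        """Waiting times over states 1..N-1."""
        return self.waiting[1:self.n_monomers]

    def check_identity(self, rtol: float = 1e-9) -> bool:
        """sum_s w_k(s) = tau_k (exact up to float summation)."""
        return bool(np.isclose(self.w.sum() + self.waiting[0], self.tau, rtol=rtol))


def waiting_times(times, s, n_monomers: int) -> tuple[np.ndarray, float]:
    """Waiting times w_k(s) for s = 1..N-1 from a sampled s(t) series.

    Each sampling interval [t_i, t_{i+1}) is attributed to the state s_i.
    The run must reach s = N; the translocation time tau is the time of the
    first arrival there, and the dwell intervals up to tau sum to tau
    exactly.  Returns (w indexed 0..N, tau); states outside 1..N-1 carry any
    residual dwell at s = 0.
    """
    times = np.asarray(times, dtype=float)
    s = np.asarray(s, dtype=np.int64)
    if times.shape != s.shape or times.ndim != 1:
        raise ValueError("times and s must be 1D arrays of equal length")
    hits = np.nonzero(s >= n_monomers)[0]
    if hits.size == 0:
        raise IncompleteRunError(
            f"series never reaches s = N = {n_monomers}; incomplete run"
        )
    end = hits[0]
    tau = times[end] - times[0]
    w = np.zeros(n_monomers + 1, dtype=float)
    dt = np.diff(times[: end + 1])
    np.add.at(w, np.clip(s[:end], 0, n_monomers), dt)
    return w, tau


@dataclass
class EnsembleRecord:
    """Aggregated waiting-time statistics over M completed runs."""

    n_monomers: int
    records: list
    tau_mean: float
    w: np.ndarray          # mean waiting time, states 1..N-1
    w_tilde: np.ndarray    # N w / <tau>
    s_tilde: np.ndarray    # s / N for s = 1..N-1

    @property
    def M(self) -> int:
        return len(self.records)

    def w_tilde_integral(self) -> float:
        """Exact step-function quadrature of w~ over s~ (equals 1)."""
        return float(self.w.sum() / self.tau_mean)

    def w_tilde_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """Step-function polyline (s~ edges, w~) whose trapezoid integral is
        exact: each state s occupies the bin [(s-1/2)/N, (s+1/2)/N]."""
        N = self.n_monomers
        edges = (np.arange(1, N)[:, None] + np.array([-0.5, 0.5])[None, :]) / N
        st = edges.ravel()
        wt = np.repeat(self.w_tilde, 2)
        return st, wt


def ensemble_waiting(records: list, n_monomers: int | None = None) -> EnsembleRecord:
    """Average waiting times over completed runs (Eqs. for w(s) and w~(s~))."""
    records = [r for r in records if r.completed]
    if not records:
        raise ValueError("empty ensemble: no completed runs")
    if n_monomers is None:
        n_monomers = records[0].n_monomers
    if any(r.n_monomers != n_monomers for r in records):
        raise ValueError("all records must share the same chain length N")
    W = np.stack([r.w for r in records])
    w = W.mean(axis=0)
    # tau from the same bookkeeping so that sum(w)/tau_mean == 1 exactly
    tau_mean = float(np.mean([r.w.sum() + r.waiting[0] for r in records]))
    s = np.arange(1, n_monomers)
    return EnsembleRecord(
        n_monomers=n_monomers,
        records=records,
        tau_mean=tau_mean,
        w=w,
        w_tilde=n_monomers * w / tau_mean,
        s_tilde=s / n_monomers,
    )
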