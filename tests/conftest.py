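"""Shared fixtures: small helper states and the reduced-scale ensembles.

The two session-scoped ensembles (N = 32, M = 32 at a weak and a strong
driving field, screened electrostatics) are the study conditions for the
qualitative reduced-scale checks; they are generated once and shared by the
engine, tracking and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from poretrans import engine
from poretrans.system import ParticleState, SystemConfig

try:
    from hypothesis import settings

    settings.register_profile("ci", deadline=None, derandomize=True,
                              max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def saw_positions(n: int, rng, bond: float = 1.0, min_dist: float = 1.05
                  ) -> np.ndarray:
    """Self-avoiding chain coordinates for overlap-free engine test states."""
    pos = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(500):
            v = rng.normal(size=3)
            v *= bond / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if i < 2 or np.min(np.linalg.norm(pos[: i - 1] - cand, axis=1)) > min_dist:
                pos[i] = cand
                break
        else:  # pragma: no cover
            raise RuntimeError("saw growth failed")
    return pos


def free_state(pos: np.ndarray, charges=None, box=(60.0, 60.0, 120.0),
               velocities=None) -> ParticleState:
    """A wall-less, all-mobile state (free chain or free beads)."""
    n = pos.shape[0]
    return ParticleState(
        positions=np.array(pos, dtype=float),
        velocities=np.zeros((n, 3)) if velocities is None else np.array(velocities),
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        species=np.zeros(n, dtype=np.int8),
        mobile=np.ones(n, dtype=bool),
        n_monomers=n,
        box=box,
    )


def free_chain_config(n: int, **kw) -> SystemConfig:
    defaults = dict(N=n, box=(60.0, 60.0, 120.0), electrostatics="none",
                    n_salt=0, explicit_ions=False)
    defaults.update(kw)
    return SystemConfig(**defaults)


@pytest.fixture(scope="session")
def weak_ensemble():
    """N=32, M=32 translocations at the weakest studied field E=0.2."""
    cfg = SystemConfig.desk(N=32, E=0.2)
    records, _ = engine.run_ensemble(cfg, M=32, seed=1)
    return cfg, records


@pytest.fixture(scope="session")
def strong_ensemble():
    """N=32, M=32 translocations at the strongest studied field E=32."""
    cfg = SystemConfig.desk(N=32, E=32.0, frame_stride=20)
    records, trajs = engine.run_ensemble(cfg, M=32, seed=1,
                                         keep_trajectories=True)
    return cfg, records, trajs


@pytest.fixture(scope="session")
def small_run_pair():
    """Six N=16 runs each at a moderate and a strong field (speed check)."""
    out = {}
    for E in (4.0, 32.0):
        cfg = SystemConfig.desk(N=16, E=E, equilibration_steps=10_000)
        records, _ = engine.run_ensemble(cfg, M=6, seed=5)
        out[E] = (cfg, records)
    return out
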