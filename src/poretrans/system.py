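"""System construction: walled box with a cylindrical pore, threaded chain,
counterions and salt, plus the constrained pre-equilibration.

Geometry convention: the membrane wall is centered on z = 0 with its pore
along the z axis; cis is -z, trans is +z.  The wall is hollow - two square
lattices of immobile beads whose excluded volume (WCA with sigma_bw) closes
the lattice gaps - with the beads inside the pore radius removed to open the
channel.  The chain starts threaded: its head section lies along the pore
axis with the head monomer just outside the trans face, and the rest of the
chain is grown as a cis-side self-avoiding walk.  Counterions (one +1 ion
per monomer) and salt pairs fill the fluid space at random without overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .tracking import translocation_coordinate
from .units import SaltSpec, UnitSystem, osf_persistence_length

__all__ = [
    "SystemConfig",
    "ParticleState",
    "build_system",
    "build_wall",
    "equilibrate_initial",
    "PlacementError",
    "SPECIES_MONOMER",
    "SPECIES_COUNTERION",
    "SPECIES_CATION",
    "SPECIES_ANION",
    "SPECIES_WALL",
    "SPECIES_NAMES",
]

SPECIES_MONOMER = 0
SPECIES_COUNTERION = 1
SPECIES_CATION = 2
SPECIES_ANION = 3
SPECIES_WALL = 4
SPECIES_NAMES = {
    SPECIES_MONOMER: "M",
    SPECIES_COUNTERION: "C",
    SPECIES_CATION: "P",
    SPECIES_ANION: "N",
    SPECIES_WALL: "W",
}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}


class PlacementError(RuntimeError):
    """Random insertion failed after bounded retries; names the crowded region."""


@dataclass
class SystemConfig:
    """All physical and numerical parameters of one simulation.

    Defaults are the full-scale study conditions (paper-scale box and salt);
    :meth:`desk` returns the reduced-scale configuration used for fast,
    qualitative ensembles.  Units: sigma, tau_u, kBT, e; friction in
    m/tau_u.
    """

    N: int = 256
    E: float = 1.0                      # field strength, kBT/(e sigma)
    box: tuple = (48.0, 49.36, 200.0)
    wall_thickness: float = 4.5
    pore_radius: float = 2.25
    k: float = 600.0                    # bond spring constant, kBT/sigma^2
    l0: float = 1.0                     # equilibrium bond length, sigma
    sigma_bb: float = 1.0               # WCA, mobile-mobile
    eps_bb: float = 1.2
    sigma_bw: float = 1.5               # WCA, mobile-wall
    eps_bw: float = 2.5
    bjerrum: float = 3.0                # lambda_B, sigma
    n_salt: int = 256
    monomer_charge: float = -1.0
    zeta: float = 1.0                   # Langevin friction, m/tau_u
    dt: float = 0.005                   # integration step, tau_u
    mass: float = 1.0
    kBT: float = 1.0
    seed: int = 0
    electrostatics: str = "direct"      # direct | screened | none
    elec_cutoff: float = 10.0
    debye_length: float | None = None   # screened mode; None = from salt spec
    charge_scale_elec: float | None = None  # None: 1 (explicit ions) or Manning
    explicit_ions: bool = True
    equilibration_steps: int = 50_000
    step_budget: int = 5_000_000
    sample_stride: int = 10             # s(t) sub-sampling, steps
    frame_stride: int = 0               # 0 = no frames
    wall_spacing: float = 1.5           # wall lattice constant, sigma
    wall_contact_offset: float = 1.5    # layer inset from the nominal face
    gate_sigma: float = 1.0             # exit-gate WCA length
    gate_eps: float = 1.2
    gate_offset: float = 0.35           # zero-force point above the exit face
    pbc_z: bool = False                 # full 3D periodicity flag

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.N < 2:
            raise ValueError("N must be at least 2")
        if self.pore_radius >= min(self.box[0], self.box[1]) / 2:
            raise ValueError("pore radius must fit inside the box cross-section")
        if self.wall_thickness >= self.box[2]:
            raise ValueError("wall thickness must be smaller than the box height")
        for name in ("k", "l0", "sigma_bb", "eps_bb", "sigma_bw", "eps_bw",
                     "bjerrum", "zeta", "dt", "mass", "kBT"):
            if getattr(self, name) <= 0 and name != "zeta":
                raise ValueError(f"{name} must be positive")
        if self.zeta < 0:
            raise ValueError("friction must be non-negative")
        if self.electrostatics not in ("direct", "screened", "none"):
            raise ValueError("electrostatics mode must be direct|screened|none")

    @property
    def half_wall(self) -> float:
        return self.wall_thickness / 2.0

    def debye_length_value(self) -> float:
        """Screening length for 'screened' mode; defaults to kappa^-1 of the
        study's salt conditions (256 molecules in the full-scale box)."""
        if self.debye_length is not None:
            return self.debye_length
        spec = SaltSpec()
        osf = osf_persistence_length(spec, UnitSystem(bjerrum_sigma=self.bjerrum))
        return osf.debye_length_sigma

    def elec_charge_scale(self) -> float:
        """Effective-charge factor for the screened pair interactions.

        Explicit-ion systems use the bare charges (counterion condensation
        emerges from the explicit ions themselves).  Implicit-ion systems
        above the Manning threshold (lambda_B > l_c) rescale the interacting
        charge by the condensation fraction l_c/lambda_B, the standard
        implicit-salt correction; without it the chain is far stiffer than
        the real, condensed system.
        """
        if self.charge_scale_elec is not None:
            return self.charge_scale_elec
        if self.explicit_ions or self.electrostatics != "screened":
            return 1.0
        return min(1.0, self.l0 / self.bjerrum)

    @classmethod
    def desk(cls, N: int = 32, E: float = 8.0, **kw) -> "SystemConfig":
        """Reduced-scale configuration for qualitative desk ensembles:
        small box, implicit ions with Debye-Hueckel screening at the study's
        salt concentration."""
        defaults = dict(
            N=N, E=E, box=(20.0, 20.0, 80.0), n_salt=0, explicit_ions=False,
            electrostatics="screened", elec_cutoff=8.0,
            equilibration_steps=50_000, step_budget=3_000_000,
        )
        defaults.update(kw)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["box"] = list(self.box)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SystemConfig":
        d = dict(d)
        if "box" in d:
            d["box"] = tuple(d["box"])
        return cls(**d)

    def with_(self, **kw) -> "SystemConfig":
        return replace(self, **kw)


@dataclass
class ParticleState:
    """Positions, velocities and identities of every bead at one time.

    Mobile beads come first (monomers 0..N-1, then ions); wall beads last
    and immobile.  Bonds connect consecutive monomers.
    """

    positions: np.ndarray
    velocities: np.ndarray
    charges: np.ndarray
    species: np.ndarray
    mobile: np.ndarray
    n_monomers: int
    box: tuple
    meta: dict = field(default_factory=dict)

    @property
    def n_mobile(self) -> int:
        return int(self.mobile.sum())

    @property
    def bonds(self) -> np.ndarray:
        i = np.arange(self.n_monomers - 1)
        return np.stack([i, i + 1], axis=1)

    @property
    def wall_positions(self) -> np.ndarray:
        return self.positions[~self.mobile]

    def monomer_positions(self) -> np.ndarray:
        return self.positions[: self.n_monomers]

    def net_charge(self) -> float:
        return float(self.charges.sum())

    def copy(self) -> "ParticleState":
        return ParticleState(
            positions=self.positions.copy(), velocities=self.velocities.copy(),
            charges=self.charges.copy(), species=self.species.copy(),
            mobile=self.mobile.copy(), n_monomers=self.n_monomers,
            box=self.box, meta=dict(self.meta),
        )


def build_wall(cfg: SystemConfig) -> np.ndarray:
    """Two square-lattice layers of immobile beads with the pore cleared.

    The layers sit at z = +-(wall_thickness/2 - wall_contact_offset): with
    the default offset equal to sigma_bw, the WCA contact surface felt by
    mobile beads coincides with the nominal wall faces at +-w/2.
    """
    bx, by, _ = cfg.box
    nx = max(1, round(bx / cfg.wall_spacing))
    ny = max(1, round(by / cfg.wall_spacing))
    xs = (np.arange(nx) + 0.5) * (bx / nx) - bx / 2
    ys = (np.arange(ny) + 0.5) * (by / ny) - by / 2
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    keep = X**2 + Y**2 >= cfg.pore_radius**2
    layer = np.stack([X[keep], Y[keep]], axis=1)
    z_off = cfg.half_wall - cfg.wall_contact_offset
    top = np.column_stack([layer, np.full(len(layer), +z_off)])
    bot = np.column_stack([layer, np.full(len(layer), -z_off)])
    return np.vstack([top, bot])


def _head_section_length(cfg: SystemConfig) -> int:
    return int(math.ceil(cfg.wall_thickness / cfg.l0)) + 1


def head_release_z(cfg: SystemConfig) -> float:
    """Constraint point of the head monomer: the exit-gate zero-force plane."""
    return cfg.half_wall + cfg.gate_offset


def build_system(cfg: SystemConfig) -> ParticleState:
    """Assemble wall, threaded chain, counterions and salt.

    Deterministic for a fixed ``cfg.seed``.  Raises :class:`PlacementError`
    when random insertion cannot find room.
    """
    rng = np.random.default_rng(cfg.seed)
    wall = build_wall(cfg)
    bx, by, bz = cfg.box

    # --- chain: head section down the pore axis, rest a cis-side SAW ------
    n_thread = min(_head_section_length(cfg), cfg.N)
    chain = np.zeros((cfg.N, 3))
    z_head = head_release_z(cfg)
    for i in range(n_thread):
        chain[i] = (0.0, 0.0, z_head - i * cfg.l0)
    min_mm = 0.9 * cfg.sigma_bb
    min_mw = 0.8 * cfg.sigma_bw
    z_cis_max = min(chain[n_thread - 1, 2], -cfg.half_wall - 0.1)
    i = n_thread
    backtracks = 0
    while i < cfg.N:
        placed = False
        for _ in range(200):
            v = rng.normal(size=3)
            v *= cfg.l0 / np.linalg.norm(v)
            cand = chain[i - 1] + v
            if cand[2] > z_cis_max or cand[2] < -bz / 2 + 1.0:
                continue
            if abs(cand[0]) > bx / 2 - 0.5 or abs(cand[1]) > by / 2 - 0.5:
                continue
            d = np.linalg.norm(chain[: i - 1] - cand, axis=1)
            if d.size and d.min() < min_mm:
                continue
            dw = np.linalg.norm(wall - cand, axis=1)
            if dw.min() < min_mw:
                continue
            chain[i] = cand
            placed = True
            break
        if placed:
            i += 1
        else:
            # back out of the dead end and regrow
            backtracks += 1
            if backtracks > 200:
                raise PlacementError(
                    f"could not grow cis chain bead {i} without overlap "
                    f"(crowded region near z = {chain[i - 1, 2]:.1f})"
                )
            i = max(n_thread, i - 8)

    # --- ions --------------------------------------------------------------
    n_ci = cfg.N if cfg.explicit_ions else 0
    n_salt = cfg.n_salt if cfg.explicit_ions else 0
    n_ions = n_ci + 2 * n_salt
    ions = np.zeros((n_ions, 3))
    occupied = [chain]
    placed_ions = []
    for j in range(n_ions):
        ok = False
        for _ in range(2000):
            cand = np.array([
                rng.uniform(-bx / 2, bx / 2),
                rng.uniform(-by / 2, by / 2),
                rng.uniform(-bz / 2 + 1.0, bz / 2 - 1.0),
            ])
            if abs(cand[2]) < cfg.half_wall + 1.0:
                continue
            near = False
            for arr in occupied:
                d2 = ((arr - cand) ** 2).sum(axis=1)
                if d2.min() < min_mm**2:
                    near = True
                    break
            if near:
                continue
            if np.linalg.norm(wall - cand, axis=1).min() < min_mw:
                continue
            ions[j] = cand
            placed_ions.append(cand)
            occupied = [chain, np.asarray(placed_ions)]
            ok = True
            break
        if not ok:
            raise PlacementError(f"could not place ion {j}: fluid region crowded")

    n_mobile = cfg.N + n_ions
    n_total = n_mobile + len(wall)
    positions = np.vstack([chain, ions, wall]) if n_ions else np.vstack([chain, wall])
    velocities = np.zeros((n_total, 3))
    charges = np.zeros(n_total)
    species = np.full(n_total, SPECIES_WALL, dtype=np.int8)
    mobile = np.zeros(n_total, dtype=bool)
    mobile[:n_mobile] = True

    charges[: cfg.N] = cfg.monomer_charge
    species[: cfg.N] = SPECIES_MONOMER
    off = cfg.N
    charges[off : off + n_ci] = +1.0
    species[off : off + n_ci] = SPECIES_COUNTERION
    off += n_ci
    charges[off : off + n_salt] = +1.0
    species[off : off + n_salt] = SPECIES_CATION
    off += n_salt
    charges[off : off + n_salt] = -1.0
    species[off : off + n_salt] = SPECIES_ANION

    if cfg.explicit_ions and abs(charges.sum()) > 1e-9:
        raise AssertionError("built system is not charge neutral")

    state = ParticleState(
        positions=positions, velocities=velocities, charges=charges,
        species=species, mobile=mobile, n_monomers=cfg.N, box=cfg.box,
        meta={"seed": cfg.seed, "head_z": z_head},
    )
    state.meta["s_built"] = translocation_coordinate(
        state.monomer_positions()[:, 2], cfg.wall_thickness
    )
    return state


def equilibrate_initial(state: ParticleState, cfg: SystemConfig,
                        steps: int | None = None, seed: int | None = None
                        ) -> ParticleState:
    """Relax the built system with the head pinned at the pore exit.

    Langevin dynamics with the driving field OFF and the head monomer
    position-constrained at its release point; non-head monomers are kept on
    the cis side of the exit face by a soft confinement plane so that every
    run is released from exactly s = 1.  Records the pre-release s in
    ``state.meta``.  ``steps=0`` returns the state unchanged.
    """
    from . import engine  # deferred: numba compilation only when needed

    if steps is None:
        steps = cfg.equilibration_steps
    if steps < 0:
        raise ValueError("steps must be non-negative")
    out = state.copy()
    if steps == 0:
        out.meta["s_pre_release"] = translocation_coordinate(
            out.monomer_positions()[:, 2], cfg.wall_thickness
        )
        return out
    engine.integrate(
        out, cfg, n_steps=steps,
        seed=cfg.seed + 1 if seed is None else seed,
        field_on=False, gate_on=False, constrain_head=True, confine_trans=True,
    )
    s_pre = translocation_coordinate(out.monomer_positions()[:, 2],
                                     cfg.wall_thickness)
    if s_pre < 1:
        raise RuntimeError("chain retracted past the pore during equilibration")
    out.meta["s_pre_release"] = s_pre
    return out
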