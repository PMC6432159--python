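"""Force field and Langevin integrator; runs single driven translocations.

Interactions (reduced units: sigma, m, tau_u, kBT):

* WCA excluded volume between all bead pairs, U = 4 eps [(s/r)^12 - (s/r)^6]
  + eps for r < 2^(1/6) s, zero beyond (energy- and force-continuous at the
  cutoff);
* harmonic bonds U = (k/2)(l - l0)^2 between consecutive monomers;
* electrostatics between charged beads: direct truncated-and-shifted Coulomb
  U = lambda_B q_i q_j (1/r - 1/r_c), or Debye-Hueckel screened
  U = lambda_B q_i q_j (e^{-r/l_D}/r - shift), minimum image in the periodic
  directions - forces are the exact negative gradients of the implemented
  energy;
* a uniform driving field -E z_hat confined to the pore slab |z| <= w/2,
  acting on every charged bead inside it;
* a WCA-like half-space gate on the head monomer that blocks re-entry past
  the pore exit once the run is released;
* immobile wall beads (WCA with sigma_bw) looked up through a 2D cell list.

The integrator is the BAOAB splitting of Langevin dynamics; at zeta = 0 it
reduces exactly to velocity Verlet, and with the same seed it reproduces a
trajectory bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .system import (SPECIES_CATION, SPECIES_COUNTERION, ParticleState,
                     SystemConfig, build_system, equilibrate_initial,
                     head_release_z)
from .tracking import REGION_PORE, TranslocationRecord, classify_regions

__all__ = [
    "ForceField",
    "Trajectory",
    "pair_wca",
    "bond_harmonic",
    "coulomb_pair",
    "compute_forces",
    "integrate",
    "langevin_step",
    "run_translocation",
    "run_ensemble",
    "pore_occupancy",
    "IntegrationError",
]

_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)

ELEC_NONE, ELEC_DIRECT, ELEC_SCREENED = 0, 1, 2
_ELEC_CODES = {"none": ELEC_NONE, "direct": ELEC_DIRECT, "screened": ELEC_SCREENED}


class IntegrationError(RuntimeError):
    """Non-finite coordinates during integration (reports max displacement)."""


# ---------------------------------------------------------------------------
# scalar potentials (reference implementations used by tests and reporting)
# ---------------------------------------------------------------------------

def pair_wca(r: float, sigma: float, eps: float) -> tuple[float, float]:
    """WCA energy and force magnitude at separation r (positive = repulsive)."""
    if r <= 0:
        raise ValueError("WCA potential is singular at r = 0")
    if r >= _SIXTH_ROOT_2 * sigma:
        return 0.0, 0.0
    sr6 = (sigma / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6) + eps
    f = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r
    return u, f


def bond_harmonic(length: float, k: float = 600.0, l0: float = 1.0
                  ) -> tuple[float, float]:
    """Harmonic bond energy and tension k(l - l0) (positive = stretched)."""
    if length < 0:
        raise ValueError("bond length must be non-negative")
    dl = length - l0
    return 0.5 * k * dl * dl, k * dl


def coulomb_pair(r: float, qi: float, qj: float, bjerrum: float,
                 debye_length: float | None = None,
                 cutoff: float | None = None) -> float:
    """Pair electrostatic energy in kBT.

    Direct form lambda_B q_i q_j / r (so unit charges at r = lambda_B
    interact with exactly +-1 kBT); optionally Debye-Hueckel screened and/or
    truncated-shifted at ``cutoff``.
    """
    if r < 1e-6:
        raise ValueError("overlapping charges: electrostatic singularity")
    if debye_length is None:
        u = bjerrum * qi * qj / r
        shift = 0.0 if cutoff is None else bjerrum * qi * qj / cutoff
    else:
        u = bjerrum * qi * qj * math.exp(-r / debye_length) / r
        shift = (0.0 if cutoff is None
                 else bjerrum * qi * qj * math.exp(-cutoff / debye_length) / cutoff)
    if cutoff is not None and r >= cutoff:
        return 0.0
    return u - shift


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _forces_kernel(pos, charge, n_mono,
                   bx, by, bz, pbc_z,
                   sig_mm, eps_mm, sig_bw, eps_bw,
                   kb, l0,
                   elec_mode, lB, rcut, lD,
                   field_on, E, half_wall,
                   gate_on, gate_sig, gate_eps, gate_z0,
                   confine_trans, conf_plane, k_conf,
                   cap_k, cap_z,
                   wall_pos, wall_sorted, cell_start, ncx, ncy, csx, csy,
                   wall_zmax,
                   F):
    nm = pos.shape[0]
    for i in range(nm):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    U = 0.0
    rc2_mm = (_SIXTH_ROOT_2 * sig_mm) ** 2
    rc_bw = _SIXTH_ROOT_2 * sig_bw
    rc2_bw = rc_bw * rc_bw
    rcut2 = rcut * rcut
    r2_floor = 0.16 * sig_mm * sig_mm  # overlap clamp, keeps forces finite

    # mobile-mobile: WCA + electrostatics in one pass
    for i in range(nm - 1):
        xi = pos[i, 0]; yi = pos[i, 1]; zi = pos[i, 2]
        qi = charge[i]
        for j in range(i + 1, nm):
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            dx -= bx * math.floor(dx / bx + 0.5)
            dy -= by * math.floor(dy / by + 0.5)
            if pbc_z:
                dz -= bz * math.floor(dz / bz + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            fr = 0.0
            if r2 < rc2_mm:
                if r2 < r2_floor:
                    r2 = r2_floor
                inv2 = sig_mm * sig_mm / r2
                inv6 = inv2 * inv2 * inv2
                U += 4.0 * eps_mm * (inv6 * inv6 - inv6) + eps_mm
                fr += 24.0 * eps_mm * (2.0 * inv6 * inv6 - inv6) / r2
            qj = charge[j]
            if elec_mode > 0 and qi != 0.0 and qj != 0.0 and r2 < rcut2:
                r = math.sqrt(r2)
                if r < 1e-6:
                    r = 1e-6
                if elec_mode == 1:
                    U += lB * qi * qj * (1.0 / r - 1.0 / rcut)
                    fr += lB * qi * qj / (r2 * r)
                else:
                    ex = math.exp(-r / lD)
                    exc = math.exp(-rcut / lD)
                    U += lB * qi * qj * (ex / r - exc / rcut)
                    fr += lB * qi * qj * ex * (1.0 / r + 1.0 / lD) / r2
            if fr != 0.0:
                F[i, 0] += fr * dx
                F[i, 1] += fr * dy
                F[i, 2] += fr * dz
                F[j, 0] -= fr * dx
                F[j, 1] -= fr * dy
                F[j, 2] -= fr * dz

    # harmonic bonds between consecutive monomers
    for i in range(n_mono - 1):
        dx = pos[i, 0] - pos[i + 1, 0]
        dy = pos[i, 1] - pos[i + 1, 1]
        dz = pos[i, 2] - pos[i + 1, 2]
        dx -= bx * math.floor(dx / bx + 0.5)
        dy -= by * math.floor(dy / by + 0.5)
        if pbc_z:
            dz -= bz * math.floor(dz / bz + 0.5)
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-9:
            r = 1e-9
        dl = r - l0
        U += 0.5 * kb * dl * dl
        fr = -kb * dl / r
        F[i, 0] += fr * dx
        F[i, 1] += fr * dy
        F[i, 2] += fr * dz
        F[i + 1, 0] -= fr * dx
        F[i + 1, 1] -= fr * dy
        F[i + 1, 2] -= fr * dz

    # immobile wall beads via 2D cell lookup
    nw = wall_pos.shape[0]
    if nw > 0:
        for i in range(nm):
            zi = pos[i, 2]
            if abs(zi) > wall_zmax:
                continue
            xi = pos[i, 0]; yi = pos[i, 1]
            cx = int((xi + 0.5 * bx) / csx)
            cy = int((yi + 0.5 * by) / csy)
            for ox in range(-1, 2):
                ix = (cx + ox) % ncx
                if ix < 0:
                    ix += ncx
                for oy in range(-1, 2):
                    iy = (cy + oy) % ncy
                    if iy < 0:
                        iy += ncy
                    c = ix * ncy + iy
                    for p in range(cell_start[c], cell_start[c + 1]):
                        j = wall_sorted[p]
                        dx = xi - wall_pos[j, 0]
                        dy = yi - wall_pos[j, 1]
                        dz = zi - wall_pos[j, 2]
                        dx -= bx * math.floor(dx / bx + 0.5)
                        dy -= by * math.floor(dy / by + 0.5)
                        r2 = dx * dx + dy * dy + dz * dz
                        if r2 < rc2_bw:
                            if r2 < 0.16 * sig_bw * sig_bw:
                                r2 = 0.16 * sig_bw * sig_bw
                            inv2 = sig_bw * sig_bw / r2
                            inv6 = inv2 * inv2 * inv2
                            U += 4.0 * eps_bw * (inv6 * inv6 - inv6) + eps_bw
                            fr = 24.0 * eps_bw * (2.0 * inv6 * inv6 - inv6) / r2
                            F[i, 0] += fr * dx
                            F[i, 1] += fr * dy
                            F[i, 2] += fr * dz

    # driving field, pore slab only (closed interval)
    if field_on:
        for i in range(nm):
            qi = charge[i]
            if qi != 0.0 and abs(pos[i, 2]) <= half_wall:
                F[i, 2] += -E * qi
                U += qi * E * pos[i, 2]

    # exit gate on the head monomer (force-continuous WCA half-space)
    if gate_on:
        d = pos[0, 2] - gate_z0
        if d < _SIXTH_ROOT_2 * gate_sig:
            if d < 0.6 * gate_sig:
                d = 0.6 * gate_sig
            inv6 = (gate_sig / d) ** 6
            U += 4.0 * gate_eps * (inv6 * inv6 - inv6) + gate_eps
            F[0, 2] += 24.0 * gate_eps * (2.0 * inv6 * inv6 - inv6) / d

    # trans-side confinement of non-head monomers (pre-release only)
    if confine_trans:
        for i in range(1, n_mono):
            dz = pos[i, 2] - conf_plane
            if dz > 0.0:
                U += 0.5 * k_conf * dz * dz
                F[i, 2] -= k_conf * dz

    # soft caps closing the box in z (unless fully periodic)
    if not pbc_z:
        for i in range(nm):
            zi = pos[i, 2]
            if zi > cap_z:
                U += 0.5 * cap_k * (zi - cap_z) ** 2
                F[i, 2] -= cap_k * (zi - cap_z)
            elif zi < -cap_z:
                U += 0.5 * cap_k * (zi + cap_z) ** 2
                F[i, 2] -= cap_k * (zi + cap_z)
    return U


@njit(cache=True)
def _run_kernel(pos, vel, charge, n_mono,
                bx, by, bz, pbc_z,
                sig_mm, eps_mm, sig_bw, eps_bw,
                kb, l0,
                elec_mode, lB, rcut, lD,
                field_on, E, half_wall,
                gate_on, gate_sig, gate_eps, gate_z0,
                confine_trans, conf_plane, k_conf,
                cap_k, cap_z,
                wall_pos, wall_sorted, cell_start, ncx, ncy, csx, csy,
                wall_zmax,
                zeta, dt, kBT, mass,
                n_steps, constrain_head, head_x, head_y, head_z,
                track, stop_at_completion,
                sample_stride, frame_stride, energy_stride,
                w_out, fp_out, s_samples, frames, frame_times, energies,
                seed):
    np.random.seed(seed)
    nm = pos.shape[0]
    F = np.zeros((nm, 3))
    if zeta > 0.0:
        c1 = math.exp(-zeta * dt / mass)
        c2 = math.sqrt(kBT / mass * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0

    U = _forces_kernel(pos, charge, n_mono, bx, by, bz, pbc_z,
                       sig_mm, eps_mm, sig_bw, eps_bw, kb, l0,
                       elec_mode, lB, rcut, lD,
                       field_on, E, half_wall,
                       gate_on, gate_sig, gate_eps, gate_z0,
                       confine_trans, conf_plane, k_conf,
                       cap_k, cap_z,
                       wall_pos, wall_sorted, cell_start, ncx, ncy, csx, csy,
                       wall_zmax, F)

    s_prev = 0
    for i in range(n_mono):
        if pos[i, 2] > half_wall:
            s_prev += 1
    n_samp = 0
    if track:
        for ss in range(fp_out.shape[0]):
            fp_out[ss] = -1.0
        fp_out[s_prev] = 0.0
        s_samples[0] = s_prev
        n_samp = 1
    n_frame = 0
    if frame_stride > 0:
        for i in range(nm):
            frames[0, i, 0] = pos[i, 0]
            frames[0, i, 1] = pos[i, 1]
            frames[0, i, 2] = pos[i, 2]
        frame_times[0] = 0.0
        n_frame = 1
    n_e = 0
    if energy_stride > 0:
        ke = 0.0
        for i in range(nm):
            ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
        energies[0] = U + 0.5 * mass * ke
        n_e = 1

    t = 0.0
    completed = False
    tau = -1.0
    max_jump = 0
    status = 0
    half_dt = 0.5 * dt

    for step in range(n_steps):
        # B
        for i in range(nm):
            inv = half_dt / mass
            vel[i, 0] += inv * F[i, 0]
            vel[i, 1] += inv * F[i, 1]
            vel[i, 2] += inv * F[i, 2]
        if constrain_head:
            vel[0, 0] = 0.0; vel[0, 1] = 0.0; vel[0, 2] = 0.0
        # A
        for i in range(nm):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        # O
        if zeta > 0.0:
            for i in range(nm):
                vel[i, 0] = c1 * vel[i, 0] + c2 * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + c2 * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + c2 * np.random.standard_normal()
            if constrain_head:
                vel[0, 0] = 0.0; vel[0, 1] = 0.0; vel[0, 2] = 0.0
        # A
        for i in range(nm):
            pos[i, 0] += half_dt * vel[i, 0]
            pos[i, 1] += half_dt * vel[i, 1]
            pos[i, 2] += half_dt * vel[i, 2]
        if constrain_head:
            pos[0, 0] = head_x; pos[0, 1] = head_y; pos[0, 2] = head_z
        U = _forces_kernel(pos, charge, n_mono, bx, by, bz, pbc_z,
                           sig_mm, eps_mm, sig_bw, eps_bw, kb, l0,
                           elec_mode, lB, rcut, lD,
                           field_on, E, half_wall,
                           gate_on, gate_sig, gate_eps, gate_z0,
                           confine_trans, conf_plane, k_conf,
                           cap_k, cap_z,
                           wall_pos, wall_sorted, cell_start, ncx, ncy,
                           csx, csy, wall_zmax, F)
        # B
        for i in range(nm):
            inv = half_dt / mass
            vel[i, 0] += inv * F[i, 0]
            vel[i, 1] += inv * F[i, 1]
            vel[i, 2] += inv * F[i, 2]
        if constrain_head:
            vel[0, 0] = 0.0; vel[0, 1] = 0.0; vel[0, 2] = 0.0
        t += dt

        if step % 200 == 0:
            ok = True
            for i in range(nm):
                if not (math.isfinite(pos[i, 0]) and math.isfinite(pos[i, 1])
                        and math.isfinite(pos[i, 2])):
                    ok = False
                    break
            if not ok:
                status = 1
                break

        if track:
            s_new = 0
            for i in range(n_mono):
                if pos[i, 2] > half_wall:
                    s_new += 1
            w_out[s_prev] += dt
            jump = s_new - s_prev
            if jump < 0:
                jump = -jump
            if jump > max_jump:
                max_jump = jump
            if s_new > s_prev:
                for ss in range(s_prev + 1, s_new + 1):
                    if fp_out[ss] < 0.0:
                        fp_out[ss] = t
            s_prev = s_new
            if s_new >= n_mono and stop_at_completion:
                completed = True
                tau = t
        if sample_stride > 0 and (step + 1) % sample_stride == 0:
            s_cur = 0
            for i in range(n_mono):
                if pos[i, 2] > half_wall:
                    s_cur += 1
            s_samples[n_samp] = s_cur
            n_samp += 1
        if frame_stride > 0 and (step + 1) % frame_stride == 0:
            for i in range(nm):
                frames[n_frame, i, 0] = pos[i, 0]
                frames[n_frame, i, 1] = pos[i, 1]
                frames[n_frame, i, 2] = pos[i, 2]
            frame_times[n_frame] = t
            n_frame += 1
        if energy_stride > 0 and (step + 1) % energy_stride == 0:
            ke = 0.0
            for i in range(nm):
                ke += vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2
            energies[n_e] = U + 0.5 * mass * ke
            n_e += 1
        if completed:
            break

    steps_done = step + 1 if n_steps > 0 else 0
    return status, steps_done, n_samp, n_frame, n_e, completed, tau, max_jump


# ---------------------------------------------------------------------------
# python-level force field and drivers
# ---------------------------------------------------------------------------

@dataclass
class ForceField:
    """Interaction parameters handed to the kernels, derived from a config."""

    sigma_bb: float
    eps_bb: float
    sigma_bw: float
    eps_bw: float
    k: float
    l0: float
    electrostatics: str
    bjerrum: float
    cutoff: float
    debye_length: float
    E: float
    half_wall: float
    gate_sigma: float
    gate_eps: float
    gate_z0: float
    charge_scale: float = 1.0
    cap_k: float = 100.0

    @classmethod
    def from_config(cls, cfg: SystemConfig) -> "ForceField":
        cutoff = min(cfg.elec_cutoff, cfg.box[0] / 2, cfg.box[1] / 2)
        lD = cfg.debye_length_value() if cfg.electrostatics == "screened" else 1.0
        gate_plane = head_release_z(cfg)
        return cls(
            sigma_bb=cfg.sigma_bb, eps_bb=cfg.eps_bb,
            sigma_bw=cfg.sigma_bw, eps_bw=cfg.eps_bw,
            k=cfg.k, l0=cfg.l0,
            electrostatics=cfg.electrostatics, bjerrum=cfg.bjerrum,
            cutoff=cutoff, debye_length=lD,
            E=cfg.E, half_wall=cfg.half_wall,
            gate_sigma=cfg.gate_sigma, gate_eps=cfg.gate_eps,
            gate_z0=gate_plane - _SIXTH_ROOT_2 * cfg.gate_sigma,
            charge_scale=cfg.elec_charge_scale(),
        )


def _wall_cells(wall_pos, bx, by, cutoff):
    if wall_pos.shape[0] == 0:
        return (np.zeros(0, np.int64), np.zeros(2, np.int64), 1, 1, bx, by)
    ncx = max(1, int(bx // cutoff))
    ncy = max(1, int(by // cutoff))
    csx, csy = bx / ncx, by / ncy
    ix = np.floor((wall_pos[:, 0] + bx / 2) / csx).astype(np.int64) % ncx
    iy = np.floor((wall_pos[:, 1] + by / 2) / csy).astype(np.int64) % ncy
    cell = ix * ncy + iy
    order = np.argsort(cell, kind="stable")
    counts = np.bincount(cell, minlength=ncx * ncy)
    starts = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return order.astype(np.int64), starts, ncx, ncy, csx, csy


def _kernel_args(state: ParticleState, cfg: SystemConfig, ff: ForceField,
                 field_on: bool, gate_on: bool, confine_trans: bool):
    mob = state.mobile
    wall_pos = np.ascontiguousarray(state.positions[~mob])
    rc_bw = _SIXTH_ROOT_2 * ff.sigma_bw
    wall_sorted, cell_start, ncx, ncy, csx, csy = _wall_cells(
        wall_pos, cfg.box[0], cfg.box[1], rc_bw
    )
    wall_zmax = (cfg.half_wall - cfg.wall_contact_offset) + rc_bw
    return dict(
        bx=cfg.box[0], by=cfg.box[1], bz=cfg.box[2], pbc_z=cfg.pbc_z,
        sig_mm=ff.sigma_bb, eps_mm=ff.eps_bb,
        sig_bw=ff.sigma_bw, eps_bw=ff.eps_bw,
        kb=ff.k, l0=ff.l0,
        elec_mode=_ELEC_CODES[ff.electrostatics],
        lB=ff.bjerrum * ff.charge_scale**2,
        rcut=ff.cutoff, lD=ff.debye_length,
        field_on=field_on, E=ff.E, half_wall=ff.half_wall,
        gate_on=gate_on, gate_sig=ff.gate_sigma, gate_eps=ff.gate_eps,
        gate_z0=ff.gate_z0,
        confine_trans=confine_trans, conf_plane=cfg.half_wall - 0.3,
        k_conf=600.0,
        cap_k=ff.cap_k, cap_z=cfg.box[2] / 2 - 0.5,
        wall_pos=wall_pos, wall_sorted=wall_sorted, cell_start=cell_start,
        ncx=ncx, ncy=ncy, csx=csx, csy=csy, wall_zmax=wall_zmax,
    )


def compute_forces(state: ParticleState, cfg: SystemConfig,
                   ff: ForceField | None = None,
                   field_on: bool = True, gate_on: bool = False,
                   confine_trans: bool = False):
    """Forces on every bead (wall rows zero) and the total potential energy."""
    if ff is None:
        ff = ForceField.from_config(cfg)
    args = _kernel_args(state, cfg, ff, field_on, gate_on, confine_trans)
    mob = state.mobile
    pos = np.ascontiguousarray(state.positions[mob])
    charge = np.ascontiguousarray(state.charges[mob])
    F = np.zeros_like(pos)
    U = _forces_kernel(pos, charge, state.n_monomers,
                       args["bx"], args["by"], args["bz"], args["pbc_z"],
                       args["sig_mm"], args["eps_mm"], args["sig_bw"],
                       args["eps_bw"], args["kb"], args["l0"],
                       args["elec_mode"], args["lB"], args["rcut"], args["lD"],
                       args["field_on"], args["E"], args["half_wall"],
                       args["gate_on"], args["gate_sig"], args["gate_eps"],
                       args["gate_z0"],
                       args["confine_trans"], args["conf_plane"], args["k_conf"],
                       args["cap_k"], args["cap_z"],
                       args["wall_pos"], args["wall_sorted"], args["cell_start"],
                       args["ncx"], args["ncy"], args["csx"], args["csy"],
                       args["wall_zmax"], F)
    out = np.zeros_like(state.positions)
    out[mob] = F
    return out, float(U)


@dataclass
class Trajectory:
    """Sub-sampled frames of the mobile beads during one run."""

    times: np.ndarray
    positions: np.ndarray     # (n_frames, n_mobile, 3)
    species: np.ndarray
    charges: np.ndarray
    box: tuple
    n_monomers: int
    s: np.ndarray
    stride_time: float

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def monomer_positions(self, i: int) -> np.ndarray:
        return self.positions[i, : self.n_monomers]

    def to_frames(self):
        from . import io as pio
        from .system import SPECIES_NAMES
        names = [SPECIES_NAMES[int(s)] for s in self.species]
        return [
            pio.Frame(time=float(t), positions=self.positions[i],
                      species=names, charges=self.charges, box=self.box)
            for i, t in enumerate(self.times)
        ]


def integrate(state: ParticleState, cfg: SystemConfig, n_steps: int, seed: int,
              field_on: bool = True, gate_on: bool = True,
              constrain_head: bool = False, confine_trans: bool = False,
              track: bool = False, stop_at_completion: bool = True,
              sample_stride: int | None = None, frame_stride: int | None = None,
              energy_stride: int = 0, zeta: float | None = None,
              dt: float | None = None, ff: ForceField | None = None) -> dict:
    """Advance ``state`` in place by up to ``n_steps`` Langevin (BAOAB) steps.

    Identical (state, seed, parameters) give bit-identical results.  Returns
    a dict with the tracking outputs that were requested; raises
    :class:`IntegrationError` on non-finite coordinates.
    """
    if ff is None:
        ff = ForceField.from_config(cfg)
    zeta = cfg.zeta if zeta is None else zeta
    dt = cfg.dt if dt is None else dt
    if dt <= 0:
        raise ValueError("dt must be positive")
    sample_stride = (cfg.sample_stride if sample_stride is None else sample_stride)
    frame_stride = (cfg.frame_stride if frame_stride is None else frame_stride)

    args = _kernel_args(state, cfg, ff, field_on, gate_on, confine_trans)
    mob = state.mobile
    pos = np.ascontiguousarray(state.positions[mob])
    vel = np.ascontiguousarray(state.velocities[mob])
    charge = np.ascontiguousarray(state.charges[mob])
    nm = pos.shape[0]
    N = state.n_monomers

    w_out = np.zeros(N + 1)
    fp_out = np.zeros(N + 1)
    n_samp_max = (n_steps // sample_stride + 2) if (track and sample_stride > 0) else 2
    s_samples = np.zeros(n_samp_max, dtype=np.int64)
    n_frame_max = (n_steps // frame_stride + 2) if frame_stride > 0 else 1
    frames = np.zeros((n_frame_max, nm, 3))
    frame_times = np.zeros(n_frame_max)
    n_e_max = (n_steps // energy_stride + 2) if energy_stride > 0 else 1
    energies = np.zeros(n_e_max)

    head = pos[0].copy()
    status, steps_done, n_samp, n_frame, n_e, completed, tau, max_jump = _run_kernel(
        pos, vel, charge, N,
        args["bx"], args["by"], args["bz"], args["pbc_z"],
        args["sig_mm"], args["eps_mm"], args["sig_bw"], args["eps_bw"],
        args["kb"], args["l0"],
        args["elec_mode"], args["lB"], args["rcut"], args["lD"],
        args["field_on"], args["E"], args["half_wall"],
        args["gate_on"], args["gate_sig"], args["gate_eps"], args["gate_z0"],
        args["confine_trans"], args["conf_plane"], args["k_conf"],
        args["cap_k"], args["cap_z"],
        args["wall_pos"], args["wall_sorted"], args["cell_start"],
        args["ncx"], args["ncy"], args["csx"], args["csy"], args["wall_zmax"],
        zeta, dt, cfg.kBT, cfg.mass,
        n_steps, constrain_head, head[0], head[1], head[2],
        track, stop_at_completion,
        sample_stride if track else 0, frame_stride, energy_stride,
        w_out, fp_out, s_samples, frames, frame_times, energies,
        int(seed) % (2**31 - 1),
    )
    if status != 0:
        raise IntegrationError(
            f"non-finite coordinates after {steps_done} steps "
            f"(max |pos| before failure {np.nanmax(np.abs(pos)):.3g})"
        )
    state.positions[mob] = pos
    state.velocities[mob] = vel
    return {
        "steps_done": int(steps_done),
        "completed": bool(completed),
        "tau": float(tau),
        "max_step_jump": int(max_jump),
        "waiting": w_out,
        "first_passage": fp_out,
        "s_samples": s_samples[:n_samp],
        "sample_dt": dt * sample_stride,
        "frames": frames[:n_frame],
        "frame_times": frame_times[:n_frame],
        "energies": energies[:n_e],
        "energy_dt": dt * energy_stride if energy_stride else 0.0,
    }


def langevin_step(state: ParticleState, cfg: SystemConfig, seed: int,
                  n_steps: int = 1, **kw) -> dict:
    """One (or a few) Langevin steps; thin wrapper over :func:`integrate`."""
    return integrate(state, cfg, n_steps=n_steps, seed=seed,
                     track=False, **kw)


def _sub_seeds(cfg_seed: int, run_seed: int, n: int = 3):
    ss = np.random.SeedSequence([int(cfg_seed) & 0x7FFFFFFF,
                                 int(run_seed) & 0x7FFFFFFF])
    return [int(x) % (2**31 - 1) for x in ss.generate_state(n)]


def run_translocation(cfg: SystemConfig, seed: int, run_id: int = 0,
                      equilibration_steps: int | None = None,
                      ) -> tuple[Trajectory, TranslocationRecord]:
    """Build, equilibrate and run one driven translocation to completion.

    Integrates until s = N or the step budget runs out; an exhausted budget
    is returned flagged (``record.completed`` False), never silently
    truncated.
    """
    s_build, s_eq, s_run = _sub_seeds(cfg.seed, seed)
    state = build_system(cfg.with_(seed=s_build))
    state = equilibrate_initial(state, cfg, steps=equilibration_steps, seed=s_eq)

    out = integrate(state, cfg, n_steps=cfg.step_budget, seed=s_run,
                    field_on=True, gate_on=True, track=True)
    n_samp = len(out["s_samples"])
    times = np.arange(n_samp) * out["sample_dt"]
    s = out["s_samples"].astype(np.int64)
    if out["completed"]:
        times = np.append(times, out["tau"])
        s = np.append(s, cfg.N)
    mob = state.mobile
    traj = Trajectory(
        times=out["frame_times"], positions=out["frames"],
        species=state.species[mob].copy(), charges=state.charges[mob].copy(),
        box=cfg.box, n_monomers=cfg.N,
        s=np.array([int((f[: cfg.N, 2] > cfg.half_wall).sum())
                    for f in out["frames"]]),
        stride_time=cfg.dt * max(cfg.frame_stride, 1),
    )
    record = TranslocationRecord(
        run_id=run_id, seed=seed, n_monomers=cfg.N,
        times=times, s=s,
        waiting=out["waiting"], first_passage=out["first_passage"],
        tau=float(out["tau"]), completed=bool(out["completed"]),
        pre_release_s=int(state.meta.get("s_pre_release", 1)),
        max_step_jump=out["max_step_jump"],
        meta={"E": cfg.E, "N": cfg.N, "steps": out["steps_done"]},
    )
    return traj, record


def run_ensemble(cfg: SystemConfig, M: int, seed: int,
                 keep_trajectories: bool = False, progress: bool = False):
    """M independent seeded runs; returns (records, trajectories or None)."""
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    run_seeds = [int(x) % (2**31 - 1) for x in ss.generate_state(M)]
    records, trajs = [], []
    for k, rs in enumerate(run_seeds):
        traj, rec = run_translocation(cfg, rs, run_id=k)
        records.append(rec)
        if keep_trajectories:
            trajs.append(traj)
        if progress:
            print(f"run {k + 1}/{M}: tau={rec.tau:.1f} completed={rec.completed}")
    return records, (trajs if keep_trajectories else None)


def pore_occupancy(traj: Trajectory, wall_thickness: float, bjerrum: float):
    """Per-frame counts (N_m,II, N_c,II) of monomers and condensed +1 ions
    in the pore region.

    A +1 ion counts as condensed when it is inside region II and within the
    Bjerrum length of any monomer.
    """
    n_frames = traj.n_frames
    n_m = np.zeros(n_frames, dtype=np.int64)
    n_c = np.zeros(n_frames, dtype=np.int64)
    is_plus = np.isin(traj.species, (SPECIES_COUNTERION, SPECIES_CATION))
    for f in range(n_frames):
        pos = traj.positions[f]
        labels = classify_regions(pos[:, 2], wall_thickness)
        mono_pore = labels[: traj.n_monomers] == REGION_PORE
        n_m[f] = mono_pore.sum()
        plus_pore = np.nonzero(is_plus & (labels == REGION_PORE))[0]
        if plus_pore.size:
            mono = traj.monomer_positions(f)
            for j in plus_pore:
                d = np.linalg.norm(mono - pos[j], axis=1)
                if d.min() <= bjerrum:
                    n_c[f] += 1
    return n_m, n_c
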