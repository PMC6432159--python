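"""File formats: extended-XYZ and LAMMPS-dump trajectories, YAML configs,
CSV analysis tables and line-oriented run logs.

The project-wide coordinate convention is: pore axis along z, wall centered
at z = 0, trans side at +z.  Trajectories on disk carry simulation units
(sigma, tau_u); conversion to real units happens only at reporting time via
:mod:`poretrans.units`.

Both dialects are gzip-transparent (a ``.gz`` suffix switches compression)
and round-trip positions at six printed decimals.  Unknown per-atom columns
are preserved on read in ``Frame.extras``.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Frame",
    "write_trajectory",
    "read_trajectory",
    "load_config",
    "dump_config",
    "config_hash",
    "RunLog",
    "TrajectoryParseError",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file; carries the offending line number."""

    def __init__(self, msg: str, line: int):
        super().__init__(f"line {line}: {msg}")
        self.line = line


@dataclass
class Frame:
    """One trajectory frame: positions plus per-atom metadata."""

    time: float
    positions: np.ndarray
    species: list
    charges: np.ndarray | None = None
    extras: dict = field(default_factory=dict)
    box: tuple | None = None

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


def _open(path, mode):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

def _write_xyz(frames, fh):
    for fr in frames:
        cols = ["species:S:1", "pos:R:3"]
        if fr.charges is not None:
            cols.append("charge:R:1")
        for name, arr in fr.extras.items():
            width = 1 if np.ndim(arr) == 1 else np.shape(arr)[1]
            cols.append(f"{name}:R:{width}")
        header = f'Properties={":".join(c for c in cols)} Time={fr.time:.6f}'
        if fr.box is not None:
            bx, by, bz = fr.box
            header = (
                f'Lattice="{bx:.6f} 0 0 0 {by:.6f} 0 0 0 {bz:.6f}" ' + header
            )
        fh.write(f"{fr.n_atoms}\n{header}\n")
        for i in range(fr.n_atoms):
            parts = [str(fr.species[i])]
            parts += [f"{v:.6f}" for v in fr.positions[i]]
            if fr.charges is not None:
                parts.append(f"{fr.charges[i]:.6f}")
            for arr in fr.extras.values():
                a = np.atleast_2d(np.asarray(arr).T).T
                parts += [f"{v:.6f}" for v in np.atleast_1d(a[i])]
            fh.write(" ".join(parts) + "\n")


def _parse_kv_header(line):
    out = {}
    key = ""
    i = 0
    n = len(line)
    while i < n:
        j = line.find("=", i)
        if j < 0:
            break
        key = line[i:j].strip().split()[-1]
        if j + 1 < n and line[j + 1] == '"':
            k = line.find('"', j + 2)
            out[key] = line[j + 2 : k]
            i = k + 1
        else:
            k = line.find(" ", j + 1)
            if k < 0:
                k = n
            out[key] = line[j + 1 : k]
            i = k + 1
    return out


def _read_xyz(fh):
    frames = []
    lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryParseError("expected atom count", i + 1)
        if i + 1 >= len(lines):
            raise TrajectoryParseError("missing comment line", i + 2)
        kv = _parse_kv_header(lines[i + 1])
        time = float(kv.get("Time", 0.0))
        box = None
        if "Lattice" in kv:
            lat = np.fromstring(kv["Lattice"], sep=" ").reshape(3, 3)
            box = (lat[0, 0], lat[1, 1], lat[2, 2])
        props = kv.get("Properties", "species:S:1:pos:R:3").split(":")
        fields = [(props[k], props[k + 1], int(props[k + 2]))
                  for k in range(0, len(props), 3)]
        species, rows = [], []
        for a in range(n):
            li = i + 2 + a
            if li >= len(lines):
                raise TrajectoryParseError("truncated frame body", li + 1)
            rows.append(lines[li].split())
        col = 0
        data: dict[str, object] = {}
        for name, typ, width in fields:
            if typ == "S":
                data[name] = [r[col] for r in rows]
            else:
                arr = np.array(
                    [[float(r[col + w]) for w in range(width)] for r in rows]
                )
                data[name] = arr[:, 0] if width == 1 else arr
            col += width
        pos = np.asarray(data.pop("pos"))
        species = list(data.pop("species", ["X"] * n))
        charges = data.pop("charge", None)
        frames.append(Frame(time=time, positions=pos, species=species,
                            charges=None if charges is None else np.asarray(charges),
                            extras=data, box=box))
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# LAMMPS dump (text dialect)
# ---------------------------------------------------------------------------

def _write_lammps(frames, fh):
    for step, fr in enumerate(frames):
        fh.write(f"ITEM: TIMESTEP\n{step}\n")
        fh.write(f"ITEM: TIME\n{fr.time:.6f}\n")
        fh.write(f"ITEM: NUMBER OF ATOMS\n{fr.n_atoms}\n")
        if fr.box is not None:
            bx, by, bz = fr.box
            fh.write("ITEM: BOX BOUNDS pp pp ff\n")
            fh.write(f"{-bx/2:.6f} {bx/2:.6f}\n{-by/2:.6f} {by/2:.6f}\n"
                     f"{-bz/2:.6f} {bz/2:.6f}\n")
        cols = "id type x y z"
        if fr.charges is not None:
            cols += " q"
        for name, arr in fr.extras.items():
            if np.ndim(arr) == 1:
                cols += f" {name}"
        fh.write(f"ITEM: ATOMS {cols}\n")
        for i in range(fr.n_atoms):
            parts = [str(i + 1), str(fr.species[i])]
            parts += [f"{v:.6f}" for v in fr.positions[i]]
            if fr.charges is not None:
                parts.append(f"{fr.charges[i]:.6f}")
            for arr in fr.extras.values():
                if np.ndim(arr) == 1:
                    parts.append(f"{np.asarray(arr)[i]:.6f}")
            fh.write(" ".join(parts) + "\n")


def _read_lammps(fh):
    lines = fh.read().splitlines()
    frames = []
    i = 0
    time = 0.0
    box = None
    while i < len(lines):
        line = lines[i]
        if not line.startswith("ITEM:"):
            raise TrajectoryParseError(f"expected ITEM header, got {line!r}", i + 1)
        item = line[5:].strip()
        if item == "TIMESTEP":
            i += 2
        elif item == "TIME":
            time = float(lines[i + 1])
            i += 2
        elif item == "NUMBER OF ATOMS":
            n = int(lines[i + 1])
            i += 2
        elif item.startswith("BOX BOUNDS"):
            lo_hi = [lines[i + 1 + k].split() for k in range(3)]
            box = tuple(float(h) - float(lo) for lo, h in lo_hi)
            i += 4
        elif item.startswith("ATOMS"):
            cols = item.split()[1:]
            rows = [lines[i + 1 + a].split() for a in range(n)]
            i += 1 + n
            get = {c: k for k, c in enumerate(cols)}
            for c in ("x", "y", "z"):
                if c not in get:
                    raise TrajectoryParseError(f"dump lacks column {c}", i)
            order = np.argsort([int(r[get["id"]]) for r in rows]) if "id" in get \
                else np.arange(n)
            rows = [rows[k] for k in order]
            pos = np.array([[float(r[get["x"]]), float(r[get["y"]]),
                             float(r[get["z"]])] for r in rows])
            species = [r[get["type"]] for r in rows] if "type" in get else ["1"] * n
            charges = (np.array([float(r[get["q"]]) for r in rows])
                       if "q" in get else None)
            extras = {}
            for c, k in get.items():
                if c in ("id", "type", "x", "y", "z", "q"):
                    continue
                extras[c] = np.array([float(r[k]) for r in rows])
            frames.append(Frame(time=time, positions=pos, species=species,
                                charges=charges, extras=extras, box=box))
        else:
            raise TrajectoryParseError(f"unknown ITEM {item!r}", i + 1)
    return frames


DIALECTS = {"xyz": (_write_xyz, _read_xyz), "lammps": (_write_lammps, _read_lammps)}


def write_trajectory(frames, path, dialect: str = "xyz") -> None:
    """Write frames to ``path`` in the chosen dialect ('xyz' or 'lammps')."""
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {sorted(DIALECTS)}")
    with _open(path, "w") as fh:
        DIALECTS[dialect][0](frames, fh)


def read_trajectory(path, dialect: str | None = None) -> list[Frame]:
    """Read frames; the dialect is sniffed from the first line if omitted."""
    with _open(path, "r") as fh:
        text = fh.read()
    if dialect is None:
        dialect = "lammps" if text.lstrip().startswith("ITEM:") else "xyz"
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {sorted(DIALECTS)}")
    return DIALECTS[dialect][1](_io.StringIO(text))


# ---------------------------------------------------------------------------
# configuration files and run logs
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Sectioned key/value config (YAML) as a nested dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("config file must hold a mapping of sections")
    return data


def dump_config(data: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_hash(data: dict) -> str:
    """Stable short hash identifying a configuration in run logs."""
    blob = yaml.safe_dump(data, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


class RunLog:
    """Line-oriented run log (seed, config hash, scheme, completion...)."""

    def __init__(self, path=None):
        self.path = Path(path) if path else None
        self.lines: list[str] = []

    def write(self, **fields) -> str:
        line = " ".join(f"{k}={v}" for k, v in fields.items())
        self.lines.append(line)
        if self.path:
            with open(self.path, "a") as fh:
                fh.write(line + "\n")
        return line


# ---------------------------------------------------------------------------
# translocation-record persistence (CSV, unit-labelled headers)
# ---------------------------------------------------------------------------

def save_records(records, directory) -> None:
    """Write an ensemble of translocation records as CSV tables.

    Layout: ``summary.csv`` (one row per run) plus per-run ``s_series_k.csv``
    (time in tau_u, s) and ``waiting_k.csv`` (state s, waiting time in
    tau_u, first-passage time in tau_u).
    """
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        rows.append(dict(run_id=r.run_id, seed=r.seed, n_monomers=r.n_monomers,
                         tau_tau_u=r.tau, completed=r.completed,
                         pre_release_s=r.pre_release_s,
                         max_step_jump=r.max_step_jump,
                         **{f"meta_{k}": v for k, v in r.meta.items()}))
        pd.DataFrame({"time_tau_u": r.times, "s": r.s}).to_csv(
            directory / f"s_series_{r.run_id}.csv", index=False)
        n = r.n_monomers
        pd.DataFrame({
            "s": np.arange(n + 1),
            "waiting_tau_u": r.waiting,
            "first_passage_tau_u": r.first_passage,
        }).to_csv(directory / f"waiting_{r.run_id}.csv", index=False)
    pd.DataFrame(rows).to_csv(directory / "summary.csv", index=False)


def load_records(directory):
    """Inverse of :func:`save_records`."""
    import pandas as pd

    from .tracking import TranslocationRecord

    directory = Path(directory)
    summary = pd.read_csv(directory / "summary.csv")
    records = []
    for _, row in summary.iterrows():
        rid = int(row["run_id"])
        ser = pd.read_csv(directory / f"s_series_{rid}.csv")
        wt = pd.read_csv(directory / f"waiting_{rid}.csv")
        meta = {k[5:]: row[k] for k in summary.columns if k.startswith("meta_")}
        records.append(TranslocationRecord(
            run_id=rid, seed=int(row["seed"]),
            n_monomers=int(row["n_monomers"]),
            times=ser["time_tau_u"].to_numpy(),
            s=ser["s"].to_numpy(dtype=np.int64),
            waiting=wt["waiting_tau_u"].to_numpy(),
            first_passage=wt["first_passage_tau_u"].to_numpy(),
            tau=float(row["tau_tau_u"]), completed=bool(row["completed"]),
            pre_release_s=int(row["pre_release_s"]),
            max_step_jump=int(row["max_step_jump"]), meta=meta,
        ))
    return records
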