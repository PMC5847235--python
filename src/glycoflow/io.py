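"""Trajectory containers and extended-XYZ input/output.

The native trajectory format is extended XYZ with per-atom velocity
columns: velocities are first-class because the flow analysis consumes
instantaneous velocities, not finite differences of positions.

Per-frame layout::

    <n_atoms>
    time=<ps> box="<lx> <ly> <lz>" [seed=<int> config=<hash>]
    <kind> <residue> <name> <mass> <x> <y> <z> <vx> <vy> <vz>

with kind one of ``solute``/``solvent``/``cation``/``anion``, positions
in Å and velocities in Å/ps.  Solvent and ion positions are wrapped
into the primary box; solute positions are stored unwrapped so
extension and orientation analyses never cross a periodic boundary.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "Frame",
    "AtomMeta",
    "Trajectory",
    "frame_count",
    "write_trajectory",
    "read_trajectory",
    "iter_frames",
    "select",
]

KINDS = ("solute", "solvent", "cation", "anion")


@dataclass
class Frame:
    time: float  # ps
    positions: np.ndarray  # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/ps
    box: np.ndarray  # (3,) Å

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities shapes differ")


@dataclass
class AtomMeta:
    """Per-atom metadata shared by all frames of a trajectory."""

    kind: np.ndarray  # str array
    residue: np.ndarray  # int array (0 for non-solute)
    name: np.ndarray  # str array
    mass: np.ndarray  # amu

    def __len__(self):
        return len(self.kind)

    def __eq__(self, other):
        return (
            isinstance(other, AtomMeta)
            and len(self) == len(other)
            and bool(np.all(self.kind == other.kind))
            and bool(np.all(self.residue == other.residue))
            and bool(np.all(self.name == other.name))
            and bool(np.allclose(self.mass, other.mass))
        )


@dataclass
class Trajectory:
    atoms: AtomMeta
    frames: list[Frame] = field(default_factory=list)
    seed: int | None = None
    config_hash: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def box(self) -> np.ndarray:
        return self.frames[0].box

    def positions_array(self, indices=None) -> np.ndarray:
        """(n_frames, n_sel, 3) stack of positions."""
        if indices is None:
            return np.stack([f.positions for f in self.frames])
        indices = np.asarray(indices)
        return np.stack([f.positions[indices] for f in self.frames])

    def velocities_array(self, indices=None) -> np.ndarray:
        if indices is None:
            return np.stack([f.velocities for f in self.frames])
        indices = np.asarray(indices)
        return np.stack([f.velocities[indices] for f in self.frames])

    def validate(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        n = self.n_atoms
        for i, f in enumerate(self.frames):
            if len(f.positions) != n:
                raise ValueError(f"frame {i}: atom count {len(f.positions)} != {n}")
        t = self.times
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times are not strictly increasing")


def frame_count(duration: float, save_interval: float) -> int:
    """Number of saved frames for a run of ``duration`` at a fixed stride.

    Both in the same time unit.  The duration must be an integer
    multiple of the stride; anything else is an error rather than a
    silent truncation.
    """
    if duration <= 0 or save_interval <= 0:
        raise ValueError("duration and save_interval must be positive")
    ratio = duration / save_interval
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(1.0, abs(ratio)):
        raise ValueError(
            f"duration {duration} is not an integer multiple of save interval "
            f"{save_interval}"
        )
    return int(n)


# ---------------------------------------------------------------------------
# extended XYZ

def _format_frame(atoms: AtomMeta, frame: Frame, header_extra: str = "") -> str:
    n = len(atoms)
    lines = [str(n)]
    box = " ".join(f"{b:.6f}" for b in frame.box)
    comment = f'time={frame.time:.6f} box="{box}"'
    if header_extra:
        comment += " " + header_extra
    lines.append(comment)
    for i in range(n):
        p = frame.positions[i]
        v = frame.velocities[i]
        lines.append(
            f"{atoms.kind[i]} {atoms.residue[i]} {atoms.name[i]} "
            f"{atoms.mass[i]:.4f} "
            f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
            f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}"
        )
    return "\n".join(lines) + "\n"


def write_trajectory(trajectory: Trajectory, sink) -> None:
    """Write a trajectory as extended XYZ (plain text)."""
    trajectory.validate()
    own = isinstance(sink, (str, Path))
    fh = open(sink, "w") if own else sink
    try:
        for i, frame in enumerate(trajectory.frames):
            extra = ""
            if i == 0:
                bits = []
                if trajectory.seed is not None:
                    bits.append(f"seed={trajectory.seed}")
                if trajectory.config_hash is not None:
                    bits.append(f"config={trajectory.config_hash}")
                extra = " ".join(bits)
            fh.write(_format_frame(trajectory.atoms, frame, extra))
    finally:
        if own:
            fh.close()


def _parse_comment(comment: str) -> dict:
    out = {}
    for tok in shlex.split(comment):
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def iter_frames(source) -> Iterator[tuple[AtomMeta, Frame, dict]]:
    """Stream (atoms, frame, header) triples from an extended-XYZ file.

    Memory use is constant in the number of frames.  A malformed or
    truncated frame raises ValueError naming the last good frame.
    """
    own = isinstance(source, (str, Path))
    fh = open(source) if own else source
    frame_idx = 0
    try:
        while True:
            line = fh.readline()
            if not line:
                return
            if not line.strip():
                continue
            try:
                n = int(line)
            except ValueError:
                raise ValueError(
                    f"bad atom-count line after frame {frame_idx - 1}: {line!r}"
                ) from None
            comment = fh.readline()
            if not comment:
                raise ValueError(f"truncated header after frame {frame_idx - 1}")
            header = _parse_comment(comment)
            if "time" not in header or "box" not in header:
                raise ValueError(f"frame {frame_idx}: missing time/box in header")
            kinds, residues, names, masses = [], [], [], []
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            for i in range(n):
                row = fh.readline()
                if not row:
                    raise ValueError(
                        f"file truncated inside frame {frame_idx} "
                        f"(last complete frame: {frame_idx - 1})"
                    )
                parts = row.split()
                if len(parts) != 10:
                    raise ValueError(
                        f"frame {frame_idx} atom {i}: expected 10 columns, "
                        f"got {len(parts)}"
                    )
                kinds.append(parts[0])
                residues.append(int(parts[1]))
                names.append(parts[2])
                masses.append(float(parts[3]))
                pos[i] = [float(x) for x in parts[4:7]]
                vel[i] = [float(x) for x in parts[7:10]]
            atoms = AtomMeta(
                kind=np.array(kinds),
                residue=np.array(residues),
                name=np.array(names),
                mass=np.array(masses),
            )
            frame = Frame(
                time=float(header["time"]),
                positions=pos,
                velocities=vel,
                box=np.array([float(x) for x in header["box"].split()]),
            )
            yield atoms, frame, header
            frame_idx += 1
    finally:
        if own:
            fh.close()


def read_trajectory(source) -> Trajectory:
    """Materialize an extended-XYZ trajectory.

    Raises ValueError for an empty file, inconsistent atom counts, or a
    truncated/malformed frame.
    """
    traj: Trajectory | None = None
    for atoms, frame, header in iter_frames(source):
        if traj is None:
            traj = Trajectory(
                atoms=atoms,
                seed=int(header["seed"]) if "seed" in header else None,
                config_hash=header.get("config"),
            )
        elif len(atoms) != traj.n_atoms:
            raise ValueError(
                f"frame {traj.n_frames}: atom count {len(atoms)} != {traj.n_atoms}"
            )
        traj.frames.append(frame)
    if traj is None:
        raise ValueError("empty trajectory file (zero frames)")
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# selections

def select(atoms: AtomMeta, spec) -> np.ndarray:
    """Resolve an atom selection to integer indices.

    ``spec`` may be integer indices, or a string: ``all``, one of the
    particle kinds (``solvent``/``cation``/``anion``/``solute``),
    ``ions``, or ``residue:<i>`` for solute residue ``i``.
    """
    if isinstance(spec, str):
        if spec == "all":
            idx = np.arange(len(atoms))
        elif spec in KINDS:
            idx = np.flatnonzero(atoms.kind == spec)
        elif spec == "ions":
            idx = np.flatnonzero(np.isin(atoms.kind, ("cation", "anion")))
        elif spec.startswith("residue:"):
            r = int(spec.split(":", 1)[1])
            idx = np.flatnonzero((atoms.kind == "solute") & (atoms.residue == r))
        else:
            raise ValueError(f"unknown selection {spec!r}")
    else:
        idx = np.asarray(spec, dtype=int)
    if idx.size == 0:
        raise ValueError(f"selection {spec!r} matched no atoms")
    return idx
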