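"""Coarse-grained dynamics of the tethered glycan under body-force flow.

The synthetic system emulates the statistical structure of the all-atom
study at desk scale: a branched solute with the Man6GlcNAc2 linkage
topology, tethered through five aglycon atoms by harmonic restraints,
immersed in single-bead solvent (plus ion beads at a given molarity) in
a periodic orthorhombic box.  Flow is driven by a constant x-direction
force applied to every solvent bead at every timestep, and temperature
is held by a Berendsen weak-coupling thermostat, which rescales all
velocities uniformly and therefore preserves directionally biased
(flow) regions instead of randomizing them.

Default parameters are those of the full-scale reference conditions:
62x66x61 Å box, 6133 solvent particles, 0.15 M NaCl, 2 fs timestep,
300 K with tau = 0.2 ps, 5e-4 kcal/mol/Å body force, 10 kcal/mol/Å^2
tether restraints, 12 Å cutoff, frames saved every 0.4 ps.
``desk_config`` returns the scaled-down configuration used throughout
the test-scale analyses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import _forces
from .io import AtomMeta, Frame, Trajectory, frame_count
from .topology import GlycanTopology, build_man6glcnac2_topology, template_coordinates
from .units import KB, KCAL_PER_MOL_TO_AMU_A2_PS2 as ACC

__all__ = [
    "SimulationConfig",
    "SystemState",
    "paper_config",
    "desk_config",
    "count_ions",
    "build_system",
    "instantaneous_temperature",
    "berendsen_scale",
    "integrate_step",
    "run_simulation",
    "Simulator",
    "IntegrationError",
]

#: water molarity used for the solvent-count -> ion-count conversion
WATER_MOLARITY = 55.5

_MASS = {"solvent": 18.015, "cation": 22.990, "anion": 35.453}


class IntegrationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """All physical and numerical parameters of one run."""

    box: tuple[float, float, float] = (62.0, 66.0, 61.0)  # Å
    n_solvent: int = 6133
    molarity: float = 0.15  # mol/L NaCl
    dt: float = 0.002  # ps (2 fs)
    duration: float = 200_000.0  # ps (200 ns)
    save_stride: float = 0.4  # ps
    temperature: float = 300.0  # K
    tau: float = 0.2  # ps, Berendsen coupling constant
    body_force: tuple[float, float, float] = (5e-4, 0.0, 0.0)  # kcal/mol/Å per solvent bead
    tether_k: float = 10.0  # kcal/mol/Å^2
    tether_ref: np.ndarray | None = None  # default: built aglycon coordinates
    seed: int = 0
    thermostat: bool = True
    n_constraints: int = 0  # subtracted from 3N in the temperature
    # coarse force field
    bond_k: float = 200.0  # kcal/mol/Å^2 in V = 1/2 k dr^2
    angle_k: float = 100.0  # kcal/mol/rad^2
    torsion_k: float = 1.5  # kcal/mol; 3-fold terms, minima at -60/60/180
    torsion_n: int = 3
    torsion_gamma: float = 0.0
    eps: float = 0.15  # kcal/mol soft-sphere prefactor
    sigma_solvent: float = 3.0  # Å
    sigma_solute: float = 2.0  # Å
    cutoff: float = 12.0  # Å
    overlap_factor: float = 0.8  # placement threshold, fraction of sigma

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if any(b <= 0 for b in self.box):
            raise ValueError("box dimensions must be positive")
        if self.molarity < 0:
            raise ValueError("molarity must be non-negative")
        if self.tether_k < 0:
            raise ValueError("tether_k must be non-negative")
        ratio = self.save_stride / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("save_stride must be an integer multiple of dt")

    @property
    def steps_per_save(self) -> int:
        return round(self.save_stride / self.dt)

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["box"] = [float(b) for b in self.box]
        d["body_force"] = [float(b) for b in self.body_force]
        if self.tether_ref is not None:
            d["tether_ref"] = np.asarray(self.tether_ref).tolist()
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "SimulationConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        for key in ("box", "body_force"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("tether_ref") is not None:
            d["tether_ref"] = np.asarray(d["tether_ref"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]

    def with_flow(self, multiplier: float = 1.0) -> "SimulationConfig":
        """Same conditions with the body force scaled (0 = diffusion)."""
        f = tuple(float(multiplier * b) for b in self.body_force)
        return replace(self, body_force=f)


def paper_config(**overrides) -> SimulationConfig:
    """The full-scale reference configuration (not run by the test suite)."""
    return SimulationConfig(**overrides)


def desk_config(**overrides) -> SimulationConfig:
    """Desk-scale configuration: same physics, minutes instead of weeks.

    ~450 solvent beads in a 26x44x26 Å box (tall in y so the ~33 Å
    solute fits below the periodic image), 8 Å cutoff, and a body force
    of 0.02 kcal/mol/Å — stronger than the full-scale 5e-4 so that the
    drift velocity rises above thermal noise within tens of ps, the
    same trade-off the flow forcing always faces between thermostat
    cancellation and runaway acceleration.
    """
    params = dict(
        box=(26.0, 44.0, 26.0),
        n_solvent=450,
        duration=40.0,
        save_stride=0.2,
        cutoff=8.0,
        body_force=(0.02, 0.0, 0.0),
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SystemState:
    positions: np.ndarray  # (n, 3) Å
    velocities: np.ndarray  # (n, 3) Å/ps
    masses: np.ndarray  # amu
    kinds: np.ndarray  # str: solute|solvent|cation|anion
    residues: np.ndarray  # int, 0 for non-solute
    names: np.ndarray  # str
    box: np.ndarray  # (3,)
    time: float = 0.0

    def __post_init__(self):
        n = len(self.positions)
        for arr in (self.velocities, self.masses, self.kinds, self.residues, self.names):
            if len(arr) != n:
                raise ValueError("state arrays have inconsistent lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def copy(self) -> "SystemState":
        return SystemState(
            self.positions.copy(), self.velocities.copy(), self.masses.copy(),
            self.kinds.copy(), self.residues.copy(), self.names.copy(),
            self.box.copy(), self.time,
        )


def count_ions(n_solvent: int, molarity: float) -> int:
    """Ion pairs for a solvent count at a given molarity.

    Uses the water-molarity-ratio convention:
    round(n_solvent * molarity / 55.5).
    """
    if n_solvent < 0 or molarity < 0:
        raise ValueError("n_solvent and molarity must be non-negative")
    return round(n_solvent * molarity / WATER_MOLARITY)


def instantaneous_temperature(velocities, masses, n_constraints: int = 0) -> float:
    """Kinetic temperature in K: sum(m v^2) / (k_B * N_dof), N_dof = 3N - n_c."""
    velocities = np.asarray(velocities, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if velocities.size == 0:
        raise ValueError("empty velocity array")
    ndof = 3 * len(masses) - n_constraints
    if ndof <= 0:
        raise ValueError("no degrees of freedom")
    mv2 = float(np.sum(masses * np.sum(velocities * velocities, axis=1)))
    return mv2 / ACC / (KB * ndof)


def berendsen_scale(t_inst: float, t0: float, dt: float, tau: float) -> float:
    """Berendsen velocity-rescaling factor.

    lambda = sqrt(1 + (dt/tau) (T0/T - 1)); applied as a uniform
    multiplication of all coupled velocities, so flow directions are
    preserved (lambda > 0).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t_inst <= 0:
        raise ValueError("cannot rescale from zero temperature")
    return float(np.sqrt(1.0 + (dt / tau) * (t0 / t_inst - 1.0)))


# ---------------------------------------------------------------------------
# system construction

def build_system(config: SimulationConfig,
                 topology: GlycanTopology | None = None) -> SystemState:
    """Place solute, solvent and ions and draw 300 K velocities.

    The solute template is positioned with the aglycon at the box base
    (small y), stem along +y, centred in x and z.  Solvent beads and
    ion pairs occupy a jittered lattice filtered against the solute so
    no pair is closer than the overlap threshold.  Raises a packing
    error when the box cannot hold the requested particle count.
    """
    box = np.asarray(config.box, dtype=float)
    rng = np.random.Generator(np.random.Philox(config.seed))

    parts_pos, parts_kind, parts_res, parts_name, parts_mass = [], [], [], [], []
    if topology is not None:
        sol = template_coordinates(topology)
        offset = np.array([box[0] / 2, 1.5, box[2] / 2]) - sol[0]
        sol = sol + offset
        parts_pos.append(sol)
        parts_kind += ["solute"] * len(sol)
        parts_res += [r for r, _ in topology.atom_order]
        parts_name += [a for _, a in topology.atom_order]
        parts_mass += [topology.atom_mass(ref) for ref in topology.atom_order]

    n_pair = count_ions(config.n_solvent, config.molarity)
    n_beads = config.n_solvent + 2 * n_pair
    if n_beads > 0:
        thr_ss = config.overlap_factor * config.sigma_solvent
        thr_su = config.overlap_factor * 0.5 * (config.sigma_solvent + config.sigma_solute)
        sites = _lattice_sites(box, n_beads, thr_ss, rng)
        if topology is not None:
            tree = cKDTree(parts_pos[0])
            d, _ = tree.query(sites)
            sites = sites[d >= thr_su]
        if len(sites) < n_beads:
            raise ValueError(
                f"packing error: box {tuple(box)} holds only {len(sites)} sites "
                f"at threshold {thr_ss:.2f} Å but {n_beads} beads requested"
            )
        sites = sites[rng.permutation(len(sites))[:n_beads]]
        parts_pos.append(sites)
        kinds = (["solvent"] * config.n_solvent
                 + ["cation"] * n_pair + ["anion"] * n_pair)
        parts_kind += kinds
        parts_res += [0] * n_beads
        parts_name += [{"solvent": "W", "cation": "NA", "anion": "CL"}[k] for k in kinds]
        parts_mass += [_MASS[k] for k in kinds]

    if not parts_pos:
        raise ValueError("nothing to build: no solute and no solvent requested")
    positions = np.concatenate(parts_pos)
    masses = np.array(parts_mass)
    sigma_v = np.sqrt(ACC * KB * config.temperature / masses)
    velocities = rng.normal(size=positions.shape) * sigma_v[:, None]
    # zero the net momentum of each species separately: a periodic fluid
    # has no mechanism to damp a residual solvent drift mode, which would
    # otherwise masquerade as flow in a zero-force run
    kinds_arr = np.array(parts_kind)
    for kind in np.unique(kinds_arr):
        grp = kinds_arr == kind
        mg = masses[grp]
        velocities[grp] -= np.sum(velocities[grp] * mg[:, None], axis=0) / mg.sum()

    return SystemState(
        positions=positions,
        velocities=velocities,
        masses=masses,
        kinds=np.array(parts_kind),
        residues=np.array(parts_res),
        names=np.array(parts_name),
        box=box,
    )


def _lattice_sites(box, n_needed, min_spacing, rng):
    """Jittered-lattice candidate positions with guaranteed min spacing."""
    target = max(int(1.3 * n_needed) + 8, n_needed)
    vol = float(np.prod(box))
    s = (vol / target) ** (1.0 / 3.0)
    dims = np.maximum(1, np.floor(box / s).astype(int))
    while np.prod(dims) < target:
        s *= 0.97
        dims = np.maximum(1, np.floor(box / s).astype(int))
    spacing = box / dims
    if spacing.min() < min_spacing:
        raise ValueError(
            f"packing error: {n_needed} beads in a {tuple(box)} Å box need a "
            f"lattice spacing below the {min_spacing:.2f} Å overlap threshold")
    jitter = np.maximum(0.0, (spacing.min() - min_spacing) / 2.0 * 0.95)
    grid = np.stack(np.meshgrid(
        *[(np.arange(d) + 0.5) * sp for d, sp in zip(dims, spacing)],
        indexing="ij"), axis=-1).reshape(-1, 3)
    return grid + rng.uniform(-jitter, jitter, size=grid.shape)


# ---------------------------------------------------------------------------
# force field assembly and integration

class Simulator:
    """Velocity-Verlet integrator over the coarse force field.

    Bonded equilibrium lengths and angles are measured from the
    idealized solute template, which therefore sits at the bonded
    minimum; 3-fold cosine torsion terms act on every linkage torsion
    quadruple so the rotamer analysis has -60/+60/180 structure to
    detect.
    """

    def __init__(self, config: SimulationConfig, state: SystemState,
                 topology: GlycanTopology | None = None):
        self.config = config
        self.state = state
        self.topology = topology
        n = state.n_atoms
        box = state.box
        if config.cutoff > box.min() / 2:
            raise ValueError("cutoff exceeds half the smallest box dimension")

        solute_mask = state.kinds == "solute"
        self.n_solute = int(solute_mask.sum())
        if topology is not None and self.n_solute != topology.n_atoms:
            raise ValueError("state does not match topology atom count")

        self.sigma = np.where(solute_mask, config.sigma_solute,
                              config.sigma_solvent).astype(float)
        self.solvent_mask = state.kinds == "solvent"
        self.body_force = np.asarray(config.body_force, dtype=float)

        if topology is not None:
            tpl = template_coordinates(topology)
            bidx = topology.bond_index_pairs()
            self.bond_idx = bidx
            self.bond_r0 = np.linalg.norm(tpl[bidx[:, 0]] - tpl[bidx[:, 1]], axis=1)
            self.bond_k = np.full(len(bidx), config.bond_k)
            # angle triples from the bond graph
            nbrs: dict[int, list[int]] = {}
            for i, j in bidx:
                nbrs.setdefault(int(i), []).append(int(j))
                nbrs.setdefault(int(j), []).append(int(i))
            triples = []
            for j, around in nbrs.items():
                around = sorted(around)
                for a in range(len(around)):
                    for b in range(a + 1, len(around)):
                        triples.append((around[a], j, around[b]))
            self.angle_idx = np.array(triples, dtype=np.int64)
            v1 = tpl[self.angle_idx[:, 0]] - tpl[self.angle_idx[:, 1]]
            v2 = tpl[self.angle_idx[:, 2]] - tpl[self.angle_idx[:, 1]]
            cost = np.sum(v1 * v2, axis=1) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            self.angle_theta0 = np.arccos(np.clip(cost, -1, 1))
            self.angle_k = np.full(len(triples), config.angle_k)
            # torsions: every linkage quadruple
            quads = []
            for linkage in topology.linkages.values():
                for _, quad in linkage.dihedrals:
                    quads.append([topology.atom_index(ref) for ref in quad])
            self.torsion_idx = np.array(quads, dtype=np.int64)
            self.torsion_k = np.full(len(quads), config.torsion_k)
            self.torsion_n = np.full(len(quads), float(config.torsion_n))
            self.torsion_gamma = np.full(len(quads), config.torsion_gamma)
            # exclusions: 1-2 and 1-3 within the solute
            excl = np.zeros((self.n_solute, self.n_solute), dtype=np.int8)
            for i, j in bidx:
                excl[i, j] = excl[j, i] = 1
            for a, j, b in triples:
                excl[a, b] = excl[b, a] = 1
            self.excl = excl
            # tether
            self.tether_idx = np.array(
                [topology.atom_index(ref) for ref in topology.tether_atoms],
                dtype=np.int64)
            if config.tether_ref is not None:
                self.tether_ref = np.asarray(config.tether_ref, dtype=float)
            else:
                self.tether_ref = state.positions[self.tether_idx].copy()
        else:
            z = np.zeros((0,), dtype=np.int64)
            self.bond_idx = np.zeros((0, 2), dtype=np.int64)
            self.bond_r0 = np.zeros(0)
            self.bond_k = np.zeros(0)
            self.angle_idx = np.zeros((0, 3), dtype=np.int64)
            self.angle_theta0 = np.zeros(0)
            self.angle_k = np.zeros(0)
            self.torsion_idx = np.zeros((0, 4), dtype=np.int64)
            self.torsion_k = np.zeros(0)
            self.torsion_n = np.zeros(0)
            self.torsion_gamma = np.zeros(0)
            self.excl = np.zeros((1, 1), dtype=np.int8)
            self.tether_idx = z
            self.tether_ref = np.zeros((0, 3))

        self.step_count = 0
        self._forces, self._pe = self.compute_forces(state.positions)

    def compute_forces(self, pos: np.ndarray):
        """Total force (kcal/mol/Å) and potential energy (kcal/mol)."""
        cfg = self.config
        f = np.zeros_like(pos)
        pe = _forces.nonbonded(pos, self.state.box, cfg.cutoff, cfg.eps,
                               self.sigma, self.excl, self.n_solute, f)
        if len(self.bond_idx):
            pe += _forces.bonds(pos, self.bond_idx, self.bond_k, self.bond_r0, f)
            pe += _forces.angles(pos, self.angle_idx, self.angle_k,
                                 self.angle_theta0, f)
            pe += _forces.torsions(pos, self.torsion_idx, self.torsion_k,
                                   self.torsion_n, self.torsion_gamma, f)
            pe += _forces.tether(pos, self.tether_idx, cfg.tether_k,
                                 self.tether_ref, f)
        f[self.solvent_mask] += self.body_force
        return f, pe

    @property
    def potential_energy(self) -> float:
        """kcal/mol, excluding the (unbounded) body-force work term."""
        return self._pe

    def kinetic_energy(self) -> float:
        s = self.state
        return 0.5 * float(np.sum(s.masses * np.sum(s.velocities ** 2, axis=1))) / ACC

    def temperature(self) -> float:
        return instantaneous_temperature(self.state.velocities, self.state.masses,
                                         self.config.n_constraints)

    def step(self, n: int = 1) -> None:
        """Advance n velocity-Verlet steps (with thermostat if enabled)."""
        cfg = self.config
        s = self.state
        dt = cfg.dt
        inv_m = (ACC / s.masses)[:, None]
        for _ in range(n):
            s.velocities += 0.5 * dt * self._forces * inv_m
            s.positions += dt * s.velocities
            self._forces, self._pe = self.compute_forces(s.positions)
            s.velocities += 0.5 * dt * self._forces * inv_m
            if cfg.thermostat:
                t_inst = self.temperature()
                lam = berendsen_scale(t_inst, cfg.temperature, dt, cfg.tau)
                s.velocities *= lam
            s.time += dt
            self.step_count += 1
        if not np.isfinite(s.positions).all() or not np.isfinite(s.velocities).all():
            raise IntegrationError(
                f"non-finite coordinates or velocities at step {self.step_count}")

    def snapshot(self) -> Frame:
        """Current frame: solvent/ions wrapped into the box, solute unwrapped."""
        s = self.state
        pos = s.positions.copy()
        non_solute = s.kinds != "solute"
        pos[non_solute] = np.mod(pos[non_solute], s.box)
        return Frame(time=s.time, positions=pos,
                     velocities=s.velocities.copy(), box=s.box.copy())

    def atom_meta(self) -> AtomMeta:
        s = self.state
        return AtomMeta(kind=s.kinds.copy(), residue=s.residues.copy(),
                        name=s.names.copy(), mass=s.masses.copy())


def integrate_step(state: SystemState, config: SimulationConfig,
                   topology: GlycanTopology | None = None) -> SystemState:
    """One velocity-Verlet step; returns the advanced state.

    Convenience wrapper over :class:`Simulator` for single-step use;
    long runs should drive a Simulator directly (it caches the force
    field tables).
    """
    sim = Simulator(config, state.copy(), topology)
    sim.step()
    return sim.state


def run_simulation(config: SimulationConfig,
                   topology: GlycanTopology | None = None,
                   progress: bool = False) -> Trajectory:
    """Build the system and integrate, saving frames at the stride.

    Frames are saved after each stride (`duration == save_stride` gives
    exactly one frame); the run is bitwise-reproducible for a fixed
    seed.  Integration blow-ups abort with the failing frame index.
    """
    n_frames = frame_count(config.duration, config.save_stride)
    state = build_system(config, topology)
    sim = Simulator(config, state, topology)
    traj = Trajectory(atoms=sim.atom_meta(), seed=config.seed,
                      config_hash=config.config_hash())
    iterator = range(n_frames)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="frames")
    for k in iterator:
        try:
            sim.step(config.steps_per_save)
        except IntegrationError as err:
            raise IntegrationError(f"frame {k}: {err}") from err
        traj.frames.append(sim.snapshot())
    return traj
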