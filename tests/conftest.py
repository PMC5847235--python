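import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from glycoflow.io import AtomMeta, Frame, Trajectory
from glycoflow.simulate import desk_config, run_simulation
from glycoflow.topology import build_man6glcnac2_topology


@pytest.fixture(scope="session")
def topology():
    return build_man6glcnac2_topology()


@pytest.fixture(scope="session")
def pair_runs(topology):
    """Matched-seed diffusion/flow desk runs (40 ps, 200 frames each)."""
    runs = {}
    for label, mult in (("diffusion", 0.0), ("flow", 1.0)):
        cfg = desk_config(duration=40.0, seed=11).with_flow(mult)
        runs[label] = run_simulation(cfg, topology)
    return runs


@pytest.fixture(scope="session")
def force_series(topology):
    """Three force levels at matched seed; second-half solvent mean v_x."""
    out = {}
    for mult in (0.25, 1.0, 2.0):
        cfg = desk_config(duration=12.0, seed=3).with_flow(mult)
        traj = run_simulation(cfg, topology)
        idx = np.flatnonzero(traj.atoms.kind == "solvent")
        vx = traj.velocities_array(idx)[:, :, 0].mean(axis=1)
        out[mult] = float(vx[len(vx) // 2:].mean())
    return out


@pytest.fixture(scope="session")
def null_run_means(topology):
    """Bulk solvent v_x from four independent zero-force runs.

    The tether exchanges momentum with its fixed anchor and the
    weak-coupling thermostat preserves drift, so a single run carries a
    slowly wandering solvent drift mode; independent replicates give an
    honest standard error for the zero-force null.
    """
    means = []
    for seed in (31, 32, 33, 34):
        cfg = desk_config(duration=12.0, seed=seed, body_force=(0.0, 0.0, 0.0))
        traj = run_simulation(cfg, topology)
        idx = np.flatnonzero(traj.atoms.kind == "solvent")
        vx = traj.velocities_array(idx)[:, :, 0].mean(axis=1)
        means.append(float(vx[len(vx) // 4:].mean()))
    return np.array(means)


@pytest.fixture
def make_random_trajectory():
    """Factory: synthetic trajectory of free particles, no simulation."""

    def _make(n_atoms=20, n_frames=6, box=(12.0, 15.0, 10.0), seed=0,
              kind="solvent"):
        rng = np.random.default_rng(seed)
        box = np.asarray(box, dtype=float)
        atoms = AtomMeta(
            kind=np.array([kind] * n_atoms),
            residue=np.zeros(n_atoms, dtype=int),
            name=np.array(["W"] * n_atoms),
            mass=np.full(n_atoms, 18.015),
        )
        frames = [
            Frame(time=0.1 * (k + 1),
                  positions=rng.uniform(0, 1, (n_atoms, 3)) * box,
                  velocities=rng.normal(size=(n_atoms, 3)),
                  box=box)
            for k in range(n_frames)
        ]
        return Trajectory(atoms=atoms, frames=frames, seed=seed)

    return _make


@pytest.fixture(scope="session")
def solute_trajectory(topology):
    """Static single-frame trajectory of the solute template (no dynamics)."""
    from glycoflow.topology import template_coordinates

    coords = template_coordinates(topology)
    n = topology.n_atoms
    atoms = AtomMeta(
        kind=np.array(["solute"] * n),
        residue=np.array([r for r, _ in topology.atom_order]),
        name=np.array([a for _, a in topology.atom_order]),
        mass=topology.masses,
    )
    box = np.array([62.0, 66.0, 61.0])
    frames = [Frame(time=0.4 * (k + 1), positions=coords.copy(),
                    velocities=np.zeros((n, 3)), box=box) for k in range(3)]
    return Trajectory(atoms=atoms, frames=frames)
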