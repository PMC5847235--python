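"""Glycan orientation relative to its tether, and the aglycon response.

The orientation of each branch is quantified by the angle ∠ABx at
vertex B between rays B→A and B→x, where A and B are the restrained
aglycon atoms CA and CB and x is the centre of mass of a sugar
residue.  Under flow the glycan bends toward the flow axis, which
shows up as a shift of the ∠ABx distributions toward lower angles.
The asparagine side-chain response is measured through the chi2
(CA-CB-CG-N) rotamer populations, expressed as Boltzmann energies per
state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory
from .topology import GlycanTopology
from .torsions import assign_rotamer_states, torsion_series, _state_name
from .units import KB

__all__ = [
    "AngleDistribution", "center_of_mass", "abx_angle", "abx_distribution",
    "chi2_energy_profile", "max_extension", "dominant_aglycon_states",
]

_AXIS = {"x": 0, "y": 1, "z": 2}


def center_of_mass(positions, masses):
    """Mass-weighted mean position; vectorized over leading dimensions."""
    positions = np.asarray(positions, dtype=float)
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if masses.size == 0 or total <= 0:
        raise ValueError("center of mass needs non-empty positive masses")
    return np.tensordot(positions, masses, axes=([-2], [0])) / total


def abx_angle(a, b, x):
    """Angle (degrees in [0, 180]) at vertex ``b`` between rays b→a, b→x."""
    a, b, x = (np.asarray(p, dtype=float) for p in (a, b, x))
    u = a - b
    v = x - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-10) or np.any(nv < 1e-10):
        raise ValueError("coincident points: angle undefined")
    c = np.sum(u * v, axis=-1) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    return ang if ang.ndim else float(ang)


@dataclass
class AngleDistribution:
    residue: int
    angles: np.ndarray  # per frame, degrees in [0, 180]
    edges: np.ndarray  # histogram bin edges
    densities: np.ndarray  # normalized so they sum to 1 over bins
    condition: str  # "diffusion" | "flow"

    @property
    def mean(self) -> float:
        return float(self.angles.mean())


def _solute_wrap_check(trajectory: Trajectory, topology: GlycanTopology):
    """Reject trajectories whose solute was stored wrapped.

    A wrapped solute shows bonded atoms separated by near-box jumps;
    analyses on raw coordinates would then be meaningless.
    """
    sol = np.flatnonzero(trajectory.atoms.kind == "solute")
    if len(sol) == 0:
        raise ValueError("trajectory has no solute atoms")
    f = trajectory.frames[0]
    bp = topology.bond_index_pairs()
    lengths = np.linalg.norm(f.positions[sol[bp[:, 0]]] - f.positions[sol[bp[:, 1]]],
                             axis=1)
    if lengths.max() > 0.5 * f.box.min():
        raise ValueError(
            "solute appears wrapped across the periodic boundary; "
            "orientation analysis needs unwrapped solute coordinates")
    return sol


def _aglycon_ab(trajectory: Trajectory, a_name="CA", b_name="CB"):
    meta = trajectory.atoms
    ai = np.flatnonzero((meta.residue == 1) & (meta.name == a_name))
    bi = np.flatnonzero((meta.residue == 1) & (meta.name == b_name))
    if len(ai) != 1 or len(bi) != 1:
        raise ValueError(f"tether atoms {a_name}/{b_name} not found on residue 1")
    return int(ai[0]), int(bi[0])


def abx_distribution(trajectory: Trajectory, topology: GlycanTopology,
                     residue_x: int, condition: str = "",
                     bin_width: float = 2.0, burn_in: float = 0.1,
                     a_name: str = "CA", b_name: str = "CB") -> AngleDistribution:
    """Per-frame ∠ABx for one residue, with its normalized histogram."""
    _solute_wrap_check(trajectory, topology)
    ai, bi = _aglycon_ab(trajectory, a_name, b_name)
    meta = trajectory.atoms
    rsel = np.flatnonzero((meta.kind == "solute") & (meta.residue == residue_x))
    if len(rsel) == 0:
        raise ValueError(f"residue {residue_x} not present in trajectory")
    skip = int(round(burn_in * trajectory.n_frames)) if burn_in < 1 else int(burn_in)
    pos = trajectory.positions_array()[skip:]
    com = center_of_mass(pos[:, rsel], meta.mass[rsel])
    angles = abx_angle(pos[:, ai], pos[:, bi], com)
    edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    counts, _ = np.histogram(angles, bins=edges)
    densities = counts / counts.sum()
    return AngleDistribution(residue=residue_x, angles=np.atleast_1d(angles),
                             edges=edges, densities=densities,
                             condition=condition)


def chi2_energy_profile(chi2_series, temperature: float = 300.0,
                        state_centers=(-60.0, 60.0, 180.0),
                        window_halfwidth: float = 60.0) -> dict[str, float | None]:
    """Boltzmann energies of the chi2 rotamer states (kcal/mol).

    Occupancies come from rotamer-state assignment; energies are
    E = -k_B T ln(p / p_max), so the dominant state is at 0 and
    unpopulated states are None (masked).  Raises when no frame falls
    in any state window.
    """
    _, occ = assign_rotamer_states(chi2_series, state_centers, window_halfwidth)
    states = [_state_name(c) for c in np.sort(np.asarray(state_centers, float))]
    pops = {s: occ[s] for s in states}
    pmax = max(pops.values())
    if pmax == 0:
        raise ValueError("all frames unassigned: no chi2 state populated")
    return {s: (None if p == 0 else float(-KB * temperature * np.log(p / pmax)) + 0.0)
            for s, p in pops.items()}


def max_extension(trajectory: Trajectory, topology: GlycanTopology,
                  axis: str = "y", tether_reference: float | None = None) -> float:
    """Maximum solute reach (Å) along an axis above the tether point.

    The tether reference coordinate defaults to the aglycon C position
    in the first frame (the restraint anchor).  Requires unwrapped
    solute coordinates.
    """
    ax = _AXIS[axis] if isinstance(axis, str) else int(axis)
    sol = _solute_wrap_check(trajectory, topology)
    if tether_reference is None:
        meta = trajectory.atoms
        ci = np.flatnonzero((meta.residue == 1) & (meta.name == "C"))
        if len(ci) != 1:
            raise ValueError("tether anchor atom C not found on residue 1")
        tether_reference = float(trajectory.frames[0].positions[int(ci[0]), ax])
    pos = trajectory.positions_array(sol)[:, :, ax]
    return float(pos.max() - tether_reference)


def dominant_aglycon_states(trajectory: Trajectory, topology: GlycanTopology,
                            top_n: int = 2, burn_in: float = 0.1):
    """Top-N (phi, psi, chi2) aglycon rotamer-state combinations.

    Returns a list of dicts with the state triple, its occupancy and
    the mean of each angle within the combination — a tabular stand-in
    for depicting the two dominant conformers.
    """
    series = {name: torsion_series(trajectory, topology, "aglycon", name)
              for name in ("phi", "psi", "chi2")}
    skip = int(round(burn_in * trajectory.n_frames))
    labels = {}
    values = {}
    for name, s in series.items():
        lab, _ = assign_rotamer_states(s.values[skip:])
        labels[name] = lab
        values[name] = s.values[skip:]
    combos = list(zip(labels["phi"], labels["psi"], labels["chi2"]))
    uniq, counts = np.unique(combos, axis=0, return_counts=True)
    order = np.argsort(counts)[::-1][:top_n]
    out = []
    n = len(combos)
    arr = np.array(combos)
    for k in order:
        mask = np.all(arr == uniq[k], axis=1)
        out.append({
            "phi_state": uniq[k][0], "psi_state": uniq[k][1],
            "chi2_state": uniq[k][2],
            "occupancy": float(counts[k] / n),
            "phi_mean": _circmean(values["phi"][mask]),
            "psi_mean": _circmean(values["psi"][mask]),
            "chi2_mean": _circmean(values["chi2"][mask]),
        })
    return out


def _circmean(deg: np.ndarray) -> float:
    """Circular mean in degrees (means of states near ±180 stay sane)."""
    rad = np.radians(deg)
    return float(np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
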