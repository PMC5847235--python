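"""Glycosidic torsion time series, population maps and Boltzmann energies.

Torsion angles follow the signed IUPAC convention, reported in degrees
in (-180, 180].  Two-dimensional population maps are histograms on
(-180, 180]^2; Boltzmann population weighting converts bin counts c to
relative free energies E = -k_B T ln(c / c_max), so the most populated
bin sits at exactly 0 and empty bins are masked.  At 300 K,
k_B T = 0.596 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory
from .topology import GlycanTopology, dihedral_quadruples
from .units import KB

__all__ = [
    "TorsionSeries", "PopulationMap", "EnergyMap",
    "dihedral_angle", "torsion_series", "population_map2d",
    "boltzmann_energy_map", "assign_rotamer_states",
]


def dihedral_angle(p1, p2, p3, p4, box=None):
    """Signed dihedral (degrees in (-180, 180]) of four points.

    Vectorized over leading dimensions.  When ``box`` is given the
    three bond vectors are taken under the minimum-image convention.
    Raises for a degenerate (zero-length) central bond.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if box is not None:
        box = np.asarray(box, dtype=float)
        b1 -= box * np.round(b1 / box)
        b2 -= box * np.round(b2 / box)
        b3 -= box * np.round(b3 / box)
    n2 = np.linalg.norm(b2, axis=-1)
    if np.any(n2 < 1e-10):
        raise ValueError("degenerate dihedral: zero-length central bond")
    a = np.cross(b1, b2)
    b = np.cross(b2, b3)
    sin_phi = np.sum(np.cross(a, b) * b2, axis=-1) / n2
    cos_phi = np.sum(a * b, axis=-1)
    ang = np.degrees(np.arctan2(sin_phi, cos_phi))
    # map -180 -> +180 so the range is (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return ang if ang.ndim else float(ang)


@dataclass
class TorsionSeries:
    linkage_id: str
    angle_name: str  # phi | psi | omega | chi2
    values: np.ndarray  # degrees in (-180, 180]
    times: np.ndarray  # ps

    def __len__(self):
        return len(self.values)


def torsion_series(trajectory: Trajectory, topology: GlycanTopology,
                   linkage_id: str, angle_name: str) -> TorsionSeries:
    """Per-frame torsion angle for one linkage over the whole trajectory."""
    quads = dict(dihedral_quadruples(topology, linkage_id))
    try:
        quad = quads[angle_name]
    except KeyError:
        raise KeyError(
            f"linkage {linkage_id!r} has no angle {angle_name!r}; "
            f"defined: {sorted(quads)}") from None
    idx = [topology.atom_index(ref) for ref in quad]
    pts = trajectory.positions_array(idx)  # (m, 4, 3), solute is unwrapped
    vals = dihedral_angle(pts[:, 0], pts[:, 1], pts[:, 2], pts[:, 3])
    return TorsionSeries(linkage_id, angle_name, np.atleast_1d(vals),
                         trajectory.times)


@dataclass
class PopulationMap:
    axis_names: tuple[str, str]
    edges: np.ndarray  # shared bin edges covering (-180, 180]
    counts: np.ndarray  # (nbins, nbins), axis A on rows
    total: int


@dataclass
class EnergyMap:
    axis_names: tuple[str, str]
    edges: np.ndarray
    energies: np.ma.MaskedArray  # kcal/mol, empty bins masked
    temperature: float


def population_map2d(series_a, series_b, bin_width: float = 5.0) -> PopulationMap:
    """2-D torsion histogram on (-180, 180] x (-180, 180].

    ``bin_width`` (degrees) must divide 360.  A sample at exactly 180
    falls in the last bin.
    """
    a = np.asarray(getattr(series_a, "values", series_a), dtype=float)
    b = np.asarray(getattr(series_b, "values", series_b), dtype=float)
    if len(a) != len(b):
        raise ValueError(f"series lengths differ: {len(a)} vs {len(b)}")
    nbins = 360.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide 360")
    edges = np.linspace(-180.0, 180.0, int(round(nbins)) + 1)
    counts, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    names = (getattr(series_a, "angle_name", "A"),
             getattr(series_b, "angle_name", "B"))
    return PopulationMap(axis_names=names, edges=edges,
                         counts=counts.astype(int), total=len(a))


def boltzmann_energy_map(population_map: PopulationMap,
                         temperature: float = 300.0) -> EnergyMap:
    """Boltzmann population weighting: E = -k_B T ln(c / c_max), kcal/mol."""
    counts = population_map.counts
    cmax = counts.max()
    if cmax == 0 or population_map.total == 0:
        raise ValueError("cannot weight an empty population map")
    with np.errstate(divide="ignore"):
        e = -KB * temperature * np.log(counts / cmax)
    energies = np.ma.masked_array(e, mask=(counts == 0))
    return EnergyMap(population_map.axis_names, population_map.edges,
                     energies, temperature)


def _circular_delta(a, b):
    """Smallest absolute angular difference in degrees."""
    d = np.abs(np.mod(a - b + 180.0, 360.0) - 180.0)
    return d


def assign_rotamer_states(series, state_centers=(-60.0, 60.0, 180.0),
                          window_halfwidth: float = 60.0):
    """Label frames by the nearest rotamer state on the circle.

    A frame is assigned to the state whose center is circularly nearest
    and within ``window_halfwidth``; otherwise it is "unassigned".
    Exactly equidistant samples resolve to the lower center.  Windows
    that overlap (after circular wrap) are a configuration error.

    Returns (labels, occupancies): labels is an array of state strings,
    occupancies a dict mapping each state (and "unassigned") to its
    fraction; the fractions sum to 1.
    """
    centers = np.sort(np.asarray(state_centers, dtype=float))
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if _circular_delta(centers[i], centers[j]) < 2 * window_halfwidth - 1e-9:
                raise ValueError(
                    f"state windows at {centers[i]} and {centers[j]} overlap "
                    f"(halfwidth {window_halfwidth})")
    vals = np.asarray(getattr(series, "values", series), dtype=float)
    d = _circular_delta(vals[:, None], centers[None, :])  # (n, k)
    nearest = np.argmin(d, axis=1)  # ties resolve to the lower center
    within = d[np.arange(len(vals)), nearest] <= window_halfwidth
    names = [_state_name(c) for c in centers]
    labels = np.where(within, np.array(names)[nearest], "unassigned")
    occ = {name: float(np.mean(labels == name)) for name in names}
    occ["unassigned"] = float(np.mean(labels == "unassigned"))
    return labels, occ


def _state_name(center: float) -> str:
    c = int(round(center))
    return f"{c:+d}" if c != 180 else "180"
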