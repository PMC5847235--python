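"""Radial distribution functions for ion-solute and ion-ion structure.

g(r) is computed from minimum-image pair distances, normalized by
shell volume, frame count and the ideal-gas pair density, so a
structureless fluid gives g(r) = 1.  Cross-group RDFs between solute
residues and ions use the member-atom convention (every atom of the
residue counts, not its centre).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Trajectory, select

__all__ = ["RDF", "radial_distribution"]


@dataclass
class RDF:
    centers: np.ndarray  # Å
    g: np.ndarray
    shell_counts: np.ndarray  # mean pair count per shell per frame
    selections: tuple[str, str]
    dr: float
    r_max: float

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"r": self.centers, "g": self.g,
                             "count": self.shell_counts})


def _pair_distances(pa, pb, box, same):
    """Minimum-image distances between two position sets (one frame)."""
    d = pa[:, None, :] - pb[None, :, :]
    d -= box * np.round(d / box)
    r = np.sqrt(np.sum(d * d, axis=-1))
    if same:
        iu = np.triu_indices(len(pa), k=1)
        return r[iu]
    return r.ravel()


def radial_distribution(trajectory: Trajectory, selection_a, selection_b,
                        dr: float = 0.1, r_max: float | None = None,
                        burn_in: float = 0.0) -> RDF:
    """g(r) between two selections under minimum image.

    ``r_max`` defaults to, and may not exceed, half the smallest box
    dimension.  Identical selections exclude self-pairs and count each
    unordered pair once.
    """
    box = trajectory.box
    limit = float(box.min()) / 2.0
    if r_max is None:
        r_max = limit
    if r_max > limit + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the smallest box "
                         f"dimension ({limit:.2f} Å)")
    if dr <= 0:
        raise ValueError("dr must be positive")
    idx_a = select(trajectory.atoms, selection_a)
    idx_b = select(trajectory.atoms, selection_b)
    same = np.array_equal(np.sort(idx_a), np.sort(idx_b))

    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    nbins = len(edges) - 1
    counts = np.zeros(nbins)
    skip = int(round(burn_in * trajectory.n_frames)) if burn_in < 1 else int(burn_in)
    frames = trajectory.frames[skip:]
    if not frames:
        raise ValueError("burn-in discards all frames")
    for f in frames:
        pa = np.mod(f.positions[idx_a], box)
        pb = np.mod(f.positions[idx_b], box)
        r = _pair_distances(pa, pb, box, same)
        h, _ = np.histogram(r, bins=edges)
        counts += h
    counts /= len(frames)

    vol = float(np.prod(box))
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    if same:
        n_ideal = len(idx_a) * (len(idx_a) - 1) / 2.0 * shell_vol / vol
    else:
        n_ideal = len(idx_a) * len(idx_b) * shell_vol / vol
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(n_ideal > 0, counts / n_ideal, 0.0)

    centers = 0.5 * (edges[:-1] + edges[1:])
    name = lambda s: s if isinstance(s, str) else f"[{len(s)} atoms]"
    return RDF(centers=centers, g=g, shell_counts=counts,
               selections=(name(selection_a), name(selection_b)),
               dr=dr, r_max=float(r_max))
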