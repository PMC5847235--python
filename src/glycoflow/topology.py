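"""Topology of the asparagine-linked Man6GlcNAc2 N-glycan.

The glycan is a branched octasaccharide: a GlcNAc(2)-GlcNAc(3)-Man(4)
core attached to an asparagine aglycon, with Man(4) branching into
Man(5) (via 1-6) and Man(8) (via 1-3), Man(5) branching into Man(6)
(1-6) and Man(7) (1-3), and Man(8) carrying Man(9) via 1-2.  Residues
are numbered 2-9 for the sugars; the aglycon is residue 1.

Each glycosidic linkage is written ``donor-acceptor`` (e.g. ``8-4``:
C1 of residue 8 bonded through a glycosidic oxygen to C3 of residue 4)
and carries the torsion-angle definitions used throughout the field:

* (1-x) linkages, x in {2, 3, 4}:  phi = H1-C1-O-Cx',  psi = C1-O-Cx'-Hx'
* (1-6) linkages:  phi = H1-C1-O-C6',  psi = C1-O-C6'-C5',
  omega = O-C6'-C5'-O5'
* the N-glycosidic aglycon link:  phi = CB-CG-N-C1',  psi = CG-N-C1'-C2',
  chi2 = CA-CB-CG-N

where the prime marks atoms of the linkage acceptor.  The coarse model
represents each sugar by the pseudo-atoms that appear in these torsion
quadruples and in the inter-proton distance analysis (ring carbons,
ring oxygen O5, glycosidic oxygen O1, and the ring "protons" H1-H5,
H61, H62); the aglycon by C, CA, CB, CG and the amide N.  Hydrogen
pseudo-atoms carry a repartitioned mass of 3 amu so the coarse model
integrates stably at a 2 fs timestep.
"""

from __future__ import annotations

import io as _stdio
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Residue",
    "Linkage",
    "GlycanTopology",
    "build_man6glcnac2_topology",
    "dihedral_quadruples",
    "load_structure",
    "write_structure",
    "template_coordinates",
]

AtomRef = tuple[int, str]

_MASSES = {"C": 12.011, "O": 15.999, "N": 14.007, "H": 3.0}

_SUGAR_ATOMS = [
    "C1", "C2", "C3", "C4", "C5", "C6", "O5",
    "H1", "H2", "H3", "H4", "H5", "H61", "H62",
]
_AGLYCON_ATOMS = ["C", "CA", "CB", "CG", "N"]


@dataclass(frozen=True)
class Residue:
    """One residue of the glycan (a sugar or the asparagine aglycon)."""

    index: int
    kind: str  # "GlcNAc" | "Man" | "Asn"
    atoms: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError(f"duplicate atom labels in residue {self.index}")


@dataclass(frozen=True)
class Linkage:
    """A glycosidic (or the N-glycosidic) linkage with its torsion quadruples."""

    donor: int
    acceptor: int
    link_class: str  # "1-2" | "1-3" | "1-4" | "1-6" | "N-glycosidic"
    dihedrals: tuple[tuple[str, tuple[AtomRef, AtomRef, AtomRef, AtomRef]], ...]

    @property
    def linkage_id(self) -> str:
        if self.link_class == "N-glycosidic":
            return "aglycon"
        return f"{self.donor}-{self.acceptor}"


@dataclass
class GlycanTopology:
    residues: dict[int, Residue]
    linkages: dict[str, Linkage]
    tether_atoms: tuple[AtomRef, ...]
    bonds: list[tuple[AtomRef, AtomRef]]
    atom_order: list[AtomRef] = field(default_factory=list)
    _index: dict[AtomRef, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atom_order:
            for ridx in sorted(self.residues):
                for name in self.residues[ridx].atoms:
                    self.atom_order.append((ridx, name))
        self._index = {ref: i for i, ref in enumerate(self.atom_order)}

    @property
    def n_atoms(self) -> int:
        return len(self.atom_order)

    def atom_index(self, ref: AtomRef) -> int:
        try:
            return self._index[ref]
        except KeyError:
            raise KeyError(f"atom {ref[1]} of residue {ref[0]} not in topology") from None

    def atom_element(self, ref: AtomRef) -> str:
        name = ref[1]
        if name in ("N",):
            return "N"
        return name[0]

    def atom_mass(self, ref: AtomRef) -> float:
        return _MASSES[self.atom_element(ref)]

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.atom_mass(r) for r in self.atom_order])

    def residue_atom_indices(self, residue_index: int) -> np.ndarray:
        return np.array(
            [i for i, (r, _) in enumerate(self.atom_order) if r == residue_index]
        )

    def bond_index_pairs(self) -> np.ndarray:
        return np.array(
            [[self.atom_index(a), self.atom_index(b)] for a, b in self.bonds]
        )

    def children(self, residue_index: int) -> list[int]:
        return sorted(
            l.donor for l in self.linkages.values() if l.acceptor == residue_index
        )

    def to_text(self) -> str:
        """Structured-text serialization for inspection."""
        out = _stdio.StringIO()
        out.write("# glycoflow topology\n[residues]\n")
        for ridx in sorted(self.residues):
            r = self.residues[ridx]
            out.write(f"{r.index}\t{r.kind}\t{','.join(r.atoms)}\n")
        out.write("[linkages]\n")
        for lid, l in self.linkages.items():
            out.write(f"{lid}\t{l.donor}->{l.acceptor}\t{l.link_class}\n")
            for name, quad in l.dihedrals:
                atoms = " ".join(f"{r}:{a}" for r, a in quad)
                out.write(f"  {name}\t{atoms}\n")
        out.write("[tether]\n")
        out.write(" ".join(f"{r}:{a}" for r, a in self.tether_atoms) + "\n")
        return out.getvalue()


def _sugar_linkage_dihedrals(donor: int, acceptor: int, x: int):
    """Torsion quadruples for a (1-x) glycosidic linkage."""
    if x == 6:
        return (
            ("phi", ((donor, "H1"), (donor, "C1"), (donor, "O1"), (acceptor, "C6"))),
            ("psi", ((donor, "C1"), (donor, "O1"), (acceptor, "C6"), (acceptor, "C5"))),
            ("omega", ((donor, "O1"), (acceptor, "C6"), (acceptor, "C5"), (acceptor, "O5"))),
        )
    return (
        ("phi", ((donor, "H1"), (donor, "C1"), (donor, "O1"), (acceptor, f"C{x}"))),
        ("psi", ((donor, "C1"), (donor, "O1"), (acceptor, f"C{x}"), (acceptor, f"H{x}"))),
    )


def build_man6glcnac2_topology() -> GlycanTopology:
    """Build the canonical Man6GlcNAc2 + Asn topology.

    Returns the residue graph (aglycon = residue 1, sugars 2-9), the
    seven glycosidic linkages plus the N-glycosidic aglycon link, the
    five-atom tether set and the coarse-model bond list.
    """
    kinds = {1: "Asn", 2: "GlcNAc", 3: "GlcNAc",
             4: "Man", 5: "Man", 6: "Man", 7: "Man", 8: "Man", 9: "Man"}
    residues: dict[int, Residue] = {}
    for ridx, kind in kinds.items():
        if kind == "Asn":
            atoms = tuple(_AGLYCON_ATOMS)
        else:
            atoms = tuple(_SUGAR_ATOMS) + (("O1",) if ridx != 2 else ())
            # residue 2 links to Asn directly through N; no glycosidic O1
        residues[ridx] = Residue(ridx, kind, atoms)

    link_specs = [  # (donor, acceptor, x)
        (3, 2, 4), (4, 3, 4),
        (5, 4, 6), (8, 4, 3),
        (6, 5, 6), (7, 5, 3),
        (9, 8, 2),
    ]
    linkages: dict[str, Linkage] = {}
    aglycon = Linkage(
        donor=2, acceptor=1, link_class="N-glycosidic",
        dihedrals=(
            ("phi", ((1, "CB"), (1, "CG"), (1, "N"), (2, "C1"))),
            ("psi", ((1, "CG"), (1, "N"), (2, "C1"), (2, "C2"))),
            ("chi2", ((1, "CA"), (1, "CB"), (1, "CG"), (1, "N"))),
        ),
    )
    linkages[aglycon.linkage_id] = aglycon
    for donor, acceptor, x in link_specs:
        l = Linkage(donor, acceptor, f"1-{x}",
                    _sugar_linkage_dihedrals(donor, acceptor, x))
        linkages[l.linkage_id] = l

    bonds: list[tuple[AtomRef, AtomRef]] = []
    # aglycon chain C-CA-CB-CG-N
    for a, b in zip(_AGLYCON_ATOMS[:-1], _AGLYCON_ATOMS[1:]):
        bonds.append(((1, a), (1, b)))
    for ridx, kind in kinds.items():
        if kind == "Asn":
            continue
        ring = ["C1", "C2", "C3", "C4", "C5", "O5", "C1"]
        for a, b in zip(ring[:-1], ring[1:]):
            bonds.append(((ridx, a), (ridx, b)))
        bonds.append(((ridx, "C5"), (ridx, "C6")))
        for c, h in [("C1", "H1"), ("C2", "H2"), ("C3", "H3"),
                     ("C4", "H4"), ("C5", "H5"), ("C6", "H61"), ("C6", "H62")]:
            bonds.append(((ridx, c), (ridx, h)))
        if ridx != 2:
            bonds.append(((ridx, "C1"), (ridx, "O1")))
    # inter-residue bonds
    bonds.append(((2, "C1"), (1, "N")))
    for donor, acceptor, x in link_specs:
        bonds.append(((donor, "O1"), (acceptor, f"C{x}")))

    return GlycanTopology(
        residues=residues,
        linkages=linkages,
        tether_atoms=tuple((1, a) for a in _AGLYCON_ATOMS),
        bonds=bonds,
    )


def dihedral_quadruples(topology: GlycanTopology, linkage_id: str):
    """Ordered (name, quadruple) pairs for one linkage.

    ``linkage_id`` is ``"donor-acceptor"`` (e.g. ``"5-4"``) or
    ``"aglycon"``.  Raises KeyError for an unknown linkage.
    """
    try:
        linkage = topology.linkages[linkage_id]
    except KeyError:
        raise KeyError(f"unknown linkage id {linkage_id!r}; "
                       f"known: {sorted(topology.linkages)}") from None
    return list(linkage.dihedrals)


# ---------------------------------------------------------------------------
# idealized template geometry

def template_coordinates(topology: GlycanTopology) -> np.ndarray:
    """Idealized coarse coordinates (Å), aglycon at the base, stem along +y.

    Rings are regular hexagons of radius 1.45 Å lying in the xy-plane;
    each branch grows outward from its attachment carbon tilted toward
    +y, so the two 1-6/1-3 branch pairs splay apart instead of clashing.
    The simulator measures its bonded equilibrium lengths and angles
    from this template, which therefore sits at the bonded minimum.
    """
    coords: dict[AtomRef, np.ndarray] = {}
    ring_centers: dict[int, np.ndarray] = {}
    yhat = np.array([0.0, 1.0, 0.0])
    # aglycon zigzag going up in the xy-plane
    zig = np.array([0.45, 1.43, 0.0])
    zag = np.array([-0.45, 1.43, 0.0])
    pos = np.zeros(3)
    for i, name in enumerate(_AGLYCON_ATOMS):
        coords[(1, name)] = pos.copy()
        pos = pos + (zig if i % 2 == 0 else zag)

    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]

    def place_sugar(ridx: int, attach: np.ndarray, parent_center: np.ndarray,
                    has_o1_bridge: bool, tilt: float):
        # grow outward from the parent ring, biased upward
        u = _unit(attach - parent_center)
        d = _unit(u + tilt * yhat)
        p = _unit(np.array([-d[1], d[0], 0.0]))
        q = np.cross(d, p)  # +/- z
        if has_o1_bridge:
            # kinked glycosidic bridge: Cx-O1-C1 angle of 120 degrees, so
            # no torsion quadruple through the bridge is ever collinear
            cos30, sin30 = math.cos(math.radians(30)), math.sin(math.radians(30))
            o1 = attach + 1.40 * (cos30 * d + sin30 * p)
            c1 = o1 + 1.40 * (cos30 * d - sin30 * p)
            coords[(ridx, "O1")] = o1
        else:
            c1 = attach + 1.45 * d
        center = c1 + 1.45 * d
        ring_centers[ridx] = center
        for k, name in enumerate(ring_names):
            ang = math.radians(60.0 * k)
            coords[(ridx, name)] = (center
                                    - 1.45 * math.cos(ang) * d
                                    + 1.45 * math.sin(ang) * p)
        c5 = coords[(ridx, "C5")]
        c6 = c5 + 1.5 * _unit(0.8 * _unit(c5 - center) + 0.6 * d)
        coords[(ridx, "C6")] = c6
        for k, (c, h) in enumerate([("C1", "H1"), ("C2", "H2"), ("C3", "H3"),
                                    ("C4", "H4"), ("C5", "H5")]):
            coords[(ridx, h)] = coords[(ridx, c)] + 1.1 * (q if k % 2 == 0 else -q)
        coords[(ridx, "H61")] = c6 + 1.1 * q
        coords[(ridx, "H62")] = c6 - 1.1 * q

    # traverse the tree from the aglycon; stem residues grow nearly
    # straight up (large tilt), branch residues splay outward (small tilt)
    place_sugar(2, coords[(1, "N")], coords[(1, "CB")], False, tilt=4.0)
    order = [(3, 2, 4, 4.0), (4, 3, 4, 4.0),
             (5, 4, 6, 0.8), (8, 4, 3, 0.8),
             (6, 5, 6, 0.6), (7, 5, 3, 0.6),
             (9, 8, 2, 0.6)]
    for donor, acceptor, x, tilt in order:
        attach = coords[(acceptor, f"C{x}")]
        place_sugar(donor, attach, ring_centers[acceptor], True, tilt=tilt)

    return np.array([coords[ref] for ref in topology.atom_order])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# PDB structure I/O (via biotite)

_RESNAME = {"GlcNAc": "NAG", "Man": "MAN", "Asn": "ASN"}


def write_structure(path, topology: GlycanTopology, coordinates: np.ndarray) -> None:
    """Write coordinates (Å) as a PDB file in topology atom order."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coordinates, dtype=float)
    arr.res_id = np.array([r for r, _ in topology.atom_order])
    arr.atom_name = np.array([a for _, a in topology.atom_order])
    arr.res_name = np.array(
        [_RESNAME[topology.residues[r].kind] for r, _ in topology.atom_order]
    )
    arr.element = np.array([topology.atom_element(ref) for ref in topology.atom_order])
    arr.chain_id = np.array(["A"] * n)
    arr.hetero = np.array([topology.residues[r].kind != "Asn"
                           for r, _ in topology.atom_order])
    f = PDBFile()
    f.set_structure(arr)
    f.write(path)


def load_structure(pdb_source, topology: GlycanTopology):
    """Map PDB coordinates onto the topology's atom references.

    Atoms are matched by (residue id, atom name).  Returns
    ``(coordinates, unmapped)`` where ``coordinates`` is an
    (n_atoms, 3) array in Å in topology atom order and ``unmapped``
    lists PDB atoms that did not correspond to any topology atom.

    Raises ValueError naming every required atom missing from the PDB.
    """
    from biotite.structure.io.pdb import PDBFile

    f = PDBFile.read(pdb_source)
    arr = f.get_structure(model=1)
    available: dict[AtomRef, np.ndarray] = {}
    unmapped: list[str] = []
    wanted = set(topology.atom_order)
    for i in range(arr.array_length()):
        ref = (int(arr.res_id[i]), str(arr.atom_name[i]))
        if ref in wanted:
            available[ref] = arr.coord[i]
        else:
            unmapped.append(f"{arr.res_name[i]}{arr.res_id[i]}:{arr.atom_name[i]}")
    missing = [ref for ref in topology.atom_order if ref not in available]
    if missing:
        names = ", ".join(f"residue {r} atom {a}" for r, a in missing)
        raise ValueError(f"structure is missing required atoms: {names}")
    coords = np.array([available[ref] for ref in topology.atom_order])
    return coords, unmapped
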