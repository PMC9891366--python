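"""Functional-group motifs (SMARTS) and hydrogen-bond detection.

Motifs are molecular: a pattern matches atoms within one molecule, and the
intermolecular physics enters through the remnant descriptor and the
attributed energies, not through the match.  Matching runs on an RDKit
molecular graph perceived either from a supplied SMILES (preferred — bond
orders are taken verbatim) or, best-effort, from the covalent bond graph
plus valence rules.

Hydrogen bonds are detected geometrically on the periodic crystal: an
X-H...A contact counts when the H...A minimum-image distance is below
2.5 A and the X-H...A angle at hydrogen exceeds 150 degrees, with N and O
as default donors and acceptors and intermolecular contacts only by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .structures import AtomicStructure, BondGraph, neighbor_pairs

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MotifPattern",
    "MotifInstance",
    "HydrogenBond",
    "DEFAULT_MOTIFS",
    "perceive_molecular_graph",
    "match_motifs",
    "detect_hbonds",
    "hbond_counts_per_molecule",
]


@dataclass(frozen=True)
class MotifPattern:
    """A named SMARTS pattern; low-count classes are flagged in reports."""

    name: str
    smarts: str
    min_count_for_reporting: int = 200

    def __post_init__(self):
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ValueError(f"pattern {self.name!r}: unparsable SMARTS {self.smarts!r}")


@dataclass(frozen=True)
class MotifInstance:
    """One matched occurrence of a pattern within one molecule."""

    pattern: str
    structure_id: str
    molecule_id: str
    atom_indices: tuple[int, ...]  # molecule frame
    crystal_indices: tuple[int, ...] = ()  # crystal frame, when mapped


@dataclass(frozen=True)
class HydrogenBond:
    donor: int  # heavy donor atom X (crystal frame)
    hydrogen: int
    acceptor: int
    distance: float  # H...A, angstrom
    angle: float  # X-H...A at hydrogen, degrees
    classification: str
    image_shift: tuple[int, int, int] = (0, 0, 0)


# A reconstruction of the common organic-crystal functional-group classes
# (water, carboxyls, nitro, amines, amides, ethers, hydrocarbons, aromatic
# rings, azoles, imides); the exact published strings are unavailable, so
# this table is editable and shipped as data, not gospel.
DEFAULT_MOTIFS: tuple[MotifPattern, ...] = (
    MotifPattern("water", "[OX2H2]"),
    MotifPattern("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    MotifPattern("nitro", "[NX3](=[OX1])[OX1]"),
    MotifPattern("nitroso", "[NX2]=[OX1]"),
    MotifPattern("primary_amine", "[NX3;H2;!$(N=O);!$(NC=O)]"),
    MotifPattern("amide", "[CX3](=[OX1])[NX3]"),
    MotifPattern("ether", "[OD2]([#6])[#6]"),
    MotifPattern("methyl", "[CX4H3]"),
    MotifPattern("ethyl", "[CX4H3][CX4H2]"),
    MotifPattern("alkane_carbon", "[CX4;!$(C=[O,N])]"),
    MotifPattern("alkene", "[CX3]=[CX3]"),
    MotifPattern("ring6_unsaturated", "[#6]1~[#6]~[#6]~[#6]~[#6]~[#6]1"),
    MotifPattern("triazole", "c1nnc[nH]1"),
    MotifPattern("tetrazole", "c1nnn[nH]1"),
    MotifPattern("imide", "[CX3](=[OX1])[NX3][CX3]=[OX1]"),
)


def perceive_molecular_graph(
    m: AtomicStructure,
    bonds: BondGraph | None = None,
    smiles: str | None = None,
) -> Chem.Mol:
    """Build an RDKit molecule for a finite molecular structure.

    With ``smiles`` given, bond orders and aromaticity are transferred from
    the SMILES template onto the coordinate-derived connectivity (the
    preferred path).  Otherwise bond orders are inferred from connectivity
    and valence rules; on failure the single-bonded graph is kept with a
    warning so matching of connectivity-only patterns still works.
    """
    if m.periodic:
        raise ValueError(f"{m.id}: motif perception needs a finite molecule")
    if bonds is None:
        from .structures import build_bond_graph

        bonds = build_bond_graph(m)
    rw = Chem.RWMol()
    for el in m.species:
        rw.AddAtom(Chem.Atom(el))
    for a, b in bonds.edges:
        rw.AddBond(int(a), int(b), Chem.BondType.SINGLE)
    conf = Chem.Conformer(len(m))
    for i, (x, y, z) in enumerate(m.positions):
        conf.SetAtomPosition(i, (float(x), float(y), float(z)))
    rw.AddConformer(conf)
    mol = rw.GetMol()

    if smiles is not None:
        template = Chem.MolFromSmiles(smiles)
        if template is None:
            raise ValueError(f"{m.id}: unparsable SMILES {smiles!r}")
        try:
            mol = AllChem.AssignBondOrdersFromTemplate(
                Chem.AddHs(template), mol
            )
            Chem.SanitizeMol(mol)
            return mol
        except Exception as exc:
            warnings.warn(
                f"{m.id}: SMILES template did not map onto the bond graph "
                f"({exc}); falling back to valence perception"
            )

    try:
        from rdkit.Chem import rdDetermineBonds

        probe = Chem.Mol(mol)
        rdDetermineBonds.DetermineBondOrders(probe, charge=0)
        Chem.SanitizeMol(probe)
        return probe
    except Exception:
        pass
    try:
        for atom in mol.GetAtoms():
            atom.SetNoImplicit(True)
        Chem.SanitizeMol(
            mol,
            Chem.SanitizeFlags.SANITIZE_ALL
            ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
            ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
        )
    except Exception as exc:
        warnings.warn(f"{m.id}: valence inconsistencies ({exc}); best-effort graph")
    mol.SetProp("perception", "single-bond-fallback")
    return mol


def match_motifs(
    mol: Chem.Mol,
    patterns: Iterable[MotifPattern] = DEFAULT_MOTIFS,
    structure_id: str = "",
    molecule_id: str = "",
    index_map: Sequence[int] | None = None,
) -> list[MotifInstance]:
    """All unique substructure matches of each pattern on one molecule.

    Symmetry-equivalent matches covering the same atom set are collapsed.
    ``index_map`` translates molecule-frame atom indices to the crystal
    frame when provided.
    """
    out: list[MotifInstance] = []
    for pat in patterns:
        query = Chem.MolFromSmarts(pat.smarts)
        if query is None:
            raise ValueError(f"pattern {pat.name!r}: unparsable SMARTS")
        seen: set[frozenset] = set()
        for match in mol.GetSubstructMatches(query, uniquify=True):
            key = frozenset(match)
            if key in seen:
                continue
            seen.add(key)
            atoms = tuple(sorted(match))
            crystal = (
                tuple(int(index_map[i]) for i in atoms) if index_map is not None else ()
            )
            out.append(
                MotifInstance(
                    pattern=pat.name,
                    structure_id=structure_id,
                    molecule_id=molecule_id,
                    atom_indices=atoms,
                    crystal_indices=crystal,
                )
            )
    return out


def _classify(donor_el: str, acceptor_el: str) -> str:
    if donor_el == "O" and acceptor_el == "O":
        return "OH...O"
    if donor_el == "O" and acceptor_el == "N":
        return "OH...N"
    if acceptor_el == "O" and donor_el == "O":
        return "O...H-O"
    if acceptor_el == "O" and donor_el == "N":
        return "O...H-N"
    return "other"


def detect_hbonds(
    crystal: AtomicStructure,
    bonds: BondGraph,
    molecule_of: Sequence[int] | None = None,
    donors: frozenset[str] = frozenset({"N", "O"}),
    acceptors: frozenset[str] = frozenset({"N", "O"}),
    max_distance: float = 2.5,
    min_angle: float = 150.0,
    intermolecular_only: bool = True,
) -> list[HydrogenBond]:
    """Geometric hydrogen bonds X-H...A in a (possibly periodic) structure.

    A bond is counted when the minimum-image H...A distance is below
    ``max_distance`` and the X-H...A angle at the hydrogen exceeds
    ``min_angle``.  Contacts through a nonzero lattice image are always
    intermolecular.  ``molecule_of`` (atom -> molecule id) enables the
    intermolecular filter for same-cell contacts.
    """
    if bonds is None:
        raise ValueError("bond graph required to identify covalent X-H pairs")
    cell = crystal.cell if crystal.cell is not None else np.eye(3)
    # covalent donor of each hydrogen
    donor_of: dict[int, tuple[int, np.ndarray]] = {}
    for (a, b), shift in zip(bonds.edges, bonds.image_shifts):
        for h, x, sh in ((a, b, np.array(shift)), (b, a, -np.array(shift))):
            if crystal.species[h] != "H":
                continue
            if crystal.species[x] in donors:
                x_pos = crystal.positions[x] + sh @ cell
                donor_of[h] = (x, x_pos)
    if not donor_of:
        return []

    found: list[HydrogenBond] = []
    ii, jj, dd, ss = neighbor_pairs(crystal, max_distance)
    for a, b, d, sh in zip(ii, jj, dd, ss):
        # each row gives two directed candidates: H=a,A=b(+sh) and H=b,A=a(-sh)
        for h, acc, shift in ((a, b, sh), (b, a, -sh)):
            if h not in donor_of or crystal.species[acc] not in acceptors:
                continue
            x, x_pos = donor_of[h]
            if acc == x and np.all(shift == 0):
                continue  # the covalent donor itself
            if intermolecular_only and molecule_of is not None:
                if np.all(shift == 0) and molecule_of[h] == molecule_of[acc]:
                    continue
            h_pos = crystal.positions[h]
            a_pos = crystal.positions[acc] + shift @ cell
            if d > max_distance:
                continue
            v1 = x_pos - h_pos
            v2 = a_pos - h_pos
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= min_angle:
                continue
            found.append(
                HydrogenBond(
                    donor=int(x), hydrogen=int(h), acceptor=int(acc),
                    distance=float(d), angle=angle,
                    classification=_classify(
                        crystal.species[x], crystal.species[acc]
                    ),
                    image_shift=tuple(int(t) for t in shift),
                )
            )
    # deduplicate (same H, acceptor, shift can appear once per direction scan)
    uniq = {}
    for hb in found:
        uniq[(hb.hydrogen, hb.acceptor, hb.image_shift)] = hb
    return sorted(
        uniq.values(), key=lambda hb: (hb.hydrogen, hb.acceptor, hb.image_shift)
    )


def hbond_counts_per_molecule(
    hbonds: Sequence[HydrogenBond],
    molecule_of: Sequence[int],
    n_molecules: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Donated and accepted hydrogen-bond counts per molecule."""
    donated = np.zeros(n_molecules, dtype=int)
    accepted = np.zeros(n_molecules, dtype=int)
    for hb in hbonds:
        donated[molecule_of[hb.hydrogen]] += 1
        accepted[molecule_of[hb.acceptor]] += 1
    return donated, accepted
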