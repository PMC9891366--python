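"""Crystal and molecular geometry containers and I/O.

Reads extended-XYZ and CIF files into :class:`AtomicStructure`, perceives
covalent bonds with a minimum-image criterion, extracts whole molecules from
periodic cells (unwrapping them across boundaries), and pairs each crystal
with the relaxed gas-phase geometries of its constituent molecules in a
:class:`CrystalRecord`.

All coordinates are Cartesian angstroms; fractional coordinates appear only
transiently at CIF ingestion.  Atom indexing is 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomicStructure",
    "BondGraph",
    "CrystalRecord",
    "COVALENT_RADII",
    "read_structures",
    "write_extxyz",
    "build_bond_graph",
    "neighbor_pairs",
    "extract_molecules",
    "assemble_crystal_record",
    "read_energy_table",
]


class StructureError(ValueError):
    """Raised for malformed files or inconsistent structures."""


class PolymericError(StructureError):
    """Raised when a periodic component is covalently bonded to its own image."""


# Cordero et al. covalent radii (angstrom); extensible beyond the C,H,N,O,S
# core of organic molecular crystals.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Br": 1.20, "I": 1.39,
}

_DEFAULT_SPECIES = ("C", "H", "N", "O", "S")


@dataclass
class AtomicStructure:
    """A periodic or finite collection of atoms.

    Parameters
    ----------
    id : str
        Free-form identifier.
    species : sequence of str
        Element symbol per atom.
    positions : (n, 3) array
        Cartesian coordinates in angstrom.
    cell : (3, 3) array, optional
        Lattice vectors as rows, in angstrom.  Required when any ``pbc``
        flag is set.
    pbc : tuple of three bool
        Periodic boundary flags.
    tags : dict
        Free-form metadata (per-frame energies, provenance, SMILES ...).
    """

    id: str
    species: tuple[str, ...]
    positions: np.ndarray
    cell: np.ndarray | None = None
    pbc: tuple[bool, bool, bool] = (False, False, False)
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.species = tuple(str(s) for s in self.species)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.species) != len(self.positions):
            raise StructureError(
                f"{self.id}: {len(self.species)} species vs "
                f"{len(self.positions)} positions"
            )
        if not np.all(np.isfinite(self.positions)):
            raise StructureError(f"{self.id}: non-finite coordinates")
        self.pbc = tuple(bool(p) for p in self.pbc)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float).reshape(3, 3)
        if any(self.pbc):
            if self.cell is None:
                raise StructureError(f"{self.id}: pbc set but no cell")
            if abs(np.linalg.det(self.cell)) <= 1e-6:
                raise StructureError(f"{self.id}: singular cell")
        for s in self.species:
            if s not in COVALENT_RADII:
                raise StructureError(f"{self.id}: unknown element symbol {s!r}")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def periodic(self) -> bool:
        return any(self.pbc)

    def composition(self) -> dict[str, int]:
        comp: dict[str, int] = {}
        for s in self.species:
            comp[s] = comp.get(s, 0) + 1
        return comp

    def composition_key(self) -> str:
        return "".join(f"{el}{n}" for el, n in sorted(self.composition().items()))


@dataclass
class BondGraph:
    """Symmetric covalent-bond graph with minimum-image shift bookkeeping."""

    n_atoms: int
    edges: list[tuple[int, int]]
    distances: list[float]
    image_shifts: list[tuple[int, int, int]]

    def neighbors(self, i: int) -> list[tuple[int, tuple[int, int, int], float]]:
        """Neighbors of atom ``i`` as (j, shift applied to j, distance)."""
        out = []
        for (a, b), d, s in zip(self.edges, self.distances, self.image_shifts):
            if a == i:
                out.append((b, s, d))
            elif b == i:
                out.append((a, tuple(-np.array(s)), d))
        return out


@dataclass
class CrystalRecord:
    """A crystal paired with the gas-phase geometries of its molecules.

    ``molecules`` holds ``(gas_structure, index_map)`` pairs where
    ``index_map[k]`` is the crystal-frame index of the gas molecule's
    ``k``-th atom.  Index maps partition the crystal's atoms exactly.
    Energies are total energies in kJ/mol.
    """

    crystal: AtomicStructure
    molecules: list[tuple[AtomicStructure, np.ndarray]]
    E_crystal: float
    E_molecules: list[float]

    def __post_init__(self) -> None:
        n_c = len(self.crystal)
        seen = np.zeros(n_c, dtype=bool)
        for gas, imap in self.molecules:
            imap = np.asarray(imap, dtype=int)
            if len(imap) != len(gas):
                raise StructureError("index map length != gas molecule size")
            if seen[imap].any():
                raise StructureError("index maps overlap")
            seen[imap] = True
            for k, ci in enumerate(imap):
                if gas.species[k] != self.crystal.species[ci]:
                    raise StructureError(
                        f"species mismatch at crystal atom {ci}: "
                        f"{gas.species[k]} vs {self.crystal.species[ci]}"
                    )
        if not seen.all():
            raise StructureError("index maps do not cover all crystal atoms")
        if len(self.E_molecules) != len(self.molecules):
            raise StructureError("one energy per molecule required")

    @property
    def n_atoms(self) -> int:
        return len(self.crystal)

    @property
    def lattice_energy(self) -> float:
        """Total lattice energy Delta_c = E_c - sum_m E_m (kJ/mol)."""
        return self.E_crystal - float(np.sum(self.E_molecules))

    @property
    def lattice_energy_per_atom(self) -> float:
        """delta_c = Delta_c / n_c (kJ per mol of atoms)."""
        return self.lattice_energy / self.n_atoms


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=("[^"]*"|\S+)')


def _parse_comment(comment: str) -> dict:
    out = {}
    for key, val in _KV_RE.findall(comment):
        out[key] = val.strip('"')
    return out


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    toks = spec.split(":")
    if len(toks) % 3:
        raise StructureError(f"bad Properties spec: {spec!r}")
    return [(toks[i], toks[i + 1], int(toks[i + 2])) for i in range(0, len(toks), 3)]


def _read_extxyz(text: str, path: str) -> list[AtomicStructure]:
    lines = text.splitlines()
    frames: list[AtomicStructure] = []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise StructureError(
                f"{path}: line {i + 1}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 2 + nat > len(lines):
            raise StructureError(f"{path}: truncated frame at line {i + 1}")
        meta = _parse_comment(lines[i + 1])
        cell = None
        pbc = (False, False, False)
        if "Lattice" in meta:
            vals = np.fromstring(meta.pop("Lattice"), sep=" ")
            if vals.size != 9:
                raise StructureError(f"{path}: line {i + 2}: bad Lattice")
            cell = vals.reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in meta:
            pbc = tuple(t in ("T", "True", "1") for t in meta.pop("pbc").split())
        props = _parse_properties(meta.pop("Properties", "species:S:1:pos:R:3"))
        cols = {}
        off = 0
        for name, _kind, ncol in props:
            cols[name] = (off, ncol)
            off += ncol
        if "species" not in cols or "pos" not in cols:
            raise StructureError(f"{path}: Properties lacks species/pos")
        species, positions = [], []
        for k in range(nat):
            toks = lines[i + 2 + k].split()
            if len(toks) < off:
                raise StructureError(f"{path}: line {i + 3 + k}: too few columns")
            s_off = cols["species"][0]
            p_off = cols["pos"][0]
            species.append(toks[s_off])
            positions.append([float(x) for x in toks[p_off:p_off + 3]])
        sid = meta.pop("id", f"{path}:{frame_no}")
        frames.append(
            AtomicStructure(
                id=sid, species=species, positions=np.array(positions),
                cell=cell, pbc=pbc, tags=meta,
            )
        )
        i += 2 + nat
        frame_no += 1
    return frames


def write_extxyz(path: str, structures: Iterable[AtomicStructure]) -> None:
    """Write structures as extended XYZ (Cartesian angstrom, 0-based ids)."""
    with open(path, "w") as fh:
        for s in structures:
            fh.write(f"{len(s)}\n")
            fields = [f'id={s.id}', 'Properties=species:S:1:pos:R:3']
            if s.cell is not None:
                flat = " ".join(f"{x:.10f}" for x in s.cell.ravel())
                fields.append(f'Lattice="{flat}"')
            fields.append('pbc="%s"' % " ".join("T" if p else "F" for p in s.pbc))
            for k, v in s.tags.items():
                v = str(v)
                fields.append(f'{k}="{v}"' if " " in v else f"{k}={v}")
            fh.write(" ".join(fields) + "\n")
            for el, (x, y, z) in zip(s.species, s.positions):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# CIF (through gemmi; symmetry operations expanded to P1)
# ---------------------------------------------------------------------------

def _read_cif(path: str) -> list[AtomicStructure]:
    import gemmi

    try:
        doc = gemmi.cif.read(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise StructureError(f"{path}: CIF parse error: {exc}") from exc
    out = []
    for block in doc:
        small = gemmi.make_small_structure_from_block(block)
        if not small.sites:
            continue
        cell = small.cell
        lat = np.array(cell.orth.mat.tolist(), dtype=float).T  # rows = vectors
        species, positions = [], []
        for site in small.get_all_unit_cell_sites():
            el = site.element.name
            frac = np.array([site.fract.x, site.fract.y, site.fract.z]) % 1.0
            species.append(el)
            positions.append(frac @ lat)
        out.append(
            AtomicStructure(
                id=block.name or str(path),
                species=species,
                positions=np.array(positions),
                cell=lat,
                pbc=(True, True, True),
                tags={"source": str(path)},
            )
        )
    if not out:
        raise StructureError(f"{path}: no atom sites found in CIF")
    return out


def read_structures(path: str, format: str | None = None) -> list[AtomicStructure]:
    """Read one or more structures from an extended-XYZ or CIF file.

    ``format`` is ``"extxyz"`` or ``"cif"``; inferred from the file suffix
    when omitted.  Per-frame key=value metadata (energies etc.) lands in
    ``tags``.
    """
    path = str(path)
    if format is None:
        format = "cif" if path.lower().endswith(".cif") else "extxyz"
    if format == "cif":
        return _read_cif(path)
    if format == "extxyz":
        with open(path) as fh:
            return _read_extxyz(fh.read(), path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# neighbor search and bond perception
# ---------------------------------------------------------------------------

def _image_ranges(cell: np.ndarray, cutoff: float) -> list[range]:
    """Lattice-image search ranges so every vector within ``cutoff`` is found."""
    vol = abs(np.linalg.det(cell))
    ranges = []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        width = vol / np.linalg.norm(np.cross(cell[j], cell[k]))
        n = int(np.ceil(cutoff / width))
        ranges.append(range(-n, n + 1))
    return ranges


def neighbor_pairs(
    s: AtomicStructure, cutoff: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All pairs (i, j) with distance <= cutoff, searching periodic images.

    Returns arrays ``(i, j, d, shift)`` with one row per ordered pair
    i < j for the (0,0,0) image, and one row per (i, j, shift) for nonzero
    image shifts (including i == j bonded to its own image, reported once
    per +shift).  ``shift`` applies to atom j: r_j' = r_j + shift @ cell.
    """
    pos = s.positions
    n = len(s)
    ii, jj, dd, ss = [], [], [], []
    if s.periodic:
        shifts = [
            (a, b, c)
            for a in _image_ranges(s.cell, cutoff)[0]
            for b in _image_ranges(s.cell, cutoff)[1]
            for c in _image_ranges(s.cell, cutoff)[2]
        ]
    else:
        shifts = [(0, 0, 0)]
    for shift in shifts:
        disp = np.array(shift, dtype=float) @ s.cell if s.periodic else np.zeros(3)
        delta = pos[None, :, :] + disp - pos[:, None, :]
        dist = np.linalg.norm(delta, axis=-1)
        if shift == (0, 0, 0):
            a, b = np.where((dist <= cutoff) & (np.arange(n)[:, None] < np.arange(n)))
        elif shift > (0, 0, 0):
            a, b = np.where(dist <= cutoff)
        else:
            continue  # mirror of a positive shift
        ii.append(a)
        jj.append(b)
        dd.append(dist[a, b])
        ss.append(np.tile(shift, (len(a), 1)))
    if not ii:
        z = np.zeros(0, dtype=int)
        return z, z, np.zeros(0), np.zeros((0, 3), dtype=int)
    return (
        np.concatenate(ii),
        np.concatenate(jj),
        np.concatenate(dd),
        np.concatenate(ss).astype(int),
    )


def build_bond_graph(s: AtomicStructure, scale: float = 1.2) -> BondGraph:
    """Perceive covalent bonds: edge iff minimum-image distance is at most
    ``scale`` times the sum of covalent radii."""
    radii = np.array([COVALENT_RADII[el] for el in s.species])
    max_bond = scale * 2.0 * radii.max()
    i, j, d, sh = neighbor_pairs(s, max_bond)
    cut = scale * (radii[i] + radii[j])
    keep = (d <= cut) & (d > 1e-8)
    # an atom exactly on top of another is a structure defect, not a bond
    if np.any((d <= 1e-8) & ((i != j) | np.any(sh != 0, axis=1))):
        raise StructureError(f"{s.id}: coincident atoms")
    return BondGraph(
        n_atoms=len(s),
        edges=[(int(a), int(b)) for a, b in zip(i[keep], j[keep])],
        distances=[float(x) for x in d[keep]],
        image_shifts=[tuple(int(x) for x in row) for row in sh[keep]],
    )


def extract_molecules(
    s: AtomicStructure, g: BondGraph
) -> list[tuple[AtomicStructure, np.ndarray]]:
    """Split a structure into whole molecules (connected bond-graph components).

    Periodic components are unwrapped: each atom is translated by the
    accumulated image shift along its bond path so every bond is at its
    direct distance.  A component bonded to its own periodic image (a cycle
    with nonzero net shift) is not molecular and raises
    :class:`PolymericError`.
    """
    adjacency: list[list[tuple[int, tuple[int, int, int]]]] = [[] for _ in range(len(s))]
    for (a, b), shift in zip(g.edges, g.image_shifts):
        adjacency[a].append((b, shift))
        adjacency[b].append((a, tuple(-x for x in shift)))

    cell = s.cell if s.cell is not None else np.eye(3)
    visited = np.full(len(s), -1, dtype=int)
    molecules = []
    for start in range(len(s)):
        if visited[start] >= 0:
            continue
        comp_id = len(molecules)
        shifts: dict[int, np.ndarray] = {start: np.zeros(3, dtype=int)}
        order = [start]
        visited[start] = comp_id
        queue = [start]
        while queue:
            a = queue.pop()
            for b, shift in adjacency[a]:
                total = shifts[a] + np.array(shift, dtype=int)
                if visited[b] < 0:
                    visited[b] = comp_id
                    shifts[b] = total
                    order.append(b)
                    queue.append(b)
                elif not np.array_equal(shifts[b], total):
                    raise PolymericError(
                        f"{s.id}: component containing atom {b} is bonded to "
                        "its own periodic image (polymeric); not a molecular "
                        "crystal"
                    )
        imap = np.array(sorted(order), dtype=int)
        pos = s.positions[imap] + np.array([shifts[k] for k in imap]) @ cell
        mol = AtomicStructure(
            id=f"{s.id}/mol{comp_id}",
            species=[s.species[k] for k in imap],
            positions=pos,
            tags={"parent": s.id},
        )
        molecules.append((mol, imap))
    return molecules


# ---------------------------------------------------------------------------
# crystal record assembly
# ---------------------------------------------------------------------------

def _element_centroid_order(mol: AtomicStructure) -> np.ndarray:
    """Deterministic per-element atom order by distance from the centroid."""
    center = mol.positions.mean(axis=0)
    d = np.linalg.norm(mol.positions - center, axis=1)
    keys = list(zip(mol.species, np.round(d, 6), range(len(mol))))
    return np.array([k[2] for k in sorted(keys)], dtype=int)


def _superposition_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial.transform import Rotation

    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    if len(a) == 1:
        return 0.0
    if len(a) == 2:
        # rotation is degenerate for a pair; optimal superposition aligns
        # the two bond axes, leaving only the length difference
        return 0.5 * abs(
            np.linalg.norm(a[1] - a[0]) - np.linalg.norm(b[1] - b[0])
        )
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def assemble_crystal_record(
    crystal: AtomicStructure,
    gas_molecules: Sequence[AtomicStructure],
    E_crystal: float,
    E_molecules: Sequence[float],
    bond_scale: float = 1.2,
) -> CrystalRecord:
    """Pair a crystal with its gas-phase molecules and total energies.

    Molecules are matched to extracted components first by composition, then
    (for several candidates of one composition) by lowest RMSD after optimal
    superposition, ties broken by input order.  Raises on any composition
    mismatch — this also guards the exact cancellation of composition
    baselines between the crystal and its molecules.
    """
    graph = build_bond_graph(crystal, scale=bond_scale)
    components = extract_molecules(crystal, graph)
    if len(components) != len(gas_molecules):
        raise StructureError(
            f"{crystal.id}: {len(components)} molecular components but "
            f"{len(gas_molecules)} gas molecules supplied"
        )

    by_comp: dict[str, list[int]] = {}
    for idx, (mol, _) in enumerate(components):
        by_comp.setdefault(mol.composition_key(), []).append(idx)

    pairs: list[tuple[AtomicStructure, np.ndarray]] = [None] * len(components)
    energies: list[float] = [None] * len(components)
    for gi, gas in enumerate(gas_molecules):
        key = gas.composition_key()
        candidates = by_comp.get(key, [])
        if not candidates:
            raise StructureError(
                f"{crystal.id}: no unassigned component matches gas molecule "
                f"{gas.id} ({key})"
            )
        g_order = _element_centroid_order(gas)
        best_ci, best_rmsd = None, np.inf
        for ci in candidates:
            mol, _ = components[ci]
            c_order = _element_centroid_order(mol)
            rmsd = _superposition_rmsd(
                mol.positions[c_order], gas.positions[g_order]
            )
            if rmsd < best_rmsd - 1e-12:
                best_ci, best_rmsd = ci, rmsd
        candidates.remove(best_ci)
        mol, imap = components[best_ci]
        c_order = _element_centroid_order(mol)
        # gas atom k corresponds to component atom c_order[pos of k in g_order]
        inv_g = np.empty(len(g_order), dtype=int)
        inv_g[g_order] = np.arange(len(g_order))
        gas_to_crystal = imap[c_order[inv_g]]
        pairs[best_ci] = (gas, gas_to_crystal)
        energies[best_ci] = float(E_molecules[gi])
    return CrystalRecord(
        crystal=crystal,
        molecules=[p for p in pairs if p is not None],
        E_crystal=float(E_crystal),
        E_molecules=[e for e in energies if e is not None],
    )


def read_energy_table(path: str):
    """Read the energy CSV (columns: id, kind, parent_id, E_kJ_per_mol)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "kind", "parent_id", "E_kJ_per_mol"}
    missing = required - set(df.columns)
    if missing:
        raise StructureError(f"{path}: energy table missing columns {sorted(missing)}")
    bad = set(df["kind"]) - {"crystal", "molecule"}
    if bad:
        raise StructureError(f"{path}: unknown kind values {sorted(bad)}")
    return df
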