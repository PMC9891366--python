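"""Synthetic molecular-crystal datasets with planted atom-centered energies.

Every downstream operation — featurization, remnant construction, model
fitting, attribution, motif matching, mapping — is testable end-to-end on
these toy datasets without any external data.  Each crystal packs a few
rigid small-molecule templates (optionally with a per-instance
conformational perturbation shared between the gas and in-crystal copies)
into a periodic box by rejection sampling, and its energies are planted:

    E_a = c_element + x_a . w*          (per atom, per phase)

with x_a the atom's true local descriptor at a fixed configuration and w*
a random planted weight vector.  Crystal and molecule totals are sums of
per-atom terms, so the planted lattice energy equals the sum of planted
per-atom remnant contributions exactly, the composition term cancels by
construction, and a remnant-space linear model can recover the planted
lattice energies to numerical precision at zero noise.  Gaussian noise
(``noise_sigma``, kJ per mol of atoms) is added last, to the crystal total
only, so the lattice-energy target carries per-atom noise of exactly that
standard deviation.

This emulates the statistical structure of a DFT lattice-energy study —
composition-dominated total-energy variance, much smaller lattice-energy
variance — not its physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import (
    AtomicStructure,
    CrystalRecord,
    neighbor_pairs,
)
from .descriptors import (
    DescriptorConfig,
    DescriptorSet,
    compute_descriptors,
    remnant_descriptor,
)

__all__ = [
    "MoleculeTemplate",
    "SyntheticSpec",
    "SyntheticDataset",
    "DEFAULT_TEMPLATES",
    "generate",
    "make_worked_micro_examples",
]


@dataclass(frozen=True)
class MoleculeTemplate:
    name: str
    species: tuple[str, ...]
    positions: tuple[tuple[float, float, float], ...]
    smiles: str | None = None
    labels: tuple[str, ...] = ()  # functional-group labels for bookkeeping

    def structure(self, sid: str) -> AtomicStructure:
        tags = {"template": self.name}
        if self.smiles:
            tags["smiles"] = self.smiles
        return AtomicStructure(
            id=sid, species=self.species, positions=np.array(self.positions),
            tags=tags,
        )


# Idealized rigid geometries (angstrom); chemically plausible, not relaxed.
DEFAULT_TEMPLATES: tuple[MoleculeTemplate, ...] = (
    MoleculeTemplate(
        "water", ("O", "H", "H"),
        ((0.0, 0.0, 0.0), (0.9572, 0.0, 0.0), (-0.2399, 0.9266, 0.0)),
        smiles="O", labels=("water",),
    ),
    MoleculeTemplate(
        "carbonyl_diatomic", ("C", "O"),
        ((0.0, 0.0, 0.0), (1.128, 0.0, 0.0)),
        smiles=None, labels=("donor_acceptor",),
    ),
    MoleculeTemplate(
        "formaldehyde", ("C", "O", "H", "H"),
        ((0.0, 0.0, 0.0), (1.21, 0.0, 0.0),
         (-0.55, 0.94, 0.0), (-0.55, -0.94, 0.0)),
        smiles="C=O", labels=("carbonyl",),
    ),
    MoleculeTemplate(
        "methanol", ("C", "O", "H", "H", "H", "H"),
        ((0.0, 0.0, 0.0), (1.43, 0.0, 0.0), (1.76, 0.87, 0.0),
         (-0.39, 0.51, 0.89), (-0.39, 0.51, -0.89), (-0.39, -1.02, 0.0)),
        smiles="CO", labels=("ether_like", "methyl"),
    ),
    MoleculeTemplate(
        "formic_acid", ("C", "O", "O", "H", "H"),
        ((0.0, 0.0, 0.0), (1.20, 0.22, 0.0), (-0.74, 1.07, 0.0),
         (-0.42, 1.89, 0.0), (-0.54, -0.96, 0.0)),
        smiles="OC=O", labels=("carboxylic_acid",),
    ),
    MoleculeTemplate(
        "methylamine", ("C", "N", "H", "H", "H", "H", "H"),
        ((0.0, 0.0, 0.0), (1.47, 0.0, 0.0), (1.85, -0.52, 0.79),
         (1.85, -0.42, -0.85), (-0.38, 0.52, 0.89), (-0.38, 0.52, -0.89),
         (-0.38, -1.03, 0.0)),
        smiles="CN", labels=("primary_amine", "methyl"),
    ),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    noise_sigma is the per-atom lattice-energy noise (kJ per mol of atoms);
    element_energies set the composition-dominated total-energy baseline;
    planted_weight_scale sets the spread of the planted descriptor-linear
    contributions; conformer_sigma perturbs each molecule instance's
    geometry (shared by the gas and crystal copies) so gas-phase
    descriptors vary across the dataset.
    """

    seed: int = 0
    n_crystals: int = 50
    templates: tuple[MoleculeTemplate, ...] = DEFAULT_TEMPLATES
    molecules_per_crystal: tuple[int, int] = (2, 3)
    cell_size_range: tuple[float, float] = (6.5, 8.5)
    min_contact: float = 1.9  # minimum intermolecular distance, angstrom
    max_placement_tries: int = 400
    noise_sigma: float = 0.0
    conformer_sigma: float = 0.04
    element_energies: dict = field(
        default_factory=lambda: {
            "H": -6.0, "C": -21.0, "N": -27.0, "O": -33.0, "S": -16.0,
        }
    )
    planted_weight_scale: float = 10.0
    descriptor_config: DescriptorConfig = DescriptorConfig(
        r_cut=4.0, n_max=3, l_max=2, sigma_atom=0.4,
        species_list=("C", "H", "N", "O"), normalize=True, n_quad=40,
    )
    gas_equals_crystal_geometry: bool = True
    pair_well_depth: float = 0.0  # optional non-linear "hard mode" term


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    records: list[CrystalRecord]
    planted_w: np.ndarray
    planted_delta_a: list[np.ndarray]  # per-crystal per-atom ground truth
    noise: np.ndarray  # per-crystal per-atom noise actually applied to E_c
    ds_solid: list[DescriptorSet]
    ds_gas: list[list[DescriptorSet]]
    ds_remnant: list[DescriptorSet]

    @property
    def planted_delta_c(self) -> np.ndarray:
        """Noise-free per-atom planted lattice energies."""
        return np.array([d.mean() for d in self.planted_delta_a])


def _min_intermolecular_distance(
    cell: np.ndarray, placed: list[np.ndarray], candidate: np.ndarray
) -> float:
    probe = AtomicStructure(
        id="probe",
        species=["C"] * (sum(len(p) for p in placed) + len(candidate)),
        positions=np.vstack(placed + [candidate]),
        cell=cell, pbc=(True, True, True),
    )
    i, j, d, sh = neighbor_pairs(probe, 3.5)
    offsets = np.cumsum([0] + [len(p) for p in placed])
    mol_of = np.concatenate(
        [np.full(len(p), k) for k, p in enumerate(placed + [candidate])]
    )
    inter = (mol_of[i] != mol_of[j]) | np.any(sh != 0, axis=1)
    return float(d[inter].min()) if inter.any() else np.inf


def _pack_molecules(
    rng: np.random.Generator, spec: SyntheticSpec,
    geometries: list[np.ndarray], cell: np.ndarray,
) -> list[np.ndarray] | None:
    """Rigid rejection-sampling placement; None if packing fails."""
    placed: list[np.ndarray] = []
    side = cell[0, 0]
    for geom in geometries:
        centered = geom - geom.mean(axis=0)
        ok = False
        for _ in range(spec.max_placement_tries):
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.uniform(0.0, side, size=3)
            cand = centered @ R.T + t
            if not placed:
                ok = True
            else:
                dmin = _min_intermolecular_distance(cell, placed, cand)
                ok = dmin >= spec.min_contact
            if ok:
                placed.append(cand)
                break
        if not ok:
            return None
    return placed


def _pairwise_well(crystal: AtomicStructure, mol_of: np.ndarray, depth: float) -> float:
    """Optional Lennard-Jones-like intermolecular term (model misspecification)."""
    if depth == 0.0:
        return 0.0
    i, j, d, sh = neighbor_pairs(crystal, 6.0)
    inter = (mol_of[i] != mol_of[j]) | np.any(sh != 0, axis=1)
    r = d[inter]
    s = 3.0  # angstrom
    return float(depth * np.sum((s / r) ** 12 - (s / r) ** 6))


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate a seeded synthetic dataset of toy molecular crystals.

    All randomness flows from ``spec.seed``; the same spec yields a
    byte-identical dataset.  Raises if a crystal cannot be packed within
    ``max_placement_tries``.
    """
    rng = np.random.default_rng(spec.seed)
    cfg = spec.descriptor_config
    w_star = rng.normal(0.0, spec.planted_weight_scale, size=cfg.n_features)

    records: list[CrystalRecord] = []
    ds_solid, ds_gas, ds_remnant = [], [], []
    planted_delta_a, noises = [], []
    for ci in range(spec.n_crystals):
        n_mol = int(rng.integers(spec.molecules_per_crystal[0],
                                 spec.molecules_per_crystal[1] + 1))
        side = float(rng.uniform(*spec.cell_size_range))
        cell = np.eye(3) * side
        tmpl_idx = rng.integers(0, len(spec.templates), size=n_mol)
        geoms, gas_structures = [], []
        for mi, ti in enumerate(tmpl_idx):
            tmpl = spec.templates[ti]
            geom = np.array(tmpl.positions)
            if spec.conformer_sigma > 0:
                geom = geom + rng.normal(0.0, spec.conformer_sigma, geom.shape)
            geoms.append(geom)
            gas = tmpl.structure(f"synth{ci}/gas{mi}")
            gas = AtomicStructure(
                id=gas.id, species=gas.species, positions=geom, tags=gas.tags
            )
            gas_structures.append(gas)
        placed = _pack_molecules(rng, spec, geoms, cell)
        if placed is None:
            raise RuntimeError(
                f"crystal {ci}: packing failed after "
                f"{spec.max_placement_tries} tries (cell {side:.2f} A, "
                f"{n_mol} molecules); enlarge the cell or reduce min_contact"
            )
        species = [s for g in gas_structures for s in g.species]
        positions = np.vstack(placed)
        crystal = AtomicStructure(
            id=f"synth{ci}", species=species, positions=positions,
            cell=cell, pbc=(True, True, True),
        )
        if not spec.gas_equals_crystal_geometry:
            gas_structures = [
                spec.templates[ti].structure(f"synth{ci}/gas{mi}")
                for mi, ti in enumerate(tmpl_idx)
            ]

        # plant energies
        dset_s = compute_descriptors(crystal, cfg)
        dset_g = [compute_descriptors(g, cfg) for g in gas_structures]
        comp_term = lambda struct: sum(
            spec.element_energies[el] for el in struct.species
        )
        E_mols = [
            comp_term(g) + float(np.sum(dg.X @ w_star))
            for g, dg in zip(gas_structures, dset_g)
        ]
        mol_of = np.concatenate(
            [np.full(len(g), k) for k, g in enumerate(gas_structures)]
        )
        E_c = (
            comp_term(crystal)
            + float(np.sum(dset_s.X @ w_star))
            + _pairwise_well(crystal, mol_of, spec.pair_well_depth)
        )
        eta = float(rng.normal(0.0, spec.noise_sigma)) if spec.noise_sigma > 0 else 0.0
        E_c += len(crystal) * eta

        # crystal atoms are the gas molecules' atoms in order, so the index
        # maps are consecutive blocks (exact by construction)
        offsets = np.cumsum([0] + [len(g) for g in gas_structures])
        rec = CrystalRecord(
            crystal=crystal,
            molecules=[
                (g, np.arange(offsets[k], offsets[k + 1]))
                for k, g in enumerate(gas_structures)
            ],
            E_crystal=E_c,
            E_molecules=E_mols,
        )
        records.append(rec)
        aligned_gas = list(dset_g)
        rem, _ = remnant_descriptor(rec, dset_s, aligned_gas)
        ds_solid.append(dset_s)
        ds_gas.append(aligned_gas)
        ds_remnant.append(rem)
        planted_delta_a.append(rem.X @ w_star)
        noises.append(eta)
    return SyntheticDataset(
        spec=spec, records=records, planted_w=w_star,
        planted_delta_a=planted_delta_a, noise=np.array(noises),
        ds_solid=ds_solid, ds_gas=ds_gas, ds_remnant=ds_remnant,
    )


# ---------------------------------------------------------------------------
# deterministic micro-fixtures for unit tests and worked examples
# ---------------------------------------------------------------------------

def _embedded_molecule(name: str, smiles: str) -> AtomicStructure:
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    conf = mol.GetConformer()
    return AtomicStructure(
        id=name,
        species=[a.GetSymbol() for a in mol.GetAtoms()],
        positions=np.array(
            [list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())]
        ),
        tags={"smiles": smiles},
    )


def make_worked_micro_examples() -> dict[str, AtomicStructure]:
    """Small deterministic fixtures used throughout the test suite.

    Includes the two-atom filter case, linear hydrogen-bond geometries at
    the acceptance thresholds, a periodic two-water cell, a polymeric
    chain, and embedded succinic-acid / phenanthrene molecules.
    """
    water = DEFAULT_TEMPLATES[0]
    w1 = np.array(water.positions)
    # donor water aimed so O-H...O is exactly linear at a chosen H...O gap
    def hbond_pair(gap: float, angle_deg: float) -> AtomicStructure:
        donor = w1.copy()
        oh = donor[1] - donor[0]
        oh_dir = oh / np.linalg.norm(oh)
        theta = np.radians(180.0 - angle_deg)
        # place acceptor O so the X-H...A angle at H equals angle_deg
        perp = np.array([-oh_dir[1], oh_dir[0], 0.0])
        a_dir = np.cos(theta) * oh_dir + np.sin(theta) * perp
        acc_o = donor[1] + gap * a_dir
        acc = w1 - w1[0] + acc_o
        # rotate acceptor hydrogens away from the contact axis
        return AtomicStructure(
            id=f"hbond_{gap:.1f}_{angle_deg:.0f}",
            species=list(water.species) * 2,
            positions=np.vstack([donor, acc]),
        )

    two_waters_cell = AtomicStructure(
        id="two_waters_cell",
        species=list(water.species) * 2,
        positions=np.vstack([w1, w1 + np.array([4.0, 0.0, 0.0])]),
        cell=np.eye(3) * 8.0,
        pbc=(True, True, True),
    )
    chain = AtomicStructure(
        id="polymer_chain",
        species=["C", "C"],
        positions=[[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]],
        cell=np.diag([3.0, 10.0, 10.0]),
        pbc=(True, True, True),
    )
    two_atom = AtomicStructure(
        id="two_atom_filter",
        species=["C", "C"],
        positions=[[0.0, 0.0, 0.0], [1.4, 0.0, 0.0]],
    )
    return {
        "two_atom_filter": two_atom,
        "hbond_linear_19": hbond_pair(1.9, 180.0),
        "hbond_far_26": hbond_pair(2.6, 180.0),
        "hbond_bent_120": hbond_pair(1.9, 120.0),
        "two_waters_cell": two_waters_cell,
        "polymer_chain": chain,
        "succinic_acid": _embedded_molecule("succinic_acid", "OC(=O)CCC(=O)O"),
        "phenanthrene": _embedded_molecule(
            "phenanthrene", "c1ccc2ccc3ccccc3c2c1"
        ),
    }
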