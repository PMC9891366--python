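"""Atom-centered 3-body power-spectrum (SOAP) descriptors.

Each atom's neighborhood is represented by a Gaussian-smeared neighbor
density, expanded in orthonormalized Gaussian radial functions times real
spherical harmonics, and contracted into the rotation-invariant power
spectrum p_{nn'l} per (element, element) channel pair.  Collections of
atoms (molecules, crystals, motifs) are represented by the arithmetic mean
of their atoms' vectors, so averaging and differencing commute: the
"remnant" representation of a crystal — solid-phase minus gas-phase
descriptor, atom by atom — averages to the difference of the collection
averages.

The expansion coefficients use the analytic identity for the angular
integral of an off-center Gaussian (a modified spherical Bessel function),
with the remaining radial integral done by Gauss-Legendre quadrature on
[0, r_cut].  A smooth cosine cutoff is applied as a per-neighbor weight.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ive, sph_harm_y

from .structures import AtomicStructure, CrystalRecord, neighbor_pairs

__all__ = [
    "DescriptorConfig",
    "DescriptorSet",
    "CollectionDescriptor",
    "compute_descriptors",
    "average_descriptor",
    "remnant_descriptor",
    "concatenate_descriptors",
]


@dataclass(frozen=True)
class DescriptorConfig:
    """Hyperparameters of the power-spectrum featurization.

    r_cut : neighborhood radius (angstrom).
    n_max : number of radial basis functions.
    l_max : angular band limit.
    sigma_atom : Gaussian smearing of the neighbor density (angstrom).
    species_list : ordered global element set; fixed across a dataset so
        all feature matrices share one column space (absent pairs are
        zero-filled).
    normalize : L2-normalize each atom's vector.
    cutoff_width : width of the smooth cosine switch at r_cut (angstrom).
    n_quad : radial quadrature points.
    """

    r_cut: float = 5.0
    n_max: int = 6
    l_max: int = 4
    sigma_atom: float = 0.3
    species_list: tuple[str, ...] = ("C", "H", "N", "O", "S")
    normalize: bool = True
    cutoff_width: float = 0.5
    n_quad: int = 60

    def __post_init__(self):
        if self.r_cut <= 0 or self.n_max < 1 or self.l_max < 0:
            raise ValueError("invalid descriptor hyperparameters")
        object.__setattr__(self, "species_list", tuple(self.species_list))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "r_cut": self.r_cut, "n_max": self.n_max, "l_max": self.l_max,
                "sigma_atom": self.sigma_atom, "species": self.species_list,
                "normalize": self.normalize, "cutoff_width": self.cutoff_width,
                "n_quad": self.n_quad, "family": "gauss-radial/power-spectrum",
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def n_features(self) -> int:
        k = len(self.species_list) * self.n_max
        return k * (k + 1) // 2 * (self.l_max + 1)

    def column_labels(self) -> list[str]:
        labels = []
        chan = [(z, n) for z in self.species_list for n in range(self.n_max)]
        for a in range(len(chan)):
            for b in range(a, len(chan)):
                for l in range(self.l_max + 1):
                    z1, n1 = chan[a]
                    z2, n2 = chan[b]
                    labels.append(f"{z1}{n1}|{z2}{n2}|l{l}")
        return labels


@dataclass
class DescriptorSet:
    """Per-atom feature matrix for one structure in one phase."""

    structure_id: str
    phase: str  # "s", "g", or "s-g"
    X: np.ndarray  # (n_atoms, n_features)
    config_hash: str

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError(f"{self.structure_id}: non-finite descriptor entries")


@dataclass
class CollectionDescriptor:
    """Average feature vector over a collection of atoms."""

    x_sigma: np.ndarray
    n_sigma: int
    scope: str  # atom | molecule | crystal | motif
    phase: str = "s"
    config_hash: str = ""
    block_origins: tuple = ()  # set by concatenate_descriptors

    def __post_init__(self):
        self.x_sigma = np.asarray(self.x_sigma, dtype=float).ravel()
        if self.n_sigma < 1:
            raise ValueError("n_sigma must be >= 1")


# ---------------------------------------------------------------------------
# radial basis
# ---------------------------------------------------------------------------

def _quadrature(cfg: DescriptorConfig):
    x, w = np.polynomial.legendre.leggauss(cfg.n_quad)
    r = 0.5 * cfg.r_cut * (x + 1.0)
    w = 0.5 * cfg.r_cut * w
    return r, w


def _radial_basis(cfg: DescriptorConfig, r: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Orthonormalized Gaussians on [0, r_cut], evaluated on the grid.

    Raw functions are Gaussians centered on an even grid with width equal to
    the grid spacing; Loewdin orthonormalization (S^{-1/2}) under the
    measure r^2 dr keeps them localized while making <g_n|g_m> = delta.
    """
    centers = np.linspace(0.0, cfg.r_cut, cfg.n_max)
    width = cfg.r_cut / max(cfg.n_max - 1, 1)
    raw = np.exp(-((r[None, :] - centers[:, None]) ** 2) / (2.0 * width**2))
    overlap = np.einsum("iq,jq,q,q->ij", raw, raw, w, r**2)
    evals, evecs = np.linalg.eigh(overlap)
    if np.any(evals <= 1e-12):
        raise ValueError("radial basis numerically dependent; lower n_max")
    inv_sqrt = evecs @ np.diag(evals**-0.5) @ evecs.T
    return inv_sqrt @ raw


def real_spherical_harmonics(l_max: int, units: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics for unit vectors.

    Returns an (n, (l_max+1)^2) array ordered (l, m) with m = -l..l.
    """
    units = np.atleast_2d(units)
    x, y, z = units[:, 0], units[:, 1], units[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    out = np.empty((len(units), (l_max + 1) ** 2))
    col = 0
    for l in range(l_max + 1):
        for m in range(-l, l + 1):
            am = abs(m)
            ylm = sph_harm_y(l, am, theta, phi)
            if m == 0:
                v = ylm.real
            elif m > 0:
                v = np.sqrt(2.0) * (-1.0) ** m * ylm.real
            else:
                v = np.sqrt(2.0) * (-1.0) ** am * ylm.imag
            out[:, col] = v
            col += 1
    return out


def _cutoff_weight(r: np.ndarray, cfg: DescriptorConfig) -> np.ndarray:
    r0 = cfg.r_cut - cfg.cutoff_width
    w = np.ones_like(r)
    mask = r > r0
    w[mask] = 0.5 * (1.0 + np.cos(np.pi * (r[mask] - r0) / cfg.cutoff_width))
    return np.clip(w, 0.0, 1.0)


def density_expansion_coefficients(
    r_neigh: np.ndarray,
    units: np.ndarray,
    weights: np.ndarray,
    cfg: DescriptorConfig,
    grid=None,
) -> np.ndarray:
    """Expansion coefficients c_{nlm} of one weighted-Gaussian neighbor set.

    The density is rho(r) = sum_j weights_j * exp(-|r - r_j|^2 / 2 sigma^2),
    projected on g_n(r) * Y_lm over the ball of radius r_cut.  Uses the
    exponentially-scaled Bessel identity so large r*r_j/sigma^2 cannot
    overflow.  Returns an (n_max, (l_max+1)^2) array.
    """
    if grid is None:
        r_q, w_q = _quadrature(cfg)
        G = _radial_basis(cfg, r_q, w_q)
    else:
        r_q, w_q, G = grid
    sig2 = cfg.sigma_atom**2
    nlm = (cfg.l_max + 1) ** 2
    if len(r_neigh) == 0:
        return np.zeros((cfg.n_max, nlm))
    rj = np.clip(np.asarray(r_neigh, dtype=float), 1e-12, None)
    x = np.clip(rj[:, None] * r_q[None, :] / sig2, 1e-14, None)  # (j, q)
    gauss = np.exp(-((r_q[None, :] - rj[:, None]) ** 2) / (2.0 * sig2))
    pref = np.sqrt(np.pi / (2.0 * x))
    M = np.empty((len(rj), cfg.n_quad, cfg.l_max + 1))
    for l in range(cfg.l_max + 1):
        M[:, :, l] = gauss * pref * ive(l + 0.5, x)
    # I[j, n, l] = int dr r^2 g_n(r) * M_j(r, l)
    I = np.einsum("nq,q,q,jql->jnl", G, w_q, r_q**2, M)
    Y = real_spherical_harmonics(cfg.l_max, units)  # (j, nlm)
    lm_l = np.concatenate(
        [np.full(2 * l + 1, l) for l in range(cfg.l_max + 1)]
    )
    c = 4.0 * np.pi * np.einsum(
        "j,jk,jnk->nk", weights, Y, I[:, :, lm_l]
    )
    return c


def _power_spectrum(c_all: np.ndarray, cfg: DescriptorConfig) -> np.ndarray:
    """Contract per-channel coefficients (K, n_lm) -> invariant vector.

    c_all combines (species, radial) channels into K = n_species * n_max
    rows.  p_{k k' l} = sum_m c_klm c_k'lm / sqrt(2l+1); the upper triangle
    k <= k' is kept, off-diagonal entries scaled by sqrt(2) to preserve the
    Euclidean norm of the full tensor.
    """
    K = c_all.shape[0]
    blocks = []
    start = 0
    for l in range(cfg.l_max + 1):
        width = 2 * l + 1
        cl = c_all[:, start:start + width]
        p = cl @ cl.T / np.sqrt(2 * l + 1)
        blocks.append(p)
        start += width
    iu, ju = np.triu_indices(K)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    # column order must match column_labels(): channel pair outer, l inner
    feats = np.empty(len(iu) * (cfg.l_max + 1))
    for idx, (a, b) in enumerate(zip(iu, ju)):
        for l in range(cfg.l_max + 1):
            feats[idx * (cfg.l_max + 1) + l] = scale[idx] * blocks[l][a, b]
    return feats


def compute_descriptors(s: AtomicStructure, cfg: DescriptorConfig) -> DescriptorSet:
    """Power-spectrum feature matrix for every atom of one structure.

    Periodic neighbors are gathered over lattice images within r_cut.  The
    central atom contributes to its own element channel (l = 0), so an atom
    with no neighbors carries a nonzero "bare atom" reference vector that
    depends only on its element.
    """
    for el in set(s.species):
        if el not in cfg.species_list:
            raise ValueError(
                f"{s.id}: element {el} not in species_list {cfg.species_list}"
            )
    spec_index = {el: k for k, el in enumerate(cfg.species_list)}
    n = len(s)
    # adjacency including both directions and self-images
    neigh: list[list[tuple[int, np.ndarray, float]]] = [[] for _ in range(n)]
    ii, jj, dd, ss = neighbor_pairs(s, cfg.r_cut)
    cell = s.cell if s.cell is not None else np.eye(3)
    for a, b, d, sh in zip(ii, jj, dd, ss):
        vec = s.positions[b] + sh @ cell - s.positions[a]
        neigh[a].append((b, vec, d))
        neigh[b].append((a, -vec, d))

    r_q, w_q = _quadrature(cfg)
    G = _radial_basis(cfg, r_q, w_q)
    grid = (r_q, w_q, G)
    nlm = (cfg.l_max + 1) ** 2
    K = len(cfg.species_list) * cfg.n_max
    X = np.empty((n, cfg.n_features))
    for i in range(n):
        c_all = np.zeros((K, nlm))
        # group neighbors (plus the central atom itself) by element
        by_z: dict[int, list[tuple[float, np.ndarray]]] = {}
        by_z.setdefault(spec_index[s.species[i]], []).append((0.0, np.array([0.0, 0.0, 1.0])))
        for b, vec, d in neigh[i]:
            if d <= 1e-12:
                continue
            by_z.setdefault(spec_index[s.species[b]], []).append((d, vec / d))
        for z, items in by_z.items():
            r_n = np.array([d for d, _ in items])
            units = np.array([u for _, u in items])
            weights = _cutoff_weight(r_n, cfg)
            weights[r_n <= 1e-12] = 1.0
            c = density_expansion_coefficients(r_n, units, weights, cfg, grid)
            c_all[z * cfg.n_max:(z + 1) * cfg.n_max] = c
        X[i] = _power_spectrum(c_all, cfg)
    if cfg.normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = np.where(norms > 0, X / np.where(norms == 0, 1.0, norms), X)
    return DescriptorSet(
        structure_id=s.id, phase="s" if s.periodic else "g",
        X=X, config_hash=cfg.config_hash,
    )


# ---------------------------------------------------------------------------
# collection averages, remnant, concatenation
# ---------------------------------------------------------------------------

def average_descriptor(
    ds: DescriptorSet, indices: Sequence[int] | None = None, scope: str = "crystal"
) -> CollectionDescriptor:
    """Arithmetic mean of selected rows (the collection-average descriptor)."""
    if indices is None:
        indices = np.arange(len(ds.X))
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("empty index list")
    if indices.min() < 0 or indices.max() >= len(ds.X):
        raise IndexError("atom index out of range")
    return CollectionDescriptor(
        x_sigma=ds.X[indices].mean(axis=0),
        n_sigma=len(indices),
        scope=scope,
        phase=ds.phase,
        config_hash=ds.config_hash,
    )


def remnant_descriptor(
    rec: CrystalRecord,
    ds_s: DescriptorSet,
    ds_g: Sequence[DescriptorSet],
) -> tuple[DescriptorSet, CollectionDescriptor]:
    """Per-atom remnant rows x^(s-g)_a and their crystal average x^(s-g)_c.

    Gas rows are aligned to crystal atoms through the record's index maps,
    so row ``i`` is the solid-phase vector of crystal atom ``i`` minus the
    gas-phase vector of the corresponding atom of its molecule.  Averaging
    and differencing commute, so the returned collection equals
    x^(s)_c - x^(g)_c.
    """
    if len(ds_g) != len(rec.molecules):
        raise ValueError("one gas DescriptorSet per molecule required")
    for g in ds_g:
        if g.config_hash != ds_s.config_hash:
            raise ValueError("descriptor config mismatch between phases")
    R = np.array(ds_s.X, copy=True)
    for (gas, imap), dsg in zip(rec.molecules, ds_g):
        if len(dsg.X) != len(gas):
            raise ValueError("gas descriptor rows != molecule size")
        R[imap] -= dsg.X
    remnant = DescriptorSet(
        structure_id=rec.crystal.id, phase="s-g", X=R,
        config_hash=ds_s.config_hash,
    )
    coll = CollectionDescriptor(
        x_sigma=R.mean(axis=0), n_sigma=len(R), scope="crystal",
        phase="s-g", config_hash=ds_s.config_hash,
    )
    return remnant, coll


def concatenate_descriptors(
    a: CollectionDescriptor, b: CollectionDescriptor
) -> CollectionDescriptor:
    """Feature-wise concatenation {a, b} with block bookkeeping."""
    if a.scope != b.scope:
        raise ValueError(f"scope mismatch: {a.scope} vs {b.scope}")
    if a.n_sigma != b.n_sigma:
        raise ValueError("collections cover different atom counts")
    origins = (
        (a.phase, len(a.x_sigma)),
        (b.phase, len(b.x_sigma)),
    )
    return CollectionDescriptor(
        x_sigma=np.concatenate([a.x_sigma, b.x_sigma]),
        n_sigma=a.n_sigma,
        scope=a.scope,
        phase=f"{a.phase}+{b.phase}",
        config_hash=f"{a.config_hash}+{b.config_hash}",
        block_origins=origins,
    )
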