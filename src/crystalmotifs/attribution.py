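"""Linear lattice-energy models and per-atom energy attribution.

The lattice (binding) energy of a molecular crystal is
Delta_c = E_c - sum_m E_m, with per-atom value delta_c = Delta_c / n_c.
Ridge regressions on collection-averaged descriptors predict per-atom
energies e_sigma (after subtracting a composition baseline) or delta_c
directly — on solid, gas, concatenated, or remnant feature spaces.  Because
the model is linear and the collection descriptor is an atom average, a
remnant-space prediction decomposes exactly into per-atom contributions
delta_a whose mean is the structure prediction.  A Gaussian filter then
redistributes each atom's raw contribution over its <= 2 A neighborhood
(weights exp(-d^2/2 varsigma^2), normalized over recipients), smoothing the
gauge-like cancellations between bonded atoms while conserving the total
exactly.  Motif contributions are averages of the filtered values over the
matched atoms; overlapping motifs mean they do not sum to delta_c.

All energies are kJ/mol; per-atom quantities are kJ per mol of atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from .structures import AtomicStructure, CrystalRecord, neighbor_pairs
from .descriptors import CollectionDescriptor, DescriptorSet

__all__ = [
    "EnergyView",
    "BaselineModel",
    "RegressionModel",
    "FilterConfig",
    "AttributionResult",
    "MotifContribution",
    "energy_view",
    "fit_baseline",
    "fit_energy_model",
    "predict_lattice_energy_combined",
    "predict_lattice_energy_direct",
    "atomic_contributions",
    "gaussian_filter",
    "motif_contribution",
    "evaluate_model",
    "fps_select",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-12, 2, 15))


@dataclass
class EnergyView:
    """Per-structure energy bookkeeping for a set of crystal records.

    e entries are per-atom energies E/n; delta_c = Delta_c / n_c.
    """

    crystal_ids: list[str]
    n_c: np.ndarray
    e_c: np.ndarray
    Delta_c: np.ndarray
    delta_c: np.ndarray
    molecule_parents: list[int]
    n_m: np.ndarray
    e_m: np.ndarray


def energy_view(records: Sequence[CrystalRecord]) -> EnergyView:
    ids, n_c, e_c, Dc, dc = [], [], [], [], []
    parents, n_m, e_m = [], [], []
    for ri, rec in enumerate(records):
        ids.append(rec.crystal.id)
        n_c.append(rec.n_atoms)
        e_c.append(rec.E_crystal / rec.n_atoms)
        Dc.append(rec.lattice_energy)
        dc.append(rec.lattice_energy_per_atom)
        for (gas, _), E in zip(rec.molecules, rec.E_molecules):
            parents.append(ri)
            n_m.append(len(gas))
            e_m.append(E / len(gas))
    return EnergyView(
        crystal_ids=ids, n_c=np.array(n_c), e_c=np.array(e_c),
        Delta_c=np.array(Dc), delta_c=np.array(dc),
        molecule_parents=parents, n_m=np.array(n_m), e_m=np.array(e_m),
    )


# ---------------------------------------------------------------------------
# composition baseline
# ---------------------------------------------------------------------------

@dataclass
class BaselineModel:
    """Per-element energies fitted to per-atom energies by least squares.

    The baseline prediction for a structure depends only on its element
    fractions, so it cancels exactly in any lattice-energy difference
    (crystal and molecules share one composition).
    """

    elements: tuple[str, ...]
    coefficients: np.ndarray  # kJ per mol of atoms, per count fraction
    fitted_on: str = ""

    def predict_per_atom(self, composition: dict[str, int]) -> float:
        n = sum(composition.values())
        frac = np.array([composition.get(el, 0) / n for el in self.elements])
        unknown = set(composition) - set(self.elements)
        if unknown:
            raise ValueError(f"elements {sorted(unknown)} not in baseline")
        return float(frac @ self.coefficients)


def fit_baseline(
    records: Sequence[CrystalRecord], include_molecules: bool = True,
    fitted_on: str = "",
) -> BaselineModel:
    """Least-squares per-element energies from per-atom total energies.

    Each crystal (and, by default, each gas molecule) contributes one row:
    its element-fraction vector against e_sigma = E_sigma / n_sigma.
    """
    elements = sorted(
        {el for rec in records for el in rec.crystal.composition()}
    )
    rows, targets = [], []

    def add(comp: dict[str, int], e: float):
        n = sum(comp.values())
        rows.append([comp.get(el, 0) / n for el in elements])
        targets.append(e)

    for rec in records:
        add(rec.crystal.composition(), rec.E_crystal / rec.n_atoms)
        if include_molecules:
            for (gas, _), E in zip(rec.molecules, rec.E_molecules):
                add(gas.composition(), E / len(gas))
    A = np.array(rows)
    if len(rows) < len(elements):
        raise ValueError(
            f"{len(rows)} structures cannot determine {len(elements)} "
            "per-element energies; pool more data"
        )
    if np.linalg.matrix_rank(A) < len(elements):
        raise ValueError(
            "rank-deficient composition matrix; pool structures with more "
            "varied compositions"
        )
    coef, *_ = np.linalg.lstsq(A, np.array(targets), rcond=None)
    return BaselineModel(tuple(elements), coef, fitted_on=fitted_on)


# ---------------------------------------------------------------------------
# ridge regression with cross-validated regularization
# ---------------------------------------------------------------------------

@dataclass
class RegressionModel:
    """Centered ridge model: prediction = (x - x_mean) . w + intercept."""

    w: np.ndarray
    intercept: float
    x_mean: np.ndarray
    lambda_: float
    feature_space: str  # s | g | concat | remnant
    cv_folds: int = 5
    cv_rmse: dict = field(default_factory=dict)  # lambda -> mean CV RMSE
    residuals: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.w):
            raise ValueError(
                f"feature dimension {X.shape[1]} != model dimension {len(self.w)}"
            )
        return (X - self.x_mean) @ self.w + self.intercept


def fit_energy_model(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
    feature_space: str = "remnant",
    random_state: int = 0,
) -> RegressionModel:
    """Ridge regression with the regularization strength chosen by k-fold CV.

    Features and targets are centered on the training set (the intercept is
    the training-target mean), so the penalty never acts on the offset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite features or targets")
    lambda_grid = [float(l) for l in lambda_grid]
    cv_rmse: dict[float, float] = {}
    if len(lambda_grid) > 1 and len(y) >= folds:
        kf = KFold(n_splits=folds, shuffle=True, random_state=random_state)
        splits = list(kf.split(X))
        for lam in lambda_grid:
            errs = []
            for tr, te in splits:
                mdl = _ridge_centered(X[tr], y[tr], lam)
                pred = (X[te] - mdl[2]) @ mdl[0] + mdl[1]
                errs.append(np.sqrt(np.mean((pred - y[te]) ** 2)))
            cv_rmse[lam] = float(np.mean(errs))
        best = min(cv_rmse, key=cv_rmse.get)
    else:
        best = lambda_grid[0]
    w, b, xm = _ridge_centered(X, y, best)
    resid = (X - xm) @ w + b - y
    return RegressionModel(
        w=w, intercept=b, x_mean=xm, lambda_=best,
        feature_space=feature_space, cv_folds=folds, cv_rmse=cv_rmse,
        residuals=resid,
    )


def _ridge_centered(X, y, lam):
    xm = X.mean(axis=0)
    ym = float(y.mean())
    ridge = Ridge(alpha=lam, fit_intercept=False, solver="cholesky")
    ridge.fit(X - xm, y - ym)
    return ridge.coef_, ym, xm


# ---------------------------------------------------------------------------
# lattice-energy prediction
# ---------------------------------------------------------------------------

def predict_lattice_energy_combined(
    x_s_c: CollectionDescriptor,
    x_g_c: CollectionDescriptor,
    model_c: RegressionModel,
    model_m: RegressionModel,
) -> float:
    """Two-model lattice energy: crystal-energy model minus molecular model.

    ``x_g_c`` is the molecule-size-weighted average of the gas molecules'
    descriptors, i.e. the plain average over all gas-phase atoms of the
    crystal.  Composition baselines cancel exactly between the two terms
    because crystal and molecules share one composition, so both models
    may be (and normally are) trained on baselined targets.
    """
    if x_s_c.n_sigma != x_g_c.n_sigma:
        raise ValueError(
            "solid and gas collections cover different atom counts; "
            "baseline cancellation would be invalid"
        )
    e_c_hat = float(model_c.predict(x_s_c.x_sigma)[0])
    e_m_hat = float(model_m.predict(x_g_c.x_sigma)[0])
    return e_c_hat - e_m_hat


def gas_collection_average(rec: CrystalRecord, ds_g: Sequence[DescriptorSet]) -> CollectionDescriptor:
    """n_m-weighted molecular average: mean gas-phase row over all atoms."""
    rows = np.concatenate([g.X for g in ds_g], axis=0)
    if len(rows) != rec.n_atoms:
        raise ValueError("gas descriptors do not cover all atoms")
    return CollectionDescriptor(
        x_sigma=rows.mean(axis=0), n_sigma=len(rows), scope="crystal",
        phase="g", config_hash=ds_g[0].config_hash,
    )


def predict_lattice_energy_direct(
    x: CollectionDescriptor, model: RegressionModel
) -> float:
    """delta_c estimate from a single model on the matching feature space."""
    space_of_phase = {"s": "s", "g": "g", "s-g": "remnant"}
    tag = space_of_phase.get(x.phase, "concat" if "+" in x.phase else x.phase)
    if tag != model.feature_space:
        raise ValueError(
            f"descriptor phase {x.phase!r} does not match model feature "
            f"space {model.feature_space!r}"
        )
    return float(model.predict(x.x_sigma)[0])


# ---------------------------------------------------------------------------
# per-atom attribution and Gaussian filter
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Gaussian contribution filter: smearing varsigma and neighbor cutoff."""

    varsigma: float = 0.5  # angstrom
    neighbor_cutoff: float = 2.0  # angstrom

    def __post_init__(self):
        if self.varsigma <= 0 or self.neighbor_cutoff <= 0:
            raise ValueError("filter parameters must be positive")


@dataclass
class AttributionResult:
    """Per-atom lattice-energy contributions, raw and filtered (kJ/mol atom)."""

    structure_id: str
    delta_a: np.ndarray
    delta_a_filtered: np.ndarray | None = None
    filter: FilterConfig | None = None

    @property
    def prediction(self) -> float:
        """Structure-level delta_c estimate (mean of per-atom values)."""
        return float(np.mean(self.delta_a))


@dataclass
class MotifContribution:
    """Average filtered contribution of a motif's member atoms."""

    pattern: str
    structure_id: str
    atom_indices: tuple[int, ...]
    epsilon: float  # kJ per mol of atoms


def atomic_contributions(
    rec: CrystalRecord, ds_remnant: DescriptorSet, model: RegressionModel
) -> AttributionResult:
    """delta_a = (x^(s-g)_a - x_mean) . w + intercept, per crystal atom.

    Linearity makes the decomposition exact: the mean over atoms equals the
    collection prediction.  Only remnant-space models decompose this way.
    """
    if model.feature_space != "remnant":
        raise ValueError("atomic attribution requires a remnant-space model")
    if len(ds_remnant.X) != rec.n_atoms:
        raise ValueError("remnant rows misaligned with crystal atoms")
    delta_a = model.predict(ds_remnant.X)
    return AttributionResult(structure_id=rec.crystal.id, delta_a=delta_a)


def smoothing_matrix(
    s: AtomicStructure, cfg: FilterConfig
) -> np.ndarray:
    """Column-stochastic redistribution matrix W of the Gaussian filter.

    f(a, b) = exp(-d_ab^2 / 2 varsigma^2) for minimum-image neighbors within
    the cutoff, f(a, a) = 1, zero beyond; column j is normalized so atom j's
    raw contribution is redistributed over its recipients without loss:
    W_ij = f(i, j) / sum_k f(k, j), hence sum(W delta) = sum(delta) exactly.
    """
    n = len(s)
    F = np.eye(n)
    ii, jj, dd, _ = neighbor_pairs(s, cfg.neighbor_cutoff)
    for a, b, d in zip(ii, jj, dd):
        if a == b:
            continue  # self-image within cutoff adds no cross-atom transfer
        g = np.exp(-(d**2) / (2.0 * cfg.varsigma**2))
        F[a, b] += g
        F[b, a] += g
    return F / F.sum(axis=0, keepdims=True)


def gaussian_filter(
    att: AttributionResult, s: AtomicStructure, cfg: FilterConfig
) -> AttributionResult:
    """Smooth per-atom contributions over <= cutoff neighborhoods.

    Conserves the total contribution exactly (the filter never changes the
    structure-level regression result)."""
    if len(att.delta_a) != len(s):
        raise ValueError("attribution length != atom count")
    W = smoothing_matrix(s, cfg)
    filtered = W @ att.delta_a
    total = att.delta_a.sum()
    if not np.isclose(filtered.sum(), total, rtol=1e-10, atol=1e-12):
        raise AssertionError("filter broke contribution conservation")
    return AttributionResult(
        structure_id=att.structure_id,
        delta_a=att.delta_a,
        delta_a_filtered=filtered,
        filter=cfg,
    )


def motif_contribution(
    att: AttributionResult, pattern: str, atom_indices: Sequence[int]
) -> MotifContribution:
    """epsilon_motif: mean filtered contribution over the motif's atoms.

    Note that a crystal's lattice energy is not the sum of its motif
    contributions: motifs overlap and epsilon is itself an average.
    """
    idx = np.asarray(atom_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("empty motif")
    values = (
        att.delta_a_filtered if att.delta_a_filtered is not None else att.delta_a
    )
    if idx.min() < 0 or idx.max() >= len(values):
        raise IndexError("motif atom index out of range")
    return MotifContribution(
        pattern=pattern,
        structure_id=att.structure_id,
        atom_indices=tuple(int(i) for i in idx),
        epsilon=float(values[idx].mean()),
    )


# ---------------------------------------------------------------------------
# evaluation and training-set selection
# ---------------------------------------------------------------------------

def evaluate_model(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """RMSE and MAE of predictions, plus the SD of the truth for context."""
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if len(pred) != len(truth):
        raise ValueError("length mismatch")
    resid = pred - truth
    return {
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "sd_truth": float(np.std(truth)),
    }


def collection_matrices(
    records: Sequence[CrystalRecord],
    ds_solid: Sequence[DescriptorSet],
    ds_gas: Sequence[Sequence[DescriptorSet]],
    ds_remnant: Sequence[DescriptorSet],
) -> dict[str, np.ndarray]:
    """Collection-averaged feature matrices and energy targets for a dataset.

    Crystal-level rows: solid average ``Xs``, gas average ``Xg`` (the
    molecule-size-weighted molecular mean), remnant average ``Xr``, and the
    concatenation ``Xconcat``; molecule-level rows ``Xm`` with per-atom
    energies ``e_m``.  Targets in kJ per mol of atoms.
    """
    Xs = np.array([d.X.mean(axis=0) for d in ds_solid])
    Xr = np.array([d.X.mean(axis=0) for d in ds_remnant])
    Xg = np.array(
        [np.vstack([g.X for g in gl]).mean(axis=0) for gl in ds_gas]
    )
    Xm, e_m, mol_parent = [], [], []
    for ri, (rec, gl) in enumerate(zip(records, ds_gas)):
        for (gas, _), E, dsg in zip(rec.molecules, rec.E_molecules, gl):
            Xm.append(dsg.X.mean(axis=0))
            e_m.append(E / len(gas))
            mol_parent.append(ri)
    ev = energy_view(records)
    return {
        "Xs": Xs, "Xg": Xg, "Xr": Xr, "Xconcat": np.hstack([Xs, Xg]),
        "Xm": np.array(Xm), "e_m": np.array(e_m),
        "mol_parent": np.array(mol_parent, dtype=int),
        "e_c": ev.e_c, "delta_c": ev.delta_c, "n_c": ev.n_c,
    }


def fit_model_suite(
    records: Sequence[CrystalRecord],
    mats: dict[str, np.ndarray],
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 5,
) -> dict[str, dict]:
    """Fit and score the seven linear lattice-energy model variants.

    Per-atom energy models (crystal and molecule) are trained and scored on
    composition-baselined targets; lattice-energy models (combined, solid,
    gas, remnant, concatenated) on raw delta_c — the baseline cancels there
    by construction.  Returns per-variant RMSE/MAE/SD on the held-out set
    plus the fitted models.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    baseline = fit_baseline([records[i] for i in train_idx])
    base_c = np.array(
        [baseline.predict_per_atom(rec.crystal.composition()) for rec in records]
    )
    e_c_b = mats["e_c"] - base_c
    mol_parent = mats["mol_parent"]
    base_m = np.array(
        [
            baseline.predict_per_atom(gas.composition())
            for rec in records
            for (gas, _) in rec.molecules
        ]
    )
    e_m_b = mats["e_m"] - base_m
    mol_train = np.where(np.isin(mol_parent, train_idx))[0]
    mol_test = np.where(np.isin(mol_parent, test_idx))[0]

    out: dict[str, dict] = {}

    def fit_score(name, X, y, tr, te, space):
        model = fit_energy_model(
            X[tr], y[tr], lambda_grid=lambda_grid, folds=folds,
            feature_space=space,
        )
        metrics = evaluate_model(model.predict(X[te]), y[te])
        out[name] = {"model": model, **metrics}
        return model

    m_c = fit_score("e_c_solid", mats["Xs"], e_c_b, train_idx, test_idx, "s")
    m_m = fit_score("e_m_gas", mats["Xm"], e_m_b, mol_train, mol_test, "g")
    # combined two-model lattice energy (baselines cancel between the terms)
    pred_comb = m_c.predict(mats["Xs"][test_idx]) - m_m.predict(
        mats["Xg"][test_idx]
    )
    out["delta_combined"] = evaluate_model(pred_comb, mats["delta_c"][test_idx])
    fit_score("delta_solid", mats["Xs"], mats["delta_c"], train_idx, test_idx, "s")
    fit_score("delta_gas", mats["Xg"], mats["delta_c"], train_idx, test_idx, "g")
    fit_score("delta_remnant", mats["Xr"], mats["delta_c"], train_idx, test_idx, "remnant")
    fit_score("delta_concat", mats["Xconcat"], mats["delta_c"], train_idx, test_idx, "concat")
    out["baseline"] = {"model": baseline}
    return out


def fps_select(X: np.ndarray, k: int, start: int = 0) -> list[int]:
    """Farthest-point sampling: greedy max-min Euclidean selection.

    Deterministic given ``start``; ties broken by lowest index.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"cannot select {k} of {n} points")
    if not 0 <= start < n:
        raise IndexError("start index out of range")
    selected = [start]
    d_min = np.linalg.norm(X - X[start], axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d_min))
        selected.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(X - X[nxt], axis=1))
    return selected
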