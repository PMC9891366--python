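import numpy as np
import pytest

from crystalmotifs.attribution import (
    AttributionResult,
    FilterConfig,
    atomic_contributions,
    evaluate_model,
    fit_baseline,
    fit_energy_model,
    fps_select,
    gaussian_filter,
    motif_contribution,
    predict_lattice_energy_combined,
    predict_lattice_energy_direct,
    smoothing_matrix,
    gas_collection_average,
    collection_matrices,
    fit_model_suite,
)
from crystalmotifs.descriptors import CollectionDescriptor
from crystalmotifs.structures import AtomicStructure, CrystalRecord
from crystalmotifs.synthetic import DEFAULT_TEMPLATES


def _record(species_sets, energies, E_c):
    """Toy record: each molecule far apart in a big periodic box."""
    all_species, all_pos, gases = [], [], []
    for mi, sp in enumerate(species_sets):
        pos = np.array([[i * 1.2 + 20.0 * mi, 0, 0] for i in range(len(sp))])
        gases.append(AtomicStructure(f"g{mi}", sp, pos - pos.mean(axis=0)))
        all_species += list(sp)
        all_pos.append(pos)
    crystal = AtomicStructure(
        "c", all_species, np.vstack(all_pos),
        cell=np.eye(3) * 100.0, pbc=(True, True, True),
    )
    starts = np.cumsum([0] + [len(s) for s in species_sets])
    molecules = [
        (gas, np.arange(starts[i], starts[i + 1]))
        for i, gas in enumerate(gases)
    ]
    return CrystalRecord(crystal, molecules, E_c, energies)


class TestBaseline:
    def test_exact_composition_linear_energies(self):
        # energies exactly linear in composition -> residuals vanish
        e = {"O": -30.0, "H": -5.0, "C": -20.0}
        recs = []
        for sp_sets in (
            [("O", "H", "H")],
            [("C", "H", "H", "H", "H")],
            [("C", "O")],
            [("O", "H", "H"), ("C", "O")],
        ):
            E_m = [sum(e[s] for s in sp) for sp in sp_sets]
            recs.append(_record(sp_sets, E_m, sum(E_m)))
        bl = fit_baseline(recs)
        for rec in recs:
            pred = bl.predict_per_atom(rec.crystal.composition())
            assert pred == pytest.approx(rec.E_crystal / rec.n_atoms, abs=1e-10)

    def test_single_element_mean(self):
        recs = [
            _record([("C", "C")], [-10.0], -10.0),
            _record([("C", "C")], [-14.0], -14.0),
        ]
        bl = fit_baseline(recs, include_molecules=False)
        assert bl.coefficients[0] == pytest.approx(-6.0)  # mean per-atom energy

    def test_two_element_normal_equations_oracle(self):
        # hand-solved 2x2 normal equations on a fixed toy design
        recs = [
            _record([("O", "H", "H")], [-13.0], -13.0),
            _record([("O", "O", "H", "H")], [-20.0], -20.0),
        ]
        bl = fit_baseline(recs, include_molecules=False)
        # rows are element fractions in sorted element order (H, O)
        assert bl.elements == ("H", "O")
        A = np.array([[2 / 3, 1 / 3], [1 / 2, 1 / 2]])
        b = np.array([-13 / 3, -5.0])
        oracle = np.linalg.solve(A.T @ A, A.T @ b)
        assert np.allclose(bl.coefficients, oracle, atol=1e-10)

    def test_rank_deficient_raises(self):
        recs = [_record([("O", "H", "H")], [-13.0], -13.0)] * 3
        with pytest.raises(ValueError, match="rank-deficient|pool"):
            fit_baseline(recs, include_molecules=False)


class TestRidge:
    def test_slope_recovery_ridgeless(self):
        x = np.linspace(-1, 1, 20)[:, None]
        m = fit_energy_model(x, 2.0 * x.ravel(), lambda_grid=[1e-12])
        assert m.w[0] == pytest.approx(2.0, abs=1e-8)

    def test_zero_targets_zero_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(15, 4))
        m = fit_energy_model(X, np.zeros(15), lambda_grid=[1.0])
        assert np.abs(m.w).max() < 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_energy_model(np.array([[np.nan]]), np.array([1.0]))

    def test_planted_recovery_noise_free(self, synth_matrices):
        X, y = synth_matrices["Xr"], synth_matrices["delta_c"]
        m = fit_energy_model(X, y, lambda_grid=[1e-12])
        assert evaluate_model(m.predict(X), y)["rmse"] < 1e-8


class TestLatticePredictions:
    def test_combined_equals_difference_of_models(self, synth_small, synth_matrices):
        mats = synth_matrices
        m_c = fit_energy_model(mats["Xs"], mats["e_c"], lambda_grid=[1e-8], feature_space="s")
        m_m = fit_energy_model(mats["Xm"], mats["e_m"], lambda_grid=[1e-8], feature_space="g")
        rec = synth_small.records[4]
        x_s = CollectionDescriptor(mats["Xs"][4], rec.n_atoms, "crystal", phase="s")
        x_g = gas_collection_average(rec, synth_small.ds_gas[4])
        combined = predict_lattice_energy_combined(x_s, x_g, m_c, m_m)
        separate = m_c.predict(x_s.x_sigma)[0] - m_m.predict(x_g.x_sigma)[0]
        assert combined == pytest.approx(separate, abs=1e-12)

    def test_identical_phases_and_weights_give_zero(self):
        from crystalmotifs.attribution import RegressionModel

        m = RegressionModel(
            w=np.array([1.0, -2.0]), intercept=0.5,
            x_mean=np.zeros(2), lambda_=0.0, feature_space="s",
        )
        m2 = RegressionModel(
            w=m.w, intercept=m.intercept, x_mean=m.x_mean,
            lambda_=0.0, feature_space="g",
        )
        x = CollectionDescriptor([0.3, 0.7], 5, "crystal", phase="s")
        xg = CollectionDescriptor([0.3, 0.7], 5, "crystal", phase="g")
        assert predict_lattice_energy_combined(x, xg, m, m2) == pytest.approx(0.0)

    def test_direct_model_linearity_and_space_guard(self):
        from crystalmotifs.attribution import RegressionModel

        m = RegressionModel(
            w=np.array([2.0, 1.0]), intercept=0.0,
            x_mean=np.zeros(2), lambda_=0.0, feature_space="remnant",
        )
        x1 = CollectionDescriptor([1.0, 0.0], 4, "crystal", phase="s-g")
        x2 = CollectionDescriptor([0.0, 3.0], 4, "crystal", phase="s-g")
        s = CollectionDescriptor(
            np.asarray(x1.x_sigma) + np.asarray(x2.x_sigma), 4, "crystal", phase="s-g"
        )
        p1 = predict_lattice_energy_direct(x1, m)
        p2 = predict_lattice_energy_direct(x2, m)
        assert predict_lattice_energy_direct(s, m) == pytest.approx(p1 + p2)
        zero = CollectionDescriptor(np.zeros(2), 4, "crystal", phase="s-g")
        assert predict_lattice_energy_direct(zero, m) == pytest.approx(0.0)
        wrong = CollectionDescriptor(np.zeros(2), 4, "crystal", phase="s")
        with pytest.raises(ValueError, match="feature"):
            predict_lattice_energy_direct(wrong, m)


class TestAttribution:
    def test_mean_contribution_equals_prediction(self, synth_small, synth_matrices):
        mats = synth_matrices
        m = fit_energy_model(
            mats["Xr"], mats["delta_c"], lambda_grid=[1e-10],
            feature_space="remnant",
        )
        for i in (0, 7, 12):
            att = atomic_contributions(
                synth_small.records[i], synth_small.ds_remnant[i], m
            )
            pred = m.predict(mats["Xr"][i])[0]
            assert att.delta_a.mean() == pytest.approx(pred, abs=1e-12)

    def test_per_structure_sums_recover_planted_totals(self, synth_small, synth_matrices):
        """The gauge-free quantity (per-structure sum) matches the planted
        ground truth on noise-free synthetic data."""
        mats = synth_matrices
        m = fit_energy_model(
            mats["Xr"], mats["delta_c"], lambda_grid=[1e-12],
            feature_space="remnant",
        )
        for i in range(0, 25, 5):
            att = atomic_contributions(
                synth_small.records[i], synth_small.ds_remnant[i], m
            )
            assert att.delta_a.sum() == pytest.approx(
                synth_small.planted_delta_a[i].sum(), abs=1e-5
            )

    def test_requires_remnant_space(self, synth_small):
        m = fit_energy_model(
            np.ones((6, synth_small.ds_solid[0].X.shape[1])), np.zeros(6),
            lambda_grid=[1.0], feature_space="s",
        )
        with pytest.raises(ValueError, match="remnant"):
            atomic_contributions(synth_small.records[0], synth_small.ds_solid[0], m)


class TestGaussianFilter:
    def test_isolated_atom_unchanged(self):
        s = AtomicStructure("iso", ["C", "C"], [[0, 0, 0], [8.0, 0, 0]])
        att = AttributionResult("iso", np.array([1.3, -0.4]))
        out = gaussian_filter(att, s, FilterConfig())
        assert np.allclose(out.delta_a_filtered, att.delta_a)

    def test_two_atom_closed_form(self, micro):
        s = micro["two_atom_filter"]
        d = np.linalg.norm(s.positions[1] - s.positions[0])
        cfg = FilterConfig(varsigma=0.5, neighbor_cutoff=2.0)
        g = np.exp(-(d**2) / (2 * cfg.varsigma**2))
        x = 2.5
        att = AttributionResult("t", np.array([x, -x]))
        out = gaussian_filter(att, s, cfg)
        expected = x * (1 - g) / (1 + g)
        assert out.delta_a_filtered[0] == pytest.approx(expected, rel=1e-12)
        assert out.delta_a_filtered[1] == pytest.approx(-expected, rel=1e-12)
        assert out.delta_a_filtered.sum() == pytest.approx(0.0, abs=1e-14)

    def test_conservation_and_contraction(self, synth_small):
        rng = np.random.default_rng(5)
        cfg = FilterConfig()
        for i in (1, 6, 11):
            s = synth_small.records[i].crystal
            delta = rng.normal(size=len(s)) * 4.0
            att = gaussian_filter(AttributionResult(s.id, delta), s, cfg)
            total = delta.sum()
            assert abs(att.delta_a_filtered.sum() - total) <= 1e-10 * max(1, abs(total))
            assert att.delta_a_filtered.var() <= delta.var() + 1e-12

    def test_smoothing_matrix_column_stochastic(self, micro):
        W = smoothing_matrix(micro["two_waters_cell"], FilterConfig())
        assert np.allclose(W.sum(axis=0), 1.0)
        assert (W >= 0).all()

    def test_invalid_varsigma(self):
        with pytest.raises(ValueError):
            FilterConfig(varsigma=-1.0)


class TestMotifContribution:
    def test_mean_of_members(self):
        att = AttributionResult(
            "t", np.array([0.0, -3.0, -5.0]),
            delta_a_filtered=np.array([0.0, -3.0, -5.0]),
        )
        mc = motif_contribution(att, "pair", [1, 2])
        assert mc.epsilon == pytest.approx(-4.0)

    def test_all_atoms_equals_structure_prediction(self):
        vals = np.array([1.0, 2.0, 3.0, -2.0])
        att = AttributionResult("t", vals, delta_a_filtered=vals)
        mc = motif_contribution(att, "all", range(4))
        assert mc.epsilon == pytest.approx(att.prediction)

    def test_water_per_molecule_convention(self):
        # per-atom motif value times 3 gives the per-water-molecule value
        vals = np.array([-10.0, -7.0, -7.0])
        att = AttributionResult("w", vals, delta_a_filtered=vals)
        mc = motif_contribution(att, "water", [0, 1, 2])
        assert 3 * mc.epsilon == pytest.approx(vals.sum())

    def test_empty_motif_raises(self):
        att = AttributionResult("t", np.array([1.0]))
        with pytest.raises(ValueError):
            motif_contribution(att, "none", [])


class TestEvaluateAndFps:
    def test_error_metrics(self):
        assert evaluate_model([1.0, 2.0], [1.0, 2.0])["rmse"] == 0.0
        m = evaluate_model([1.0, -1.0, 1.0, -1.0], [0.0, 0.0, 0.0, 0.0])
        assert m["rmse"] == pytest.approx(1.0)
        assert m["mae"] == pytest.approx(1.0)

    def test_rmse_converges_to_noise_sd(self):
        rng = np.random.default_rng(1)
        resid = rng.normal(0.0, 0.7, size=20000)
        m = evaluate_model(resid, np.zeros_like(resid))
        assert m["rmse"] == pytest.approx(0.7, rel=0.03)

    def test_fps_line_oracle(self):
        X = np.array([[0.0], [1.0], [10.0]])
        assert fps_select(X, 3, start=0) == [0, 2, 1]

    def test_fps_full_selection_is_permutation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 3))
        sel = fps_select(X, 9, start=4)
        assert sorted(sel) == list(range(9))

    def test_fps_beats_random_min_distance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        def min_pairwise(idx):
            P = X[list(idx)]
            D = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
            return D[np.triu_indices(len(P), 1)].min()
        fps_d = min_pairwise(fps_select(X, 8, start=0))
        wins = sum(
            fps_d >= min_pairwise(rng.choice(60, 8, replace=False))
            for _ in range(100)
        )
        assert wins >= 95


def test_model_suite_reports_all_seven_variants(synth_small, synth_matrices):
    tr = fps_select(synth_matrices["Xr"], 20, start=0)
    te = sorted(set(range(25)) - set(tr))
    suite = fit_model_suite(synth_small.records, synth_matrices, tr, te)
    expected = {
        "e_c_solid", "e_m_gas", "delta_combined", "delta_solid",
        "delta_gas", "delta_remnant", "delta_concat", "baseline",
    }
    assert set(suite) == expected
    for name in expected - {"baseline"}:
        assert np.isfinite(suite[name]["rmse"])
    # the conceptually nonsensical gas-only space cannot beat the remnant
    assert suite["delta_remnant"]["rmse"] <= suite["delta_gas"]["rmse"]
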