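import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from crystalmotifs.descriptors import (
    CollectionDescriptor,
    DescriptorConfig,
    average_descriptor,
    compute_descriptors,
    concatenate_descriptors,
    density_expansion_coefficients,
    real_spherical_harmonics,
    remnant_descriptor,
    _quadrature,
    _radial_basis,
)
from crystalmotifs.structures import AtomicStructure, CrystalRecord
from crystalmotifs.attribution import fit_energy_model
from crystalmotifs.synthetic import DEFAULT_TEMPLATES


def _struct(species, positions, **kw):
    return AtomicStructure("t", species, np.asarray(positions, float), **kw)


def oracle_expansion_coefficients(r_j, unit_j, weight, cfg):
    """3-D quadrature of the density-expansion integral over the r_cut ball.

    Independent of the implementation's Bessel-identity route: integrates
    rho(r) g_n(r) Y_lm(r_hat) r^2 dr dOmega on a product grid.
    """
    rr, rw = np.polynomial.legendre.leggauss(80)
    rr = 0.5 * cfg.r_cut * (rr + 1.0)
    rw = 0.5 * cfg.r_cut * rw
    ct, cw = np.polynomial.legendre.leggauss(60)
    phis = np.linspace(0.0, 2 * np.pi, 61)[:-1]
    pw = 2 * np.pi / 60
    theta = np.arccos(ct)
    Rg, Tg, Pg = np.meshgrid(rr, theta, phis, indexing="ij")
    pts = np.stack(
        [
            Rg * np.sin(Tg) * np.cos(Pg),
            Rg * np.sin(Tg) * np.sin(Pg),
            Rg * np.cos(Tg),
        ],
        axis=-1,
    )
    rho = np.zeros(Rg.shape)
    for rj, uj, wj in zip(r_j, unit_j, weight):
        center = rj * np.asarray(uj)
        rho += wj * np.exp(
            -np.sum((pts - center) ** 2, axis=-1) / (2 * cfg.sigma_atom**2)
        )
    units = pts.reshape(-1, 3) / Rg.reshape(-1, 1)
    Y = real_spherical_harmonics(cfg.l_max, units).reshape(*Rg.shape, -1)
    big_cfg = DescriptorConfig(**{**cfg.__dict__, "n_quad": 80})
    G = _radial_basis(big_cfg, rr, rw)
    out = np.empty((cfg.n_max, (cfg.l_max + 1) ** 2))
    for n in range(cfg.n_max):
        out[n] = np.einsum(
            "rtp,rtpk,r,r,t->k", rho, Y, G[n] * rw, rr**2, cw
        ) * pw
    return out


def test_power_spectrum_matches_quadrature_oracle(small_cfg):
    """O-H dimer expansion coefficients agree with brute-force 3-D quadrature."""
    r_j = [1.0]
    unit_j = [np.array([0.6, -0.64, 0.48]) / np.linalg.norm([0.6, -0.64, 0.48])]
    w = [0.7]
    c_impl = density_expansion_coefficients(
        np.array(r_j), np.array(unit_j), np.array(w), small_cfg
    )
    c_oracle = oracle_expansion_coefficients(r_j, unit_j, w, small_cfg)
    rel = np.abs(c_impl - c_oracle).max() / np.abs(c_oracle).max()
    assert rel < 1e-4


class TestInvariances:
    def test_rotation_translation(self, small_cfg):
        s = _struct(["O", "H", "H"], DEFAULT_TEMPLATES[0].positions)
        ref = compute_descriptors(s, small_cfg).X
        R = Rotation.random(random_state=3).as_matrix()
        moved = _struct(
            ["O", "H", "H"], np.asarray(s.positions) @ R.T + [2.0, -1.0, 0.5]
        )
        assert np.abs(compute_descriptors(moved, small_cfg).X - ref).max() < 1e-8

    def test_permutation(self, small_cfg):
        s = _struct(["O", "H", "H"], DEFAULT_TEMPLATES[0].positions)
        perm = [2, 0, 1]
        permuted = _struct(
            [s.species[p] for p in perm], s.positions[perm]
        )
        ref = compute_descriptors(s, small_cfg).X
        got = compute_descriptors(permuted, small_cfg).X
        assert np.abs(got - ref[perm]).max() < 1e-8

    def test_locality(self, small_cfg):
        s = _struct(["O", "H"], [[0, 0, 0], [1.0, 0, 0]])
        far = _struct(["O", "H", "C"], [[0, 0, 0], [1.0, 0, 0], [50, 0, 0]])
        ref = compute_descriptors(s, small_cfg).X
        got = compute_descriptors(far, small_cfg).X
        assert np.abs(got[:2] - ref).max() < 1e-12

    def test_periodic_consistency_big_box(self, small_cfg):
        s = _struct(["O", "H", "H"], DEFAULT_TEMPLATES[0].positions)
        boxed = AtomicStructure(
            "boxed", s.species, s.positions + 10.0,
            cell=np.eye(3) * 40.0, pbc=(True, True, True),
        )
        ref = compute_descriptors(s, small_cfg).X
        assert np.abs(compute_descriptors(boxed, small_cfg).X - ref).max() < 1e-10

    def test_isolated_atoms_share_bare_reference(self, small_cfg):
        s = _struct(["C", "C"], [[0, 0, 0], [50.0, 0, 0]])
        X = compute_descriptors(s, small_cfg).X
        assert np.abs(X[0] - X[1]).max() < 1e-12
        assert np.linalg.norm(X[0]) > 0  # the bare-atom reference, not zero

    def test_unknown_species_rejected(self, small_cfg):
        s = _struct(["S"], [[0, 0, 0]])
        with pytest.raises(ValueError, match="species_list"):
            compute_descriptors(s, small_cfg)


class TestAveraging:
    def test_simple_means(self, small_cfg):
        ds = compute_descriptors(
            _struct(["O", "H", "H"], DEFAULT_TEMPLATES[0].positions), small_cfg
        )
        one = average_descriptor(ds, [1])
        assert np.array_equal(one.x_sigma, ds.X[1])
        both = average_descriptor(ds, [0, 1])
        assert np.allclose(both.x_sigma, ds.X[[0, 1]].mean(axis=0))
        with pytest.raises(ValueError):
            average_descriptor(ds, [])

    def test_crystal_average_is_molecule_weighted_mean(self, synth_small):
        """Collection averaging: the crystal mean equals the n_m-weighted
        mean of its molecules' means (and the plain atom mean)."""
        rec = synth_small.records[0]
        ds_s = synth_small.ds_solid[0]
        crystal_avg = average_descriptor(ds_s).x_sigma
        weighted = np.zeros_like(crystal_avg)
        for gas, imap in rec.molecules:
            weighted += len(gas) * average_descriptor(ds_s, imap).x_sigma
        weighted /= rec.n_atoms
        assert np.abs(crystal_avg - weighted).max() < 1e-12


class TestRemnant:
    def _record_two_waters(self, separation, cfg, side=12.0):
        w = np.array(DEFAULT_TEMPLATES[0].positions)
        crystal = AtomicStructure(
            "c", list("OHH") * 2,
            np.vstack([w, w + [separation, 0, 0]]),
            cell=np.eye(3) * side, pbc=(True, True, True),
        )
        gas = [
            AtomicStructure(f"g{i}", list("OHH"), w) for i in range(2)
        ]
        rec = CrystalRecord(
            crystal, [(gas[0], np.arange(3)), (gas[1], np.arange(3, 6))],
            0.0, [0.0, 0.0],
        )
        ds_s = compute_descriptors(crystal, cfg)
        ds_g = [compute_descriptors(g, cfg) for g in gas]
        return remnant_descriptor(rec, ds_s, ds_g)

    def test_zero_when_gas_matches_and_no_contacts(self):
        cfg = DescriptorConfig(
            r_cut=2.0, n_max=2, l_max=1, sigma_atom=0.4,
            species_list=("H", "O"), normalize=True, n_quad=30,
        )
        rem, coll = self._record_two_waters(5.5, cfg)
        assert np.abs(rem.X).max() < 1e-12
        assert np.abs(coll.x_sigma).max() < 1e-12

    def test_norm_vanishes_as_cutoff_shrinks_below_contact(self):
        norms = []
        for r_cut in (4.5, 3.0, 2.0):
            cfg = DescriptorConfig(
                r_cut=r_cut, n_max=2, l_max=1, sigma_atom=0.4,
                species_list=("H", "O"), normalize=True, n_quad=30,
            )
            rem, _ = self._record_two_waters(4.0, cfg)
            norms.append(np.linalg.norm(rem.X))
        assert norms[0] > 1e-3
        assert norms[0] > norms[1] >= norms[2]
        assert norms[2] < 1e-12  # cutoff below the minimum contact distance

    def test_differencing_commutes_with_averaging(self, synth_small):
        rec = synth_small.records[2]
        ds_s = synth_small.ds_solid[2]
        ds_g = synth_small.ds_gas[2]
        rem, coll = remnant_descriptor(rec, ds_s, ds_g)
        x_s = ds_s.X.mean(axis=0)
        x_g = np.vstack([g.X for g in ds_g]).mean(axis=0)
        assert np.abs(coll.x_sigma - (x_s - x_g)).max() < 1e-12
        assert np.abs(rem.X.mean(axis=0) - coll.x_sigma).max() < 1e-14


class TestConcatenation:
    def test_values_and_norm(self):
        a = CollectionDescriptor([1.0, 2.0], 3, "crystal", phase="s")
        b = CollectionDescriptor([3.0], 3, "crystal", phase="g")
        cat = concatenate_descriptors(a, b)
        assert np.array_equal(cat.x_sigma, [1.0, 2.0, 3.0])
        twice = concatenate_descriptors(a, CollectionDescriptor([1.0, 2.0], 3, "crystal"))
        assert np.linalg.norm(twice.x_sigma) ** 2 == pytest.approx(
            2 * np.linalg.norm(a.x_sigma) ** 2
        )
        with pytest.raises(ValueError):
            concatenate_descriptors(
                a, CollectionDescriptor([1.0], 3, "motif")
            )

    def test_zeroed_gas_block_equals_solid_model(self, synth_matrices):
        """Fitting on {x_s, 0} reproduces the solid-only model exactly in
        the ridgeless limit."""
        mats = synth_matrices
        Xs, y = mats["Xs"], mats["delta_c"]
        Xcat0 = np.hstack([Xs, np.zeros_like(mats["Xg"])])
        m_s = fit_energy_model(Xs, y, lambda_grid=[1e-12])
        m_cat = fit_energy_model(Xcat0, y, lambda_grid=[1e-12])
        assert np.allclose(
            m_s.predict(Xs), m_cat.predict(Xcat0), atol=1e-8
        )
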