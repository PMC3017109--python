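"""ENM construction, energetics (finite-difference oracles), and NMA."""

import numpy as np
import pytest

from ienm import enm_core
from ienm.structures_io import Structure


def ring_structure(n=10, radius=6.0):
    ang = 2 * np.pi * np.arange(n) / n
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), 0.05 * np.arange(n)])
    return Structure(["A"] * n, range(1, n + 1), ["ALA"] * n, coords)


@pytest.fixture
def small_model(barrel_pair):
    begin, *_ = barrel_pair
    sub = begin.select(begin.chain_ids == "A")
    return enm_core.build_enm(sub)


class TestBuildEnm:
    def test_bonded_spring_k(self):
        s = Structure(["A", "A"], [1, 2], ["ALA", "ALA"],
                      [[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]])
        m = enm_core.build_enm(s, cutoff=10.0)
        assert m.n_springs == 1
        assert m.k[0] == 10.0 and m.bonded[0]
        assert m.d0[0] == pytest.approx(3.8)

    def test_nonbonded_beyond_cutoff_absent(self):
        s = Structure(["A", "B"], [1, 1], ["ALA", "ALA"],
                      [[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        m = enm_core.build_enm(s, cutoff=10.0)
        assert m.n_springs == 0

    def test_bonded_kept_beyond_cutoff(self):
        # chain integrity: sequential neighbours keep a spring past R_c
        s = Structure(["A", "A"], [1, 2], ["ALA", "ALA"],
                      [[0.0, 0.0, 0.0], [12.0, 0.0, 0.0]])
        m = enm_core.build_enm(s, cutoff=10.0)
        assert m.n_springs == 1 and m.bonded[0] and m.k[0] == 10.0

    def test_ring_matches_bruteforce_pair_scan(self):
        s = ring_structure()
        cutoff = 4.5  # spans nearest + next-nearest neighbours on this ring
        m = enm_core.build_enm(s, cutoff=cutoff)
        expected = set()
        for i in range(s.n_atoms):
            for j in range(i + 1, s.n_atoms):
                d = np.linalg.norm(s.coords[j] - s.coords[i])
                bonded = abs(s.resnums[j] - s.resnums[i]) == 1
                if d < cutoff or bonded:
                    expected.add((i, j))
        assert m.pair_set() == expected

    def test_masked_pairs_absent(self, barrel_pair):
        begin, *_ = barrel_pair
        full = enm_core.build_enm(begin)
        nb = [(int(i), int(j)) for i, j, b in zip(full.i, full.j, full.bonded) if not b]
        mask = set(nb[:5])
        masked = enm_core.build_enm(begin, masked_pairs=mask)
        assert masked.pair_set() == full.pair_set() - mask


class TestEnergetics:
    def test_reference_is_minimum(self, small_model):
        e, g = enm_core.enm_energy_gradient(small_model, small_model.reference.coords)
        assert e == pytest.approx(0.0, abs=1e-20)
        assert np.abs(g).max() == pytest.approx(0.0, abs=1e-12)

    def test_single_spring_closed_form(self):
        s = Structure(["A", "B"], [1, 1], ["ALA", "ALA"],
                      [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        m = enm_core.build_enm(s, cutoff=2.0, k_nonbonded=1.0)
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        e, _ = enm_core.enm_energy_gradient(m, coords)
        assert e == pytest.approx(0.5)  # k/2 (d - d0)^2 = 0.5 * 1 * 1

    def test_gradient_matches_finite_differences(self, small_model):
        rng = np.random.default_rng(3)
        coords = small_model.reference.coords + 0.3 * rng.standard_normal(
            small_model.reference.coords.shape
        )
        _, g = enm_core.enm_energy_gradient(small_model, coords)
        h = 1e-6
        flat = coords.reshape(-1)
        for idx in rng.choice(flat.size, size=12, replace=False):
            fp, fm = flat.copy(), flat.copy()
            fp[idx] += h
            fm[idx] -= h
            ep, _ = enm_core.enm_energy_gradient(small_model, fp)
            em, _ = enm_core.enm_energy_gradient(small_model, fm)
            fd = (ep - em) / (2 * h)
            assert g.reshape(-1)[idx] == pytest.approx(fd, rel=1e-6, abs=1e-8)

    def test_coincident_atoms_error(self):
        s = Structure(["A", "B"], [1, 1], ["ALA", "ALA"],
                      [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        m = enm_core.build_enm(s, cutoff=2.0)
        with pytest.raises(ValueError, match="coincident"):
            enm_core.enm_energy_gradient(m, np.zeros((2, 3)))

    def test_energy_nonnegative_random_probes(self, small_model):
        rng = np.random.default_rng(11)
        for _ in range(10):
            coords = small_model.reference.coords + rng.standard_normal(
                small_model.reference.coords.shape
            )
            e, _ = enm_core.enm_energy_gradient(small_model, coords)
            assert e >= 0.0


class TestHessian:
    def test_translation_invariance(self, small_model):
        H = enm_core.enm_hessian(small_model)
        n = small_model.n_atoms
        for axis in range(3):
            v = np.zeros((n, 3))
            v[:, axis] = 1.0
            assert np.abs(H @ v.reshape(-1)).max() == pytest.approx(0.0, abs=1e-10)

    def test_rotation_invariance_at_reference(self, small_model):
        H = enm_core.enm_hessian(small_model)
        basis = enm_core.rigid_body_basis(small_model.reference.coords)
        for v in basis:
            assert np.abs(H @ v).max() == pytest.approx(0.0, abs=1e-8)

    def test_matches_finite_difference_of_gradient(self, small_model):
        rng = np.random.default_rng(4)
        coords = small_model.reference.coords + 0.2 * rng.standard_normal(
            small_model.reference.coords.shape
        )
        H = enm_core.enm_hessian(small_model, coords).toarray()
        flat = coords.reshape(-1)
        h = 1e-5
        for idx in rng.choice(flat.size, size=8, replace=False):
            fp, fm = flat.copy(), flat.copy()
            fp[idx] += h
            fm[idx] -= h
            _, gp = enm_core.enm_energy_gradient(small_model, fp)
            _, gm = enm_core.enm_energy_gradient(small_model, fm)
            fd_col = (gp - gm).reshape(-1) / (2 * h)
            np.testing.assert_allclose(H[:, idx], fd_col, rtol=1e-5, atol=1e-6)

    def test_symmetric(self, small_model):
        H = enm_core.enm_hessian(small_model)
        assert abs(H - H.T).max() == pytest.approx(0.0, abs=1e-12)


class TestNormalModes:
    def test_two_atom_closed_form(self):
        k = 2.5
        s = Structure(["A", "B"], [1, 1], ["ALA", "ALA"],
                      [[0.0, 0.0, 0.0], [0.0, 0.0, 1.5]])
        m = enm_core.build_enm(s, cutoff=3.0, k_nonbonded=k)
        # a single spring between unit masses vibrates at eigenvalue 2k,
        # but a 2-atom network has only 5 rigid modes; use the dense Hessian
        vals = np.linalg.eigvalsh(enm_core.enm_hessian(m).toarray())
        assert vals[-1] == pytest.approx(2 * k, rel=1e-12)
        assert np.abs(vals[:-1]).max() < 1e-12

    def test_sparse_equals_dense_oracle(self, barrel_pair):
        begin, *_ = barrel_pair
        sub = begin.select(np.isin(begin.chain_ids, ["A", "B"]))
        model = enm_core.build_enm(sub)
        modes_sparse = enm_core.normal_modes(model, 8, dense_threshold=0)
        modes_dense = enm_core.normal_modes(model, 8, dense_threshold=10**6)
        np.testing.assert_allclose(
            modes_sparse.eigenvalues, modes_dense.eigenvalues, atol=1e-8
        )
        for vs, vd in zip(modes_sparse.eigenvectors, modes_dense.eigenvectors):
            assert min(np.abs(vs - vd).max(), np.abs(vs + vd).max()) < 1e-6

    def test_orthonormal_and_positive(self, small_model):
        modes = enm_core.normal_modes(small_model, 10)
        G = modes.eigenvectors @ modes.eigenvectors.T
        np.testing.assert_allclose(G, np.eye(10), atol=1e-8)
        assert np.all(modes.eigenvalues > 0)
        assert np.all(np.diff(modes.eigenvalues) >= -1e-12)

    def test_disconnected_network_reported(self):
        # two chains far apart: no inter-chain springs
        coords = np.vstack([ring_structure(6).coords, ring_structure(6).coords + 100.0])
        s = Structure(["A"] * 6 + ["B"] * 6, list(range(1, 7)) * 2, ["ALA"] * 12, coords)
        model = enm_core.build_enm(s, cutoff=6.0)
        with pytest.raises(enm_core.DisconnectedNetworkError, match="2 connected"):
            enm_core.normal_modes(model, 4)

    def test_masking_never_increases_eigenvalues(self, barrel_pair):
        # spring removal weakens the network: dense-spectrum interlacing
        begin, *_ = barrel_pair
        sub = begin.select(begin.chain_ids == "A")
        full = enm_core.build_enm(sub)
        nb = [(int(i), int(j)) for i, j, b in zip(full.i, full.j, full.bonded) if not b]
        masked = enm_core.build_enm(sub, masked_pairs=set(nb[::7]))
        vals_full = np.linalg.eigvalsh(enm_core.enm_hessian(full).toarray())
        vals_masked = np.linalg.eigvalsh(enm_core.enm_hessian(masked).toarray())
        assert np.all(vals_masked <= vals_full + 1e-10)


class TestOverlap:
    def test_parallel_orthogonal_and_sign_flip(self, small_model):
        modes = enm_core.normal_modes(small_model, 6)
        v = modes.eigenvectors[0]
        assert enm_core.overlap(v, 3.0 * v) == pytest.approx(1.0)
        assert enm_core.overlap(v, modes.eigenvectors[1]) == pytest.approx(0.0, abs=1e-10)
        assert enm_core.overlap(-v, 3.0 * v) == pytest.approx(1.0)

    def test_zero_delta_rejected(self, small_model):
        modes = enm_core.normal_modes(small_model, 1)
        with pytest.raises(ValueError, match="zero"):
            enm_core.overlap(modes.eigenvectors[0], np.zeros(3 * small_model.n_atoms))

    def test_cumulative_overlap_m1_and_monotone(self, small_model):
        modes = enm_core.normal_modes(small_model, 10)
        rng = np.random.default_rng(5)
        delta = rng.standard_normal(3 * small_model.n_atoms)
        assert enm_core.cumulative_overlap(modes, delta, 1) == pytest.approx(
            enm_core.overlap(modes.eigenvectors[0], delta)
        )
        cums = [enm_core.cumulative_overlap(modes, delta, M) for M in range(1, 11)]
        assert np.all(np.diff(cums) >= -1e-12)

    def test_complete_basis_parseval(self, small_model):
        n3 = 3 * small_model.n_atoms
        modes = enm_core.normal_modes(small_model, n3 - 6)
        rng = np.random.default_rng(6)
        delta = rng.standard_normal(n3)
        # remove the rigid-body component so the non-rigid basis is complete
        rigid = enm_core.rigid_body_basis(small_model.reference.coords)
        delta -= rigid.T @ (rigid @ delta)
        assert enm_core.cumulative_overlap(modes, delta) == pytest.approx(1.0, abs=1e-8)


class TestDisplaceAlongMode:
    def test_rmsd_exact_and_reversible(self, small_model):
        modes = enm_core.normal_modes(small_model, 1)
        v = modes.eigenvectors[0]
        s = small_model.reference
        out = enm_core.displace_along_mode(s, v, 3.0)
        rmsd = np.sqrt(np.mean(np.sum((out.coords - s.coords) ** 2, axis=1)))
        assert rmsd == pytest.approx(3.0, abs=1e-10)
        back = enm_core.displace_along_mode(out, -v, 3.0)
        np.testing.assert_allclose(back.coords, s.coords, atol=1e-10)

    def test_zero_displacement_identity(self, small_model):
        modes = enm_core.normal_modes(small_model, 1)
        out = enm_core.displace_along_mode(small_model.reference, modes.eigenvectors[0], 0.0)
        np.testing.assert_array_equal(out.coords, small_model.reference.coords)


def test_scan_cutoff_returns_grid(barrel_pair):
    begin, end, amap, _ = barrel_pair
    from ienm.ienm_path import make_double_well

    dw = make_double_well(begin, end, amap)
    end_sup = begin.with_coords(dw.end_target)
    df = enm_core.scan_cutoff(begin, end_sup, n_modes=5, cutoffs=[8.0, 10.0, 12.0])
    assert list(df["cutoff"]) == [8.0, 10.0, 12.0]
    assert df["cumulative_overlap"].between(0, 1).all()
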