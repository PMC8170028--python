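import numpy as np
import pytest

from flexitomo.nma import (
    ElasticNetwork, ModeSelection, build_hessian, collectivity,
    compute_modes_cartesian, compute_modes_rtb, deform, load_modes,
    pseudoatom_cutoff, rmsd, save_modes, select_modes,
)
from flexitomo.phantoms import make_globular_structure
from flexitomo.structures import AtomicStructure


def tirion_energy(coords_flat, pairs, rest_lengths, k=1.0):
    """Independent scalar Tirion energy for the finite-difference oracle."""
    r = coords_flat.reshape(-1, 3)
    e = 0.0
    for (i, j), d0 in zip(pairs, rest_lengths):
        d = np.linalg.norm(r[i] - r[j])
        e += 0.5 * k * (d - d0) ** 2
    return e


class TestHessian:
    def test_dimer_closed_form(self):
        net = ElasticNetwork([[0.0, 0, 0], [1.0, 0, 0]], cutoff=2.0)
        H = build_hessian(net).toarray()
        w = np.sort(np.linalg.eigvalsh(H))
        np.testing.assert_allclose(w[:5], 0.0, atol=1e-12)
        assert w[5] == pytest.approx(2.0)

    def test_translation_invariance_any_geometry(self, rng):
        net = ElasticNetwork(rng.uniform(-5, 5, (12, 3)), cutoff=6.0)
        H = build_hessian(net)
        for axis in range(3):
            t = np.zeros(36)
            t[axis::3] = 1.0
            np.testing.assert_allclose(H @ t, 0.0, atol=1e-12)

    def test_matches_finite_differences_of_tirion_energy(self, rng):
        coords = rng.uniform(-4, 4, (20, 3))
        net = ElasticNetwork(coords, cutoff=5.0)
        pairs = net.pairs()
        rest = [np.linalg.norm(coords[i] - coords[j]) for i, j in pairs]
        H = build_hessian(net).toarray()
        x0 = coords.ravel().copy()
        h = 1e-5
        num = np.empty_like(H)
        for a in range(len(x0)):
            for b in range(a, len(x0)):
                xs = []
                for sa, sb in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    x = x0.copy()
                    x[a] += sa * h
                    x[b] += sb * h
                    xs.append(tirion_energy(x, pairs, rest))
                num[a, b] = num[b, a] = (xs[0] - xs[1] - xs[2] + xs[3]) / (4 * h * h)
        np.testing.assert_allclose(H, num, atol=1e-5)


class TestCartesianModes:
    def test_dimer_stretch_mode(self):
        net = ElasticNetwork([[0.0, 0, 0], [1.0, 0, 0]], cutoff=2.0)
        ms = compute_modes_cartesian(net, 6)
        np.testing.assert_allclose(ms.eigenvalues[:5], 0.0, atol=1e-10)
        # would-be 7th mode is the bond stretch; request all 6 DOF modes here
        full = compute_modes_cartesian(net, 6)
        assert full.n_modes == 6

    def test_orthonormal_columns(self, rng):
        net = ElasticNetwork(rng.uniform(-5, 5, (15, 3)), cutoff=6.0)
        ms = compute_modes_cartesian(net, 10)
        G = ms.modes.T @ ms.modes
        assert np.abs(G - np.eye(10)).max() < 1e-8

    def test_six_zero_modes_for_connected_network(self, rng):
        net = ElasticNetwork(rng.uniform(-4, 4, (25, 3)), cutoff=7.0)
        ms = compute_modes_cartesian(net, 10)
        assert np.all(ms.eigenvalues[:6] <= 1e-8 * ms.eigenvalues[-1] + 1e-12)
        assert ms.eigenvalues[6] > 1e-6

    def test_agrees_with_dense_full_spectrum(self, rng):
        coords = rng.uniform(-5, 5, (30, 3))
        net = ElasticNetwork(coords, cutoff=6.0)
        ms = compute_modes_cartesian(net, 12)
        brute = np.sort(np.linalg.eigvalsh(build_hessian(net).toarray()))
        np.testing.assert_allclose(ms.eigenvalues, brute[:12], atol=1e-9)


class TestRTB:
    def test_single_block_gives_only_rigid_modes(self):
        s = make_globular_structure(80, atoms_per_residue=80, seed=3)
        ms = compute_modes_rtb(s, residues_per_block=1, cutoff=10.0, n_modes=6)
        assert ms.n_modes == 6
        np.testing.assert_allclose(ms.eigenvalues, 0.0, atol=1e-9)

    def test_reduced_dimension_is_six_per_block(self, small_ref):
        from flexitomo.nma import _block_basis

        res = np.unique(small_ref.residue_index)
        total = 0
        for r in res:
            atoms = small_ref.coords[small_ref.residue_index == r]
            total += _block_basis(atoms).shape[1]
        # every 4-atom non-degenerate residue contributes the full 6 DOFs
        assert total == 6 * len(res)

    def test_low_mode_subspace_overlaps_cartesian(self, rng):
        # 30-residue toy chain (4 atoms per residue) with a gentle curve so
        # the bending-mode spectrum is non-degenerate
        t = np.arange(30) * 3.8
        backbone = np.stack([t, 6 * np.sin(t / 20), 4 * np.cos(t / 28)], axis=1)
        coords = np.repeat(backbone, 4, axis=0) + rng.normal(0, 1.0, (120, 3))
        s = AtomicStructure(coords, residue_index=np.repeat(np.arange(30), 4))
        rtb = compute_modes_rtb(s, residues_per_block=1, cutoff=9.0, n_modes=12)
        cart = compute_modes_cartesian(ElasticNetwork(s.coords, 9.0), 12)
        # principal cosines between the first 3 non-rigid mode subspaces
        A = rtb.modes[:, 6:9]
        B = cart.modes[:, 6:9]
        sv = np.linalg.svd(A.T @ B, compute_uv=False)
        assert sv.min() > 0.9

    def test_rtb_eigenvalues_bound_cartesian_from_above(self):
        s = make_globular_structure(100, atoms_per_residue=4, seed=6)
        rtb = compute_modes_rtb(s, residues_per_block=1, cutoff=9.0, n_modes=10)
        cart = compute_modes_cartesian(ElasticNetwork(s.coords, 9.0), 10)
        # Rayleigh-Ritz on a subspace can only raise eigenvalues
        assert np.all(rtb.eigenvalues >= cart.eigenvalues - 1e-9)


class TestCollectivity:
    def test_uniform_displacement_is_one(self):
        n = 50
        u = np.tile([1.0, 0.0, 0.0], n)
        u /= np.linalg.norm(u)
        assert collectivity(u) == pytest.approx(1.0)

    def test_single_atom_is_one_over_n(self):
        n = 50
        u = np.zeros(3 * n)
        u[0] = 1.0
        assert collectivity(u) == pytest.approx(1.0 / n)

    def test_matches_scalar_formula(self, rng):
        u = rng.normal(size=60)
        u /= np.linalg.norm(u)
        # independent scalar evaluation
        p = [sum(u[3 * i + k] ** 2 for k in range(3)) for i in range(20)]
        total = sum(p)
        ent = -sum((x / total) * np.log(x / total) for x in p if x > 0)
        assert collectivity(u) == pytest.approx(np.exp(ent) / 20, rel=1e-12)

    def test_bounds_on_random_modes(self, rng):
        n = 40
        for _ in range(200):
            u = rng.normal(size=3 * n)
            k = collectivity(u / np.linalg.norm(u))
            assert 1.0 / n - 1e-12 <= k <= 1.0 + 1e-12

    def test_zero_mode_rejected(self):
        with pytest.raises(ValueError):
            collectivity(np.zeros(30))


class TestSelection:
    def test_zero_threshold_gives_modes_7_onwards(self, small_modes):
        sel = select_modes(small_modes, 3, min_collectivity=0.0)
        assert sel.indices == [7, 8, 9]

    def test_rigid_modes_never_selectable(self):
        with pytest.raises(ValueError):
            ModeSelection(indices=[5, 7])

    def test_collectivity_filter_and_manual_extra(self, small_modes):
        kappa = small_modes.collectivities
        thresh = float(np.sort(kappa[6:])[-2])  # keeps exactly 2 candidates
        sel = select_modes(small_modes, 2, min_collectivity=thresh, extra=(11,))
        assert len(sel.indices) == 3
        assert 11 in sel.indices
        assert all(kappa[i - 1] >= thresh for i in sel.indices if i != 11)

    def test_warns_when_too_few_qualify(self, small_modes):
        with pytest.warns(UserWarning):
            sel = select_modes(small_modes, 5, min_collectivity=0.999)
        assert len(sel.indices) < 5

    def test_stable_under_mode_sign_flips(self, small_modes):
        import copy

        flipped = copy.deepcopy(small_modes)
        flipped.modes = -flipped.modes
        flipped.collectivities = np.array([
            collectivity(flipped.modes[:, m]) for m in range(flipped.n_modes)
        ])
        a = select_modes(small_modes, 3, min_collectivity=0.2)
        b = select_modes(flipped, 3, min_collectivity=0.2)
        assert a.indices == b.indices


class TestDeformAndRMSD:
    def test_zero_amplitudes_identity(self, small_ref, small_modes):
        sel = select_modes(small_modes, 2)
        out = deform(small_ref, small_modes, sel, [0.0, 0.0])
        np.testing.assert_array_equal(out.coords, small_ref.coords)

    def test_original_unchanged(self, small_ref, small_modes):
        sel = select_modes(small_modes, 1)
        before = small_ref.coords.copy()
        deform(small_ref, small_modes, sel, [50.0])
        np.testing.assert_array_equal(small_ref.coords, before)

    def test_parseval_identity(self, small_ref, small_modes):
        sel = select_modes(small_modes, 1)
        for a in (1.0, -25.0, 300.0):
            out = deform(small_ref, small_modes, sel, [a])
            expected = abs(a) / np.sqrt(small_ref.n_atoms)
            assert rmsd(small_ref, out) == pytest.approx(expected, abs=1e-10)

    def test_amplitude_count_mismatch(self, small_ref, small_modes):
        sel = select_modes(small_modes, 2)
        with pytest.raises(ValueError):
            deform(small_ref, small_modes, sel, [1.0])

    def test_rmsd_basics(self, rng):
        a = AtomicStructure(rng.normal(size=(30, 3)))
        assert rmsd(a, a) == 0.0
        moved = a.coords.copy()
        moved[4] += [0.0, 3.0, 4.0]  # displacement 5
        assert rmsd(a, AtomicStructure(moved)) == pytest.approx(5 / np.sqrt(30))

    def test_rmsd_matches_scalar_loop(self, rng):
        a = rng.normal(size=(25, 3))
        b = rng.normal(size=(25, 3))
        direct = np.sqrt(sum(
            sum((a[i, k] - b[i, k]) ** 2 for k in range(3)) for i in range(25)
        ) / 25)
        assert rmsd(a, b) == pytest.approx(direct, rel=1e-12)

    def test_rmsd_size_mismatch(self, rng):
        with pytest.raises(ValueError):
            rmsd(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


class TestPseudoatomCutoff:
    def test_equilateral_triangle(self):
        pts = [[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]]
        for q in (0.01, 0.5, 1.0):
            assert pseudoatom_cutoff(np.array(pts), q) == pytest.approx(1.0)

    def test_full_percentile_is_max_distance(self, rng):
        pts = rng.uniform(-3, 3, (20, 3))
        from scipy.spatial.distance import pdist

        assert pseudoatom_cutoff(pts, 1.0) == pytest.approx(pdist(pts).max())

    def test_matches_bruteforce_sorted_pairs(self, rng):
        pts = rng.uniform(0, 10, (30, 3))
        d = sorted(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(30) for j in range(i + 1, 30)
        )
        got = pseudoatom_cutoff(pts, 0.1)
        assert np.quantile(d, 0.1) == pytest.approx(got)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            pseudoatom_cutoff(np.zeros((5, 3)), 0.5)


def test_modes_persist_roundtrip(tmp_path, small_modes):
    save_modes(small_modes, tmp_path / "modes")
    back = load_modes(tmp_path / "modes")
    np.testing.assert_allclose(back.modes, small_modes.modes, atol=1e-9)
    np.testing.assert_allclose(back.eigenvalues, small_modes.eigenvalues, atol=1e-12)
    np.testing.assert_array_equal(back.mode_numbering, small_modes.mode_numbering)
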