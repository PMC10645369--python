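import numpy as np
import pytest

from pottsfocus.alignment import Q, encode_sequence
from pottsfocus.lattice import (
    N_CONTACTS,
    N_SITES,
    GroundTruth,
    LatticeWorld,
    SamplerConfig,
    cube_symmetries,
    fold_energy,
    ground_truth_effects,
    make_world,
    metropolis_sample,
    numeric_bias_variance,
    select_wildtype,
)
from pottsfocus.mj import mj_matrix


class TestGeometry:
    def test_symmetry_group_size_and_closure(self):
        syms = cube_symmetries()
        assert syms.shape == (48, 27)
        # all distinct permutations, identity included
        assert len({tuple(s) for s in syms}) == 48
        assert any(np.array_equal(s, np.arange(27)) for s in syms)

    def test_every_fold_is_a_compact_self_avoiding_walk(self, repertoire):
        paths = repertoire.paths
        # every fold visits each cube site exactly once
        assert np.all(np.sort(paths, axis=1) == np.arange(27)[None, :])
        # consecutive residues are lattice nearest neighbours
        coords = np.stack([paths % 3, (paths // 3) % 3, paths // 9], axis=2)
        steps = np.abs(np.diff(coords, axis=1)).sum(axis=2)
        assert np.all(steps == 1)

    def test_contact_count_identity(self, repertoire):
        # 54 cube edges minus the 26 chain bonds leaves 28 contacts
        assert repertoire.contacts.shape[1:] == (N_CONTACTS, 2)
        gaps = repertoire.contacts[:, :, 1] - repertoire.contacts[:, :, 0]
        assert gaps.min() >= 2  # never adjacent along the chain

    def test_canonical_forms_are_unique(self, repertoire):
        sample = repertoire.paths[::500]
        keys = {tuple(p) for p in sample}
        assert len(keys) == len(sample)


class TestMjMatrix:
    def test_symmetric_and_hydrophobic_core(self):
        mj = mj_matrix()
        assert np.allclose(mj, mj.T)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        # strongest attraction among hydrophobics, weakest among charged/small
        assert mj[aa.index("F"), aa.index("F")] == pytest.approx(-7.26)
        assert mj[aa.index("K"), aa.index("K")] == pytest.approx(-0.12)


class TestEnergiesAndFitness:
    def test_homopolymer_energy(self, repertoire):
        mj = mj_matrix()
        seq = np.full(27, 3, dtype=np.int8)
        e = fold_energy(repertoire.contacts[0], seq, mj)
        assert e == pytest.approx(28 * mj[3, 3])

    def test_zero_matrix_gives_zero(self, repertoire):
        seq = np.arange(27, dtype=np.int8) % 20
        assert fold_energy(repertoire.contacts[5], seq, np.zeros((20, 20))) == 0.0

    def test_bruteforce_energy(self, repertoire, rng):
        mj = mj_matrix()
        seq = rng.integers(0, 20, size=27).astype(np.int8)
        contacts = repertoire.contacts[123]
        expected = sum(mj[seq[a], seq[b]] for a, b in contacts)
        assert fold_energy(contacts, seq, mj) == pytest.approx(expected)

    def test_gap_rejected(self, repertoire):
        seq = np.full(27, 20, dtype=np.int8)
        with pytest.raises(ValueError):
            fold_energy(repertoire.contacts[0], seq, mj_matrix())

    def test_pnat_closed_forms(self, repertoire):
        seq = np.arange(27, dtype=np.int8) % 20
        # single-fold world: P_nat = 1, H = 0
        world1 = LatticeWorld(contacts=repertoire.contacts[:1].copy(),
                              native_path=repertoire.paths[0].copy(),
                              fold_ids=np.array([0]))
        assert world1.p_nat(seq) == pytest.approx(1.0)
        assert world1.fitness(seq) == pytest.approx(0.0)
        # two identical folds: P_nat = 0.5
        world2 = LatticeWorld(contacts=np.repeat(repertoire.contacts[:1], 2, axis=0),
                              native_path=repertoire.paths[0].copy(),
                              fold_ids=np.array([0, 0]))
        assert world2.p_nat(seq) == pytest.approx(0.5)

    def test_pnat_softmax_toy(self, repertoire):
        # 3-fold world with energies (e0, e1, e2): closed-form softmax
        world = LatticeWorld(contacts=repertoire.contacts[:3].copy(),
                             native_path=repertoire.paths[0].copy(),
                             fold_ids=np.arange(3))
        seq = np.arange(27, dtype=np.int8) % 20
        e = world.energies(seq)
        expected = np.exp(-e[0]) / np.exp(-e).sum()
        assert world.p_nat(seq) == pytest.approx(expected)

    def test_pnat_invariant_under_decoy_order(self, small_world, rng):
        seq = rng.integers(0, 20, size=27).astype(np.int8)
        perm = np.concatenate(([0], 1 + rng.permutation(small_world.n_folds - 1)))
        shuffled = LatticeWorld(contacts=small_world.contacts[perm].copy(),
                                native_path=small_world.native_path.copy(),
                                fold_ids=small_world.fold_ids[perm])
        assert shuffled.p_nat(seq) == pytest.approx(small_world.p_nat(seq), abs=1e-12)


class TestWildtype:
    def test_window_and_positive_mutations(self, small_world, small_wt):
        pnat = small_world.p_nat(small_wt)
        assert 0.990 <= pnat <= 0.997
        truth = ground_truth_effects(small_world, small_wt)
        assert (truth.effects[truth.mask] < 0).any()  # beneficial mutations exist

    def test_deterministic(self, small_world, small_wt):
        again = select_wildtype(small_world, seed=2)
        assert np.array_equal(small_wt, again)


class TestGroundTruth:
    def test_shapes_and_wt_zero(self, small_world, small_wt):
        truth = ground_truth_effects(small_world, small_wt)
        assert truth.effects.shape == (27, 20)
        assert np.all(truth.effects[np.arange(27), small_wt] == 0.0)
        assert truth.mask.sum() <= 27 * 19
        assert not truth.mask[np.arange(27), small_wt].any()

    def test_effects_match_direct_recomputation(self, small_world, small_wt):
        truth = ground_truth_effects(small_world, small_wt)
        h_wt = small_world.fitness(small_wt)
        for i, a in [(0, 1), (13, 7), (26, 19)]:
            if a == small_wt[i]:
                continue
            mut = small_wt.copy()
            mut[i] = a
            assert truth.effects[i, a] == pytest.approx(
                small_world.fitness(mut) - h_wt, abs=1e-9
            )

    def test_theta_masks_outliers(self, small_world, small_wt):
        truth = ground_truth_effects(small_world, small_wt, theta=0.5)
        assert truth.n_observable < 27 * 19
        assert np.all(np.abs(truth.effects[truth.mask]) < 0.5)


class TestMetropolis:
    def test_deterministic_under_seed(self, small_world, small_wt):
        cfg = SamplerConfig(gamma=0.05, n_samples=40, n_chains=2, seed=9)
        a1 = metropolis_sample(small_world, small_wt, cfg)
        a2 = metropolis_sample(small_world, small_wt, cfg)
        assert np.array_equal(a1.seqs, a2.seqs)

    def test_mean_distance_decreases_with_gamma(self, small_world, small_wt):
        means = []
        for gamma in (0.0, 0.05):
            vals = []
            for seed in range(3):
                cfg = SamplerConfig(gamma=gamma, n_samples=60, n_chains=3,
                                    seed=100 + seed)
                aln = metropolis_sample(small_world, small_wt, cfg)
                vals.append(aln.distances_to_wt().mean())
            means.append(np.mean(vals))
        assert means[1] < means[0]

    def test_unit_weights_and_wt_start(self, small_world, small_wt):
        cfg = SamplerConfig(gamma=0.0, n_samples=10, seed=4)
        aln = metropolis_sample(small_world, small_wt, cfg)
        assert np.all(aln.weights == 1.0)
        assert aln.n_rows == 10 and aln.n_sites == N_SITES

    def test_sampled_sequences_stay_fit(self, small_world, small_wt):
        # beta = 1000 confines the chain to the high-P_nat network
        cfg = SamplerConfig(gamma=0.0, n_samples=30, n_chains=3, seed=7)
        aln = metropolis_sample(small_world, small_wt, cfg)
        pnats = np.array([small_world.p_nat(s) for s in aln.seqs])
        assert np.median(pnats) > 0.9


class TestNumericBiasVariance:
    def test_perfect_predictor_is_zero(self, small_world, small_wt):
        truth = ground_truth_effects(small_world, small_wt)
        preds = [truth.fitness_effects.copy() for _ in range(3)]
        mu2, s2, _ = numeric_bias_variance(preds, truth)
        assert mu2 == pytest.approx(0.0, abs=1e-18)
        assert s2 == pytest.approx(0.0, abs=1e-18)

    def test_known_shift_and_noise(self, small_world, small_wt, rng):
        truth = ground_truth_effects(small_world, small_wt)
        # constant shift contributes nothing (rank correlations ignore it)
        preds = [truth.fitness_effects + 3.0 for _ in range(4)]
        mu2, s2, _ = numeric_bias_variance(preds, truth)
        assert mu2 == pytest.approx(0.0, abs=1e-18)
        # pure noise contributes variance, not (much) bias
        noisy = [truth.fitness_effects + rng.normal(scale=0.3, size=(27, 20))
                 for _ in range(50)]
        mu2, s2, _ = numeric_bias_variance(noisy, truth)
        assert s2 == pytest.approx(0.09, rel=0.15)
        assert mu2 < 0.01

    def test_requires_repeats_and_mask(self, small_world, small_wt):
        truth = ground_truth_effects(small_world, small_wt)
        with pytest.raises(ValueError):
            numeric_bias_variance([truth.effects], truth)
        empty = GroundTruth(wt=small_wt, effects=truth.effects, theta=0.0,
                            mask=np.zeros_like(truth.mask))
        with pytest.raises(ValueError):
            numeric_bias_variance([truth.effects, truth.effects], empty)


class TestStructuralFormula:
    def test_equal_variances_make_curve_linear(self):
        # with V_struct = V_nonstruct = v the effective curve is exactly
        # linear in K: J0(K) = (Kmax - K) * v
        nc, kmax, v = 28, 351, 0.7
        def j0(k):
            return (nc - min(k, nc)) * v + (kmax - nc - max(0, k - nc)) * v
        ks = np.arange(0, 60)
        vals = np.array([j0(k) for k in ks])
        assert np.allclose(np.diff(vals), -v)
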