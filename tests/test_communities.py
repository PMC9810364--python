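import numpy as np
import pytest

from conftest import random_symmetric_stack, set_partitions
from dynconn.communities import (
    REFERENCE_PRESET,
    CommunitySequence,
    MultilayerParams,
    louvain_multilayer,
    multilayer_modularity,
    repeat_detection,
    shuffled_null,
    sweep_parameters,
)
from dynconn.communities import _supra_modularity
from dynconn.metrics import flexibility


def _two_cliques():
    A = np.zeros((6, 6))
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                if i != j:
                    A[i, j] = 1.0
    return A[None, :, :]


def brute_force_max_q(stack, params):
    """Exhaustive best-partition search over all node-layer set partitions."""
    L, N, _ = stack.shape
    B, two_mu = _supra_modularity(stack, params.gamma, params.omega)
    B = B.toarray()
    best = -np.inf
    for part in set_partitions(N * L):
        lab = np.asarray(part)
        q = B[lab[:, None] == lab[None, :]].sum() / two_mu
        if q > best:
            best = q
    return best


class TestParams:
    def test_reference_preset(self):
        assert REFERENCE_PRESET.gamma == pytest.approx(1.1364)
        assert REFERENCE_PRESET.omega == pytest.approx(0.5)
        assert REFERENCE_PRESET.n_iterations == 100

    @pytest.mark.parametrize("kwargs", [
        {"gamma": 0.0}, {"gamma": -1.0}, {"omega": -0.1},
        {"n_iterations": 0}, {"gamma": np.inf},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            MultilayerParams(**kwargs)


class TestModularity:
    def test_two_clique_closed_form(self):
        labels = np.array([[1], [1], [1], [2], [2], [2]])
        q = multilayer_modularity(_two_cliques(), labels,
                                  MultilayerParams(gamma=1.0, omega=0.0))
        assert q == pytest.approx(0.5)

    def test_one_community_single_layer(self, rng):
        stack = random_symmetric_stack(rng, 5, 1)
        labels = np.ones((5, 1), dtype=int)
        q = multilayer_modularity(stack, labels, MultilayerParams(1.0, 0.0))
        # single community: within-layer term cancels exactly
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_omega_zero_equals_sum_of_layer_terms(self, rng):
        stack = random_symmetric_stack(rng, 5, 3)
        labels = rng.integers(1, 3, size=(5, 3))
        q_multi = multilayer_modularity(stack, labels, MultilayerParams(1.0, 0.0))
        per_layer = 0.0
        for l in range(3):
            A = stack[l]
            k = A.sum(1)
            m2 = k.sum()
            lab = labels[:, l]
            same = lab[:, None] == lab[None, :]
            per_layer += (A[same].sum() - np.outer(k, k)[same].sum() / m2)
        total = sum(stack[l].sum() for l in range(3))
        assert q_multi == pytest.approx(per_layer / total)

    def test_relabeling_invariance(self, rng):
        stack = random_symmetric_stack(rng, 4, 2)
        labels = rng.integers(1, 3, size=(4, 2))
        params = MultilayerParams(1.1, 0.4)
        q1 = multilayer_modularity(stack, labels, params)
        q2 = multilayer_modularity(stack, labels + 7, params)
        assert q1 == pytest.approx(q2)

    def test_shape_mismatch_rejected(self, rng):
        stack = random_symmetric_stack(rng, 4, 2)
        with pytest.raises(ValueError, match="shape"):
            multilayer_modularity(stack, np.ones((3, 2), int),
                                  MultilayerParams())

    def test_zero_layer_warns(self):
        stack = np.zeros((2, 3, 3))
        stack[1] = 0.5 * (1 - np.eye(3))
        with pytest.warns(UserWarning, match="zero total weight"):
            multilayer_modularity(stack, np.ones((3, 2), int),
                                  MultilayerParams(1.0, 0.1))


class TestLouvain:
    def test_recovers_two_cliques(self):
        stack = np.repeat(_two_cliques(), 3, axis=0)
        res = louvain_multilayer(stack, MultilayerParams(1.0, 0.5, seed=0))
        assert res.n_communities == 2
        # each clique uniform across nodes and layers
        assert len(set(res.labels[:3].ravel())) == 1
        assert len(set(res.labels[3:].ravel())) == 1

    def test_identical_layers_strong_coupling_freezes_labels(self, rng):
        A = random_symmetric_stack(rng, 6, 1)[0]
        stack = np.repeat(A[None], 8, axis=0)
        res = louvain_multilayer(stack, MultilayerParams(1.0, 1.0, seed=1))
        assert flexibility(res.labels).xi.max() == 0.0

    def test_beats_reference_partitions(self, rng):
        stack = random_symmetric_stack(rng, 6, 3)
        params = MultilayerParams(1.0, 0.5, seed=2)
        res = louvain_multilayer(stack, params)
        singletons = np.arange(1, 7)[:, None] + np.arange(3)[None, :] * 6
        q_single = multilayer_modularity(stack, singletons, params)
        q_one = multilayer_modularity(stack, np.ones((6, 3), int), params)
        assert res.quality >= q_single - 1e-12
        assert res.quality >= q_one - 1e-12

    def test_quality_matches_independent_evaluation(self, rng):
        stack = random_symmetric_stack(rng, 5, 3)
        params = MultilayerParams(1.1, 0.3, seed=3)
        res = louvain_multilayer(stack, params)
        assert res.quality == pytest.approx(
            multilayer_modularity(stack, res.labels, params))

    def test_deterministic_given_seed(self, rng):
        stack = random_symmetric_stack(rng, 6, 4)
        params = MultilayerParams(1.0, 0.5, seed=11)
        a = louvain_multilayer(stack, params)
        b = louvain_multilayer(stack, params)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_small_instances_rejected(self, rng):
        with pytest.raises(ValueError):
            louvain_multilayer(random_symmetric_stack(rng, 5, 1),
                               MultilayerParams())
        with pytest.raises(ValueError):
            louvain_multilayer(random_symmetric_stack(rng, 1, 5),
                               MultilayerParams())

    def test_nonfinite_rejected(self):
        stack = np.full((2, 3, 3), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            louvain_multilayer(stack, MultilayerParams())


class TestBruteForceOracle:
    @pytest.mark.parametrize("n,l", [(4, 2), (3, 3)])
    def test_louvain_never_exceeds_and_usually_matches(self, n, l):
        rng = np.random.default_rng(100 + n * 10 + l)
        matches = 0
        trials = 8
        for t in range(trials):
            stack = random_symmetric_stack(rng, n, l)
            params = MultilayerParams(gamma=1.0, omega=0.3, seed=t)
            bq = brute_force_max_q(stack, params)
            lq = louvain_multilayer(stack, params).quality
            assert lq <= bq + 1e-9
            if abs(lq - bq) < 1e-9:
                matches += 1
        assert matches >= 0.9 * trials


class TestShuffledNull:
    def test_weight_multiset_preserved_per_layer(self, rng):
        stack = random_symmetric_stack(rng, 6, 4)
        null = shuffled_null(stack, seed=5)
        for l in range(4):
            np.testing.assert_allclose(np.sort(stack[l].ravel()),
                                       np.sort(null[l].ravel()))

    def test_single_layer_rejected(self, rng):
        with pytest.raises(ValueError, match="L >= 2"):
            shuffled_null(random_symmetric_stack(rng, 5, 1), seed=0)

    def test_planted_stack_real_beats_null(self):
        rng = np.random.default_rng(7)
        truth = np.array([1] * 5 + [2] * 5)
        stack = np.zeros((6, 10, 10))
        for l in range(6):
            W = 0.05 * rng.random((10, 10)) + 0.8 * (truth[:, None] == truth[None, :])
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            stack[l] = W
        params = MultilayerParams(1.0, 0.5, seed=8)
        q_real = np.mean([
            louvain_multilayer(stack, params,
                               rng=np.random.default_rng(i)).quality
            for i in range(3)
        ])
        q_null = np.mean([
            louvain_multilayer(shuffled_null(stack, seed=i), params,
                               rng=np.random.default_rng(i)).quality
            for i in range(3)
        ])
        assert q_real > q_null


class TestSweep:
    def _planted_stack(self, seed=9):
        rng = np.random.default_rng(seed)
        truth = np.array([1] * 4 + [2] * 4)
        stack = np.zeros((5, 8, 8))
        for l in range(5):
            W = 0.05 * rng.random((8, 8)) + 0.7 * (truth[:, None] == truth[None, :])
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0)
            stack[l] = W
        return stack, truth

    def test_degenerate_single_cell_grid(self):
        stack, _ = self._planted_stack()
        res = sweep_parameters(stack, gamma_grid=[1.05], omega_grid=[0.5],
                               n_null=2, n_runs=2, seed=0)
        assert res.selected == (1.05, 0.5)
        assert res.mean_communities[0, 0] > 1

    def test_planted_recovery_under_sweep(self):
        from sklearn.metrics import adjusted_rand_score

        stack, truth = self._planted_stack()
        res = sweep_parameters(stack, gamma_grid=[0.8, 1.0, 1.2],
                               omega_grid=[0.5], n_null=2, n_runs=2, seed=1)
        g, o = res.selected
        best = louvain_multilayer(stack, MultilayerParams(g, o, seed=2))
        ari = adjusted_rand_score(truth, best.labels[:, 0])
        assert ari >= 0.9

    def test_empty_grid_rejected(self):
        stack, _ = self._planted_stack()
        with pytest.raises(ValueError, match="nonempty"):
            sweep_parameters(stack, gamma_grid=[], omega_grid=[0.5])

    def test_no_multicommunity_cell_rejected(self, rng):
        # tiny gamma on a dense uniform stack -> one giant community
        stack = np.repeat((0.5 * (1 - np.eye(4)))[None], 3, axis=0)
        with pytest.raises(ValueError, match="more than one community"):
            sweep_parameters(stack, gamma_grid=[0.01], omega_grid=[1.0],
                             n_null=1, n_runs=1, seed=0)


class TestRepeatDetection:
    def test_singleton_ensemble(self, rng):
        stack = random_symmetric_stack(rng, 5, 3)
        params = MultilayerParams(1.0, 0.5, n_iterations=1, seed=3)
        (only,) = repeat_detection(stack, params)
        assert isinstance(only, CommunitySequence)

    def test_master_seed_reproducibility(self, rng):
        stack = random_symmetric_stack(rng, 5, 3)
        params = MultilayerParams(1.0, 0.5, n_iterations=4, seed=21)
        e1 = repeat_detection(stack, params)
        e2 = repeat_detection(stack, params)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_stability_on_easy_instance(self):
        from sklearn.metrics import adjusted_rand_score

        stack = np.repeat(_two_cliques(), 3, axis=0)
        ensemble = repeat_detection(stack, MultilayerParams(1.0, 0.5,
                                                            n_iterations=10,
                                                            seed=4))
        base = ensemble[0].labels.ravel()
        aris = [adjusted_rand_score(base, e.labels.ravel()) for e in ensemble[1:]]
        assert min(aris) >= 0.8


class TestOmegaMonotonicity:
    def test_mean_flexibility_weakly_decreases_with_omega(self):
        rng = np.random.default_rng(30)
        for trial in range(5):
            stack = random_symmetric_stack(rng, 6, 6)
            means = []
            for omega in (0.0, 0.5, 2.0):
                params = MultilayerParams(1.0, omega, n_iterations=8,
                                          seed=trial)
                ens = repeat_detection(stack, params)
                means.append(np.mean([flexibility(e.labels).xi.mean()
                                      for e in ens]))
            assert means[0] >= means[1] - 0.05
            assert means[1] >= means[2] - 0.05
            assert means[0] >= means[2] - 0.05
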