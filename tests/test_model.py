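import numpy as np
import pytest

from cregulon import (
    CRegulonModel,
    fit_decomposition,
    initialize,
    objective,
    select_mu,
)
from cregulon.model import elbow_point, select_n_modules


def random_instance(rng, m=6, k=3, l=2):
    """Random symmetric C matrices in [0, 1]."""
    c_list = []
    for _ in range(k):
        sym = rng.uniform(0, 1, size=(m, m))
        c_list.append((sym + sym.T) / 2)
    return c_list


class TestObjective:
    def test_zero_factors(self, rng):
        c_list = random_instance(rng)
        x = np.zeros((6, 2))
        a = np.full((3, 2), 0.5)
        expected = sum((c**2).sum() for c in c_list)
        assert objective(c_list, x, a, mu=1.0) == pytest.approx(expected)

    def test_exact_fit_zero(self):
        x = np.array([[0.6, 0.0], [0.5, 0.0], [0.0, 0.7]])
        a = np.array([[0.3, 0.7]])
        c = (x * a[0]) @ x.T
        assert objective([c], x, a, mu=0.0) == pytest.approx(0.0, abs=1e-15)

    def test_loop_oracle(self, rng):
        m, k, l = 5, 3, 2
        c_list = random_instance(rng, m, k, l)
        x = rng.uniform(0, 1, size=(m, l))
        a = rng.uniform(0, 1, size=(k, l))
        mu = 0.7
        expected = 0.0
        for kk in range(k):
            recon = np.zeros((m, m))
            for i in range(m):
                for j in range(m):
                    for ll in range(l):
                        recon[i, j] += x[i, ll] * a[kk, ll] * x[j, ll]
            expected += ((c_list[kk] - recon) ** 2).sum()
            expected -= mu * np.abs(c_list[kk] * recon).sum()
        assert objective(c_list, x, a, mu) == pytest.approx(expected, abs=1e-10)


class TestInitialize:
    def test_uniform_association_rows(self, rng):
        c_list = random_instance(rng, m=5, k=4, l=2)
        _x0, a0 = initialize(c_list, 2, seed=0)
        np.testing.assert_allclose(a0, np.full((4, 2), 0.5))

    def test_rank_one_direction(self):
        v = np.array([0.6, 0.5, 0.3, 0.1])
        c = np.outer(v, v)
        x0, _a0 = initialize([c], 1, seed=0)
        cos = x0[:, 0] @ v / (np.linalg.norm(x0) * np.linalg.norm(v))
        assert cos > 0.999

    def test_mean_of_identical_matrices(self, rng):
        c = random_instance(rng, m=4, k=1)[0]
        x_single, _ = initialize([c], 2, seed=3)
        x_repeated, _ = initialize([c, c, c], 2, seed=3)
        np.testing.assert_allclose(x_single, x_repeated)

    def test_too_many_modules(self, rng):
        with pytest.raises(ValueError, match="modules"):
            initialize(random_instance(rng, m=3), 4, seed=0)


class TestSelectMu:
    def test_perfect_initial_fit(self):
        x0 = np.array([[0.6], [0.5]])
        a0 = np.array([[1.0]])
        c = (x0 * a0[0]) @ x0.T
        assert select_mu([c], x0, a0) == 0.0

    def test_degenerate_guard(self, rng):
        c_list = random_instance(rng, m=4, k=2)
        x0 = np.zeros((4, 2))
        a0 = np.full((2, 2), 0.5)
        with pytest.warns(UserWarning, match="mu"):
            assert select_mu(c_list, x0, a0) == 0.0

    def test_hand_computation(self):
        c = np.array([[0.5, 0.2], [0.2, 0.4]])
        x0 = np.array([[0.5], [0.4]])
        a0 = np.array([[1.0]])
        recon = (x0 * a0[0]) @ x0.T
        expected = ((c - recon) ** 2).sum() / (c * recon).sum()
        assert select_mu([c], x0, a0) == pytest.approx(expected, rel=1e-12)


class TestFit:
    def test_rank_one_recovery(self):
        v = np.array([0.6, 0.5, 0.4, 0.0, 0.0])
        res = fit_decomposition([np.outer(v, v)], 1, seed=0)
        cos = res.x[:, 0] @ v / (np.linalg.norm(res.x) * np.linalg.norm(v))
        assert cos > 0.99
        np.testing.assert_allclose(res.a, [[1.0]])

    def test_block_diagonal_support(self):
        b1 = np.outer([0.7, 0.6, 0, 0], [0.7, 0.6, 0, 0])
        b2 = np.outer([0, 0, 0.6, 0.7], [0, 0, 0.6, 0.7])
        res = fit_decomposition([b1 + 0.3 * b2, 0.3 * b1 + b2], 2, seed=1)
        # each column is supported on one block
        support = res.x > 0.05
        blocks = [frozenset(np.nonzero(support[:, l])[0]) for l in range(2)]
        assert set(blocks) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_all_zero_matrices(self):
        res = fit_decomposition([np.zeros((4, 4))] * 2, 2, seed=0)
        assert res.x.max() == pytest.approx(0.0, abs=1e-8)
        assert res.loss_trace[-1] == pytest.approx(0.0, abs=1e-12)

    def test_reproducible_bitwise(self, rng):
        c_list = random_instance(rng)
        r1 = fit_decomposition(c_list, 2, seed=42)
        r2 = fit_decomposition(c_list, 2, seed=42)
        assert np.array_equal(r1.loss_trace, r2.loss_trace)
        assert np.array_equal(r1.x, r2.x)
        assert np.array_equal(r1.a, r2.a)

    def test_permutation_equivariant_updates(self, rng):
        c_list = random_instance(rng, m=5, k=2)
        x_init = rng.uniform(0.1, 1.0, size=(5, 2))
        perm = rng.permutation(5)
        res = fit_decomposition(c_list, 2, mu=1.0, seed=0, x_init=x_init)
        res_p = fit_decomposition(
            [c[np.ix_(perm, perm)] for c in c_list],
            2,
            mu=1.0,
            seed=0,
            x_init=x_init[perm],
        )
        np.testing.assert_allclose(res_p.x, res.x[perm], atol=1e-10)
        np.testing.assert_allclose(res_p.loss_trace, res.loss_trace, atol=1e-10)

    def test_descent_and_constraints_on_random_instances(self, rng):
        for _ in range(5):
            c_list = random_instance(rng, m=6, k=3)
            res = fit_decomposition(c_list, 2, seed=0)
            assert res.loss_trace[-1] <= res.loss_trace[0] + 1e-10
            col_norms = np.sqrt((res.x**2).sum(axis=0))
            assert (res.x >= 0).all()
            assert (col_norms <= 1 + 1e-8).all()
            assert (res.x.sum(axis=1) <= 1 + 1e-8).all()
            np.testing.assert_allclose(res.a.sum(axis=1), 1.0, atol=1e-8)
            assert np.isfinite(res.loss_trace).all()


class TestModelResults:
    def test_from_effects_and_summary(self, rng):
        c_list = random_instance(rng, m=5, k=3)
        model = CRegulonModel(c_list, tf_ids=[f"T{i}" for i in range(5)])
        res = model.fit(2, seed=0)
        assert res.x_frame.shape == (5, 2)
        assert list(res.a_frame.columns) == ["M1", "M2"]
        text = res.summary()
        assert "modules: 2" in text and "mu" in text

    def test_top_tfs_ranked(self):
        import dataclasses

        from cregulon import CRegulonResults

        res = CRegulonResults(
            x=np.array([[0.1, 0.0], [0.9, 0.0], [0.5, 0.7]]),
            a=np.array([[0.5, 0.5]]),
            mu=0.0,
            n_modules=2,
            loss_trace=np.array([0.0]),
            seed=0,
            converged=True,
            tf_ids=["A", "B", "C"],
        )
        assert res.top_tfs(0) == ["B", "C", "A"]
        assert res.top_tfs(1) == ["C"]  # zero loadings are not members
        assert dataclasses.is_dataclass(res)


class TestSelectNModules:
    def test_elbow_hand_examples(self):
        # flat losses -> smallest candidate; the printed sequence -> 2
        assert elbow_point([1, 2, 3], [5.0, 5.0, 5.0]) == 1
        assert elbow_point([1, 2, 3, 4], [100.0, 40.0, 38.0, 37.0]) == 2

    def test_returns_loss_table(self, rng):
        c_list = random_instance(rng, m=5, k=2)
        chosen, table = select_n_modules(c_list, [1, 2, 3], seed=0)
        assert chosen in {1, 2, 3}
        assert list(table.columns) == ["n_modules", "loss"]
        assert len(table) == 3
        assert (table["loss"] >= 0).all()

    def test_rejects_unsorted_range(self, rng):
        with pytest.raises(ValueError):
            select_n_modules(random_instance(rng), [3, 1], seed=0)
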