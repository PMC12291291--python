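import numpy as np
import pytest
from scipy import integrate, stats

from cregulon import (
    RegulatoryNetwork,
    attach_res,
    pair_effects,
    select_targets,
    significant_tf_pairs,
)


class TestPairEffects:
    def test_outer_product_oracle(self, rng):
        x = rng.uniform(0, 1, size=(6, 3))
        ce = pair_effects(x, 1)
        for i in range(6):
            for j in range(6):
                assert ce[i, j] == pytest.approx(x[i, 1] * x[j, 1])

    def test_zero_loading_zero_row(self):
        x = np.array([[0.0, 0.3], [0.8, 0.1], [0.5, 0.2]])
        ce = pair_effects(x, 0)
        assert (ce[0, :] == 0).all()
        assert ce[1, 2] == pytest.approx(0.4)

    def test_module_out_of_range(self):
        with pytest.raises(IndexError):
            pair_effects(np.ones((3, 2)), 2)


class TestSignificantTfPairs:
    def test_exchangeable_null_gives_no_pairs(self):
        ce = np.full((6, 6), 0.2)
        pairs, params = significant_tf_pairs(ce, alpha=0.05)
        assert pairs == []
        assert params is not None

    def test_planted_module_recovered_against_null_bulk(self, rng):
        # 3 strongly loaded TFs among 20 weakly loaded ones: exactly the 3
        # within-module pairs should clear the Gamma null
        x = np.zeros((20, 1))
        x[:3, 0] = 0.55
        x[3:, 0] = rng.uniform(0.005, 0.04, 17)
        pairs, _ = significant_tf_pairs(pair_effects(x, 0), alpha=0.05)
        assert {(p[0], p[1]) for p in pairs} == {
            ("TF1", "TF2"),
            ("TF1", "TF3"),
            ("TF2", "TF3"),
        }

    def test_pvalues_match_numerical_tail_integration(self, rng):
        x = np.concatenate([rng.uniform(0.3, 0.7, 4), rng.uniform(0.0, 0.1, 8)])
        ce = np.outer(x, x)
        pairs, (shape, scale) = significant_tf_pairs(ce, alpha=0.5)
        assert pairs
        for _tf1, _tf2, value, p in pairs[:5]:
            tail, _err = integrate.quad(
                lambda t: stats.gamma.pdf(t, shape, scale=scale), value, np.inf
            )
            assert p == pytest.approx(tail, abs=1e-6)

    def test_monotone_in_alpha(self, rng):
        x = rng.uniform(0, 1, size=12)
        ce = np.outer(x, x)
        loose, _ = significant_tf_pairs(ce, alpha=0.1)
        strict, _ = significant_tf_pairs(ce, alpha=0.01)
        assert {(p[0], p[1]) for p in strict} <= {(p[0], p[1]) for p in loose}

    def test_canonical_pair_order(self, rng):
        x = rng.uniform(0, 1, size=9)
        labels = [f"TF{i + 1}" for i in range(9)]
        pairs, _ = significant_tf_pairs(np.outer(x, x), alpha=0.9)
        seen = set()
        for tf1, tf2, ce, _p in pairs:
            # upper triangle only: first index below second, no duplicates
            assert labels.index(tf1) < labels.index(tf2)
            assert (tf1, tf2) not in seen
            seen.add((tf1, tf2))
        assert [p[2] for p in pairs] == sorted((p[2] for p in pairs), reverse=True)

    def test_unfittable_null(self):
        ce = np.zeros((5, 5))
        ce[0, 1] = ce[1, 0] = 0.5
        with pytest.warns(UserWarning, match="Gamma"):
            pairs, params = significant_tf_pairs(ce, alpha=0.05)
        assert pairs == [] and params is None


def toy_network(strength, triplets=()):
    strength = np.asarray(strength, dtype=float)
    return RegulatoryNetwork(
        cluster_id="c1",
        strength=strength,
        tf_ids=[f"TF{i + 1}" for i in range(strength.shape[0])],
        tg_ids=[f"TG{j + 1}" for j in range(strength.shape[1])],
        triplets=list(triplets),
    )


class TestSelectTargets:
    def test_one_hot_column_rank_one_algebra(self, rng):
        r = rng.uniform(0.1, 1, size=(3, 5))
        net = toy_network(r)
        x = np.zeros((3, 2))
        x[1, 0] = 0.8
        edges, (mean, sd) = select_targets(x, 0, net, ["TF2"], alpha_tg=0.999)
        # S row for TF2 is 0.8^2 * R_2; all its TGs are candidates
        scores = {tg: s for _tf, tg, s, _p in edges}
        for j in range(5):
            assert scores[f"TG{j + 1}"] == pytest.approx(0.64 * r[1, j])

    def test_constant_scores_select_nothing(self):
        net = toy_network(np.full((2, 4), 0.5))
        x = np.array([[0.5, 0.0], [0.5, 0.0]])
        edges, _ = select_targets(x, 0, net, ["TF1", "TF2"], alpha_tg=0.01)
        assert edges == []

    def test_loop_oracle_equivalence(self, rng):
        r = rng.uniform(0, 1, size=(4, 6))
        r[r < 0.3] = 0.0
        net = toy_network(r)
        x = rng.uniform(0, 1, size=(4, 2))
        module_tfs = ["TF1", "TF3"]
        alpha = 0.2
        edges, (mean, sd) = select_targets(x, 1, net, module_tfs, alpha_tg=alpha)
        # independent loop computation of S and the Gaussian tail test
        s = np.zeros((4, 6))
        proj = sum(x[i, 1] * r[i] for i in range(4))
        for i in range(4):
            s[i] = x[i, 1] * proj
        cand = [
            (i, j)
            for i in (0, 2)
            for j in range(6)
            if r[i, j] > 0
        ]
        vals = np.array([s[i, j] for i, j in cand])
        expect_mean, expect_sd = vals.mean(), vals.std(ddof=1)
        assert mean == pytest.approx(expect_mean)
        assert sd == pytest.approx(expect_sd)
        expected_edges = {
            (f"TF{i + 1}", f"TG{j + 1}")
            for (i, j), v in zip(cand, vals)
            if stats.norm.sf(v, expect_mean, expect_sd) <= alpha
        }
        assert {(tf, tg) for tf, tg, _s, _p in edges} == expected_edges

    def test_empty_candidates_warn(self):
        net = toy_network(np.zeros((2, 3)))
        x = np.ones((2, 1)) * 0.5
        with pytest.warns(UserWarning, match="candidate"):
            edges, params = select_targets(x, 0, net, ["TF1"], alpha_tg=0.01)
        assert edges == [] and params is None


class TestAttachRes:
    def test_edge_without_triplet_kept(self):
        out = attach_res([("TF1", "TG1", 1.0, 0.001)], [])
        assert out == []

    def test_join_and_cobound_flag(self):
        edges = [("TF1", "TG1", 1.0, 0.001), ("TF2", "TG1", 0.9, 0.002)]
        triplets = [
            ("TF1", "chr1:100-200", "TG1", 0.5),
            ("TF2", "chr1:100-200", "TG1", 0.4),
            ("TF1", "chr1:300-400", "TG1", 0.2),
            ("TF1", "chr1:100-200", "TG2", 0.9),  # not a selected edge
        ]
        out = attach_res(edges, triplets)
        flags = {(tf, re, tg): cb for tf, re, tg, cb in out}
        assert flags[("TF1", "chr1:100-200", "TG1")] is True
        assert flags[("TF2", "chr1:100-200", "TG1")] is True
        assert flags[("TF1", "chr1:300-400", "TG1")] is False
        assert ("TF1", "chr1:100-200", "TG2") not in flags

    def test_matches_join_oracle(self, rng):
        tfs = [f"TF{i}" for i in range(3)]
        tgs = [f"TG{j}" for j in range(4)]
        res = [f"chr1:{k * 100}-{k * 100 + 50}" for k in range(5)]
        triplets = [
            (rng.choice(tfs), rng.choice(res), rng.choice(tgs), float(rng.uniform()))
            for _ in range(30)
        ]
        edges = [(tf, tg, 1.0, 0.001) for tf in tfs[:2] for tg in tgs[:2]]
        out = {(tf, re, tg) for tf, re, tg, _cb in attach_res(edges, triplets)}
        wanted = {(tf, tg) for tf, tg, _s, _p in edges}
        expected = {
            (tf, re, tg) for tf, re, tg, _s in triplets if (tf, tg) in wanted
        }
        assert out == expected
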