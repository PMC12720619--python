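"""Comparison statistics: decile silencing, KS and Wilcoxon oracles,
edge clustering, differential-degree conservation, Fisher overlap tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from omicnets import ggm, netcompare as nc, synth


def _self_pairs(weights, tfs=None):
    tfs = tfs or [f"t{i}" for i in range(len(weights))]
    return pd.DataFrame({"weight": weights}, index=pd.Index(tfs, name="tf_id"))


class TestDetectSilencing:
    def test_first_decile_flags_smallest(self):
        w = [float(i) for i in range(10)]
        report = nc.detect_silencing({"S1": _self_pairs(w)}, decile=0.10)
        assert report.union == {"t0"}

    def test_all_equal_flags_all(self):
        report = nc.detect_silencing({"S1": _self_pairs([0.5] * 8)})
        assert len(report.union) == 8

    def test_union_over_subtypes(self):
        a = _self_pairs([-1.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        b = _self_pairs([0.9, -1.0, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.1])
        report = nc.detect_silencing({"S1": a, "S2": b}, decile=0.10)
        assert report.union == {"t0", "t1"}

    def test_invariant_to_tf_relabeling(self):
        w = [0.3, -0.5, 0.1, 0.9, 0.0, 0.4, 0.2, 0.6, 0.8, 0.7]
        r1 = nc.detect_silencing({"S1": _self_pairs(w)})
        relabeled = _self_pairs(w, tfs=[f"zz{i}" for i in range(10)])
        r2 = nc.detect_silencing({"S1": relabeled})
        flagged1 = {int(t[1:]) for t in r1.union}
        flagged2 = {int(t[2:]) for t in r2.union}
        assert flagged1 == flagged2

    def test_mismatched_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            nc.detect_silencing(
                {"S1": _self_pairs([1, 2, 3]), "S2": _self_pairs([1, 2, 3, 4])}
            )


class TestDriverShift:
    def test_identical_samples(self):
        table = _self_pairs([0.1, 0.2, 0.3, 0.4, 0.1, 0.2, 0.3, 0.4])
        stat, p = nc.driver_shift_test(table, {"t0", "t1", "t2", "t3"})
        assert stat == 0.0
        assert p == 1.0

    def test_maximal_separation(self):
        table = _self_pairs([-3, -2, -1.5, 1, 2, 3])
        stat, _ = nc.driver_shift_test(table, {"t0", "t1", "t2"})
        assert stat == 1.0

    def test_exact_p_matches_permutation_enumeration(self):
        """One-sided KS p equals the exact permutation distribution of D+
        over all group assignments (n1 = n2 = 4, distinct values)."""
        values = [0.05, 0.3, 0.8, 1.2, 2.0, 2.5, 3.3, 4.1]
        drivers = {"t0", "t2", "t4", "t6"}
        table = _self_pairs(values)
        stat, p = nc.driver_shift_test(table, drivers)

        def dplus(group_a, group_b):
            pooled = sorted(values)
            best = 0.0
            for v in pooled:
                fa = sum(x <= v for x in group_a) / len(group_a)
                fb = sum(x <= v for x in group_b) / len(group_b)
                best = max(best, fa - fb)
            return best

        obs = dplus([values[i] for i in (0, 2, 4, 6)],
                    [values[i] for i in (1, 3, 5, 7)])
        assert abs(stat - obs) < 1e-12
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            a = [values[i] for i in combo]
            b = [values[i] for i in range(8) if i not in combo]
            if dplus(a, b) >= obs - 1e-12:
                count += 1
            total += 1
        assert abs(p - count / total) < 1e-9

    def test_group_size_errors(self):
        with pytest.raises(ValueError):
            nc.driver_shift_test(_self_pairs([1, 2, 3]), {"t0"})


class TestTopCrossEdgesAndClustering:
    def _nets(self, weight_maps):
        """Build one network per subtype over M:{t0,t1} x E:{t0,t1,t2}."""
        nets = {}
        nodes = ["t0", "t1", "t0", "t1", "t2"]
        layers = ["M", "M", "E", "E", "E"]
        for s, entries in weight_maps.items():
            w = np.zeros((5, 5))
            for (i, j), v in entries.items():
                w[i, j] = w[j, i] = v
            nets[s] = ggm.PartialCorrelationNetwork(
                nodes=nodes, layers=layers, weights=w, lambdas=(0, 0)
            )
        return nets

    def test_single_strong_edge_ranks_first_and_self_pairs_excluded(self):
        nets = self._nets({
            "S1": {(0, 4): 1.0, (0, 2): 0.9},  # (0,2) is the t0 self pair
            "S2": {(0, 4): 1.0, (0, 2): 0.9},
        })
        top = nc.top_cross_edges(nets, k=3)
        assert top.index[0] == ("t0", "t2")  # M:t0 -- E:t2 strongest cross edge
        assert ("t0", "t0") not in top.index
        assert len(top) == 3  # only 4 candidates minus nothing -> capped at k

    def test_k_larger_than_candidates_returns_all(self):
        nets = self._nets({"S1": {(0, 4): 0.5}})
        top = nc.top_cross_edges(nets, k=100)
        assert len(top) == 4  # 2x3 ME pairs minus 2 self pairs

    def test_ranking_matches_full_sort_oracle(self, rng):
        entries1 = {(i, j): rng.normal() for i in (0, 1) for j in (2, 3, 4)}
        entries2 = {k: rng.normal() for k in entries1}
        nets = self._nets({"S1": entries1, "S2": entries2})
        top = nc.top_cross_edges(nets, k=4)
        scores = {}
        names = ["t0", "t1", "t0", "t1", "t2"]
        for (i, j) in entries1:
            if names[i] == names[j]:
                continue
            scores[(names[i], names[j])] = (
                abs(entries1[(i, j)]) + abs(entries2[(i, j)])
            ) / 2
        expected = sorted(scores, key=lambda k: (-scores[k], k))[:4]
        assert list(top.index) == expected

    def test_cluster_duplicated_rows_perfect_split(self):
        rows = [[1.0, -1.0]] * 5 + [[0.8, 0.8]] * 5
        mat = pd.DataFrame(rows, index=[(f"a{i}", f"b{i}") for i in range(10)],
                           columns=["S1", "S2"])
        labels, order = nc.cluster_edges(mat, n_clusters=2)
        assert len(set(labels.iloc[:5])) == 1
        assert len(set(labels.iloc[5:])) == 1
        assert labels.iloc[0] != labels.iloc[5]
        assert sorted(order) == list(range(10))

    def test_singletons_and_errors(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 2)))
        labels, _ = nc.cluster_edges(mat, n_clusters=4)
        assert len(set(labels)) == 4
        with pytest.raises(ValueError):
            nc.cluster_edges(mat, n_clusters=5)
        with pytest.raises(ValueError):
            nc.cluster_edges(mat.iloc[:1], n_clusters=1)


class TestPerNodeShift:
    def _net(self, w):
        return ggm.PartialCorrelationNetwork(
            nodes=["c0", "c1", "e0", "e1", "e2", "e3", "e4", "e5"],
            layers=["C"] * 2 + ["E"] * 6,
            weights=w,
            lambdas=(0, 0),
        )

    def _weights(self, c0_edges, c1_edges):
        w = np.zeros((8, 8))
        for j, v in enumerate(c0_edges):
            w[0, 2 + j] = w[2 + j, 0] = v
        for j, v in enumerate(c1_edges):
            w[1, 2 + j] = w[2 + j, 1] = v
        return w

    def test_identical_networks_degenerate(self):
        w = self._weights([0.1] * 6, [0.2] * 6)
        out = nc.per_node_shift_test(self._net(w), self._net(w.copy()))
        assert (out["p"] == 1.0).all()
        assert out["degenerate"].all()

    def test_six_positive_differences_exact_one_sided(self):
        wa = self._weights([0.2] * 6, [0.0] * 6)
        wb = self._weights([0.1] * 6, [0.0] * 6)
        out = nc.per_node_shift_test(self._net(wa), self._net(wb),
                                     alternative="greater")
        assert abs(out.loc["c0", "p"] - 1 / 64) < 1e-12

    def test_bh_adjustment_matches_hand_computation(self, rng):
        wa = self._weights(rng.normal(size=6) * 0.2, rng.normal(size=6) * 0.2)
        wb = self._weights(rng.normal(size=6) * 0.2, rng.normal(size=6) * 0.2)
        out = nc.per_node_shift_test(self._net(wa), self._net(wb))
        p = out["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        q_expected = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            q_expected[i] = running
        np.testing.assert_allclose(out["q"].to_numpy(), q_expected, atol=1e-12)


class TestDifferentialDegree:
    def _pair(self, diff, tf_mods, gene_mods):
        tfs = [f"tf{i}" for i in range(diff.shape[0])]
        genes = [f"g{j}" for j in range(diff.shape[1])]
        a = nc.BipartiteNetwork(pd.DataFrame(diff, index=tfs, columns=genes), "A")
        b = nc.BipartiteNetwork(
            pd.DataFrame(np.zeros_like(diff), index=tfs, columns=genes), "B"
        )
        assignments = {t: m for t, m in zip(tfs, tf_mods)}
        assignments.update({g: m for g, m in zip(genes, gene_mods)})
        part = nc.ModulePartition(assignments, n_modules=max(tf_mods + gene_mods) + 1)
        return a, b, part

    def test_identical_networks_zero(self):
        a, _, part = self._pair(np.ones((2, 2)), [0, 1], [0, 1])
        dd = nc.differential_degree(a, a, part)
        assert (dd.genes[["in_degree", "out_degree"]] == 0).all().all()
        assert (dd.tfs[["in_degree", "out_degree"]] == 0).all().all()

    def test_hand_example_2x2(self):
        """A - B = [[1, 2], [3, 4]], g1 and t1 alone in module 0:
        diff_g1(0) = 1 and diff_g1(not 0) = 3."""
        a, b, part = self._pair(np.array([[1.0, 2.0], [3.0, 4.0]]), [0, 1], [0, 1])
        dd = nc.differential_degree(a, b, part)
        assert dd.genes.loc["g0", "in_degree"] == 1.0
        assert dd.genes.loc["g0", "out_degree"] == 3.0
        assert dd.tfs.loc["tf0", "in_degree"] == 1.0
        assert dd.tfs.loc["tf0", "out_degree"] == 2.0

    def test_conservation_on_random_fixtures(self, rng):
        for _ in range(20):
            diff = rng.normal(size=(5, 8))
            tf_mods = list(rng.integers(0, 3, size=5))
            gene_mods = list(rng.integers(0, 3, size=8))
            mods = set(tf_mods) | set(gene_mods)
            if mods != set(range(max(mods) + 1)):
                continue
            a, b, part = self._pair(diff, tf_mods, gene_mods)
            dd = nc.differential_degree(a, b, part)
            total_gene = diff.sum(axis=0)
            got = (dd.genes["in_degree"] + dd.genes["out_degree"]).to_numpy()
            np.testing.assert_allclose(got, total_gene, atol=1e-12)

    def test_swapping_networks_negates_degrees(self, rng):
        diff = rng.normal(size=(4, 6))
        a, b, part = self._pair(diff, [0, 0, 1, 1], [0, 1, 0, 1, 0, 1])
        fwd = nc.differential_degree(a, b, part)
        rev = nc.differential_degree(b, a, part)
        np.testing.assert_allclose(
            fwd.genes["in_degree"], -rev.genes["in_degree"], atol=1e-12
        )

    def test_dimension_mismatch_errors(self):
        a, b, part = self._pair(np.ones((2, 2)), [0, 1], [0, 1])
        c = nc.BipartiteNetwork(
            pd.DataFrame(np.ones((2, 3)), index=a.tf_ids,
                         columns=["g0", "g1", "gX"]),
            "C",
        )
        with pytest.raises(ValueError):
            nc.differential_degree(a, c, part)


class TestModuleInOutTest:
    def test_no_signal_no_significance(self):
        a, b, part, _ = synth.generate_bipartite_pair(8, 20, 2, 0, 0.0, 0.1, seed=1)
        tests = nc.module_inout_test(nc.differential_degree(a, b, part))
        assert (tests["p"].dropna() > 0.001).all()

    def test_planted_module_minimal_p(self):
        a, b, part, _ = synth.generate_bipartite_pair(12, 40, 4, 2, 2.0, 0.0, seed=2)
        tests = nc.module_inout_test(nc.differential_degree(b, a, part))
        gene_p = tests.loc["gene"]["p"].dropna()
        assert gene_p.idxmin() == 2

    def test_bonferroni_is_min_one_c_times_p(self):
        a, b, part, _ = synth.generate_bipartite_pair(9, 21, 3, 0, 0.5, 0.2, seed=3)
        tests = nc.module_inout_test(nc.differential_degree(a, b, part))
        gene = tests.loc["gene"].dropna(subset=["p"])
        np.testing.assert_allclose(
            gene["p_bonferroni"], np.minimum(gene["p"] * len(gene), 1.0), atol=1e-12
        )

    def test_singleton_module_skipped_with_flag(self):
        tfs = ["tf0", "tf1"]
        genes = ["g0", "g1", "g2"]
        w = pd.DataFrame(np.ones((2, 3)), index=tfs, columns=genes)
        a = nc.BipartiteNetwork(w, "A")
        b = nc.BipartiteNetwork(w * 2, "B")
        part = nc.ModulePartition(
            {"tf0": 0, "tf1": 1, "g0": 0, "g1": 0, "g2": 1}, n_modules=2
        )
        tests = nc.module_inout_test(nc.differential_degree(a, b, part))
        assert bool(tests.loc[("gene", 1), "degenerate"])
        assert math.isnan(tests.loc[("gene", 1), "p"])


class TestDifferentialTargeting:
    def _nets(self, wa, wb):
        tfs = [f"tf{i}" for i in range(wa.shape[0])]
        genes = [f"g{j}" for j in range(wa.shape[1])]
        return (
            nc.BipartiteNetwork(pd.DataFrame(wa, index=tfs, columns=genes), "A"),
            nc.BipartiteNetwork(pd.DataFrame(wb, index=tfs, columns=genes), "B"),
        )

    def test_identical_networks_empty_result(self):
        a, b = self._nets(np.ones((2, 3)), np.ones((2, 3)))
        assert nc.differential_targeting(a, b, {"tf0"}, top_k=5) == []

    def test_single_differing_edge(self):
        wa = np.zeros((2, 3))
        wb = wa.copy()
        wb[0, 2] = 1.0
        a, b = self._nets(wa, wb)
        assert nc.differential_targeting(a, b, {"tf0", "tf1"}, top_k=1) == ["g2"]

    def test_matches_full_sort_oracle(self, rng):
        wa, wb = rng.normal(size=(3, 6)), rng.normal(size=(3, 6))
        a, b = self._nets(wa, wb)
        got = nc.differential_targeting(a, b, {"tf0", "tf1", "tf2"}, top_k=8)
        diffs = []
        for i in range(3):
            for j in range(6):
                diffs.append((abs(wa[i, j] - wb[i, j]), f"tf{i}", f"g{j}"))
        diffs.sort(key=lambda t: (-t[0], t[1], t[2]))
        expected = []
        for _, _, g in diffs[:8]:
            if g not in expected:
                expected.append(g)
        assert got == expected

    def test_empty_tf_set_errors(self):
        a, b = self._nets(np.ones((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            nc.differential_targeting(a, b, set(), top_k=3)


class TestAnnotationOverlap:
    def test_disjoint_halves_exact_p(self):
        universe = {f"x{i}" for i in range(10)}
        members = set(sorted(universe)[:5])
        odds, p = nc.annotation_overlap_test(members, members, universe)
        assert abs(p - 2 / 252) < 1e-12
        assert odds == (5.5 * 5.5) / (0.5 * 0.5)  # Haldane-corrected

    def test_annotated_equals_universe(self):
        universe = {f"x{i}" for i in range(8)}
        members = set(sorted(universe)[:3])
        odds, p = nc.annotation_overlap_test(members, universe, universe)
        assert p == 1.0
        assert np.isfinite(odds)

    def test_independent_sets_p_near_uniform(self):
        """Under independent membership the two-sided p is approximately
        uniform: the rejection rate at alpha=0.2 stays near 0.2."""
        rng = np.random.default_rng(7)
        universe = [f"x{i}" for i in range(60)]
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            members = set(rng.choice(universe, size=20, replace=False))
            annotated = set(rng.choice(universe, size=20, replace=False))
            _, p = nc.annotation_overlap_test(members, annotated, set(universe))
            hits += p < 0.2
        # Fisher is conservative, so the rate may only fall below nominal
        assert hits / n_rep <= 0.25

    def test_subset_validation(self):
        with pytest.raises(ValueError):
            nc.annotation_overlap_test({"a"}, {"b"}, {"b"})
        with pytest.raises(ValueError):
            nc.annotation_overlap_test(set(), set(), set())
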