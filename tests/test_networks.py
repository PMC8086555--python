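"""Bipartite/unipartite networks, Raup-Crick partitioning, index oracles."""

import networkx as nx
import numpy as np
import pytest

import endonet as en
from endonet.networks import _adjacency, _edge_index_arrays, _lcc_stats, pack_matrix
from conftest import make_presence
from _oracles import (
    assortativity_naive,
    clustering_naive,
    mean_path_naive,
    nestedness_temperature_naive,
    raup_crick_pair_naive,
)


def taxon_net(graph: nx.Graph) -> en.TaxonNetwork:
    return en.TaxonNetwork(
        nodes=[str(n) for n in graph.nodes],
        edges={frozenset((str(a), str(b))) for a, b in graph.edges},
    )


class TestBipartite:
    def test_link_count(self):
        pres = make_presence([[1, 0], [1, 1]], organs=["bud", "bud"])
        net = en.build_bipartite(pres, "bud")
        assert len(net.links) == 3
        assert len(net.links) == pres.presence.sum()

    def test_absent_taxon_not_a_node(self):
        pres = make_presence(
            [[1, 1, 0, 0], [0, 0, 1, 1]], organs=["bud", "bud", "twig", "twig"]
        )
        net = en.build_bipartite(pres, "bud")
        assert net.fungus_nodes == ["t0"]

    def test_missing_organ_rejected(self):
        pres = make_presence([[1, 1]], organs=["bud", "bud"])
        with pytest.raises(en.OtuValidationError):
            en.build_bipartite(pres, "twig")

    def test_connectance(self):
        net = en.BipartiteNetwork(
            plant_nodes=["s1", "s2"],
            fungus_nodes=["a", "b", "c"],
            links={("s1", "a"), ("s1", "b"), ("s2", "c")},
        )
        assert en.connectance(net) == pytest.approx(0.5)

    def test_connectance_complete(self):
        links = {(s, t) for s in ("s1", "s2") for t in ("a", "b")}
        net = en.BipartiteNetwork(["s1", "s2"], ["a", "b"], links)
        assert en.connectance(net) == 1.0


class TestNestednessTemperature:
    def test_perfect_staircase_is_zero(self):
        n = 8
        stair = np.array([[1] * (n - i) + [0] * i for i in range(n)])
        assert en.nestedness_temperature(stair) == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        mat = (rng.random((12, 9)) < 0.45).astype(int)
        t0 = en.nestedness_temperature(mat)
        for s in range(5):
            r = np.random.default_rng(s)
            perm = mat[r.permutation(12)][:, r.permutation(9)]
            assert en.nestedness_temperature(perm) == pytest.approx(t0, abs=1e-12)

    def test_checkerboard_matches_naive_oracle(self):
        cb = (np.indices((6, 6)).sum(axis=0) % 2).astype(int)
        mine = en.nestedness_temperature(cb)
        oracle = nestedness_temperature_naive(pack_matrix(cb))
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_random_matrices_match_naive_oracle(self):
        for s in range(10):
            rng = np.random.default_rng(s)
            mat = (rng.random((8, 7)) < rng.uniform(0.2, 0.7)).astype(int)
            if mat.sum() in (0, mat.size):
                continue
            mine = en.nestedness_temperature(mat)
            oracle = nestedness_temperature_naive(pack_matrix(mat))
            assert mine == pytest.approx(oracle, abs=1e-9)

    @pytest.mark.parametrize("mat", [np.ones((3, 3)), np.zeros((3, 3))])
    def test_degenerate_fill_rejected(self, mat):
        with pytest.raises(ValueError):
            en.nestedness_temperature(mat.astype(int))

    def test_range(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            mat = (rng.random((10, 10)) < 0.5).astype(int)
            if mat.sum() in (0, mat.size):
                continue
            assert 0.0 <= en.nestedness_temperature(mat) <= 100.0


class TestProjection:
    def test_shared_sample_edge(self):
        pres = make_presence([[1, 0], [1, 1], [0, 1]], organs=["bud", "bud"])
        proj = en.project_to_taxa(en.build_bipartite(pres, "bud"))
        assert frozenset(("t0", "t1")) in proj.edges
        assert frozenset(("t1", "t2")) in proj.edges
        assert frozenset(("t0", "t2")) not in proj.edges

    def test_complete_bipartite_gives_complete_projection(self):
        pres = make_presence(np.ones((4, 3), dtype=int), organs=["bud"] * 3)
        proj = en.project_to_taxa(en.build_bipartite(pres, "bud"))
        assert proj.n_edges == 6  # C(4, 2)


def _skewed_background(seed=3, n_samples=12):
    """Background with strongly skewed per-sample richness."""
    rng = np.random.default_rng(seed)
    w = np.array([30, 25, 20, 15, 3, 3, 2, 2, 2, 1, 1, 1], dtype=float)
    bg = (rng.random((60, n_samples)) < (w / w.max() * 0.8)).astype(int)
    return bg[bg.sum(axis=1) > 0]


class TestRaupCrick:
    def test_identical_occupancy_sets_high_rc(self):
        rng = np.random.default_rng(0)
        bg = (rng.random((10, 12)) < 0.5).astype(int)
        bg = bg[bg.sum(axis=1) > 0]
        pair = np.zeros((2, 12), dtype=int)
        pair[:, :3] = 1  # same three samples, occupancy 3 of 12
        rc = en.raup_crick_matrix(np.vstack([pair, bg]), n_null=999, seed=1)
        assert rc.rc[0, 1] > 0.95

    def test_disjoint_sets_low_rc_under_skewed_richness(self):
        bg = _skewed_background()
        rich_order = np.argsort(-bg.sum(axis=0))
        pair = np.zeros((2, 12), dtype=int)
        pair[0, rich_order[:3]] = 1
        pair[1, rich_order[3:6]] = 1  # equal occupancy, disjoint samples
        rc = en.raup_crick_matrix(np.vstack([pair, bg]), n_null=999, seed=0)
        assert rc.rc[0, 1] < 0.05

    def test_pairwise_values_match_naive_sampler(self):
        rng = np.random.default_rng(11)
        mat = (rng.random((8, 10)) < 0.45).astype(int)
        mat = mat[mat.sum(axis=1) > 0]
        rc = en.raup_crick_matrix(mat, n_null=999, seed=2)
        oracle_rng = np.random.default_rng(1234)
        for i, j in [(0, 1), (1, 2), (0, 3)]:
            oracle = raup_crick_pair_naive(mat, i, j, 999, oracle_rng)
            # both are Monte-Carlo estimates of the same quantity
            assert abs(rc.rc[i, j] - oracle) < 0.08

    def test_range_symmetry_reproducibility(self):
        bg = _skewed_background(seed=5)
        a = en.raup_crick_matrix(bg, n_null=99, seed=3)
        b = en.raup_crick_matrix(bg, n_null=99, seed=3)
        np.testing.assert_array_equal(a.rc, b.rc)
        assert (a.rc >= 0).all() and (a.rc <= 1).all()
        np.testing.assert_allclose(a.rc, a.rc.T)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            en.raup_crick_matrix(np.ones((3, 2), dtype=int))


class TestPartition:
    def _rc(self, values):
        n = len(values) + 1
        rc = np.zeros((n, n))
        rc[0, 1:] = rc[1:, 0] = values
        return en.RaupCrickMatrix([f"t{i}" for i in range(n)], rc, 999, 0)

    def test_thresholds(self):
        rc = self._rc([0.7, 0.30, 0.495])
        pos, neg = en.partition_cooccurrence(rc)
        assert frozenset(("t0", "t1")) in pos.edges
        assert frozenset(("t0", "t2")) in neg.edges
        assert frozenset(("t0", "t3")) not in pos.edges | neg.edges

    def test_edge_sets_disjoint(self):
        rng = np.random.default_rng(1)
        vals = rng.random(10)
        pos, neg = en.partition_cooccurrence(self._rc(vals))
        assert not (pos.edges & neg.edges)

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            en.partition_cooccurrence(self._rc([0.5]), 0.4, 0.6)


class TestAssortativity:
    def test_star_graph(self):
        assert en.assortativity(taxon_net(nx.star_graph(4))) == pytest.approx(-1.0)

    def test_regular_graph_undefined(self):
        assert en.assortativity(taxon_net(nx.cycle_graph(6))) is None

    def test_matches_naive_pearson(self):
        for s in range(10):
            g = nx.gnp_random_graph(50, 0.1, seed=s)
            if g.number_of_edges() == 0:
                continue
            mine = en.assortativity(taxon_net(g))
            oracle = assortativity_naive([(str(a), str(b)) for a, b in g.edges])
            if oracle is None:
                assert mine is None
            else:
                assert mine == pytest.approx(oracle, abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            en.assortativity(en.TaxonNetwork(["a", "b"], set()))


class TestRichClub:
    def test_complete_graph_is_one(self):
        assert en.rich_club(taxon_net(nx.complete_graph(7)), n_rand=10, seed=0) == 1.0

    def test_star_graph_undefined(self):
        assert en.rich_club(taxon_net(nx.star_graph(5)), n_rand=10, seed=0) is None

    def test_planted_dense_core_above_one(self):
        g = nx.gnp_random_graph(60, 0.08, seed=5)
        deg = dict(g.degree())
        top = sorted(deg, key=deg.get, reverse=True)[:10]
        for i, a in enumerate(top):
            for b in top[i + 1 :]:
                g.add_edge(a, b)
        value = en.rich_club(taxon_net(g), n_rand=50, seed=1)
        assert value is not None and value > 1.0

    def test_degree_sequence_preserved_by_rewiring(self):
        from endonet.networks import _rewired_edges

        g = nx.gnp_random_graph(40, 0.2, seed=3)
        u, v, n = _edge_index_arrays(taxon_net(g))
        rewired = _rewired_edges(u, v, 10 * len(u), np.random.default_rng(0))
        deg0 = np.bincount(np.concatenate([u, v]), minlength=n)
        arr = np.array(sorted(rewired))
        deg1 = np.bincount(np.concatenate([arr[:, 0], arr[:, 1]]), minlength=n)
        np.testing.assert_array_equal(deg0, deg1)
        assert len(rewired) == len(u)


class TestSmallWorld:
    def test_complete_graph_is_one(self):
        assert en.small_world(taxon_net(nx.complete_graph(6)), n_rand=5, seed=0) == 1.0

    def test_watts_strogatz_regime(self):
        g = nx.watts_strogatz_graph(50, 6, 0.05, seed=1)
        assert en.small_world(taxon_net(g), n_rand=50, seed=0) > 1.0

    def test_component_stats_match_brute_force(self):
        for s in range(10):
            g = nx.gnp_random_graph(30, 0.12, seed=s)
            net = taxon_net(g)
            if net.n_edges == 0:
                continue
            u, v, n = _edge_index_arrays(net)
            stats = _lcc_stats(_adjacency(u, v, n))
            comp = max(nx.connected_components(g), key=len)
            sub = g.subgraph(comp)
            order = sorted(sub.nodes)
            adj = nx.to_numpy_array(sub, nodelist=order).astype(int)
            assert stats[0] == pytest.approx(clustering_naive(adj), abs=1e-12)
            assert stats[1] == pytest.approx(mean_path_naive(adj), abs=1e-12)

    def test_small_component_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            en.small_world(taxon_net(g), n_rand=5, seed=0)


class TestOrganIndexReport:
    def test_ranges_and_determinism(self, default_community):
        table, _ = default_community
        pres = en.to_presence(en.filter_otus(table))
        r1 = en.organ_index_report(pres, "twig", n_null=99, n_rand=10, seed=4)
        r2 = en.organ_index_report(pres, "twig", n_null=99, n_rand=10, seed=4)
        assert r1.as_dict() == r2.as_dict()
        assert 0 <= r1.main.connectance <= 1
        assert 0 <= r1.main.nestedness_T <= 100
        if r1.main.assortativity is not None:
            assert -1 <= r1.main.assortativity <= 1
        for variant in (r1.positive, r1.negative):
            if variant.small_world is not None:
                assert variant.small_world > 0

    def test_deltas_equal_elementwise_subtraction(self, default_community):
        table, _ = default_community
        pres = en.to_presence(en.filter_otus(table))
        bud = en.organ_index_report(pres, "bud", n_null=49, n_rand=5, seed=0)
        twig = en.organ_index_report(pres, "twig", n_null=49, n_rand=5, seed=0)
        delta = twig.main.connectance - bud.main.connectance
        assert delta == pytest.approx(
            twig.main.as_dict()["connectance"] - bud.main.as_dict()["connectance"]
        )

    def test_deterministic_indices_invariant_to_relabeling(self, default_community):
        table, _ = default_community
        pres = en.to_presence(en.filter_otus(table))
        rng = np.random.default_rng(9)
        order_t = rng.permutation(len(pres.taxon_ids))
        order_s = rng.permutation(len(pres.sample_ids))
        shuffled = en.PresenceMatrix(
            taxon_ids=[pres.taxon_ids[i] for i in order_t],
            sample_ids=[pres.sample_ids[j] for j in order_s],
            presence=pres.presence[np.ix_(order_t, order_s)],
            metadata=pres.metadata,
        )
        for organ in ("bud", "twig"):
            a = en.build_bipartite(pres, organ)
            b = en.build_bipartite(shuffled, organ)
            assert en.connectance(a) == pytest.approx(en.connectance(b))
            assert en.nestedness_temperature(
                a.presence_array()
            ) == pytest.approx(en.nestedness_temperature(b.presence_array()), abs=1e-9)
            pa = en.project_to_taxa(a)
            pb = en.project_to_taxa(b)
            assert en.assortativity(pa) == pytest.approx(en.assortativity(pb))


class TestPermutationCompare:
    def test_identical_organs_no_signal(self):
        rng = np.random.default_rng(0)
        half = (rng.random((20, 6)) < 0.5).astype(int)
        mat = np.hstack([half, half])  # twig block mirrors bud block
        mat = mat[mat.sum(axis=1) > 0]
        pres = make_presence(mat, organs=["bud"] * 6 + ["twig"] * 6)
        res = en.permutation_compare(pres, "connectance", n_perm=99, seed=0)
        assert res.delta_observed == 0.0
        assert res.p > 0.05

    def test_p_lower_bound_and_reproducibility(self, default_community):
        table, _ = default_community
        pres = en.to_presence(en.filter_otus(table))
        a = en.permutation_compare(pres, "nestedness_T", n_perm=49, seed=5)
        b = en.permutation_compare(pres, "nestedness_T", n_perm=49, seed=5)
        assert a.p == b.p and a.delta_observed == b.delta_observed
        assert a.p >= 1 / 50
        assert a.tail in ("left", "right")

    def test_small_organ_rejected(self):
        pres = make_presence(
            [[1, 1, 1], [1, 0, 1]], organs=["bud", "twig", "twig"]
        )
        with pytest.raises(ValueError):
            en.permutation_compare(pres, "connectance", n_perm=9, seed=0)

    def test_power_under_strong_organ_effect(self):
        """A strong per-taxon organ preference shifts per-sample richness,
        which the bipartite-index comparison should detect reliably."""
        rejections = 0
        n_sets = 100
        for s in range(n_sets):
            params = en.CommunityParams(
                seed=1000 + s, n_taxa=40, organ_effect_mu=2.0, organ_effect_sd=0.5
            )
            table, _ = en.generate_community(params)
            pres = en.to_presence(table)
            res = en.permutation_compare(pres, "connectance", n_perm=99, seed=s)
            rejections += res.p <= 0.05
        assert rejections / n_sets > 0.8
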