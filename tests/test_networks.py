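"""Tests of parsimony-network construction and the temporal KS test."""

import itertools

import networkx as nx
import numpy as np
import pytest

from concerted import haplotypes as hp
from concerted import networks as net
from concerted.networks import (MonthlyProfile, build_network, classify_nodes,
                                ks_temporal_test, monthly_profile,
                                parsimony_connection_limit)
from concerted.simulate import ReadSet


def table_from(seq_counts: dict[str, int], months: dict[str, int] | None = None):
    """HaplotypeTable from {sequence: count}; optional per-sequence month."""
    seqs, samples, month_idx = [], [], []
    for i, (seq, n) in enumerate(seq_counts.items()):
        m = months[seq] if months else 1
        seqs.extend([seq] * n)
        samples.extend([f"env_m{m:02d}"] * n)
        month_idx.extend([m] * n)
    reads = ReadSet(sequences=seqs, sample_ids=samples,
                    provenance="environmental", month_index=month_idx)
    return hp.dereplicate(reads)


def exhaustive_msn_edges(seqs: list[str]) -> set[frozenset]:
    """Union of all minimum spanning trees of the complete Hamming graph,
    by explicit enumeration of spanning trees (oracle for <= 6 nodes)."""
    n = len(seqs)
    if n == 1:
        return set()
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[(i, j)] = sum(a != b for a, b in zip(seqs[i], seqs[j]))
    best_weight = None
    union: set[frozenset] = set()
    for tree in itertools.combinations(dist, n - 1):
        g = nx.Graph(tree)
        if g.number_of_nodes() != n or not nx.is_connected(g):
            continue
        w = sum(dist[e] for e in tree)
        if best_weight is None or w < best_weight:
            best_weight = w
            union = set(frozenset(e) for e in tree)
        elif w == best_weight:
            union |= set(frozenset(e) for e in tree)
    return union


class TestConnectionLimit:
    def test_limit_grows_with_sequence_length(self):
        limits = [parsimony_connection_limit(L) for L in (50, 380, 1000)]
        assert limits == sorted(limits)
        assert parsimony_connection_limit(380) == 6

    def test_one_step_always_accepted(self):
        assert parsimony_connection_limit(2) >= 1

    def test_invalid_length(self):
        with pytest.raises(ValueError):
            parsimony_connection_limit(0)


class TestBuildNetwork:
    def test_two_haplotypes_one_step(self):
        table = table_from({"AAAA": 10, "AAAT": 2})
        network = build_network(table, limit=5)
        assert len(network.sampled_nodes) == 2
        assert network.sampled_edges == [("hap1", "hap2", 1)]
        assert network.graph.number_of_edges() == 1

    def test_two_step_link_gets_one_intermediate(self):
        table = table_from({"AAAA": 10, "AATT": 2})
        network = build_network(table, limit=5)
        inferred = [x for x, d in network.graph.nodes(data=True)
                    if not d["sampled"]]
        assert len(inferred) == 1
        assert network.graph.number_of_edges() == 2
        # the intermediate differs from both endpoints at exactly one site
        mid_seq = network.graph.nodes[inferred[0]]["sequence"]
        assert sum(a != b for a, b in zip(mid_seq, "AAAA")) == 1
        assert sum(a != b for a, b in zip(mid_seq, "AATT")) == 1

    def test_link_beyond_limit_leaves_singleton(self):
        table = table_from({"AAAAAAAA": 10, "TTTTTTTT": 2})
        network = build_network(table, limit=3)
        assert network.graph.number_of_edges() == 0
        assert nx.number_connected_components(network.graph) == 2

    def test_matches_exhaustive_minimum_spanning_network(self):
        """Edge set equals the union of all minimum spanning trees on
        random small instances (exhaustive oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            L = int(rng.integers(4, 9))
            seqs: set[str] = set()
            while len(seqs) < n:
                seqs.add("".join("ACGT"[b] for b in rng.integers(0, 3, L)))
            ordered = sorted(seqs)
            table = table_from({s: i + 1 for i, s in enumerate(ordered)})
            network = build_network(table, limit=L)
            id_of = {table.sequences[h]: h for h in table.counts.index}
            got = {frozenset((u, v)) for u, v, _ in network.sampled_edges}
            want = {frozenset((id_of[ordered[i]], id_of[ordered[j]]))
                    for i, j in (tuple(e) for e in
                                 exhaustive_msn_edges(ordered))}
            assert got == want

    def test_unequal_lengths_raise(self):
        table = hp.dereplicate(ReadSet(sequences=["AAAA", "AAA"],
                                       sample_ids=["s", "s"],
                                       provenance="strain"))
        with pytest.raises(ValueError):
            build_network(table)

    def test_dominant_is_rank_one(self):
        table = table_from({"AAAA": 2, "AAAT": 20})
        network = build_network(table)
        assert table.sequences[network.dominant_id] == "AAAT"


class TestMonthlyProfile:
    def test_pools_reads_by_month(self):
        table = table_from({"AAAA": 6, "AAAT": 3},
                           months={"AAAA": 3, "AAAT": 7})
        prof = monthly_profile("hap1", table, n_months=12)
        assert prof.counts[2] == 6 and prof.total == 6

    def test_conservation_over_nodes(self):
        table = table_from({"AAAA": 6, "AAAT": 3, "AATT": 2},
                           months={"AAAA": 1, "AAAT": 2, "AATT": 2})
        profs = [monthly_profile(h, table, 3) for h in table.counts.index]
        total = np.sum([p.counts for p in profs], axis=0)
        assert total.tolist() == [6, 5, 0]
        assert total.sum() == table.N

    def test_intermediate_node_has_empty_profile(self):
        table = table_from({"AAAA": 6, "AATT": 3},
                           months={"AAAA": 1, "AATT": 2})
        assert monthly_profile("med1", table, 3).total == 0

    def test_missing_dates_raise(self):
        table = hp.dereplicate(ReadSet(sequences=["AAAA"], sample_ids=["s"],
                                       provenance="strain"))
        with pytest.raises(ValueError):
            monthly_profile("hap1", table)


class TestKSTemporalTest:
    def test_identical_profiles_have_zero_d(self):
        p = MonthlyProfile(np.array([5, 10, 5, 0, 0, 30]))
        res = ks_temporal_test(p, p, n_perm=200, seed=1)
        assert res.D == 0.0
        assert res.p_mc == 1.0
        assert res.congruent

    def test_disjoint_months_give_maximal_d_and_minimal_p(self):
        a = MonthlyProfile(np.array([200] + [0] * 11))
        b = MonthlyProfile(np.array([0] * 11 + [200]))
        res = ks_temporal_test(a, b, n_perm=1000, seed=1)
        assert res.D == 1.0
        assert res.p_mc == pytest.approx(1 / 1001)
        assert not res.congruent

    def test_p_never_zero(self):
        a = MonthlyProfile(np.array([50, 0]))
        b = MonthlyProfile(np.array([0, 50]))
        res = ks_temporal_test(a, b, n_perm=50, seed=0)
        assert res.p_mc >= 1 / 51

    def test_zero_total_profile_raises(self):
        a = MonthlyProfile(np.array([0, 0]))
        b = MonthlyProfile(np.array([1, 1]))
        with pytest.raises(ValueError):
            ks_temporal_test(a, b)

    def test_mismatched_months_raise(self):
        with pytest.raises(ValueError):
            ks_temporal_test(MonthlyProfile(np.array([1, 1])),
                             MonthlyProfile(np.array([1, 1, 1])))

    def test_order_preserving_relabelling_keeps_d(self):
        """D (and hence p at fixed seed) is unchanged by an order-preserving
        month relabelling applied to both profiles (inserting empty months),
        but NOT by an order-breaking permutation - the ECDF is
        order-dependent."""
        a = MonthlyProfile(np.array([30, 10, 5, 40]))
        b = MonthlyProfile(np.array([10, 20, 30, 25]))
        base = ks_temporal_test(a, b, n_perm=300, seed=7)
        # order-preserving: spread the same counts over more months
        a2 = MonthlyProfile(np.array([30, 0, 10, 5, 0, 40]))
        b2 = MonthlyProfile(np.array([10, 0, 20, 30, 0, 25]))
        stretched = ks_temporal_test(a2, b2, n_perm=300, seed=7)
        assert stretched.D == pytest.approx(base.D)
        # order-breaking: cyclically shift the months of both profiles
        # (a plain reversal would preserve D by symmetry)
        a3 = MonthlyProfile(np.roll(a.counts, 1))
        b3 = MonthlyProfile(np.roll(b.counts, 1))
        shifted = ks_temporal_test(a3, b3, n_perm=300, seed=7)
        assert shifted.D != pytest.approx(base.D)


class TestClassifyNodes:
    def test_congruent_and_divergent_partition(self):
        rng = np.random.default_rng(3)
        profile = np.array([0.3, 0.1, 0.05, 0.05, 0.2, 0.3])
        base = "ACGTACGTACGT"
        months = {}
        counts = {}
        # dominant and two tracking minors share the seasonal profile
        variants = [base, base[:-1] + "A", base[:-1] + "C", "T" + base[1:]]
        seqs, samples, month_idx = [], [], []
        for vi, v in enumerate(variants):
            n = 4000 if vi == 0 else 80
            if vi < 3:
                ms = rng.choice(6, size=n, p=profile) + 1
            else:  # the anomalous node: reads only in the rarest month
                ms = np.full(n, 4)
            for m in ms:
                seqs.append(v)
                samples.append(f"env_m{m:02d}")
                month_idx.append(int(m))
        table = hp.dereplicate(ReadSet(sequences=seqs, sample_ids=samples,
                                       provenance="environmental",
                                       month_index=month_idx))
        network = build_network(table, limit=6)
        labels = classify_nodes(network, table, n_perm=500, seed=9)
        id_of = {table.sequences[h]: h for h in table.counts.index}
        assert id_of[variants[3]] in labels["divergent"]
        assert id_of[variants[1]] in labels["congruent"]
        assert id_of[variants[2]] in labels["congruent"]

    def test_empty_selection_gives_empty_partition(self):
        table = table_from({"AAAA": 5})
        network = build_network(table)
        labels = classify_nodes(network, table, nodes=[])
        assert labels == {"congruent": [], "divergent": [], "results": []}


class TestExports:
    def test_nexus_round_trip(self, tmp_path):
        table = table_from({"AAAA": 6, "AAAT": 3, "AATT": 2},
                           months={"AAAA": 1, "AAAT": 2, "AATT": 2})
        network = build_network(table, limit=4)
        path = tmp_path / "net.nex"
        net.write_nexus(network, table, path)
        taxa, seqs, traits, edges = net.read_nexus_network(path)
        assert taxa == network.sampled_nodes
        assert seqs == {h: table.sequences[h] for h in taxa}
        for h in taxa:
            assert traits[h] == list(monthly_profile(h, table, 2).counts)
        assert sorted(map(tuple, edges)) == sorted(
            tuple(e) for e in network.graph.edges())

    def test_edge_list_and_gml(self, tmp_path):
        table = table_from({"AAAA": 6, "AAAT": 3})
        network = build_network(table)
        net.write_edge_list(network, tmp_path / "edges.tsv")
        net.write_gml(network, tmp_path / "net.gml")
        assert (tmp_path / "edges.tsv").read_text().splitlines()[1:] == \
            ["hap1\thap2"]
        g = nx.read_gml(tmp_path / "net.gml")
        assert set(g.nodes) == {"hap1", "hap2"}
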