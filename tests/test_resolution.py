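"""Distances, K2P correction, neighbor joining, bootstrap, ambiguity report."""

import math

import numpy as np
import pytest

from edmark.resolution import (
    DistanceMatrix,
    SaturationError,
    bipartitions,
    bootstrap_supports,
    complete_deletion,
    distance_matrix,
    k2p_distance,
    nj_tree,
    nt_differences,
    p_distance,
    resolution_report,
)
from edmark.seqio import SeqRecord


class TestPairwise:
    def test_nt_differences_counts_hamming(self):
        assert nt_differences("ACGT", "ACGT") == 0
        assert nt_differences("ACGT", "ACGA") == 1
        assert nt_differences("AC-T", "ACGT") == 0  # gapped column dropped

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            nt_differences("ACG", "ACGT")

    def test_p_distance_values(self):
        assert p_distance("A" * 167, "A" * 166 + "C") == pytest.approx(1 / 167)
        assert p_distance("ACGT", "ACGT") == 0.0
        assert p_distance("AAAA", "CCCC") == 1.0

    def test_one_diff_over_167_prints_as_0_6_percent(self):
        assert round(100 * p_distance("A" * 167, "A" * 166 + "C"), 1) == 0.6

    def test_k2p_closed_form_transitions_only(self):
        # 10 transitions over 100 sites: d = -1/2 ln(0.8)
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)
        assert k2p_distance(a, b) == pytest.approx(0.1116, abs=1e-4)

    def test_k2p_zero_for_identical(self):
        assert k2p_distance("ACGT" * 10, "ACGT" * 10) == 0.0

    def test_k2p_saturation_signalled(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "G" * 10)

    def test_k2p_dominates_p_distance(self):
        rng = np.random.default_rng(5)
        for _ in range(40):
            a = "".join(rng.choice(list("ACGT"), 120))
            b = list(a)
            for i in rng.choice(120, size=rng.integers(1, 25), replace=False):
                b[i] = rng.choice([c for c in "ACGT" if c != a[i]])
            b = "".join(b)
            assert k2p_distance(a, b) >= p_distance(a, b) > 0


class TestMatrix:
    def test_symmetry_zero_diagonal_all_models(self, refdb):
        for model in ("p", "k2p", "diffs"):
            dm = distance_matrix(refdb, model=model)
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)

    def test_identical_sequences_zero_matrix(self):
        dm = distance_matrix(
            [SeqRecord(id="a", seq="ACGT"), SeqRecord(id="b", seq="ACGT")]
        )
        assert np.all(dm.data == 0)

    def test_complete_deletion_drops_any_gapped_column(self):
        seqs = ["AC-T", "ACGT", "ACG-"]
        assert complete_deletion(seqs) == ["AC", "AC", "AC"]

    def test_complete_vs_pairwise_gap_modes_differ(self):
        recs = [
            SeqRecord(id="a", seq="ACGTA"),
            SeqRecord(id="b", seq="ACGGA"),
            SeqRecord(id="c", seq="ACG-A"),
        ]
        comp = distance_matrix(recs, model="diffs", gap_mode="complete")
        pw = distance_matrix(recs, model="diffs", gap_mode="pairwise")
        assert comp[("a", "b")] == 0  # the differing column is gapped in c
        assert pw[("a", "b")] == 1

    def test_summary_min_mean_max(self):
        dm = distance_matrix(
            [SeqRecord(id="a", seq="AAAA"), SeqRecord(id="b", seq="AAAC"),
             SeqRecord(id="c", seq="ACCC")],
            model="diffs",
        )
        assert dm.summary() == {"min": 1.0, "mean": 2.0, "max": 3.0}

    def test_planted_panel_core_minimum(self, planted):
        panel, truth, _ = planted
        s, e = truth.core
        cores = [SeqRecord(id=r.id, seq=r.seq[s:e]) for r in panel.records]
        dm = distance_matrix(cores, model="diffs")
        assert dm.summary()["min"] == truth.min_core_diffs
        a, b = truth.subspecies_pair
        assert dm[(a, b)] == truth.min_core_diffs


def random_additive_tree(rng, n):
    """A random binary tree topology with positive branch lengths, returned
    as (bipartitions, leaf path-length matrix) — the independent oracle for
    NJ consistency."""
    # start from a star over 3 leaves and attach leaves one at a time
    labels = [f"L{i:02d}" for i in range(n)]
    # adjacency: node -> list of (neighbor, length); leaves are labels
    nxt = [0]

    def new_node():
        nxt[0] += 1
        return f"_v{nxt[0]}"

    edges = {}

    def add_edge(u, v, w):
        edges.setdefault(u, []).append((v, w))
        edges.setdefault(v, []).append((u, w))

    def del_edge(u, v):
        edges[u] = [(x, w) for x, w in edges[u] if x != v]
        edges[v] = [(x, w) for x, w in edges[v] if x != u]

    def blen():
        return float(rng.uniform(0.5, 3.0))

    center = new_node()
    for lbl in labels[:3]:
        add_edge(center, lbl, blen())
    for lbl in labels[3:]:
        # split a uniformly chosen edge
        all_edges = sorted(
            {tuple(sorted((u, v))) for u in edges for v, _ in edges[u]}
        )
        u, v = all_edges[rng.integers(len(all_edges))]
        w = dict(edges[u])[v]
        mid = new_node()
        del_edge(u, v)
        a = float(rng.uniform(0.2, 0.8)) * w
        add_edge(u, mid, a)
        add_edge(mid, v, w - a)
        add_edge(mid, lbl, blen())

    # path lengths by BFS from each leaf
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in edges[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]

    # bipartitions: remove each internal edge, collect leaf side
    ref = labels[0]
    full = frozenset(labels)
    bips = set()
    internal = [k for k in edges if k.startswith("_v")]
    for u in internal:
        for v, _ in edges[u]:
            if not v.startswith("_v"):
                continue
            # leaves reachable from v without crossing u
            seen = {u, v}
            stack = [v]
            side = set()
            while stack:
                x = stack.pop()
                for y, _w in edges[x]:
                    if y in seen:
                        continue
                    seen.add(y)
                    if y.startswith("_v"):
                        stack.append(y)
                    else:
                        side.add(y)
            if 1 < len(side) < n - 1:
                bips.add(frozenset(side) if ref not in side else full - frozenset(side))
    return labels, d, bips


class TestNeighborJoining:
    def test_exact_recovery_on_four_taxon_additive_matrix(self):
        # ((A:1,B:2):1,(C:3,D:4)) -> path-length matrix
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        tree = nj_tree(DistanceMatrix(labels=list("ABCD"), data=d, model="p",
                                      gap_mode="complete"))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        internals = [x.length for x in tree.non_tips(include_self=False)]
        assert internals == [pytest.approx(1.0)]

    def test_three_taxa_resolved_exactly(self):
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(labels=list("ABC"), data=d, model="p",
                                      gap_mode="complete"))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_label_permutation_invariance(self, refdb):
        dm = distance_matrix(refdb, model="p")
        tree1 = nj_tree(dm)
        order = np.arange(len(dm.labels))[::-1]
        dm2 = DistanceMatrix(
            labels=[dm.labels[i] for i in order],
            data=dm.data[np.ix_(order, order)],
            model="p", gap_mode="complete",
        )
        tree2 = nj_tree(dm2)
        assert bipartitions(tree1) == bipartitions(tree2)

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(42)
        for trial in range(12):
            n = int(rng.integers(4, 13))
            labels, d, true_bips = random_additive_tree(rng, n)
            dm = DistanceMatrix(labels=labels, data=d, model="p",
                                gap_mode="complete")
            tree = nj_tree(dm)
            assert bipartitions(tree) == true_bips, f"trial {trial}, n={n}"

    def test_agrees_with_skbio_on_real_distances(self, refdb):
        import skbio

        dm = distance_matrix(refdb, model="k2p")
        mine = nj_tree(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(dm.data, dm.labels))
        assert bipartitions(mine) == bipartitions(theirs)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0, 1], [1, 0]], float)
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"], data=d, model="p",
                                   gap_mode="complete"))


class TestBootstrap:
    @staticmethod
    def two_clade_records(sep_sites, seed=0, length=300):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), length))

        def mutate(s, positions):
            s = list(s)
            for p in positions:
                s[p] = "A" if s[p] != "A" else "G"
            return "".join(s)

        shared = list(range(sep_sites))
        recs = [
            SeqRecord(id=f"A{i}", seq=mutate(base, [length - 1 - i]))
            for i in range(5)
        ] + [
            SeqRecord(id=f"B{i}", seq=mutate(base, shared + [length - 20 - i]))
            for i in range(5)
        ]
        return recs

    def test_separated_clades_get_high_support(self):
        recs = self.two_clade_records(sep_sites=40)
        tree = bootstrap_supports(recs, model="p", replicates=100, seed=1)
        clade_b = frozenset(f"B{i}" for i in range(5))
        found = False
        for node in tree.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if tips in (clade_b, frozenset(f"A{i}" for i in range(5))):
                assert node.support >= 99.0
                found = True
        assert found

    def test_support_grows_with_divergence(self):
        def mean_sep_support(sep):
            recs = self.two_clade_records(sep_sites=sep)
            tree = bootstrap_supports(recs, model="p", replicates=60, seed=2)
            clade_b = frozenset(f"B{i}" for i in range(5))
            for node in tree.non_tips(include_self=False):
                tips = frozenset(t.name for t in node.tips())
                if tips in (clade_b, frozenset(f"A{i}" for i in range(5))):
                    return node.support
            return 0.0

        assert mean_sep_support(2) <= mean_sep_support(30)

    def test_single_replicate_supports_are_0_or_100(self):
        recs = self.two_clade_records(sep_sites=30)
        tree = bootstrap_supports(recs, model="p", replicates=1, seed=3)
        sups = {n.support for n in tree.non_tips(include_self=False)
                if hasattr(n, "support")}
        assert sups <= {0.0, 100.0}

    def test_same_seed_reproduces_supports(self):
        recs = self.two_clade_records(sep_sites=10)
        t1 = bootstrap_supports(recs, model="p", replicates=40, seed=9)
        t2 = bootstrap_supports(recs, model="p", replicates=40, seed=9)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                    if hasattr(n, "support"))
        assert s1 == s2

    def test_supports_bounded(self, refdb):
        tree = bootstrap_supports(list(refdb.records), model="k2p",
                                  replicates=30, seed=0)
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                assert 0.0 <= n.support <= 100.0


class TestResolutionReport:
    def test_subspecies_pair_flagged_at_tolerance_2(self, planted, refdb):
        panel, truth, _ = planted
        dm = distance_matrix(refdb, model="diffs")
        taxmap = {r.id: r.taxon for r in refdb.records}
        report = resolution_report(dm, taxmap, assignment_tolerance=2)
        # the fixture's closest pair sits above tolerance 2 by default (5)
        assert report.summary["min"] == truth.min_core_diffs
        assert report.ambiguous_pairs.empty
        wide = resolution_report(dm, taxmap, assignment_tolerance=5)
        flagged = {
            frozenset((r.id_a, r.id_b)) for r in wide.ambiguous_pairs.itertuples()
        }
        assert frozenset(truth.subspecies_pair) in flagged

    def test_tolerance_zero_flags_only_identical(self):
        recs = [SeqRecord(id="a", seq="ACGT"), SeqRecord(id="b", seq="ACGT"),
                SeqRecord(id="c", seq="AGGT")]
        dm = distance_matrix(recs, model="diffs")
        report = resolution_report(dm, assignment_tolerance=0)
        flagged = {
            frozenset((r.id_a, r.id_b)) for r in report.ambiguous_pairs.itertuples()
        }
        assert flagged == {frozenset(("a", "b"))}

    def test_one_diff_subspecies_fixture_flagged(self):
        from edmark.simdata import MarkerFixtureSpec, plant_marker_alignment

        panel, truth = plant_marker_alignment(
            MarkerFixtureSpec(min_core_diffs=1, seed=4)
        )
        s, e = truth.core
        cores = [SeqRecord(id=r.id, seq=r.seq[s:e]) for r in panel.records]
        dm = distance_matrix(cores, model="diffs")
        report = resolution_report(dm, assignment_tolerance=2)
        flagged = {
            frozenset((r.id_a, r.id_b)) for r in report.ambiguous_pairs.itertuples()
        }
        assert frozenset(truth.subspecies_pair) in flagged

    def test_requires_diffs_matrix(self, refdb):
        with pytest.raises(ValueError):
            resolution_report(distance_matrix(refdb, model="p"))
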