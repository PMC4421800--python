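"""Family parsing, copy tables, cluster chaining, consensus coding,
p-distances and neighbour joining with its additive-recovery guarantee."""

import numpy as np
import pandas as pd
import pytest

from mirgonad.evo import (Cluster, MirnaLocus, bootstrap_support, consensus,
                          copy_number_table, detect_clusters, family_copy_counts,
                          nj_tree, p_distance_matrix, parse_family,
                          random_additive_tree, tree_bipartitions)


def _locus(name, start=0, species="sp", contig="chr1", length=80):
    return MirnaLocus(species, name, contig, start, start + length)


class TestFamilies:
    @pytest.mark.parametrize(
        "name,family",
        [
            ("mir-92a", "miR-92"),
            ("mir-92b", "miR-92"),
            ("miR-19b-1", "miR-19"),
            ("miR-19b-2", "miR-19"),
            ("miR-7", "miR-7"),
            ("hsa-miR-17-5p", "miR-17"),
            ("dre-mir-430a-12", "miR-430"),
            ("let-7a", "let-7"),
        ],
    )
    def test_parse_family(self, name, family):
        assert parse_family(name) == family

    def test_unparseable_name_passes_through_with_warning(self):
        with pytest.warns(UserWarning):
            assert parse_family("weird-thing") == "weird-thing"

    def test_single_and_multi_copy_fractions(self):
        loci = {
            "sp1": [_locus("mir-1"), _locus("mir-92a", 200), _locus("mir-92b", 400),
                    _locus("mir-92a-2", 600)],
            "sp2": [_locus("mir-1", species="sp2"), _locus("mir-92", 200, species="sp2")],
        }
        tab = copy_number_table(loci).set_index("species")
        # both families are conserved (present in both species)
        assert tab.loc["sp1", "single_copy_fraction"] == 0.5
        assert tab.loc["sp1", "multi_copy_fraction"] == 0.5
        assert tab.loc["sp1", "max_copies"] == 3
        assert tab.loc["sp2", "multi_copy_fraction"] == 0.0

    def test_copy_table_equals_brute_force_recount(self):
        rng = np.random.default_rng(0)
        fams = [f"mir-{i}" for i in range(1, 15)]
        loci = {}
        for sp in ("a", "b", "c"):
            loci[sp] = []
            for i, f in enumerate(fams):
                for c in range(int(rng.integers(0, 4))):
                    loci[sp].append(_locus(f"{f}{'abc'[c]}", 100 * i + c, species=sp))
        tab = copy_number_table(loci).set_index("species")
        for sp in loci:
            counts = family_copy_counts(loci[sp])
            presence = {}
            for s2 in loci:
                for f in family_copy_counts(loci[s2]).index:
                    presence.setdefault(f, set()).add(s2)
            conserved = {f: c for f, c in counts.items() if len(presence[f]) >= 2}
            multi = sum(1 for c in conserved.values() if c > 1)
            assert tab.loc[sp, "n_multi_copy"] == multi
            if conserved:
                assert tab.loc[sp, "multi_copy_fraction"] == pytest.approx(
                    multi / len(conserved)
                )


class TestClusters:
    def test_eight_members_within_one_kb(self):
        loci = [_locus(f"mir-{i}", 1000 + 120 * i, length=80) for i in range(8)]
        clusters = detect_clusters(loci, max_gap=10_000)
        assert len(clusters) == 1 and len(clusters[0].members) == 8

    def test_distant_loci_split(self):
        loci = [_locus("mir-1", 0), _locus("mir-2", 50_000)]
        clusters = detect_clusters(loci, max_gap=10_000)
        assert [len(c.members) for c in clusters] == [1, 1]

    def test_order_invariance_and_brute_force(self):
        rng = np.random.default_rng(1)
        loci = [_locus(f"mir-{i}", int(rng.integers(0, 200_000))) for i in range(40)]
        gap = 3000
        shuffled = list(loci)
        rng.shuffle(shuffled)
        a = [tuple(m.name for m in c.members) for c in detect_clusters(loci, gap)]
        b = [tuple(m.name for m in c.members) for c in detect_clusters(shuffled, gap)]
        assert a == b
        # brute force: sort, split where gap exceeded
        srt = sorted(loci, key=lambda m: m.start)
        groups, cur = [], [srt[0]]
        for m in srt[1:]:
            if m.start - max(x.end for x in cur) <= gap:
                cur.append(m)
            else:
                groups.append(cur)
                cur = [m]
        groups.append(cur)
        assert a == [tuple(x.name for x in g) for g in groups]


class TestConsensus:
    def test_identical_sequences_all_uppercase(self):
        assert consensus(["ACGTT"] * 5) == "ACGTT"

    def test_minority_position_lowercase(self):
        seqs = ["TAAAA"] * 6 + ["AAAAA"] * 4
        # position 1: 60% T < 0.9 threshold -> lowercase
        assert consensus(seqs, 0.9) == "tAAAA"

    def test_case_threshold_boundary(self):
        seqs = ["TAAAA"] * 9 + ["AAAAA"]
        assert consensus(seqs, 0.9) == "TAAAA"

    def test_idempotence_case_stripped(self):
        rng = np.random.default_rng(2)
        seqs = []
        base = "ACGTACGTACGTACGT"
        for _ in range(20):
            s = list(base)
            for p in rng.choice(len(s), size=2, replace=False):
                s[p] = "ACGT"[rng.integers(4)]
            seqs.append("".join(s))
        c1 = consensus(seqs)
        assert consensus([c1.upper()]).upper() == c1.upper()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            consensus([])


class TestDistances:
    def test_identical_and_simple_pairs(self):
        aln = {"a": "ACGTACGTAC", "b": "ACGTACGTAC", "c": "ACGTACGTTT"}
        d = p_distance_matrix(aln)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == pytest.approx(0.2)
        assert np.allclose(d, d.T)

    def test_pairwise_deletion_of_gaps(self):
        aln = {"a": "AC-TA", "b": "ACGTT"}
        # comparable sites: A,C,T,A vs A,C,T,T -> 1/4
        assert p_distance_matrix(aln).loc["a", "b"] == pytest.approx(0.25)

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(ValueError):
            p_distance_matrix({"a": "--AA", "b": "AA--"})

    def test_random_recount(self):
        rng = np.random.default_rng(3)
        aln = {
            f"s{i}": "".join("ACGT-"[b] for b in rng.choice(5, 60, p=[0.23] * 4 + [0.08]))
            for i in range(5)
        }
        d = p_distance_matrix(aln)
        names = list(aln)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                sites = [
                    (x, y) for x, y in zip(aln[a], aln[b]) if x != "-" and y != "-"
                ]
                expected = sum(1 for x, y in sites if x != y) / len(sites)
                assert d.loc[a, b] == pytest.approx(expected)


def _tree_leaf_distances(node, acc=None):
    """Path lengths between all leaf pairs of a tree."""
    if not node.children:
        return {node.name: 0.0}
    sides = []
    pairs = {}
    for child, bl in node.children:
        sub = _tree_leaf_distances(child, acc)
        if isinstance(sub, tuple):
            sub, sub_pairs = sub
            pairs.update(sub_pairs)
        sides.append({k: v + bl for k, v in sub.items()})
    for x in range(len(sides)):
        for y in range(x + 1, len(sides)):
            for na, da in sides[x].items():
                for nb, db in sides[y].items():
                    pairs[frozenset((na, nb))] = da + db
    merged = {}
    for s in sides:
        merged.update(s)
    return merged, pairs


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        tree = nj_tree(d)
        bl = {c.name: b for c, b in tree.children}
        assert bl["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert bl["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert bl["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_additive_round_trip_exact(self):
        """Exact topology and branch-length recovery on 100 random
        additive matrices of 4-10 taxa."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 11))
            true_tree, dmat = random_additive_tree(n, rng)
            rec = nj_tree(dmat)
            assert tree_bipartitions(rec) == tree_bipartitions(true_tree)
            _, pairs = _tree_leaf_distances(rec)
            for (pair, dist) in pairs.items():
                a, b = sorted(pair)
                assert dist == pytest.approx(dmat.loc[a, b], abs=1e-9)

    def test_against_independent_implementation(self):
        """Topology agrees with scikit-bio's neighbour joining."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        for _ in range(5):
            n = int(rng.integers(5, 9))
            _t, dmat = random_additive_tree(n, rng)
            mine = tree_bipartitions(nj_tree(dmat))
            sk = skbio_nj(DistanceMatrix(dmat.to_numpy(), ids=list(dmat.index)))
            theirs = set()
            leaves = frozenset(dmat.index)
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                other = leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    theirs.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            assert mine == theirs

    def test_asymmetric_matrix_rejected(self):
        d = pd.DataFrame([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float,
                         index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            nj_tree(d)


class TestBootstrap:
    def _clean_alignment(self):
        # two well-separated clades, no homoplasy: every resample
        # reproduces the split
        a = "A" * 30 + "C" * 30
        b = "A" * 30 + "C" * 29 + "T"
        c = "G" * 30 + "C" * 30
        d = "G" * 30 + "C" * 29 + "A"
        return {"a": a, "b": b, "c": c, "d": d}

    def test_unambiguous_split_full_support(self):
        support = bootstrap_support(self._clean_alignment(), n_replicates=50, seed=1)
        assert support
        assert all(v == 1.0 for v in support.values())

    def test_single_replicate_support_binary(self):
        rng = np.random.default_rng(9)
        aln = {
            f"s{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 40)) for i in range(5)
        }
        support = bootstrap_support(aln, n_replicates=1, seed=2)
        assert set(support.values()) <= {0.0, 1.0}

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(10)
        aln = {
            f"s{i}": "".join("ACGT"[b] for b in rng.integers(0, 4, 60)) for i in range(6)
        }
        s1 = bootstrap_support(aln, n_replicates=30, seed=5)
        s2 = bootstrap_support(aln, n_replicates=30, seed=5)
        assert s1 == s2
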