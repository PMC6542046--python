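import numpy as np
import pytest

from httguard.consensus_evo import (
    CopyRecord,
    DistanceMatrix,
    build_consensus,
    defragment,
    find_orfs,
    k2p_distance_matrix,
    longest_orf,
    is_cherry,
    midpoint_root,
    nj_tree,
    pairwise_identity,
    select_top_copies,
    star_score,
)
from httguard.io_formats import Interval, SeqRecord
from httguard.repeatmask import RepeatAnnotation
from httguard.simfixtures import evolve_te_family, make_te_ancestor, mutate_sequence
from conftest import mutate_subs, random_seq
from oracles import orf_scan_oracle


class TestBuildConsensus:
    def test_identical_fragments_reproduce_sequence(self, rng):
        seed = SeqRecord(id="seed", residues=random_seq(rng, 400))
        frags = [SeqRecord(id=f"f{i}", residues=seed.residues) for i in range(10)]
        model = build_consensus(frags, seed)
        assert model.consensus.residues == seed.residues
        assert model.n_input_fragments == 10
        assert len(model.coverage) == 400

    def test_empty_fragment_list_errors(self, rng):
        with pytest.raises(ValueError):
            build_consensus([], SeqRecord(id="s", residues="ACGT"))

    def test_ancestor_recovery_from_diverged_copies(self, rng):
        ancestor = make_te_ancestor(900, rng, name="anc")
        copies, _ = evolve_te_family(ancestor, 30, 0.10, 2.0, 0.0005, rng)
        # seed is itself a diverged relative, not the ancestor
        seed_seq, _ = mutate_sequence(ancestor.residues, 0.10, 2.0, 0.0005, rng)
        model = build_consensus(copies, SeqRecord(id="seed", residues=seed_seq))
        ident = pairwise_identity([model.consensus, ancestor]).values[0, 1]
        assert ident >= 99.0

    def test_low_coverage_column_falls_back_to_seed(self):
        seed = SeqRecord(id="seed", residues="ACGTACGTACGTACGTACGTACGT")
        # two fragments disagreeing with the seed at one covered column
        frag = "ACGTACGAACGTACGTACGT"
        frags = [SeqRecord(id="f1", residues=frag), SeqRecord(id="f2", residues=frag)]
        model = build_consensus(frags, seed, min_coverage=3)
        assert model.consensus.residues == seed.residues  # coverage 2 < 3 everywhere


class TestPairwiseIdentity:
    def test_identical_pair_is_100(self, rng):
        s = SeqRecord(id="a", residues=random_seq(rng, 100))
        t = SeqRecord(id="b", residues=s.residues)
        m = pairwise_identity([s, t])
        assert m.get("a", "b") == 100.0

    def test_hand_countable_example(self):
        m = pairwise_identity(
            [SeqRecord(id="a", residues="ACGT"), SeqRecord(id="b", residues="ACGA")]
        )
        assert m.get("a", "b") == pytest.approx(75.0)

    def test_symmetric_with_diagonal_100(self, rng):
        recs = [
            SeqRecord(id=f"s{i}", residues=random_seq(rng, 80)) for i in range(4)
        ]
        m = pairwise_identity(recs)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 100.0)

    def test_substitution_only_pairs_match_column_oracle(self, rng):
        # at low divergence the optimal alignment is gapless, so identity
        # must equal the direct mismatch count
        for _ in range(50):
            n = int(rng.integers(60, 200))
            a = random_seq(rng, n)
            n_subs = int(rng.integers(0, n // 10))
            b = mutate_subs(rng, a, n_subs)
            m = pairwise_identity(
                [SeqRecord(id="a", residues=a), SeqRecord(id="b", residues=b)]
            )
            assert m.get("a", "b") == pytest.approx(100.0 * (n - n_subs) / n)


def _ann(seq_id, start, end, strand="+", family="fam", cons=(0, 100), div=5.0):
    return RepeatAnnotation(
        Interval(seq_id, start, end, strand), family, div, 100.0, consensus_span=cons
    )


class TestDefragment:
    def test_split_copy_merges_with_fragment_conservation(self):
        anns = [
            _ann("c", 1000, 1500, cons=(0, 500)),
            _ann("c", 1800, 2300, cons=(500, 1000)),  # 300 bp insertion between
        ]
        copies = defragment(anns)
        assert len(copies) == 1
        assert len(copies[0].fragments) == 2
        assert copies[0].merged_length == 1000
        assert (copies[0].genomic_span.start, copies[0].genomic_span.end) == (1000, 2300)

    def test_tandem_full_length_copies_stay_separate(self):
        # consensus coordinates restart -> not collinear
        anns = [
            _ann("c", 1000, 2000, cons=(0, 1000)),
            _ann("c", 2100, 3100, cons=(0, 1000)),
        ]
        copies = defragment(anns)
        assert len(copies) == 2

    def test_opposite_strands_never_merge(self):
        anns = [
            _ann("c", 1000, 1500, "+", cons=(0, 500)),
            _ann("c", 1600, 2100, "-", cons=(500, 1000)),
        ]
        assert len(defragment(anns)) == 2

    def test_gap_over_max_gap_not_merged(self):
        anns = [
            _ann("c", 0, 500, cons=(0, 500)),
            _ann("c", 6000, 6500, cons=(500, 1000)),
        ]
        assert len(defragment(anns, max_gap=5000)) == 2

    def test_intervening_other_family_breaks_chain(self):
        anns = [
            _ann("c", 1000, 1500, cons=(0, 500)),
            _ann("c", 1600, 1900, family="other", cons=(0, 300)),
            _ann("c", 2000, 2500, cons=(500, 1000)),
        ]
        copies = defragment(anns)
        fam_copies = [c for c in copies if c.fragments[0].family == "fam"]
        assert len(fam_copies) == 2

    def test_minus_strand_collinearity_mirrored(self):
        # on the minus strand, downstream genomic fragments carry upstream
        # consensus coordinates
        anns = [
            _ann("c", 1000, 1500, "-", cons=(500, 1000)),
            _ann("c", 1800, 2300, "-", cons=(0, 500)),
        ]
        assert len(defragment(anns)) == 1

    def test_fragment_count_conserved(self, rng):
        anns = []
        pos = 0
        for i in range(30):
            start = pos + int(rng.integers(100, 2000))
            end = start + int(rng.integers(100, 800))
            anns.append(
                _ann("c", start, end,
                     strand="+" if rng.random() < 0.5 else "-",
                     cons=(int(rng.integers(0, 500)), int(rng.integers(500, 1000))))
            )
            pos = end
        copies = defragment(anns)
        assert sum(len(c.fragments) for c in copies) == len(anns)


class TestSelectTopCopies:
    def _copy(self, length, div):
        return CopyRecord(
            species="sp",
            fragments=[],
            genomic_span=Interval("c", 0, max(length, 1)),
            strand="+",
            merged_length=length,
            mean_divergence_pct=div,
        )

    def test_length_primary_divergence_secondary(self):
        copies = [self._copy(500, 5), self._copy(400, 2), self._copy(400, 9)]
        top = select_top_copies(copies, n=3)
        assert [(c.merged_length, c.mean_divergence_pct) for c in top] == [
            (500, 5), (400, 2), (400, 9)
        ]

    def test_n_larger_than_list_returns_all(self):
        copies = [self._copy(100, 1)]
        assert select_top_copies(copies, n=100) == copies

    def test_matches_sort_oracle(self, rng):
        for _ in range(100):
            copies = [
                self._copy(int(rng.integers(100, 1000)), float(rng.integers(0, 30)))
                for _ in range(20)
            ]
            top = select_top_copies(copies, n=10)
            expected = sorted(
                copies, key=lambda c: (-c.merged_length, c.mean_divergence_pct)
            )[:10]
            assert top == expected


class TestOrfs:
    def test_single_long_orf(self):
        seq = "ATG" + "AAA" * 50 + "TAA"
        orfs = find_orfs(seq, min_codons=30)
        plus_one = [o for o in orfs if o.frame == 1]
        assert len(plus_one) == 1
        assert len(plus_one[0].peptide) == 51
        assert (plus_one[0].start, plus_one[0].end) == (0, 153)

    def test_reverse_strand_coordinates(self, rng):
        from httguard.alignkit import revcomp
        from oracles import translate_oracle

        fwd = "ATG" + "GAA" * 40 + "TAA"
        pad_l, pad_r = "CCTTCC", "GGTTGG"
        seq = pad_l + revcomp(fwd) + pad_r
        orfs = [o for o in find_orfs(seq, min_codons=30) if o.frame < 0]
        assert orfs
        # the forward-strand coordinates must cut out exactly the segment
        # whose reverse complement translates to the reported peptide
        for o in orfs:
            sub = seq[o.start : o.end]
            assert translate_oracle(revcomp(sub)) == o.peptide
        minus_one = [o for o in orfs if o.frame == -1]
        assert minus_one and "MEE" in minus_one[0].peptide

    def test_agrees_with_exhaustive_scan_oracle(self, rng):
        for _ in range(50):
            seq = random_seq(rng, 2000)
            got = sorted((o.frame, o.peptide) for o in find_orfs(seq, 30))
            expected = sorted(orf_scan_oracle(seq, 30))
            assert got == expected

    def test_longest_orf_tiebreak_by_frame_order(self):
        assert longest_orf("A" * 300, min_codons=30).frame == 1


class TestTrees:
    def _additive_dm(self):
        # tree: ((A:1,B:2):1,(C:3,D:4):1) -> additive distances
        d = {
            ("A", "B"): 3, ("A", "C"): 6, ("A", "D"): 7,
            ("B", "C"): 7, ("B", "D"): 8, ("C", "D"): 7,
        }
        labels = ["A", "B", "C", "D"]
        vals = np.zeros((4, 4))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i < j:
                    vals[i, j] = vals[j, i] = d[(x, y)]
        return DistanceMatrix(labels, vals)

    def test_nj_recovers_additive_topology_and_lengths(self):
        tree = nj_tree(self._additive_dm())
        assert is_cherry(tree, "A", "B")
        assert is_cherry(tree, "C", "D")
        assert not is_cherry(tree, "A", "C")
        # pairwise path lengths reproduce the additive matrix
        tips = {t.name: t for t in tree.tips()}
        dm = self._additive_dm()
        for i, x in enumerate(dm.labels):
            for j, y in enumerate(dm.labels):
                if i < j:
                    assert tree.find(x).distance(tree.find(y)) == pytest.approx(
                        dm.values[i, j]
                    )

    def test_three_taxa_unique_topology(self):
        vals = np.array([[0.0, 2, 3], [2, 0, 3], [3, 3, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], vals))
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0.0]])))

    def test_asymmetric_matrix_rejected(self):
        vals = np.array([[0.0, 1, 2], [9, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], vals)

    def test_midpoint_root_equidistant_on_ultrametric(self):
        vals = np.array(
            [[0.0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0.0]]
        )
        tree = midpoint_root(nj_tree(DistanceMatrix(list("abcd"), vals)))
        depths = [tree.find(n).accumulate_to_ancestor(tree) for n in "abcd"]
        assert max(depths) - min(depths) < 1e-9

    def test_star_score_zero_for_star_and_positive_for_caterpillar(self):
        from skbio.tree import TreeNode

        star = TreeNode.read(["(a:1,b:1,c:1,d:1);"])
        assert star_score(star) == 0.0
        cat = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        # 2 internal units over 6 total
        assert star_score(cat) == pytest.approx(2 / 6)

    def test_k2p_distance_matrix_symmetric_zero_diagonal(self, rng):
        anc = make_te_ancestor(600, rng)
        recs = []
        for i in range(3):
            seq, _ = mutate_sequence(anc.residues, 0.1, 2.0, 0.0, rng)
            recs.append(SeqRecord(id=f"t{i}", residues=seq))
        dm = k2p_distance_matrix(recs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert dm.values[0, 1] > 0
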