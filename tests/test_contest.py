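import numpy as np
import pytest

from httguard.alignkit import SearchDatabase, revcomp
from httguard.contest import (
    classify,
    select_long_reads,
    select_pairs_noref,
    select_pairs_reference,
    summarize,
)
from httguard.io_formats import Interval, ReadPair, SeqRecord
from httguard.simfixtures import Placement
from conftest import mutate_subs, random_seq


@pytest.fixture
def classification_world(rng):
    """Focal species genome, a self-taxon relative, a non-self genome, and
    a repeat family shared as needed."""
    te = SeqRecord(id="rte", residues=random_seq(rng, 600))
    focal_bg = random_seq(rng, 4000)
    relative = mutate_subs(rng, focal_bg, 400)  # 10% diverged relative
    alien_bg = random_seq(rng, 4000)
    self_db = SearchDatabase(
        [
            SeqRecord(id="focal_chr", residues=focal_bg, species_tag="focal"),
            SeqRecord(id="relative_chr", residues=relative, species_tag="relative"),
        ],
        label="self",
    )
    nonself_db = SearchDatabase(
        [SeqRecord(id="alien_chr", residues=alien_bg, species_tag="alien")],
        label="non-self",
    )
    return te, focal_bg, alien_bg, self_db, nonself_db


class TestClassify:
    def test_focal_flank_classified_self(self, classification_world):
        te, focal_bg, _, self_db, nonself_db = classification_world
        read = SeqRecord(id="r", residues=focal_bg[1000:1150])
        c = classify(read, self_db, nonself_db, "focal", [te])
        assert c.verdict == "self"
        assert c.best_hit.subject_species == "relative"
        assert c.discarded_own_genome_hits >= 1  # exact own-genome hit dropped

    def test_alien_flank_classified_nonself(self, classification_world):
        te, _, alien_bg, self_db, nonself_db = classification_world
        read = SeqRecord(id="r", residues=alien_bg[2000:2150])
        c = classify(read, self_db, nonself_db, "focal", [te])
        assert c.verdict == "non-self"
        assert c.best_hit.subject_species == "alien"

    def test_own_genome_only_hit_is_unassigned(self, rng):
        # focal region private to the focal genome: discarding own-genome
        # hits leaves nothing
        te = SeqRecord(id="rte", residues=random_seq(rng, 600))
        private = random_seq(rng, 2000)
        self_db = SearchDatabase(
            [SeqRecord(id="focal_chr", residues=private, species_tag="focal")],
            label="self",
        )
        nonself_db = SearchDatabase(
            [SeqRecord(id="alien_chr", residues=random_seq(rng, 2000),
                       species_tag="alien")],
            label="non-self",
        )
        read = SeqRecord(id="r", residues=private[500:650])
        c = classify(read, self_db, nonself_db, "focal", [te])
        assert c.verdict == "unassigned"
        assert c.discarded_own_genome_hits >= 1

    def test_identical_subject_in_both_databases_is_ambiguous(self, rng):
        te = SeqRecord(id="rte", residues=random_seq(rng, 600))
        shared = random_seq(rng, 2000)
        self_db = SearchDatabase(
            [SeqRecord(id="s_chr", residues=shared, species_tag="s_sp")], "self"
        )
        nonself_db = SearchDatabase(
            [SeqRecord(id="n_chr", residues=shared, species_tag="n_sp")], "non-self"
        )
        read = SeqRecord(id="r", residues=shared[100:250])
        c = classify(read, self_db, nonself_db, "focal", [te])
        assert c.verdict == "ambiguous"

    def test_te_only_read_is_low_quality_after_masking(self, classification_world):
        te, _, _, self_db, nonself_db = classification_world
        read = SeqRecord(id="r", residues=te.residues[100:250])
        c = classify(read, self_db, nonself_db, "focal", [te])
        assert c.verdict == "low-quality"

    def test_invariant_to_read_reverse_complement(self, classification_world):
        te, focal_bg, _, self_db, nonself_db = classification_world
        read = SeqRecord(id="r", residues=focal_bg[1000:1150])
        rc = SeqRecord(id="r", residues=revcomp(read.residues))
        a = classify(read, self_db, nonself_db, "focal", [te])
        b = classify(rc, self_db, nonself_db, "focal", [te])
        assert (a.verdict, a.best_hit.subject_id, a.best_hit.bitscore) == (
            b.verdict, b.best_hit.subject_id, b.best_hit.bitscore
        )

    def test_invariant_to_database_record_order(self, classification_world):
        te, focal_bg, _, self_db, nonself_db = classification_world
        flipped = SearchDatabase(list(reversed(self_db.records)), "self")
        read = SeqRecord(id="r", residues=focal_bg[2500:2650])
        a = classify(read, self_db, nonself_db, "focal", [te])
        b = classify(read, flipped, nonself_db, "focal", [te])
        assert (a.verdict, a.best_hit.subject_id) == (b.verdict, b.best_hit.subject_id)

    def test_removing_own_genome_never_changes_verdict(self, classification_world):
        te, focal_bg, _, self_db, nonself_db = classification_world
        slim = SearchDatabase(
            [r for r in self_db.records if r.species_tag != "focal"], "self"
        )
        for start in (500, 1500, 3000):
            read = SeqRecord(id="r", residues=focal_bg[start : start + 150])
            a = classify(read, self_db, nonself_db, "focal", [te])
            b = classify(read, slim, nonself_db, "focal", [te])
            assert a.verdict == b.verdict


class TestSelection:
    def _pair(self, pid, s1, s2):
        return ReadPair(
            SeqRecord(id=f"{pid}/1", residues=s1, qualities=[40] * len(s1)),
            SeqRecord(id=f"{pid}/2", residues=s2, qualities=[40] * len(s2)),
            pid,
        )

    def test_noref_keeps_flank_mate_of_rte_pairs(self, rng):
        te = SeqRecord(id="rte", residues=random_seq(rng, 600))
        flank = random_seq(rng, 150)
        pairs = [
            self._pair("p0", te.residues[10:160], flank),       # keep -> flank
            self._pair("p1", te.residues[0:150], te.residues[200:350]),  # both
            self._pair("p2", random_seq(rng, 150), random_seq(rng, 150)),  # none
        ]
        informative, counters = select_pairs_noref(pairs, te)
        assert [r.id for r in informative] == ["p0/2"]
        assert counters == {"both_rte": 1, "neither_rte": 0, "reciprocal_fail": 0,
                            "kept": 1} or counters["kept"] == 1

    def test_reference_mode_discards_pairs_with_both_mates_in_rte(self, rng):
        te = SeqRecord(id="rte", residues=random_seq(rng, 600))
        bed = [Interval("chr1", 1000, 1600)]
        flank = random_seq(rng, 150)
        pairs = [
            self._pair("in_both", te.residues[:150], te.residues[300:450]),
            self._pair("one_in", te.residues[100:250], flank),
            self._pair("none_in", flank, random_seq(rng, 150)),
            self._pair("unmapped", flank, flank),
        ]
        mappings = {
            "in_both": (Placement("chr1", 1050, 1200, False),
                        Placement("chr1", 1300, 1450, True)),
            "one_in": (Placement("chr1", 1100, 1250, False),
                       Placement("chr1", 2000, 2150, True)),
            "none_in": (Placement("chr1", 3000, 3150, False),
                        Placement("chr1", 3400, 3550, True)),
            "unmapped": (None, None),
        }
        kept, counters = select_pairs_reference(pairs, mappings, bed, te)
        assert [(info.id, rte.id) for info, rte in kept] == [("one_in/2", "one_in/1")]
        assert counters["both_in_rte"] == 1
        assert counters["unmapped"] == 1

    def test_reference_mode_reciprocal_check_rejects_non_rte_mate(self, rng):
        te = SeqRecord(id="rte", residues=random_seq(rng, 600))
        other_family = SeqRecord(id="other", residues=random_seq(rng, 600))
        bed = [Interval("chr1", 1000, 1600)]
        # the mate that maps into the interval is actually another family
        pair = self._pair("p", other_family.residues[:150], random_seq(rng, 150))
        mappings = {"p": (Placement("chr1", 1100, 1250, False),
                          Placement("chr1", 2000, 2150, True))}
        kept, counters = select_pairs_reference(
            pair and [pair], mappings, bed, te, repeat_library=[te, other_family]
        )
        assert kept == []
        assert counters["reciprocal_fail"] == 1

    def test_long_read_selection_by_orf(self, rng, toy_scenario):
        data = toy_scenario
        selected = select_long_reads(data.long_reads, data.rte_orf_protein)
        selected_ids = {r.id for r in selected}
        overlapping = {
            rid for rid, ov in data.truth.te_overlap.items()
            if ov and rid.startswith("rec_long")
        }
        # every selected read truly overlaps the element
        assert selected_ids <= overlapping

    def test_counts_conserved_across_verdicts(self, rng, toy_scenario):
        data = toy_scenario
        te = data.te_ancestor
        informative, _ = select_pairs_noref(data.pairs[:150], te)
        self_db = SearchDatabase(data.self_records, "self")
        nonself_db = SearchDatabase(data.nonself_records, "non-self")
        cls = [
            classify(r, self_db, nonself_db, "recipient", [te]) for r in informative
        ]
        s = summarize(cls)
        assert (
            s.n_self + s.n_nonself + s.n_ambiguous + s.n_unassigned + s.n_low_quality
            == s.n_selected
            == len(informative)
        )


class TestSummarize:
    def test_published_count_example(self):
        # 5478 selected long reads, 5309 with better non-self (host) hits
        s = summarize({"self": 169, "nonself": 5309})
        assert s.n_selected == 5478
        assert s.frac_nonself == pytest.approx(5309 / 5478, abs=1e-4)
        assert s.frac_nonself == pytest.approx(0.969, abs=1e-3)
        assert s.call == "contamination"

    def test_all_self_is_endogenous(self):
        s = summarize({"self": 10, "nonself": 0})
        assert s.frac_self == 1.0
        assert s.call == "endogenous/HTT-consistent"

    def test_zero_assigned_inconclusive_with_warning(self):
        s = summarize({"unassigned": 5})
        assert s.call == "inconclusive"
        assert s.warning is not None

    def test_fractions_match_hand_ratios_on_random_counts(self, rng):
        for _ in range(20):
            ns, nn = int(rng.integers(0, 500)), int(rng.integers(0, 500))
            na, nu = int(rng.integers(0, 50)), int(rng.integers(0, 50))
            s = summarize({"self": ns, "nonself": nn, "ambiguous": na,
                           "unassigned": nu})
            assert s.n_selected == ns + nn + na + nu
            if ns + nn:
                assert s.frac_self == pytest.approx(ns / (ns + nn))
                assert s.frac_self + s.frac_nonself == pytest.approx(1.0)

    def test_majority_threshold_controls_call(self):
        s = summarize({"self": 75, "nonself": 25}, call_threshold=0.80)
        assert s.call == "inconclusive"
        s = summarize({"self": 85, "nonself": 15}, call_threshold=0.80)
        assert s.call == "endogenous/HTT-consistent"
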