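"""Annotation cascade: conserved-miRNA matching rules, piRNA calling,
partition and priority properties."""

import pandas as pd
import pytest

from mirgonad.align import HitLocus
from mirgonad.annotate import (DEFAULT_PRIORITY, ConservedMatcher, FeatureIndex,
                               annotate_cascade, call_pirna, category_counts,
                               match_conserved_mirna, select_mature_representative)
from mirgonad.preprocess import SequenceTag

MATURE = "TAGCTTATCAGACTGATGTTGA"  # 22 nt
PRECURSOR = "GGACGT" + MATURE + "GTGAAACT" + "TCAACATCAGTCTGATAAGCTA" + "CCATGA"
REFS = ({"ref-miR-21-5p": MATURE}, {"ref-mir-21": PRECURSOR}, {"ref-miR-21-5p": ["ref-mir-21"]})


def _tag(seq, tid="tag_000001", counts=None):
    return SequenceTag(tid, seq, counts or {"ovary": 5})


def _mut(seq, pos, base=None):
    alt = base or next(b for b in "ACGT" if b != seq[pos])
    return seq[: pos] + alt + seq[pos + 1 :]


class TestConservedMatching:
    def test_exact_tag_matches(self):
        m = match_conserved_mirna(_tag(MATURE), *REFS)
        assert m is not None
        assert m.mature_id == "ref-miR-21-5p"
        assert m.overlap == 22 and m.mismatches == 0
        assert m.offset_on_precursor == 6

    def test_two_mismatches_outside_seed_allowed(self):
        # reference differs from the (precursor-resident) tag at
        # positions 10 and 15 -- outside the seed (positions 2-8)
        mature_refs = {"ref-miR-21-5p": _mut(_mut(MATURE, 10), 15)}
        m = match_conserved_mirna(_tag(MATURE), mature_refs, REFS[1], REFS[2])
        assert m is not None and m.mismatches == 2

    def test_three_mismatches_outside_seed_rejected(self):
        mature_refs = {"ref-miR-21-5p": _mut(_mut(_mut(MATURE, 10), 15), 18)}
        assert match_conserved_mirna(_tag(MATURE), mature_refs, REFS[1], REFS[2]) is None

    def test_seed_mismatch_rejected(self):
        mature_refs = {"ref-miR-21-5p": _mut(MATURE, 3)}  # seed position 4
        assert match_conserved_mirna(_tag(MATURE), mature_refs, REFS[1], REFS[2]) is None

    def test_short_overlap_rejected(self):
        # a 15-nt fragment of the mature: overlap below the 16-nt floor
        assert match_conserved_mirna(_tag(MATURE[:15]), *REFS) is None
        # 16-nt fragment passes (and maps into the precursor)
        assert match_conserved_mirna(_tag(MATURE[:16]), *REFS) is not None

    def test_tag_absent_from_precursor_rejected(self):
        # matches the mature but does not occur in any linked precursor
        tag = _tag(_mut(MATURE, 12))
        assert match_conserved_mirna(tag, *REFS) is None

    def test_missing_precursor_link_is_configuration_error(self):
        with pytest.raises(ValueError):
            ConservedMatcher({"m1": MATURE}, {}, {"m1": []})
        with pytest.raises(ValueError):
            ConservedMatcher({"m1": MATURE}, {}, {"m1": ["nope"]})

    def test_order_independence(self):
        """Shuffling the reference set does not change assignments."""
        mature_refs = {"ref-miR-21-5p": MATURE, "zz-miR-9-5p": _mut(MATURE, 20)}
        m2p = {"ref-miR-21-5p": ["ref-mir-21"], "zz-miR-9-5p": ["ref-mir-21"]}
        a = match_conserved_mirna(_tag(MATURE), mature_refs, REFS[1], m2p)
        rev = dict(reversed(list(mature_refs.items())))
        b = match_conserved_mirna(_tag(MATURE), rev, REFS[1], m2p)
        assert a.mature_id == b.mature_id == "ref-miR-21-5p"


class TestRepresentative:
    def test_highest_count_wins(self):
        tags = [_tag("A" * 20, "t1", {"o": 50}), _tag("C" * 20, "t2", {"o": 10}),
                _tag("G" * 20, "t3", {"o": 3})]
        assert select_mature_representative(tags).tag_id == "t1"

    def test_single_tag(self):
        t = _tag("A" * 20)
        assert select_mature_representative([t]) is t

    def test_tie_breaks_to_smaller_sequence(self):
        tags = [_tag("TTTTAAAACCCCGGGGTTTT", "t1", {"o": 20}),
                _tag("AAAATTTTCCCCGGGGTTTT", "t2", {"o": 20})]
        assert select_mature_representative(tags).tag_id == "t2"


FEATURES = pd.DataFrame(
    [
        {"seqid": "chr1", "ftype": "exon", "start": 1000, "end": 1300, "strand": "+",
         "feature_id": "g1_exon1", "parent": "g1"},
        {"seqid": "chr1", "ftype": "intron", "start": 1300, "end": 1700, "strand": "+",
         "feature_id": "g1_intron1", "parent": "g1"},
        {"seqid": "chr1", "ftype": "repeat", "start": 3000, "end": 3500, "strand": "+",
         "feature_id": "rep1", "parent": ""},
    ]
)


class TestPirnaCall:
    def test_intergenic_in_band_called(self):
        tag = _tag("T" + "ACG" * 9)  # 28 nt, 5' U
        hit = HitLocus(0, "chr1", 5000, 5028, "+")
        ok, rec = call_pirna(tag, [hit], FEATURES)
        assert ok and rec.first_nt == "U" and rec.length == 28

    def test_below_band_not_called(self):
        tag = _tag("T" * 22)
        ok, _ = call_pirna(tag, [HitLocus(0, "chr1", 5000, 5022, "+")], FEATURES)
        assert not ok

    def test_genic_locus_not_called(self):
        tag = _tag("T" + "ACG" * 9)
        ok, _ = call_pirna(tag, [HitLocus(0, "chr1", 1100, 1128, "+")], FEATURES)
        assert not ok

    def test_repeat_locus_respects_flag(self):
        tag = _tag("T" + "ACG" * 9)
        hit = [HitLocus(0, "chr1", 3100, 3128, "+")]
        assert call_pirna(tag, hit, FEATURES)[0]
        assert not call_pirna(tag, hit, FEATURES, require_unannotated=True)[0]


class TestCascade:
    def test_intron_sense_single_applicable_class(self):
        tag = _tag("ACGT" * 5)
        hits = {tag.tag_id: [HitLocus(0, "chr1", 1400, 1420, "+")]}
        recs = annotate_cascade([tag], hits, FEATURES, {}, {}, {})
        assert recs[0].category == "intron_sense"

    def test_unmapped_tag_is_unannotated_not_an_error(self):
        tag = _tag("ACGT" * 5)
        recs = annotate_cascade([tag], {}, FEATURES, {}, {}, {})
        assert recs[0].category == "unannotated"

    def test_partition_on_full_synthetic_run(self, pipeline_result):
        """Every tag gets exactly one category; category counts sum to
        the number of tags."""
        counts = category_counts(pipeline_result.records)
        assert counts.sum() == len(pipeline_result.tags)
        assert len(pipeline_result.records) == len(pipeline_result.tags)

    def test_priority_monotonicity(self, pipeline_result):
        """Moving a category earlier in the priority never decreases
        its count."""
        res = pipeline_result
        toy = res.toy
        tags = res.tags[:3000]
        findex = FeatureIndex(toy.features)
        from mirgonad.align import SeedIndex, map_tags

        index = SeedIndex(toy.sequence, k=12)
        raw = map_tags((t.sequence for t in tags), index, 0, 20)
        genome_hits = {t.tag_id: raw[t.sequence][0] for t in tags}
        base = annotate_cascade(tags, genome_hits, findex, {}, {}, {})
        promoted = ("piRNA",) + tuple(c for c in DEFAULT_PRIORITY if c != "piRNA")
        moved = annotate_cascade(tags, genome_hits, findex, {}, {}, {}, priority=promoted)
        n_base = sum(r.category == "piRNA" for r in base)
        n_moved = sum(r.category == "piRNA" for r in moved)
        assert n_moved >= n_base
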