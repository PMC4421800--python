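"""Hairpin discovery: window extraction, duplex metrics against an
independent structure walk, criteria checks and planted recovery."""

import numpy as np
import pytest

from mirgonad.align import HitLocus, map_tag, SeedIndex
from mirgonad.folding import FoldResult, dotbracket_to_pairs
from mirgonad.hairpin import (DiscoveryParams, DuplexMetrics, HairpinCandidate,
                              discover_novel, evaluate_duplex,
                              evaluate_precursor_criteria, extract_candidate_windows)
from mirgonad.preprocess import SequenceTag


def _fr(structure, seq=None):
    seq = seq or "A" * len(structure)
    return FoldResult(seq, structure, -20.0, dotbracket_to_pairs(structure))


class TestWindows:
    def test_window_arithmetic(self):
        genome = {"c": "A" * 10_000}
        [w] = extract_candidate_windows([HitLocus(0, "c", 500, 522, "+")], genome, 100)
        assert (w.start, w.end) == (400, 622)
        assert (w.tag_start, w.tag_end) == (100, 122)

    def test_window_clipped_at_contig_start(self):
        genome = {"c": "A" * 10_000}
        [w] = extract_candidate_windows([HitLocus(0, "c", 30, 52, "+")], genome, 100)
        assert w.start == 0
        assert (w.tag_start, w.tag_end) == (30, 52)

    def test_minus_strand_orientation(self):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[b] for b in rng.integers(0, 4, 400))
        genome = {"c": seq}
        [w] = extract_candidate_windows([HitLocus(0, "c", 200, 222, "-")], genome, 50)
        from mirgonad.align import revcomp

        assert w.sequence == revcomp(seq[150:272])
        assert w.sequence[w.tag_start : w.tag_end] == revcomp(seq[200:222])


class TestDuplexMetrics:
    def test_perfect_duplex(self):
        # 20-bp stem with a 10-nt loop
        s = "(" * 20 + "." * 10 + ")" * 20
        m = evaluate_duplex(_fr(s), (0, 20), (30, 50))
        assert m == DuplexMetrics(20, 0, 0, 10)

    def test_single_bulge_counts_once_on_one_arm(self):
        # 3-nt bulge on the mature arm only: bulge 3, asymmetry 3
        s = "((((((((((" + "..." + "((((((((((" + "...." + ")))))))))))))))))))) "
        s = s.strip()
        m = evaluate_duplex(_fr(s), (0, 23), (27, 47))
        assert m.paired == 20
        assert m.bulge == 3
        assert m.asymmetry == 3
        assert m.loop_space == 4

    def test_overlapping_arms_rejected(self):
        with pytest.raises(ValueError):
            evaluate_duplex(_fr("." * 40), (0, 22), (20, 40))

    def test_metrics_match_structure_walk_on_folded_candidates(self, pipeline_result):
        """Recompute every candidate's duplex metrics from its pairing
        table with an independent walk."""
        checked = 0
        for r in pipeline_result.novel_results:
            c = r.candidate
            if c.star is None:
                continue
            pt = c.fold.pair_table()
            lo, hi = c.mature
            slo, shi = c.star
            paired = sum(1 for i in range(lo, hi) if slo <= pt[i] < shi)
            assert paired == c.metrics.paired

            def runs(a0, a1, o0, o1):
                pos = [i for i in range(a0, a1) if o0 <= pt[i] < o1]
                if not pos:
                    return 0, 0
                tot = best = cur = 0
                for i in range(pos[0], pos[-1] + 1):
                    if o0 <= pt[i] < o1:
                        cur = 0
                    else:
                        tot += 1
                        cur += 1
                        best = max(best, cur)
                return tot, best

            um, rm = runs(lo, hi, slo, shi)
            us, rs = runs(slo, shi, lo, hi)
            assert c.metrics.bulge == max(rm, rs)
            assert c.metrics.asymmetry == abs(um - us)
            checked += 1
        assert checked >= 20


def _candidate(**over):
    base = dict(
        reference="c", start=0, end=100, strand="+", precursor="A" * 100,
        fold=FoldResult("A" * 100, "." * 100, -25.0, []),
        mature=(10, 32), star=(40, 62),
        metrics=DuplexMetrics(paired=20, bulge=0, asymmetry=0, loop_space=8),
        cut_depth=10, copy_count=1, arm="5p",
    )
    base.update(over)
    return HairpinCandidate(**base)


class TestCriteria:
    def test_free_energy_just_above_threshold_rejected(self):
        cand = _candidate(fold=FoldResult("A" * 100, "." * 100, -17.5, []))
        ok, reasons = evaluate_precursor_criteria(cand, DiscoveryParams())
        assert not ok and reasons == ["free_energy"]

    def test_thirteen_pairs_rejected(self):
        cand = _candidate(metrics=DuplexMetrics(13, 0, 0, 8))
        ok, reasons = evaluate_precursor_criteria(cand, DiscoveryParams())
        assert not ok and reasons == ["min_pairs"]

    def test_all_thresholds_reported_by_name(self):
        cand = _candidate(
            mature=(10, 40),  # 30 nt
            fold=FoldResult("A" * 100, "." * 100, -5.0, []),
            metrics=DuplexMetrics(paired=5, bulge=6, asymmetry=9, loop_space=40),
            cut_depth=1, copy_count=25,
        )
        ok, reasons = evaluate_precursor_criteria(cand, DiscoveryParams())
        assert not ok
        assert reasons == ["mature_length", "cut_depth", "copy_number", "free_energy",
                           "loop_space", "min_pairs", "max_bulge", "asymmetry"]

    def test_passing_candidate_has_no_reasons(self):
        ok, reasons = evaluate_precursor_criteria(_candidate(), DiscoveryParams())
        assert ok and reasons == []


class TestDiscovery:
    def test_low_cut_depth_rejected(self, small_toy):
        """A mature supported by 2 reads at the modal 5' end fails the
        cut-depth criterion."""
        toy = small_toy
        fid = next(f for f, h in toy.hairpins.items() if h.reason == "cut_depth")
        h = toy.hairpins[fid]
        s, e = h.arms[h.mature_arm]
        mature = toy.sequence[h.reference][s:e]
        tag = SequenceTag("tag_000001", mature, {"testis": 2})
        index = SeedIndex(toy.sequence, k=12)
        hits = {"tag_000001": map_tag(mature, index, 0, 20)}
        results = discover_novel([tag], hits, toy.sequence, DiscoveryParams())
        ours = [r for r in results if r.candidate.start < e and r.candidate.end > s]
        assert len(ours) == 1
        assert not ours[0].accepted
        assert ours[0].reasons == ["cut_depth"]

    def test_planted_recovery_small_genome(self, small_toy):
        """All planted hairpins accepted, all decoys rejected for their
        designated reason, on the reduced synthetic genome."""
        toy = small_toy
        index = SeedIndex(toy.sequence, k=12)
        tags, hits = [], {}
        i = 0
        for fid, h in sorted(toy.hairpins.items()):
            if h.kind == "conserved":
                continue
            s, e = h.arms[h.mature_arm]
            mature = toy.sequence[h.reference][s:e]
            i += 1
            tid = f"tag_{i:06d}"
            n = 2 if h.reason == "cut_depth" else 50
            tags.append(SequenceTag(tid, mature, {"testis": n}))
            hits[tid] = map_tag(mature, index, 0, 20)
        results = discover_novel(tags, hits, toy.sequence, DiscoveryParams())
        for fid, h in sorted(toy.hairpins.items()):
            if h.kind == "conserved":
                continue
            mine = [r for r in results
                    if r.candidate.strand == "+"
                    and r.candidate.start < h.end and r.candidate.end > h.start]
            assert mine, fid
            if h.kind == "novel":
                assert any(r.accepted for r in mine), fid
            else:
                assert all(not r.accepted for r in mine), fid
                assert any(r.reasons == [h.reason] for r in mine), (fid, mine[0].reasons)
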