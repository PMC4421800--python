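"""Novel miRNA discovery from genome-mapped, unannotated tags.

Candidate genomic windows (tag locus plus ~100 nt of flank on either
side) are folded; the mature arm is placed from the read evidence, the
star arm is inferred from the pairing partners with the 2-nt 3'
overhang of Dicer processing, the precursor is trimmed to the duplex
plus a short margin and refolded, and each candidate is scored against
the full discovery criteria:

* mature length within 18-26 nt,
* read depth at the modal 5' cut site of at least 3,
* at most 20 genomic copies of the mature sequence,
* precursor free energy of at most -18 kcal/mol,
* at most 35 nt between the mature and star arms,
* at least 14 base pairs in the mature/star duplex,
* no bulge longer than 4 nt inside the duplex,
* duplex asymmetry (difference of unpaired counts) of at most 5.

Rejected candidates report every violated criterion by name, which is
what makes decoy auditing possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import HitLocus, revcomp
from .annotate import select_mature_representative
from .folding import FoldResult, fold

#: criterion names, in evaluation order
CRITERIA = (
    "mature_length",
    "cut_depth",
    "copy_number",
    "free_energy",
    "loop_space",
    "min_pairs",
    "max_bulge",
    "asymmetry",
)


@dataclass
class DiscoveryParams:
    """Thresholds of the novel-miRNA discovery criteria (defaults are
    the standard stem-loop prediction settings; energies in kcal/mol)."""

    mature_len_min: int = 18
    mature_len_max: int = 26
    min_cut_depth: int = 3
    max_copies: int = 20
    max_free_energy: float = -18.0
    max_loop_space: int = 35
    min_duplex_pairs: int = 14
    max_bulge: int = 4
    max_asymmetry: int = 5
    precursor_flank: int = 10
    window_flank: int = 100
    locus_merge_gap: int = 50
    #: tags up to this much longer than mature_len_max still enter
    #: discovery, so over-long matures are rejected by name rather than
    #: silently skipped
    length_slack: int = 4


@dataclass
class DuplexMetrics:
    paired: int
    bulge: int
    asymmetry: int
    loop_space: int


@dataclass
class CandidateWindow:
    reference: str
    start: int  # genomic, 0-based half-open, plus strand
    end: int
    strand: str
    tag_start: int  # position of the tag within the window (strand-oriented)
    tag_end: int
    sequence: str  # strand-oriented window sequence


@dataclass
class HairpinCandidate:
    reference: str
    start: int  # precursor genomic interval on the plus strand
    end: int
    strand: str
    precursor: str  # strand-oriented precursor sequence
    fold: FoldResult
    mature: tuple[int, int]  # precursor-local, half-open
    star: tuple[int, int] | None
    metrics: DuplexMetrics
    cut_depth: int
    copy_count: int
    arm: str  # 5p / 3p

    @property
    def mature_seq(self) -> str:
        return self.precursor[self.mature[0] : self.mature[1]]

    @property
    def star_seq(self) -> str:
        return "" if self.star is None else self.precursor[self.star[0] : self.star[1]]


def extract_candidate_windows(
    loci: list[HitLocus], genome: dict[str, str], flank: int = 100
) -> list[CandidateWindow]:
    """One strand-oriented candidate window per tag locus, clipped at
    contig edges."""
    out = []
    for hit in loci:
        ref = genome[hit.reference]
        ws = max(0, hit.start - flank)
        we = min(len(ref), hit.end + flank)
        seq = ref[ws:we]
        if hit.strand == "+":
            ts, te = hit.start - ws, hit.end - ws
        else:
            seq = revcomp(seq)
            ts, te = we - hit.end, we - hit.start
        out.append(CandidateWindow(hit.reference, ws, we, hit.strand, ts, te, seq))
    return out


def _unpaired_runs(pt, arm, other) -> tuple[int, int]:
    """(total unpaired, longest unpaired run) within the duplex span of
    ``arm``, where paired means paired into ``other``."""
    lo, hi = arm
    olo, ohi = other
    paired_pos = [i for i in range(lo, hi) if olo <= pt[i] < ohi]
    if not paired_pos:
        return 0, 0
    total = run = best = 0
    for i in range(paired_pos[0], paired_pos[-1] + 1):
        if olo <= pt[i] < ohi:
            run = 0
        else:
            total += 1
            run += 1
            best = max(best, run)
    return total, best


def evaluate_duplex(fr: FoldResult, mature: tuple[int, int], star: tuple[int, int]) -> DuplexMetrics:
    """Duplex metrics of a mature/star arm pair on a folded precursor.

    paired = base pairs joining the arms; bulge = longest unpaired run
    inside the duplex on either arm; asymmetry = |unpaired(mature) -
    unpaired(star)| inside the duplex; loop space = bases strictly
    between the arm intervals.
    """
    if not (mature[1] <= star[0] or star[1] <= mature[0]):
        raise ValueError("mature and star arms overlap")
    pt = fr.pair_table()
    paired = sum(1 for i in range(*mature) if star[0] <= pt[i] < star[1])
    u_m, run_m = _unpaired_runs(pt, mature, star)
    u_s, run_s = _unpaired_runs(pt, star, mature)
    if mature[1] <= star[0]:
        loop = star[0] - mature[1]
    else:
        loop = mature[0] - star[1]
    return DuplexMetrics(paired, max(run_m, run_s), abs(u_m - u_s), loop)


def build_candidate(
    genome: dict[str, str],
    locus: HitLocus,
    params: DiscoveryParams,
    cut_depth: int,
    copy_count: int,
) -> HairpinCandidate:
    """Fold the window around a mature locus and assemble the candidate."""
    window = extract_candidate_windows([locus], genome, params.window_flank)[0]
    wseq = window.sequence
    fr = fold(wseq)
    pt = fr.pair_table()
    ms, me = window.tag_start, window.tag_end
    partners = sorted({int(pt[i]) for i in range(ms, me) if pt[i] >= 0 and not (ms <= pt[i] < me)})
    right = [p for p in partners if p >= me]
    left = [p for p in partners if p < ms]
    side = right if len(right) >= len(left) else left

    if side:
        ss, se = min(side), max(side) + 1
        if side is right:
            se = min(se + 2, len(wseq))  # 2-nt 3' overhang of the star strand
        else:
            se = min(se + 2, ms)
        star_local: tuple[int, int] | None = (ss, se)
        lo = min(ms, ss)
        hi = max(me, se)
    else:
        star_local = None
        lo, hi = ms, me
    ps = max(0, lo - params.precursor_flank)
    pe = min(len(wseq), hi + params.precursor_flank)
    pseq = wseq[ps:pe]
    pfr = fold(pseq)
    mature = (ms - ps, me - ps)
    star = None if star_local is None else (star_local[0] - ps, star_local[1] - ps)
    if star is not None:
        metrics = evaluate_duplex(pfr, mature, star)
    else:
        metrics = DuplexMetrics(0, 0, 0, 0)
    if window.strand == "+":
        gstart, gend = window.start + ps, window.start + pe
    else:
        gstart, gend = window.end - pe, window.end - ps
    arm = "5p" if star is None or mature[0] < star[0] else "3p"
    return HairpinCandidate(
        window.reference,
        gstart,
        gend,
        window.strand,
        pseq,
        pfr,
        mature,
        star,
        metrics,
        cut_depth,
        copy_count,
        arm,
    )


def evaluate_precursor_criteria(
    cand: HairpinCandidate, params: DiscoveryParams
) -> tuple[bool, list[str]]:
    """Check every discovery criterion; returns (accepted, violations)."""
    reasons = []
    mlen = cand.mature[1] - cand.mature[0]
    if not (params.mature_len_min <= mlen <= params.mature_len_max):
        reasons.append("mature_length")
    if cand.cut_depth < params.min_cut_depth:
        reasons.append("cut_depth")
    if cand.copy_count > params.max_copies:
        reasons.append("copy_number")
    if cand.fold.delta_g > params.max_free_energy:
        reasons.append("free_energy")
    if cand.metrics.loop_space > params.max_loop_space:
        reasons.append("loop_space")
    if cand.metrics.paired < params.min_duplex_pairs:
        reasons.append("min_pairs")
    if cand.metrics.bulge > params.max_bulge:
        reasons.append("max_bulge")
    if cand.metrics.asymmetry > params.max_asymmetry:
        reasons.append("asymmetry")
    return (not reasons), reasons


@dataclass
class NovelResult:
    """One evaluated candidate locus (accepted or rejected)."""

    candidate: HairpinCandidate
    accepted: bool
    reasons: list[str]
    representative_tag: str
    supporting_tags: list[str] = field(default_factory=list)


def _expressed_loci(tags, hits_by_tag, merge_gap):
    """Chain tag loci into expressed locus groups per (reference, strand)."""
    entries: dict[tuple[str, str], list[tuple[int, int, object]]] = {}
    for tag in tags:
        loci, _trunc = hits_by_tag.get(tag.tag_id, ([], False))
        for h in loci:
            entries.setdefault((h.reference, h.strand), []).append((h.start, h.end, tag))
    groups = []
    for (ref, strand), items in sorted(entries.items()):
        items.sort(key=lambda x: (x[0], x[1]))
        cur: list[tuple[int, int, object]] = []
        cur_end = None
        for start, end, tag in items:
            if cur and start > cur_end + merge_gap:
                groups.append((ref, strand, cur))
                cur = []
                cur_end = None
            cur.append((start, end, tag))
            cur_end = end if cur_end is None else max(cur_end, end)
        if cur:
            groups.append((ref, strand, cur))
    return groups


def discover_novel(
    tags,
    hits_by_tag: dict[str, tuple[list[HitLocus], bool]],
    genome: dict[str, str],
    params: DiscoveryParams | None = None,
) -> list[NovelResult]:
    """Evaluate every expressed locus of miRNA-compatible tags.

    ``tags`` are collapsed tags that survived the annotation cascade
    unassigned; ``hits_by_tag`` maps tag ids to their (0-mismatch)
    genome loci with a truncation flag from the copy-number cap.
    Overlapping tag loci (within ``locus_merge_gap``) form one candidate
    locus whose mature is the highest-count tag; the modal 5' terminus
    read support defines the cut-site depth.
    """
    params = params or DiscoveryParams()
    lo = params.mature_len_min
    hi = params.mature_len_max + params.length_slack
    pool = [t for t in tags if lo <= len(t.sequence) <= hi and hits_by_tag.get(t.tag_id, ([], 0))[0]]
    results = []
    for ref, strand, items in _expressed_loci(pool, hits_by_tag, params.locus_merge_gap):
        group_tags = sorted({id(t): t for _, _, t in items}.values(), key=lambda t: t.tag_id)
        rep = select_mature_representative(group_tags)
        rep_locus = next(
            HitLocus(0, ref, s, e, strand) for s, e, t in items if t.tag_id == rep.tag_id
        )
        # modal 5' terminus, weighted by read counts
        weights: dict[int, int] = {}
        for s, e, t in items:
            fp = s if strand == "+" else e - 1
            weights[fp] = weights.get(fp, 0) + t.total_count
        modal = min(weights, key=lambda p: (-weights[p], p))
        cut_depth = weights[modal]
        loci, truncated = hits_by_tag[rep.tag_id]
        copy_count = (params.max_copies + 1) if truncated else len(loci)
        cand = build_candidate(genome, rep_locus, params, cut_depth, copy_count)
        accepted, reasons = evaluate_precursor_criteria(cand, params)
        results.append(
            NovelResult(cand, accepted, reasons, rep.tag_id, [t.tag_id for t in group_tags])
        )
    results.sort(key=lambda r: (r.candidate.reference, r.candidate.start, r.candidate.strand))
    return results


def novel_tag_ids(results) -> set[str]:
    """Tags supporting any accepted novel precursor."""
    out: set[str] = set()
    for r in results:
        if r.accepted:
            out.update(r.supporting_tags)
    return out
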