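"""Hierarchical annotation of collapsed tags into small-RNA categories.

Every tag receives exactly one category from a fixed-priority cascade:
structural ncRNAs first (rRNA, tRNA, snRNA, snoRNA, matched against the
reference sets at up to two mismatches), then conserved miRNAs (matched
against a miRBase-style mature set), then repeat- and gene-derived
fragments by genomic overlap, then novel miRNAs (from hairpin
discovery), then piRNAs (length band + intergenic origin), and finally
``unannotated``.  The cascade partitions the tag set: category counts
always sum to the number of tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import HitLocus, canonical_dna

CATEGORIES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA_conserved",
    "repeat",
    "exon_sense",
    "exon_antisense",
    "intron_sense",
    "intron_antisense",
    "miRNA_novel",
    "piRNA",
    "unannotated",
)

#: Default cascade order: structural ncRNA before miRNA/piRNA calling.
DEFAULT_PRIORITY = CATEGORIES[:-1]

_NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
_GENOMIC_CLASSES = ("repeat", "exon_sense", "exon_antisense", "intron_sense", "intron_antisense")


@dataclass
class AnnotationRecord:
    tag_id: str
    category: str
    evidence: str = ""
    mismatches: int | None = None


@dataclass
class ConservedMatch:
    """A tag identified as a conserved miRNA variant.

    Requires >= 16 nt overlap with the reference mature, no mismatch in
    the seed (mature positions 2-8), at most two mismatches outside it,
    and a perfect match onto a linked reference precursor.
    """

    tag_id: str
    mature_id: str
    overlap: int
    mismatches: int
    precursor_id: str
    offset_on_precursor: int


SEED_POSITIONS = range(1, 8)  # 0-based indices of mature positions 2-8


def match_conserved_mirna(
    tag,
    mature_refs: dict[str, str],
    precursor_refs: dict[str, str],
    mature_to_precursors: dict[str, list[str]],
    min_overlap: int = 16,
    max_mismatches_outside_seed: int = 2,
) -> ConservedMatch | None:
    """Best conserved-miRNA assignment for one tag, or None.

    The tag is slid along each reference mature at every offset giving
    at least ``min_overlap`` aligned nt; seed mismatches disqualify an
    offset outright.  The best (max overlap, then min mismatches, then
    reference id) qualifying match whose tag also occurs verbatim in a
    linked precursor is returned.
    """
    seq = canonical_dna(tag.sequence)
    best = None
    for mid in sorted(mature_refs):
        for pid in mature_to_precursors.get(mid, ()):
            if pid not in precursor_refs:
                raise ValueError(f"mature reference {mid} linked to unknown precursor {pid}")
        if not mature_to_precursors.get(mid):
            raise ValueError(f"mature reference {mid} has no precursor link")
        ref = canonical_dna(mature_refs[mid])
        for off in range(-(len(seq) - min_overlap), len(ref) - min_overlap + 1):
            lo = max(0, off)
            hi = min(len(ref), off + len(seq))
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            mm = 0
            seed_ok = True
            for rpos in range(lo, hi):
                if ref[rpos] != seq[rpos - off]:
                    if rpos in SEED_POSITIONS:
                        seed_ok = False
                        break
                    mm += 1
            if not seed_ok or mm > max_mismatches_outside_seed:
                continue
            key = (-overlap, mm, mid)
            if best is None or key < best[0]:
                for pid in mature_to_precursors[mid]:
                    pos = canonical_dna(precursor_refs[pid]).find(seq)
                    if pos >= 0:
                        best = (key, ConservedMatch(tag.tag_id, mid, overlap, mm, pid, pos))
                        break
    return None if best is None else best[1]


class ConservedMatcher:
    """Reusable conserved-miRNA matcher over fixed reference sets.

    Since a qualifying tag must occur verbatim in some reference
    precursor, a fast substring screen over the concatenated precursors
    rejects most tags before the sliding mature-overlap search runs.
    """

    def __init__(self, mature_refs, precursor_refs, mature_to_precursors, **kwargs):
        self.mature_refs = {k: canonical_dna(v) for k, v in mature_refs.items()}
        self.precursor_refs = {k: canonical_dna(v) for k, v in precursor_refs.items()}
        self.mature_to_precursors = mature_to_precursors
        self.kwargs = kwargs
        for mid, pids in mature_to_precursors.items():
            if not pids:
                raise ValueError(f"mature reference {mid} has no precursor link")
            for pid in pids:
                if pid not in self.precursor_refs:
                    raise ValueError(f"mature {mid} linked to unknown precursor {pid}")
        self._blob = "#".join(self.precursor_refs.values())

    def match(self, tag) -> ConservedMatch | None:
        if canonical_dna(tag.sequence) not in self._blob:
            return None
        return match_conserved_mirna(
            tag, self.mature_refs, self.precursor_refs, self.mature_to_precursors, **self.kwargs
        )

    def match_all(self, tags) -> dict[str, ConservedMatch]:
        out = {}
        for t in tags:
            m = self.match(t)
            if m is not None:
                out[t.tag_id] = m
        return out


def select_mature_representative(tags):
    """Highest-expressed tag of an isomiR group; ties break to the
    lexicographically smaller sequence."""
    if not tags:
        raise ValueError("empty tag group")
    return min(tags, key=lambda t: (-t.total_count, canonical_dna(t.sequence)))


@dataclass
class PirnaRecord:
    tag_id: str
    length: int
    first_nt: str
    locus: HitLocus


class FeatureIndex:
    """Plain-list overlap lookup over a feature table.

    The table needs columns seqid, ftype, start, end (0-based half-open),
    strand, feature_id; genomes here are small enough that a per-contig
    linear scan is the simplest correct structure.
    """

    def __init__(self, features: pd.DataFrame):
        self._by_ref: dict[str, list[tuple[int, int, str, str, str]]] = {}
        for row in features.itertuples(index=False):
            self._by_ref.setdefault(row.seqid, []).append(
                (int(row.start), int(row.end), row.strand, row.ftype, str(row.feature_id))
            )
        for v in self._by_ref.values():
            v.sort()

    def overlapping(self, hit: HitLocus) -> list[tuple[int, int, str, str, str]]:
        out = []
        for start, end, strand, ftype, fid in self._by_ref.get(hit.reference, ()):
            if start >= hit.end:
                break
            if end > hit.start:
                out.append((start, end, strand, ftype, fid))
        return out


def _as_index(features) -> FeatureIndex:
    return features if isinstance(features, FeatureIndex) else FeatureIndex(features)


def is_intergenic(features, hit: HitLocus, genic_classes=("exon", "intron")) -> bool:
    return not any(f[3] in genic_classes for f in _as_index(features).overlapping(hit))


def call_pirna(
    tag,
    loci: list[HitLocus],
    features,
    length_band: tuple[int, int] = (24, 32),
    require_unannotated: bool = False,
) -> tuple[bool, PirnaRecord | None]:
    """piRNA call: length in band and an intergenic (optionally also
    repeat-free) genomic locus.  The 5' nucleotide is recorded but never
    required -- the uridine bias is a population-level statistic."""
    findex = _as_index(features)
    n = len(tag.sequence)
    if not (length_band[0] <= n <= length_band[1]) or not loci:
        return False, None
    genic = ("exon", "intron", "repeat") if require_unannotated else ("exon", "intron")
    for hit in loci:
        if is_intergenic(findex, hit, genic):
            first = canonical_dna(tag.sequence)[0].replace("T", "U")
            return True, PirnaRecord(tag.tag_id, n, first, hit)
    return False, None


def annotate_cascade(
    tags,
    genome_hits: dict[str, list[HitLocus]],
    features,
    ncrna_hits: dict[str, list[HitLocus]],
    ncrna_classes: dict[str, str],
    conserved: dict[str, ConservedMatch],
    novel_tag_ids: set[str] = frozenset(),
    priority=DEFAULT_PRIORITY,
    pirna_band: tuple[int, int] = (24, 32),
    pirna_require_unannotated: bool = False,
) -> list[AnnotationRecord]:
    """Assign one category per tag; first matching category in
    ``priority`` wins, tags matching nothing are ``unannotated``.

    ``ncrna_classes`` maps ncRNA reference ids to their class;
    ``novel_tag_ids`` are tags supporting accepted novel precursors
    (empty on a first pass before discovery has run).
    """
    findex = _as_index(features)
    records = []
    for tag in tags:
        rec = None
        loci = genome_hits.get(tag.tag_id, [])
        nc = ncrna_hits.get(tag.tag_id, [])
        for cat in priority:
            if cat in _NCRNA_CLASSES:
                match = [h for h in nc if ncrna_classes.get(h.reference) == cat]
                if match:
                    best = match[0]
                    rec = AnnotationRecord(tag.tag_id, cat, best.reference, best.mismatches)
                    break
            elif cat == "miRNA_conserved":
                cm = conserved.get(tag.tag_id)
                if cm is not None:
                    rec = AnnotationRecord(tag.tag_id, cat, cm.mature_id, cm.mismatches)
                    break
            elif cat in _GENOMIC_CLASSES:
                ftype = cat.split("_")[0]
                want_sense = not cat.endswith("antisense")
                done = False
                for hit in loci:
                    for fstart, fend, fstrand, ft, fid in findex.overlapping(hit):
                        if ft != ftype:
                            continue
                        if ftype in ("exon", "intron") and (fstrand == hit.strand) != want_sense:
                            continue
                        rec = AnnotationRecord(tag.tag_id, cat, fid, hit.mismatches)
                        done = True
                        break
                    if done:
                        break
                if done:
                    break
            elif cat == "miRNA_novel":
                if tag.tag_id in novel_tag_ids:
                    rec = AnnotationRecord(tag.tag_id, cat, "novel_precursor")
                    break
            elif cat == "piRNA":
                ok, prec = call_pirna(tag, loci, findex, pirna_band, pirna_require_unannotated)
                if ok:
                    rec = AnnotationRecord(
                        tag.tag_id, "piRNA", f"{prec.locus.reference}:{prec.locus.start}"
                    )
                    break
        if rec is None:
            rec = AnnotationRecord(tag.tag_id, "unannotated")
        records.append(rec)
    return records


def category_counts(records, by_reads: dict[str, int] | None = None) -> pd.Series:
    """Tag (or read, given per-tag totals) counts per category."""
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += by_reads.get(r.tag_id, 1) if by_reads else 1
    return pd.Series(counts)


def pirna_stage_sets(records, tags_by_id) -> tuple[dict[str, set], pd.DataFrame]:
    """Per-stage unique piRNA sequence sets and their pairwise overlaps."""
    stage_sets: dict[str, set] = {}
    for r in records:
        if r.category != "piRNA":
            continue
        tag = tags_by_id[r.tag_id]
        for stage, cnt in tag.counts.items():
            if cnt > 0:
                stage_sets.setdefault(stage, set()).add(tag.sequence)
    stages = sorted(stage_sets)
    rows = []
    for i, a in enumerate(stages):
        for b in stages[i:]:
            rows.append(
                {
                    "stage_a": a,
                    "stage_b": b,
                    "unique_a": len(stage_sets[a]),
                    "unique_b": len(stage_sets[b]),
                    "shared": len(stage_sets[a] & stage_sets[b]),
                }
            )
    return stage_sets, pd.DataFrame(rows)
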