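"""Raw-read cleanup and collapsing into unique tags.

Raw libraries are 50-nt sequencer reads: an 18-30 nt small-RNA insert
followed by the 3' adapter (and filler).  Cleanup removes, in a fixed
order, low-quality reads, 5'-adapter contamination, reads with no
detectable 3' adapter, over-long inserts, poly(A) stretches and inserts
below the minimum length; what survives is the clean-insert set.  Clean
inserts are collapsed into unique tags carrying per-stage read counts,
the unit every downstream statistic is computed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO

#: Discard rules, in the order they are applied and tallied.
DISCARD_RULES = (
    "low_quality",
    "adapter5_contamination",
    "adapter3_missing",
    "insert_too_long",
    "poly_a",
    "insert_too_short",
)


@dataclass
class FilterParams:
    adapter3: str
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_len: int = 18
    max_len: int = 32
    quality_floor: float = 20.0
    min_adapter_overlap: int = 6
    adapter_mismatch: int = 1
    polya_fraction: float = 0.8

    def __post_init__(self):
        if not self.adapter3 or not self.adapter5:
            raise ValueError("adapters must be non-empty")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class FilterResult:
    clean: list[str] = field(default_factory=list)
    #: indices into the raw read list, parallel to ``clean``
    clean_read_indices: list[int] = field(default_factory=list)
    tally: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DISCARD_RULES})

    @property
    def n_clean(self) -> int:
        return len(self.clean)

    @property
    def n_discarded(self) -> int:
        return sum(self.tally.values())


def _find_adapter3(seq: str, adapter: str, min_overlap: int, max_mm: int) -> int:
    """Leftmost start of the (possibly truncated) 3' adapter, or -1.

    The adapter is detected as its longest prefix of at least
    ``min_overlap`` nt occurring in the read with at most ``max_mm``
    mismatches; at the read end shorter-than-full prefixes are allowed.
    """
    alen = len(adapter)
    for start in range(len(seq) - min_overlap + 1):
        span = min(alen, len(seq) - start)
        window = seq[start : start + span]
        mm = sum(1 for a, b in zip(window, adapter) if a != b)
        if mm <= max_mm:
            return start
    return -1


def filter_and_trim(reads, params: FilterParams) -> FilterResult:
    """Apply the cleanup cascade to ``(sequence, quality)`` read pairs.

    ``reads`` is an iterable of ``(seq, phred_scores)``; quality may be
    ``None`` when the source carries no qualities.  Returns clean
    inserts plus the per-rule discard tally (first matching rule wins).
    """
    res = FilterResult()
    a5 = params.adapter5.upper().replace("U", "T")
    a3 = params.adapter3.upper().replace("U", "T")
    for idx, (seq, quals) in enumerate(reads):
        seq = seq.upper().replace("U", "T")
        if quals is not None and len(quals) and (sum(quals) / len(quals)) < params.quality_floor:
            res.tally["low_quality"] += 1
            continue
        # 5' adapter contamination: read begins with a 5'-adapter suffix
        if any(
            seq.startswith(a5[-k:])
            for k in range(params.min_adapter_overlap, len(a5) + 1)
        ):
            res.tally["adapter5_contamination"] += 1
            continue
        cut = _find_adapter3(seq, a3, params.min_adapter_overlap, params.adapter_mismatch)
        if cut < 0:
            res.tally["adapter3_missing"] += 1
            continue
        insert = seq[:cut]
        if len(insert) > params.max_len:
            res.tally["insert_too_long"] += 1
            continue
        if insert and insert.count("A") / len(insert) >= params.polya_fraction:
            res.tally["poly_a"] += 1
            continue
        if len(insert) < params.min_len:
            res.tally["insert_too_short"] += 1
            continue
        res.clean.append(insert)
        res.clean_read_indices.append(idx)
    return res


def read_fastq(path) -> list[tuple[str, list[int]]]:
    """Load a FASTQ file as ``(sequence, phred_scores)`` pairs."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((str(rec.seq), rec.letter_annotations["phred_quality"]))
    return out


@dataclass
class SequenceTag:
    """A unique clean-insert sequence with per-stage read counts."""

    tag_id: str
    sequence: str
    counts: dict[str, int]

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


def collapse(clean_by_stage: dict[str, list[str]]) -> list[SequenceTag]:
    """Collapse clean inserts into unique tags with per-stage counts.

    Tags are ordered by (total count desc, sequence) and assigned stable
    ids ``tag_000001`` ...; for every stage the tag counts sum exactly
    to the number of clean inserts of that stage.
    """
    stages = list(clean_by_stage)
    acc: dict[str, dict[str, int]] = {}
    for stage in stages:
        for seq in clean_by_stage[stage]:
            if seq not in acc:
                acc[seq] = {s: 0 for s in stages}
            acc[seq][stage] += 1
    ordered = sorted(acc.items(), key=lambda kv: (-sum(kv[1].values()), kv[0]))
    return [
        SequenceTag(f"tag_{i + 1:06d}", seq, counts) for i, (seq, counts) in enumerate(ordered)
    ]


def write_tags_fasta(tags, path) -> None:
    """Collapsed tags as FASTA with ``tag_<id>_x<count>`` headers."""
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f">{t.tag_id}_x{t.total_count}\n{t.sequence}\n")


def write_tag_counts(tags, stages, path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tsequence\t" + "\t".join(stages) + "\ttotal\n")
        for t in tags:
            row = "\t".join(str(t.counts.get(s, 0)) for s in stages)
            fh.write(f"{t.tag_id}\t{t.sequence}\t{row}\t{t.total_count}\n")
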