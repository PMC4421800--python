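"""Ungapped mapping of small-RNA tags against small reference sets.

Mapping of clean tags follows two distinct regimes: against the genome
no mismatch is tolerated, against the ncRNA reference databases up to
two mismatches are allowed.  Both are served by one seed-and-verify
mapper: an exact k-mer index over the references, pigeonhole seeding of
the query (a tag with at most ``m`` mismatches must contain one of
``m + 1`` disjoint chunks matching exactly), and full Hamming-distance
verification of every candidate diagonal, on both strands.

All hit loci up to a configurable cap are reported; the cap mirrors the
maximal-copy-number rule of novel-miRNA discovery.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")


def canonical_dna(seq: str) -> str:
    """Uppercase DNA alphabet; U read as T."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class UnmappableTagError(ValueError):
    """Raised for tags with too many ambiguous bases to map."""


@dataclass(frozen=True, order=True)
class HitLocus:
    """One ungapped alignment of a tag: 0-based half-open coordinates."""

    mismatches: int
    reference: str
    start: int
    end: int
    strand: str


class SeedIndex:
    """Exact k-mer index over a set of reference sequences (plus strand).

    ``k`` must not exceed ``floor(L / (m + 1))`` for the shortest query
    length L and largest mismatch budget m the index will serve, or
    pigeonhole seeding loses completeness; the default k = 6 covers
    18-nt tags at budget 2.
    """

    def __init__(self, references: dict[str, str], k: int = 6):
        if not references:
            raise ValueError("empty reference set")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.references = {name: canonical_dna(seq) for name, seq in references.items()}
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.references.items():
            for i in range(len(seq) - k + 1):
                self._kmers.setdefault(seq[i : i + k], []).append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._kmers.get(kmer, [])


def _hamming_within(a: str, b: str, budget: int) -> int:
    d = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            d += 1
            if d > budget:
                return -1
    return d


def map_tag(
    tag: str,
    index: SeedIndex,
    max_mismatches: int = 0,
    max_hits: int | None = None,
) -> tuple[list[HitLocus], bool]:
    """Report all loci of ``tag`` within the mismatch budget.

    Returns ``(hits, truncated)``; hits are sorted by (mismatches,
    reference, start, strand) and truncated to ``max_hits`` with the
    flag set when more loci exist.  ``N`` bases count as mismatches
    everywhere; a tag with more than 2 Ns is rejected.
    """
    tag = canonical_dna(tag)
    if tag.count("N") > 2:
        raise UnmappableTagError(f"tag has {tag.count('N')} N bases")
    k = index.k
    n_chunks = max_mismatches + 1
    if len(tag) < n_chunks * k:
        raise ValueError(
            f"tag length {len(tag)} too short for k={k} at budget {max_mismatches}"
        )
    found: set[tuple[str, int, str]] = set()
    hits: list[HitLocus] = []
    for strand, query in (("+", tag), ("-", revcomp(tag))):
        chunk = len(query) // n_chunks
        for c in range(n_chunks):
            off = c * chunk
            for ref, pos in index.lookup(query[off : off + k]):
                start = pos - off
                refseq = index.references[ref]
                if start < 0 or start + len(query) > len(refseq):
                    continue
                key = (ref, start, strand)
                if key in found:
                    continue
                d = _hamming_within(refseq[start : start + len(query)], query, max_mismatches)
                if d >= 0:
                    found.add(key)
                    hits.append(HitLocus(d, ref, start, start + len(query), strand))
    hits.sort()
    truncated = max_hits is not None and len(hits) > max_hits
    if truncated:
        hits = hits[:max_hits]
    return hits, truncated


def map_tags(
    tags,
    index: SeedIndex,
    max_mismatches: int = 0,
    max_hits: int | None = None,
) -> dict[str, tuple[list[HitLocus], bool]]:
    """Map many tag sequences; unmappable tags get an empty hit list."""
    out = {}
    for t in tags:
        try:
            out[t] = map_tag(t, index, max_mismatches, max_hits)
        except UnmappableTagError:
            out[t] = ([], False)
    return out
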