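"""Seed-match target-site scanning of 3'UTR sequences.

A site is a stretch of the UTR complementary to the miRNA seed.  Site
types follow the canonical hierarchy (miRNA positions counted 1-based
from the 5' end):

* 8mer     -- perfect match to positions 2-8 plus an A opposite position 1,
* 7mer-m8  -- perfect match to positions 2-8,
* 7mer-A1  -- perfect match to positions 2-7 plus the A,
* 6mer     -- perfect match to positions 2-7 only.

Every matching window is reported once with its most stringent type.
Matching is purely seed-based; no context or free-energy scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import canonical_dna, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


@dataclass(frozen=True)
class SeedSite:
    utr_id: str
    start: int  # 0-based half-open on the UTR, minimal site span
    end: int
    site_type: str
    mirna_id: str
    seed_match: str  # UTR sequence of the site


def classify_window(utr: str, pos: int, mirna: str) -> str | None:
    """Site type of the 6mer-core window starting at ``pos`` (the UTR
    position pairing miRNA position 7), or None.  Sequences must be
    canonical DNA."""
    core = revcomp(mirna[1:7])  # complement of seed positions 2-7
    if utr[pos : pos + 6] != core:
        return None
    has_m8 = pos >= 1 and len(mirna) >= 8 and utr[pos - 1] == revcomp(mirna[7])
    has_a1 = utr[pos + 6 : pos + 7] == "A"
    if has_m8 and has_a1:
        return "8mer"
    if has_m8:
        return "7mer-m8"
    if has_a1:
        return "7mer-A1"
    return "6mer"


def scan_seed_sites(utr: str, mirna: str, utr_id: str = "utr", mirna_id: str = "miRNA") -> list[SeedSite]:
    """All seed-match sites of one mature miRNA on one UTR, ordered by
    position, each window reported once with its best type."""
    u = canonical_dna(utr)
    m = canonical_dna(mirna)
    if len(m) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    if len(u) < 7:
        return []
    sites = []
    for pos in range(len(u) - 5):
        t = classify_window(u, pos, m)
        if t is None:
            continue
        start = pos - 1 if t in ("8mer", "7mer-m8") else pos
        end = pos + 7 if t in ("8mer", "7mer-A1") else pos + 6
        sites.append(SeedSite(utr_id, start, end, t, mirna_id, u[start:end]))
    return sites


def site_conservation(
    aligned_utrs: dict[str, str],
    reference: str,
    site: SeedSite,
    clades: dict[str, list[str]] | None = None,
) -> tuple[dict[str, bool], float, dict[str, float]]:
    """Presence of a reference-row seed site across an aligned UTR block.

    The site's ungapped reference coordinates are mapped through the
    alignment; a species retains the site when its row spells the
    identical site sequence (no gaps) over those columns.  Returns
    per-species presence, the overall conserved fraction, and per-clade
    fractions for any supplied clade grouping.
    """
    ref_aln = canonical_dna(aligned_utrs[reference])
    # map ungapped reference positions to alignment columns
    cols = []
    ungapped = 0
    for i, c in enumerate(ref_aln):
        if c != "-":
            if site.start <= ungapped < site.end:
                cols.append(i)
            ungapped += 1
    if len(cols) != site.end - site.start:
        raise ValueError("site overlaps an all-gap region of the reference row")
    target = "".join(ref_aln[i] for i in cols)
    presence = {}
    for sp, row in aligned_utrs.items():
        row = canonical_dna(row)
        word = "".join(row[i] for i in cols)
        presence[sp] = word == target and "-" not in word
    frac = sum(presence.values()) / len(presence)
    clade_frac = {}
    for clade, members in (clades or {}).items():
        got = [presence[m] for m in members if m in presence]
        clade_frac[clade] = sum(got) / len(got) if got else float("nan")
    return presence, frac, clade_frac


def write_sites_bed(sites, path) -> None:
    """Sites as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.utr_id}\t{s.start}\t{s.end}\t{s.mirna_id}|{s.site_type}\n")


def write_sites_tsv(sites, path) -> None:
    """Sites as TSV with 1-based inclusive coordinates (report style)."""
    with open(path, "w") as fh:
        fh.write("utr_id\tstart\tend\tsite_type\tmirna_id\tseed_match\n")
        for s in sites:
            fh.write(f"{s.utr_id}\t{s.start + 1}\t{s.end}\t{s.site_type}\t{s.mirna_id}\t{s.seed_match}\n")
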