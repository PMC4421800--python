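"""Synthetic multi-stage gonad small-RNA dataset with known truth.

The generator builds a toy genome carrying every feature class the
annotation cascade knows about -- conserved and novel miRNA hairpins,
decoy hairpins that each violate exactly one discovery criterion,
intergenic piRNA clusters, structural ncRNAs (rRNA/tRNA/snRNA/snoRNA),
gene models with exons and introns, and repeats -- and then simulates
three raw FASTQ libraries (ovary, ovotestis, testis) from it: miRNA
reads with isomiR jitter, piRNA reads with a controlled 5'-uridine
fraction and a 26-28 nt length peak, decoy fragments, artifact reads
for the cleanup filters, and uniform-random noise.

Every read is recorded in a truth table, so conservation laws,
annotation accuracy, isomiR recovery and arm usage can be checked
exactly.  Planted hairpins are constructed (and re-drawn until) the
discovery module itself accepts them; each decoy is re-drawn until
discovery rejects it for precisely its designated reason.  All
randomness flows through one seeded generator: the same spec and seed
reproduce the dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import HitLocus, SeedIndex, map_tag, revcomp
from .hairpin import DiscoveryParams, build_candidate, evaluate_precursor_criteria
from .preprocess import _find_adapter3

DNA = np.array(list("ACGT"))
STAGES = ("ovary", "ovotestis", "testis")
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

#: designated violations of the default decoy set
DEFAULT_DECOY_REASONS = (
    "mature_length",
    "cut_depth",
    "copy_number",
    "free_energy",
    "loop_space",
    "min_pairs",
    "max_bulge",
    "asymmetry",
    "free_energy",
    "min_pairs",
)

_CLUSTER_NAMES = ("mir-17", "mir-18a", "mir-19a", "mir-19b-1", "mir-20a", "mir-92a-1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class CapacityError(ValueError):
    """Planted features do not fit in the requested genome length."""


@dataclass
class GenomeSpec:
    """Layout of the toy genome.  All counts must be non-negative."""

    genome_length: int = 190_000
    n_novel_hairpins: int = 20
    decoy_reasons: tuple[str, ...] = DEFAULT_DECOY_REASONS
    n_conserved_hairpins: int = 8
    n_pirna_clusters: int = 3
    n_decoy_ncrnas: dict[str, int] = field(
        default_factory=lambda: {"rRNA": 1, "tRNA": 2, "snRNA": 1, "snoRNA": 1}
    )
    n_gene_models: int = 2
    n_repeats: int = 3
    rng_seed: int = 0
    #: minimum gap between any two features (keeps genic/intergenic
    #: labels unambiguous); used between members of the planted
    #: conserved-miRNA cluster
    spacing: int = 200
    #: gap around every other feature, so the planted cluster is the
    #: only group of precursors within cluster-detection range
    isolation: int = 2000
    pirna_cluster_length: int = 2000

    def __post_init__(self):
        counts = [
            self.n_novel_hairpins,
            self.n_conserved_hairpins,
            self.n_pirna_clusters,
            self.n_gene_models,
            self.n_repeats,
            *self.n_decoy_ncrnas.values(),
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all feature counts must be >= 0")


@dataclass
class HairpinTruth:
    feature_id: str
    kind: str  # novel / decoy / conserved
    reason: str | None  # designated violation, decoys only
    reference: str
    start: int  # feature (precursor) genomic interval
    end: int
    mature_arm: str  # 5p or 3p
    arms: dict[str, tuple[int, int]]  # genomic interval per arm
    precursor_seq: str


@dataclass
class ToyGenome:
    spec: GenomeSpec
    sequence: dict[str, str]
    features: pd.DataFrame
    hairpins: dict[str, HairpinTruth]
    mature_refs: dict[str, str]
    precursor_refs: dict[str, str]
    mature_to_precursors: dict[str, list[str]]
    ncrna_refs: dict[str, str]
    ncrna_classes: dict[str, str]

    def arm_sequence(self, fid: str, arm: str) -> str:
        h = self.hairpins[fid]
        s, e = h.arms[arm]
        return self.sequence[h.reference][s:e]


def _rand_seq(rng, n: int, probs=None) -> str:
    return "".join(DNA[rng.choice(4, size=n, p=probs)])


# ---------------------------------------------------------------------------
# hairpin design


def _make_duplex(rng, segments, gc: float = 0.55, au_only: bool = False, n_wobble: int = 2):
    """Build mature and star arm sequences from a duplex layout.

    ``segments`` is a list of ``("p", n)`` paired runs and
    ``("l", a, b)`` loops with ``a`` unpaired nt on the mature arm and
    ``b`` on the star arm.  The star arm is returned 5'->3' as it will
    appear downstream of the loop.  ``n_wobble`` paired columns are
    turned into G:U pairs so the star is not an exact reverse
    complement of the mature.
    """
    cols = []  # (mature base or "", star base or "")
    for seg in segments:
        if seg[0] == "p":
            for _ in range(seg[1]):
                if au_only:
                    m = "AT"[rng.integers(2)]
                else:
                    m = "GC"[rng.integers(2)] if rng.random() < gc else "AT"[rng.integers(2)]
                cols.append([m, _COMP[m]])
        else:
            _, a, b = seg
            for _ in range(a):
                cols.append(["AC"[rng.integers(2)], ""])
            for _ in range(b):
                cols.append(["", "CA"[rng.integers(2)]])
    target = "T" if au_only else "G"
    candidates = [i for i, (m, s) in enumerate(cols) if s and m == target]
    rng.shuffle(candidates)
    for i in candidates[:n_wobble]:
        cols[i][1] = "G" if au_only else "T"  # U:G / G:U wobble
    mature = "".join(m for m, _ in cols if m)
    star = "".join(s for _, s in cols if s)[::-1]
    return mature, star


@dataclass
class _HairpinPlan:
    segments: list
    loop_len: int
    mature_arm: str
    gc: float = 0.55
    au_only: bool = False
    n_wobble: int = 2
    loop_alphabet: str = "AC"
    pad: int = 10

    def draw(self, rng):
        mature, star = _make_duplex(rng, self.segments, self.gc, self.au_only, self.n_wobble)
        if self.au_only:  # keep arms clear of the poly(A) discard rule
            for _ in range(50):
                if max(mature.count("A"), star.count("A")) / len(mature) <= 0.7:
                    break
                mature, star = _make_duplex(rng, self.segments, self.gc, True, self.n_wobble)
        loop = "".join(self.loop_alphabet[rng.integers(2)] for _ in range(self.loop_len))
        pad5 = _rand_seq(rng, self.pad)
        pad3 = _rand_seq(rng, self.pad)
        if self.mature_arm == "5p":
            left, right = mature, star
        else:
            left, right = star, mature
        seq = pad5 + left + loop + right + pad3
        arms = {
            "5p": (self.pad, self.pad + len(left)),
            "3p": (self.pad + len(left) + self.loop_len, len(seq) - self.pad),
        }
        return seq, arms


def _plan_for(kind: str, reason: str | None, rng) -> _HairpinPlan:
    arm = "5p" if rng.random() < 0.5 else "3p"
    if kind in ("novel", "conserved") or reason in ("cut_depth", "copy_number"):
        L = int(rng.integers(21, 24))
        return _HairpinPlan([("p", L)], int(rng.integers(6, 11)), arm)
    if reason == "mature_length":
        return _HairpinPlan([("p", 28)], 8, arm)
    if reason == "free_energy":
        return _HairpinPlan([("p", 18)], 8, arm, au_only=True, n_wobble=2)
    if reason == "loop_space":
        return _HairpinPlan([("p", 22)], 40, arm, gc=0.7)
    if reason == "min_pairs":
        segs = [("p", 5), ("l", 2, 2), ("p", 5), ("l", 3, 3), ("p", 3)]
        return _HairpinPlan(segs, 8, arm, gc=0.95, n_wobble=1)
    if reason == "max_bulge":
        return _HairpinPlan([("p", 8), ("l", 5, 0), ("p", 9)], 8, arm, gc=0.65)
    if reason == "asymmetry":
        segs = [("p", 6), ("l", 4, 0), ("p", 5), ("l", 2, 0), ("p", 5)]
        return _HairpinPlan(segs, 8, arm, gc=0.75)
    raise ValueError(f"unknown decoy reason {reason!r}")


# ---------------------------------------------------------------------------
# genome assembly


def _layout(spec: GenomeSpec, items, rng) -> dict[str, tuple[int, int]]:
    """Assign non-overlapping intervals; ``items`` are (id, length,
    gap-after) with every gap at least ``spacing``."""
    pos = {}
    cursor = spec.spacing
    for fid, length, gap in items:
        cursor += int(rng.integers(0, 80))
        start = cursor
        end = start + length
        if end + spec.spacing > spec.genome_length:
            raise CapacityError(
                f"features exceed genome length {spec.genome_length} at {fid}"
            )
        pos[fid] = (start, end)
        cursor = end + max(gap, spec.spacing)
    return pos


def build_toy_genome(spec: GenomeSpec, params: DiscoveryParams | None = None) -> ToyGenome:
    """Construct the genome, its feature annotation and reference sets.

    Planted novel hairpins are guaranteed (by construction plus
    verification against the discovery module) to satisfy every
    discovery criterion; each decoy violates exactly its designated
    criterion.  piRNA clusters are intergenic and G-poor so they cannot
    form stable stems.
    """
    params = params or DiscoveryParams()
    rng = np.random.default_rng(spec.rng_seed)
    ref = "chr1"

    # ---- plan features and their lengths
    plans: dict[str, _HairpinPlan] = {}
    drawn: dict[str, tuple[str, dict]] = {}
    items: list[tuple[str, int]] = []

    n_cluster = min(spec.n_conserved_hairpins, len(_CLUSTER_NAMES))
    conserved_ids = []
    for i in range(spec.n_conserved_hairpins):
        name = _CLUSTER_NAMES[i] if i < len(_CLUSTER_NAMES) else f"mir-{100 + i}"
        fid = f"conserved_{name}"
        conserved_ids.append(fid)
        plans[fid] = _plan_for("conserved", None, rng)
        drawn[fid] = plans[fid].draw(rng)
        gap = spec.spacing if i + 1 < n_cluster else spec.isolation
        items.append((fid, len(drawn[fid][0]), gap))
    novel_ids = []
    for i in range(spec.n_novel_hairpins):
        fid = f"novel_{i + 1:03d}"
        novel_ids.append(fid)
        plans[fid] = _plan_for("novel", None, rng)
        drawn[fid] = plans[fid].draw(rng)
        items.append((fid, len(drawn[fid][0]), spec.isolation))
    decoy_ids = []
    for i, reason in enumerate(spec.decoy_reasons):
        fid = f"decoy_{i + 1:02d}_{reason}"
        decoy_ids.append(fid)
        plans[fid] = _plan_for("decoy", reason, rng)
        drawn[fid] = plans[fid].draw(rng)
        items.append((fid, len(drawn[fid][0]), spec.isolation))
    copy_decoys = [fid for fid in decoy_ids if fid.endswith("copy_number")]
    n_extra_copies = {fid: params.max_copies for fid in copy_decoys}
    for fid, n in n_extra_copies.items():
        h = drawn[fid]
        s, e = h[1][_mature_arm_of(plans[fid])]
        for c in range(n):
            items.append((f"{fid}_copy{c + 1:02d}", e - s, spec.isolation))
    for i in range(spec.n_pirna_clusters):
        items.append((f"pirna_cluster_{i + 1}", spec.pirna_cluster_length, spec.isolation))
    ncrna_lengths = {"rRNA": 120, "tRNA": 72, "snRNA": 100, "snoRNA": 80}
    ncrna_ids = []
    for cls in sorted(spec.n_decoy_ncrnas):
        for i in range(spec.n_decoy_ncrnas[cls]):
            fid = f"{cls}_{i + 1}"
            ncrna_ids.append(fid)
            items.append((fid, ncrna_lengths[cls], spec.isolation))
    gene_parts = {}
    for i in range(spec.n_gene_models):
        fid = f"gene_{i + 1}"
        gene_parts[fid] = (300, 400, 300)  # exon1, intron, exon2
        items.append((fid, sum(gene_parts[fid]), spec.isolation))
    repeat_ids = [f"repeat_{i + 1}" for i in range(spec.n_repeats)]
    for fid in repeat_ids:
        items.append((fid, 500, spec.isolation))

    pos = _layout(spec, items, rng)

    # ---- background sequence, then patch features in
    genome = list(_rand_seq(rng, spec.genome_length))
    pirna_probs = np.array([0.35, 0.26, 0.04, 0.35])  # A C G T: G-poor, U-rich

    def patch(fid, seq):
        s, e = pos[fid]
        genome[s:e] = list(seq)

    for fid in conserved_ids + novel_ids + decoy_ids:
        patch(fid, drawn[fid][0])
    for fid, n in n_extra_copies.items():
        arm = _mature_arm_of(plans[fid])
        seq, arms = drawn[fid]
        mseq = seq[arms[arm][0] : arms[arm][1]]
        for c in range(n):
            patch(f"{fid}_copy{c + 1:02d}", mseq)
    for i in range(spec.n_pirna_clusters):
        fid = f"pirna_cluster_{i + 1}"
        patch(fid, _rand_seq(rng, spec.pirna_cluster_length, pirna_probs))

    # ---- verify planted/decoy hairpin contracts, re-drawing on failure
    hp_ids = conserved_ids + novel_ids + decoy_ids
    reasons_by_id = dict(zip(decoy_ids, spec.decoy_reasons))
    for round_ in range(40):
        gdict = {ref: "".join(genome)}
        index = SeedIndex(gdict, k=12)  # 0-mismatch regime: one chunk
        failures = []
        for fid in hp_ids:
            ok = _check_hairpin(fid, plans[fid], drawn[fid], pos[fid], gdict, index, params,
                                reasons_by_id.get(fid), n_extra_copies.get(fid, 0))
            if not ok:
                failures.append(fid)
        if not failures:
            break
        for fid in failures:
            drawn[fid] = plans[fid].draw(rng)
            patch(fid, drawn[fid][0])
            if fid in n_extra_copies:
                arm = _mature_arm_of(plans[fid])
                seq, arms = drawn[fid]
                mseq = seq[arms[arm][0] : arms[arm][1]]
                for c in range(n_extra_copies[fid]):
                    patch(f"{fid}_copy{c + 1:02d}", mseq)
    else:
        raise RuntimeError(f"could not satisfy hairpin contracts for {failures}")

    genome_str = "".join(genome)

    # ---- feature table
    rows = []

    def add(fid, ftype, s, e, strand="+", parent=""):
        rows.append(
            {"seqid": ref, "ftype": ftype, "start": s, "end": e, "strand": strand,
             "feature_id": fid, "parent": parent}
        )

    hairpins = {}
    for fid in hp_ids:
        s, e = pos[fid]
        seq, arms = drawn[fid]
        kind = ("conserved" if fid in conserved_ids else
                "novel" if fid in novel_ids else "decoy")
        garms = {a: (s + i0, s + i1) for a, (i0, i1) in arms.items()}
        hairpins[fid] = HairpinTruth(
            fid, kind, reasons_by_id.get(fid), ref, s, e,
            _mature_arm_of(plans[fid]), garms, seq,
        )
        add(fid, "miRNA_hairpin", s, e)
    for fid, n in n_extra_copies.items():
        for c in range(n):
            cid = f"{fid}_copy{c + 1:02d}"
            add(cid, "mature_copy", *pos[cid])
    for i in range(spec.n_pirna_clusters):
        fid = f"pirna_cluster_{i + 1}"
        add(fid, "piRNA_cluster", *pos[fid])
    ncrna_refs, ncrna_classes = {}, {}
    for fid in ncrna_ids:
        cls = fid.rsplit("_", 1)[0]
        s, e = pos[fid]
        add(fid, cls, s, e)
        ncrna_refs[fid] = genome_str[s:e]
        ncrna_classes[fid] = cls
    for gid, (e1, inlen, e2) in gene_parts.items():
        s, e = pos[gid]
        strand = "+" if int(gid.split("_")[1]) % 2 else "-"
        add(gid, "gene", s, e, strand)
        add(f"{gid}_exon1", "exon", s, s + e1, strand, gid)
        add(f"{gid}_intron1", "intron", s + e1, s + e1 + inlen, strand, gid)
        add(f"{gid}_exon2", "exon", s + e1 + inlen, e, strand, gid)
    for fid in repeat_ids:
        add(fid, "repeat", *pos[fid])

    features = pd.DataFrame(rows)

    # ---- miRBase-style reference sets for the conserved hairpins
    mature_refs, precursor_refs, m2p = {}, {}, {}
    for fid in conserved_ids:
        h = hairpins[fid]
        base = fid.replace("conserved_", "")
        pid = f"dre-{base}"
        precursor_refs[pid] = h.precursor_seq
        for arm in ("5p", "3p"):
            s, e = h.arms[arm]
            true_mature = genome_str[s:e]
            mid = f"dre-{base.replace('mir', 'miR')}-{arm}"
            mature_refs[mid] = _mutate_outside_seed(true_mature, rng, n_mismatches=2)
            m2p[mid] = [pid]

    return ToyGenome(
        spec, {ref: genome_str}, features, hairpins,
        mature_refs, precursor_refs, m2p, ncrna_refs, ncrna_classes,
    )


def _mature_arm_of(plan: _HairpinPlan) -> str:
    return plan.mature_arm


def _mutate_outside_seed(seq: str, rng, n_mismatches: int) -> str:
    """Reference mature with mismatches vs the genomic mature, kept
    outside seed positions 2-8 (0-based 1..7)."""
    out = list(seq)
    eligible = [i for i in range(len(seq)) if not (1 <= i <= 7)]
    rng.shuffle(eligible)
    for i in eligible[: int(rng.integers(0, n_mismatches + 1))]:
        out[i] = [b for b in "ACGT" if b != out[i]][rng.integers(3)]
    return "".join(out)


def _check_hairpin(fid, plan, drawnv, interval, gdict, index, params, reason, n_copies):
    """Evaluate a planted feature exactly the way discovery will."""
    seq, arms = drawnv
    s, _e = interval
    arm = plan.mature_arm
    a0, a1 = arms[arm]
    mature = seq[a0:a1]
    ref = next(iter(gdict))
    hits, truncated = map_tag(mature, index, 0, max_hits=params.max_copies)
    copies = (params.max_copies + 1) if truncated else len(hits)
    cut_depth = 2 if reason == "cut_depth" else 10
    locus = HitLocus(0, ref, s + a0, s + a1, "+")
    cand = build_candidate(gdict, locus, params, cut_depth, copies)
    accepted, reasons = evaluate_precursor_criteria(cand, params)
    if reason is None:
        # planted and conserved hairpins must pass everything, with a
        # unique mature locus (plus its own hairpin only)
        return accepted and copies == 1
    if reason == "copy_number":
        return reasons == [reason] and copies == n_copies + 1
    return reasons == [reason]


# ---------------------------------------------------------------------------
# library simulation


@dataclass
class LibraryProfile:
    """Per-stage simulation profile.

    ``abundance`` maps an abundance key to a read count; keys are
    ``<hairpin_id>:<arm>`` for hairpin arms, ``<cluster_id>`` for piRNA
    clusters, ``<ncrna_id>``, ``<gene_id>:<part>:<sense|antisense>``,
    and ``<repeat_id>:<sense|antisense>``.
    """

    stage: str
    abundance: dict[str, int]
    pirna_first_u_prob: float = 0.8
    pirna_len_range: tuple[int, int] = (24, 32)
    pirna_len_probs: tuple[float, ...] = (0.06, 0.10, 0.24, 0.26, 0.18, 0.08, 0.04, 0.025, 0.015)
    off5_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.85, -1: 0.06, 1: 0.06, -2: 0.015, 2: 0.015}
    )
    off3_probs: dict[int, float] = field(
        default_factory=lambda: {0: 0.65, 1: 0.14, -1: 0.14, 2: 0.05, -2: 0.02}
    )
    nta_probs: dict[int, float] = field(default_factory=lambda: {0: 0.90, 1: 0.07, 2: 0.03})
    no_jitter: frozenset = frozenset()
    adapter3: str = DEFAULT_ADAPTER3
    noise_read_fraction: float = 0.02
    ncrna_mismatch_prob: float = 0.3
    low_quality_fraction: float = 0.004
    adapter3_missing_fraction: float = 0.006
    polya_fraction: float = 0.003
    short_insert_fraction: float = 0.003

    def __post_init__(self):
        if not 0.0 <= self.pirna_first_u_prob <= 1.0:
            raise ValueError("pirna_first_u_prob must be in [0, 1]")
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("abundances must be >= 0")


def default_profiles(toy: ToyGenome) -> dict[str, LibraryProfile]:
    """The standard study conditions: three gonad stages with conserved
    miRNAs mostly shared across stages, novel miRNAs mostly
    stage-specific, testis-enriched piRNA output summing to 10,000
    reads at a 0.8 5'-U fraction, and all decoy classes populated."""
    rng = np.random.default_rng(toy.spec.rng_seed + 1)
    ab: dict[str, dict[str, int]] = {s: {} for s in STAGES}
    no_jitter = set()

    conserved = [f for f, h in toy.hairpins.items() if h.kind == "conserved"]
    novel = [f for f, h in toy.hairpins.items() if h.kind == "novel"]
    decoys = [f for f, h in toy.hairpins.items() if h.kind == "decoy"]

    for i, fid in enumerate(conserved):
        guide = toy.hairpins[fid].mature_arm
        star = "3p" if guide == "5p" else "5p"
        both_arms = i < max(0, len(conserved) - 2)
        if i == len(conserved) - 2:
            stages = ("ovary",)
        elif i == len(conserved) - 1:
            stages = ("testis",)
        else:
            stages = STAGES
        for st in stages:
            n = int(rng.integers(120, 360))
            ab[st][f"{fid}:{guide}"] = int(round(n * (0.8 if both_arms else 1.0)))
            if both_arms:
                ab[st][f"{fid}:{star}"] = n - ab[st][f"{fid}:{guide}"]
    for i, fid in enumerate(novel):
        guide = toy.hairpins[fid].mature_arm
        star = "3p" if guide == "5p" else "5p"
        both_arms = i % 4 == 3
        if i < 12:
            stages = (STAGES[i % 3],)
        elif i < 17:
            stages = tuple(sorted({STAGES[i % 3], STAGES[(i + 1) % 3]}, key=STAGES.index))
        else:
            stages = STAGES
        for st in stages:
            n = int(rng.integers(40, 120))
            ab[st][f"{fid}:{guide}"] = int(round(n * (0.75 if both_arms else 1.0)))
            if both_arms:
                ab[st][f"{fid}:{star}"] = n - ab[st][f"{fid}:{guide}"]
    for fid in decoys:
        h = toy.hairpins[fid]
        key = f"{fid}:{h.mature_arm}"
        no_jitter.add(key)
        if h.reason == "cut_depth":
            ab["testis"][key] = 2
        else:
            for st in STAGES:
                ab[st][key] = int(rng.integers(30, 61))

    pirna_totals = {"ovary": 2500, "ovotestis": 3000, "testis": 4500}
    clusters = sorted(
        toy.features[toy.features["ftype"] == "piRNA_cluster"]["feature_id"]
    )
    for st in STAGES:
        w = rng.dirichlet(np.ones(len(clusters)) * 8) if clusters else []
        left = pirna_totals[st]
        for i, fid in enumerate(clusters):
            n = int(round(pirna_totals[st] * w[i])) if i < len(clusters) - 1 else left
            n = min(n, left)
            ab[st][fid] = n
            left -= n

    for fid in sorted(toy.ncrna_refs):
        for st in STAGES:
            ab[st][fid] = int(rng.integers(90, 220))
    genes = sorted(toy.features[toy.features["ftype"] == "gene"]["feature_id"])
    for gid in genes:
        for st in STAGES:
            ab[st][f"{gid}:exon:sense"] = int(rng.integers(40, 80))
            ab[st][f"{gid}:exon:antisense"] = int(rng.integers(15, 35))
            ab[st][f"{gid}:intron:sense"] = int(rng.integers(25, 55))
            ab[st][f"{gid}:intron:antisense"] = int(rng.integers(8, 20))
    repeats = sorted(toy.features[toy.features["ftype"] == "repeat"]["feature_id"])
    for fid in repeats:
        for st in STAGES:
            ab[st][f"{fid}:sense"] = int(rng.integers(40, 110))
            ab[st][f"{fid}:antisense"] = int(rng.integers(20, 60))

    return {
        st: LibraryProfile(stage=st, abundance=ab[st], no_jitter=frozenset(no_jitter))
        for st in STAGES
    }


def _sample_probs(rng, probs: dict):
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    return keys[rng.choice(len(keys), p=p)]


def simulate_libraries(
    toy: ToyGenome, profiles: dict[str, LibraryProfile], seed: int | None = None
) -> tuple[dict[str, list[tuple[str, str]]], pd.DataFrame]:
    """Simulate raw 50-nt reads for every stage plus the truth table.

    Returns ``reads_by_stage`` (lists of ``(sequence, quality)``) and a
    truth DataFrame with one row per read.  Reads are the insert plus
    the 3' adapter, clipped/padded to 50 nt.  Feature read counts equal
    the requested abundances exactly.
    """
    if set(profiles) != set(STAGES):
        raise ValueError(f"profiles must cover stages {STAGES}")
    rng = np.random.default_rng(toy.spec.rng_seed + 2 if seed is None else seed)
    genome = toy.sequence
    ftab = toy.features.set_index("feature_id")
    reads_by_stage: dict[str, list[tuple[str, str]]] = {}
    truth_rows = []

    for stage in STAGES:
        prof = profiles[stage]
        entries = []  # (insert, quality, truth fields)

        def emit(insert, cls, fid, arm="", off5=0, off3=0, nta="", quality=None):
            entries.append((insert, quality, cls, fid, arm, off5, off3, nta))

        for key in sorted(prof.abundance):
            n = prof.abundance[key]
            if n == 0:
                continue
            parts = key.split(":")
            fid = parts[0]
            if fid in toy.hairpins:
                self_arm = parts[1]
                h = toy.hairpins[fid]
                s, e = h.arms[self_arm]
                contig = genome[h.reference]
                for _ in range(n):
                    if key in prof.no_jitter:
                        off5 = off3 = 0
                        nta_len = 0
                    else:
                        while True:  # keep variants inside the clean-read length window
                            off5 = _sample_probs(rng, prof.off5_probs)
                            off3 = _sample_probs(rng, prof.off3_probs)
                            nta_len = _sample_probs(rng, prof.nta_probs)
                            if 18 <= (e + off3) - (s + off5) + nta_len <= 32:
                                break
                    ins = contig[s + off5 : e + off3]
                    nta = ""
                    for k in range(nta_len):
                        nxt = contig[e + off3 + k] if e + off3 + k < len(contig) else "A"
                        nta += "T" if nxt != "T" else "A"
                    emit(ins + nta, "miRNA_" + h.kind, fid, self_arm, off5, off3, nta)
            elif fid.startswith("pirna_cluster"):
                cs, ce = int(ftab.loc[fid, "start"]), int(ftab.loc[fid, "end"])
                contig = genome[ftab.loc[fid, "seqid"]]
                lens = np.arange(prof.pirna_len_range[0], prof.pirna_len_range[1] + 1)
                lp = np.array(prof.pirna_len_probs, dtype=float)
                lp = lp / lp.sum()
                for _ in range(n):
                    ln = int(lens[rng.choice(len(lens), p=lp)])
                    want_u = rng.random() < prof.pirna_first_u_prob
                    for _try in range(200):
                        st0 = int(rng.integers(cs, ce - ln))
                        if (contig[st0] == "T") == want_u:
                            break
                    emit(contig[st0 : st0 + ln], "piRNA", fid)
            elif fid in toy.ncrna_refs:
                seq = toy.ncrna_refs[fid]
                cls = toy.ncrna_classes[fid]
                for _ in range(n):
                    ln = int(rng.integers(18, 29))
                    st0 = int(rng.integers(0, len(seq) - ln + 1))
                    ins = list(seq[st0 : st0 + ln])
                    if rng.random() < prof.ncrna_mismatch_prob:
                        for p in rng.choice(ln, size=int(rng.integers(1, 3)), replace=False):
                            ins[p] = [b for b in "ACGT" if b != ins[p]][rng.integers(3)]
                    emit("".join(ins), cls, fid)
            elif len(parts) == 3:  # gene part reads
                gid, part, orient = parts
                strand = ftab.loc[gid, "strand"]
                sub = toy.features[
                    (toy.features["parent"] == gid) & (toy.features["ftype"] == part)
                ]
                contig = genome[ftab.loc[gid, "seqid"]]
                ivs = [(int(r.start), int(r.end)) for r in sub.itertuples(index=False)]
                for _ in range(n):
                    s0, e0 = ivs[int(rng.integers(len(ivs)))]
                    ln = int(rng.integers(20, 29))
                    st0 = int(rng.integers(s0, e0 - ln))
                    ins = contig[st0 : st0 + ln]
                    read_sense = orient == "sense"
                    if (strand == "-") == read_sense:  # read on the minus strand
                        ins = revcomp(ins)
                    emit(ins, f"{part}_{orient}", gid)
            elif len(parts) == 2 and parts[0].startswith("repeat"):
                rid, orient = parts
                s0, e0 = int(ftab.loc[rid, "start"]), int(ftab.loc[rid, "end"])
                contig = genome[ftab.loc[rid, "seqid"]]
                for _ in range(n):
                    ln = int(rng.integers(20, 29))
                    st0 = int(rng.integers(s0, e0 - ln))
                    ins = contig[st0 : st0 + ln]
                    if orient == "antisense":
                        ins = revcomp(ins)
                    emit(ins, "repeat", rid)
            else:
                raise ValueError(f"abundance requested for unknown feature {key!r}")

        n_feature = len(entries)
        for _ in range(int(prof.noise_read_fraction * n_feature)):
            emit(_rand_seq(rng, int(rng.integers(18, 31))), "noise", "noise")
        for _ in range(int(prof.low_quality_fraction * n_feature)):
            emit(_rand_seq(rng, 22), "artifact_low_quality", "artifact", quality="#" * 50)
        for _ in range(int(prof.adapter3_missing_fraction * n_feature)):
            while True:
                filler = _rand_seq(rng, 50)
                if _find_adapter3(filler, prof.adapter3, 6, 1) < 0:
                    break
            emit(filler, "artifact_no_adapter", "artifact")
        for _ in range(int(prof.polya_fraction * n_feature)):
            emit("A" * 24, "artifact_poly_a", "artifact")
        for _ in range(int(prof.short_insert_fraction * n_feature)):
            emit(_rand_seq(rng, 15), "artifact_short", "artifact")

        order = rng.permutation(len(entries))
        reads = []
        for new_i, old_i in enumerate(order):
            ins, quality, cls, fid, arm, off5, off3, nta = entries[old_i]
            if cls == "artifact_no_adapter":
                raw = ins[:50]
            else:
                raw = (ins + prof.adapter3 + "A" * 50)[:50]
            qual = quality if quality is not None else "I" * 50
            rid = f"{stage}_{new_i + 1:06d}"
            reads.append((raw, qual))
            truth_rows.append(
                {"read_id": rid, "stage": stage, "feature_id": fid, "truth_class": cls,
                 "arm": arm, "off5": off5, "off3": off3, "nta": nta, "insert": ins}
            )
        reads_by_stage[stage] = reads

    return reads_by_stage, pd.DataFrame(truth_rows)


def simulate_homolog_alignment(
    n_species: int = 8, length: int = 72, seed: int = 0, rate: float = 0.08
) -> tuple[dict[str, str], object]:
    """A gap-free precursor-homolog alignment evolved down a random tree.

    A random additive tree is drawn, an ancestral sequence is placed at
    the root, and substitutions accumulate along branches in proportion
    to branch length times ``rate``.  Returns the alignment and the
    generating tree (whose topology NJ should recover for moderate
    rates).
    """
    from .evo import random_additive_tree

    rng = np.random.default_rng(seed)
    tree, _d = random_additive_tree(n_species, rng)
    root_seq = _rand_seq(rng, length)

    aln: dict[str, str] = {}

    def evolve(seq: str, node, blen: float):
        n_sub = rng.poisson(max(blen, 0.0) * rate * len(seq))
        s = list(seq)
        for p in rng.choice(len(s), size=min(n_sub, len(s)), replace=False):
            s[p] = [b for b in "ACGT" if b != s[p]][rng.integers(3)]
        seq = "".join(s)
        if not node.children:
            aln[node.name] = seq
        for child, bl in node.children:
            evolve(seq, child, bl)

    evolve(root_seq, tree, 0.0)
    return aln, tree


def simulate_utrs(
    matures: dict[str, str], n_utrs: int = 6, utr_length: int = 500, seed: int = 0
) -> tuple[dict[str, str], pd.DataFrame]:
    """Toy 3'UTR set with planted seed-match sites of known type.

    For each mature miRNA one site of each canonical type is planted in
    a dedicated UTR (8mer, 7mer-m8, 7mer-A1, 6mer, cycling); remaining
    UTRs stay random.  Returns the UTRs and a truth table of planted
    (utr, mirna, position, type) rows.
    """
    from .align import revcomp as _rc

    rng = np.random.default_rng(seed)
    utrs = {f"utr_{i + 1}": list(_rand_seq(rng, utr_length)) for i in range(n_utrs)}
    names = sorted(utrs)
    types = ("8mer", "7mer-m8", "7mer-A1", "6mer")
    rows = []
    for i, (mid, mat) in enumerate(sorted(matures.items())):
        mat = mat.upper().replace("U", "T")
        utr_id = names[i % len(names)]
        t = types[i % len(types)]
        core = _rc(mat[1:7])
        m8 = _rc(mat[7])
        if t == "8mer":
            site = m8 + core + "A"
        elif t == "7mer-m8":
            site = m8 + core + ("C" if rng.random() < 0.5 else "G")
        elif t == "7mer-A1":
            site = _pick_non(rng, m8) + core + "A"
        else:
            site = _pick_non(rng, m8) + core + _pick_non(rng, "A")
        pos = int(rng.integers(30, utr_length - 40))
        utrs[utr_id][pos : pos + len(site)] = list(site)
        rows.append({"utr_id": utr_id, "mirna_id": mid, "pos": pos, "site_type": t})
    return {k: "".join(v) for k, v in utrs.items()}, pd.DataFrame(rows)


def _pick_non(rng, base: str) -> str:
    return [b for b in "ACGT" if b != base][rng.integers(3)]


def truth_isomir_sets(truth: pd.DataFrame) -> dict[str, dict[str, set]]:
    """Per-parent (``feature:arm``) isomiR variant sets, per stage and
    overall, as generated -- the oracle for isomiR recovery."""
    out: dict[str, dict[str, set]] = {}
    mi = truth[truth["truth_class"].isin(["miRNA_conserved", "miRNA_novel", "miRNA_decoy"])]
    for row in mi.itertuples(index=False):
        parent = f"{row.feature_id}:{row.arm}"
        d = out.setdefault(parent, {"all": set(), **{s: set() for s in STAGES}})
        var = (int(row.off5), int(row.off3), row.nta)
        d["all"].add(var)
        d[row.stage].add(var)
    return out
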