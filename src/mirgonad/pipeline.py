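"""End-to-end orchestration: simulate -> preprocess -> map -> annotate
-> discover -> quantify -> evolve -> scan targets.

One :class:`PipelineConfig` drives every stage; a run writes all
tabular/FASTA/GFF/newick outputs plus a manifest recording parameter
values, per-stage tallies and output checksums.  Re-running the same
config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import evo, io, quant, synthio, targets
from .align import SeedIndex, map_tags
from .hairpin import DiscoveryParams, discover_novel, novel_tag_ids
from .preprocess import FilterParams, collapse, filter_and_trim

__version__ = "0.1.0"

STAGE_PAIRS = (("ovary", "ovotestis"), ("ovotestis", "testis"), ("ovary", "testis"))


@dataclass
class PipelineConfig:
    outdir: str = "mirgonad_run"
    seed: int = 1
    genome: dict = field(default_factory=dict)  # GenomeSpec overrides
    discovery: dict = field(default_factory=dict)  # DiscoveryParams overrides
    filter: dict = field(default_factory=dict)  # FilterParams overrides (adapter3 auto)
    priority: tuple = ann.DEFAULT_PRIORITY
    pirna_band: tuple[int, int] = (24, 32)
    pirna_require_unannotated: bool = False
    specificity_threshold_rpm: float = 1.0
    bootstrap_replicates: int = 200
    cluster_max_gap: int = 1000
    homolog_species: int = 8
    homolog_length: int = 72
    n_utrs: int = 6
    utr_length: int = 500
    write_outputs: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["priority"] = list(self.priority)
        d["pirna_band"] = list(self.pirna_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "priority" in d:
            d["priority"] = tuple(d["priority"])
        if "pirna_band" in d:
            d["pirna_band"] = tuple(d["pirna_band"])
        return cls(**d)


@dataclass
class PipelineResult:
    config: PipelineConfig
    toy: synthio.ToyGenome
    truth: pd.DataFrame
    tags: list
    filter_results: dict
    records: list
    novel_results: list
    counts: pd.DataFrame
    totals: dict[str, int]
    mirna_counts: pd.DataFrame
    manifest: dict


def _named_novel(novel_results):
    """Accepted candidates with stable position-based names."""
    accepted = [r for r in novel_results if r.accepted]
    return [(f"nov-mir-{i + 1}", r) for i, r in enumerate(accepted)]


def conserved_precursor_records(tags_by_id, conserved_matches, precursor_refs):
    """Per-reference-precursor arm annotation from the observed tags:
    each mature's anchor is its highest-count matched tag."""
    groups: dict[tuple[str, str], list] = {}
    for tid, m in conserved_matches.items():
        groups.setdefault((m.precursor_id, m.mature_id), []).append((tags_by_id[tid], m))
    per_prec: dict[str, dict[str, tuple[int, int]]] = {}
    for (pid, _mid), members in sorted(groups.items()):
        rep_tag, rep_m = min(
            members, key=lambda tm: (-tm[0].total_count, tm[0].sequence)
        )
        iv = (rep_m.offset_on_precursor, rep_m.offset_on_precursor + len(rep_tag.sequence))
        arm = "5p" if (iv[0] + iv[1]) / 2 < len(precursor_refs[pid]) / 2 else "3p"
        per_prec.setdefault(pid, {})
        if arm not in per_prec[pid]:
            per_prec[pid][arm] = iv
    return [
        quant.PrecursorRecord(pid, precursor_refs[pid], arms)
        for pid, arms in sorted(per_prec.items())
    ]


def novel_precursor_records(named_novel):
    recs = []
    for name, r in named_novel:
        c = r.candidate
        arms = {c.arm: c.mature}
        if c.star is not None:
            arms["3p" if c.arm == "5p" else "5p"] = c.star
        recs.append(quant.PrecursorRecord(name, c.precursor, arms))
    return recs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.outdir)
    if config.write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": config.to_dict(), "tallies": {}}

    # ---- simulate
    spec = synthio.GenomeSpec(rng_seed=config.seed, **config.genome)
    params = DiscoveryParams(**config.discovery)
    toy = synthio.build_toy_genome(spec, params)
    profiles = synthio.default_profiles(toy)
    reads_by_stage, truth = synthio.simulate_libraries(toy, profiles)
    manifest["tallies"]["reads_in"] = {s: len(r) for s, r in reads_by_stage.items()}

    # ---- preprocess
    fparams = FilterParams(adapter3=synthio.DEFAULT_ADAPTER3, **config.filter)
    clean_by_stage, filter_results = {}, {}
    for stage in synthio.STAGES:
        quals = [
            (seq, [ord(c) - 33 for c in q]) for seq, q in reads_by_stage[stage]
        ]
        res = filter_and_trim(quals, fparams)
        clean_by_stage[stage] = res.clean
        filter_results[stage] = res
    tags = collapse(clean_by_stage)
    tags_by_id = {t.tag_id: t for t in tags}
    totals = {s: len(c) for s, c in clean_by_stage.items()}
    manifest["tallies"]["clean_reads"] = totals
    manifest["tallies"]["discards"] = {s: dict(filter_results[s].tally) for s in synthio.STAGES}
    manifest["tallies"]["unique_tags"] = len(tags)

    # ---- map
    genome_index = SeedIndex(toy.sequence, k=12)  # 0-mismatch regime
    genome_hits_raw = map_tags(
        (t.sequence for t in tags), genome_index, max_mismatches=0, max_hits=params.max_copies
    )
    genome_hits = {t.tag_id: genome_hits_raw[t.sequence][0] for t in tags}
    hits_with_flags = {t.tag_id: genome_hits_raw[t.sequence] for t in tags}
    ncrna_hits = {}
    if toy.ncrna_refs:
        nc_index = SeedIndex(toy.ncrna_refs, k=6)
        nc_raw = map_tags((t.sequence for t in tags), nc_index, max_mismatches=2, max_hits=50)
        ncrna_hits = {t.tag_id: nc_raw[t.sequence][0] for t in tags}

    # ---- annotate (first pass), discover, annotate (final)
    matcher = ann.ConservedMatcher(
        toy.mature_refs, toy.precursor_refs, toy.mature_to_precursors
    )
    conserved_matches = matcher.match_all(tags)
    findex = ann.FeatureIndex(toy.features)
    first_pass = ann.annotate_cascade(
        tags, genome_hits, findex, ncrna_hits, toy.ncrna_classes, conserved_matches,
        priority=config.priority, pirna_band=config.pirna_band,
        pirna_require_unannotated=config.pirna_require_unannotated,
    )
    pending_ids = {r.tag_id for r in first_pass if r.category in ("piRNA", "unannotated")}
    pending = [t for t in tags if t.tag_id in pending_ids]
    novel_results = discover_novel(pending, hits_with_flags, toy.sequence, params)
    named = _named_novel(novel_results)
    records = ann.annotate_cascade(
        tags, genome_hits, findex, ncrna_hits, toy.ncrna_classes, conserved_matches,
        novel_tag_ids=novel_tag_ids(novel_results), priority=config.priority,
        pirna_band=config.pirna_band,
        pirna_require_unannotated=config.pirna_require_unannotated,
    )
    cat_counts = ann.category_counts(records)
    manifest["tallies"]["categories"] = {k: int(v) for k, v in cat_counts.items()}
    manifest["tallies"]["novel_accepted"] = len(named)
    manifest["tallies"]["novel_rejected"] = len(novel_results) - len(named)

    # ---- quantify
    counts = pd.DataFrame(
        {s: [t.counts.get(s, 0) for t in tags] for s in synthio.STAGES},
        index=[t.tag_id for t in tags],
    )
    rpm = quant.rpm_normalize(counts, totals)
    precursors = conserved_precursor_records(
        tags_by_id, conserved_matches, toy.precursor_refs
    ) + novel_precursor_records(named)
    assignments, n_unassigned = quant.assign_tags_to_precursors(tags, precursors)
    mirna_counts = (
        pd.DataFrame(
            [
                {"parent": a.parent, **{s: a.counts.get(s, 0) for s in synthio.STAGES}}
                for a in assignments
            ]
        )
        .groupby("parent")
        .sum()
        .sort_index()
        if assignments
        else pd.DataFrame(columns=list(synthio.STAGES))
    )
    mirna_rpm = quant.rpm_normalize(mirna_counts, totals) if len(mirna_counts) else mirna_counts
    spec_classes = quant.specificity_table(mirna_rpm, config.specificity_threshold_rpm)
    iso_sets, iso_means, _ = quant.isomir_stats(tags, precursors, synthio.STAGES)
    usage = quant.arm_usage(assignments)
    bias = quant.first_nt_bias(tags, synthio.STAGES)
    lengths = quant.length_distribution(tags, synthio.STAGES)
    de_tables = {
        (a, b): quant.diff_expression(mirna_counts, a, b, totals)
        for a, b in STAGE_PAIRS
        if len(mirna_counts)
    }
    manifest["tallies"]["mean_isomirs"] = {k: round(float(v), 3) for k, v in iso_means.items()}

    # ---- piRNA reporting
    stage_sets, overlaps = ann.pirna_stage_sets(records, tags_by_id)
    manifest["tallies"]["pirna_unique"] = {s: len(v) for s, v in sorted(stage_sets.items())}

    # ---- evolution
    loci = []
    genome_seq = next(iter(toy.sequence.values()))
    contig = next(iter(toy.sequence))
    for pid, pseq in sorted(toy.precursor_refs.items()):
        pos = genome_seq.find(pseq)
        if pos >= 0:
            loci.append(evo.MirnaLocus("toy", pid, contig, pos, pos + len(pseq)))
    for name, r in named:
        c = r.candidate
        loci.append(evo.MirnaLocus("toy", name, c.reference, c.start, c.end, c.strand))
    clusters = evo.detect_clusters(loci, config.cluster_max_gap)
    fam_counts = evo.family_copy_counts(loci)
    aln, _tree = synthio.simulate_homolog_alignment(
        config.homolog_species, config.homolog_length, seed=config.seed + 3
    )
    nj = evo.nj_tree(evo.p_distance_matrix(aln))
    support = evo.bootstrap_support(aln, config.bootstrap_replicates, seed=config.seed + 4)
    cons = evo.consensus(list(aln.values()))
    manifest["tallies"]["clusters"] = [
        {"contig": c.contig, "n": len(c.members), "span": c.span} for c in clusters
        if len(c.members) > 1
    ]

    # ---- target scanning
    guide_matures = {}
    for rec in precursors:
        for arm, (a0, a1) in sorted(rec.arms.items()):
            guide_matures[f"{rec.precursor_id}-{arm}"] = rec.sequence[a0:a1]
    utrs, utr_truth = synthio.simulate_utrs(
        guide_matures, config.n_utrs, config.utr_length, seed=config.seed + 5
    )
    all_sites = []
    for uid in sorted(utrs):
        for mid in sorted(guide_matures):
            all_sites.extend(targets.scan_seed_sites(utrs[uid], guide_matures[mid], uid, mid))
    manifest["tallies"]["target_sites"] = len(all_sites)

    result = PipelineResult(
        config, toy, truth, tags, filter_results, records, novel_results,
        counts, totals, mirna_counts, manifest,
    )

    if config.write_outputs:
        _write_outputs(
            out, toy, reads_by_stage, truth, tags, filter_results, records, novel_results,
            named, counts, rpm, mirna_counts, mirna_rpm, spec_classes, iso_sets, iso_means,
            usage, bias, lengths, de_tables, stage_sets, overlaps, loci, clusters,
            fam_counts, aln, nj, support, cons, utrs, utr_truth, all_sites, manifest,
            tags_by_id,
        )
    return result


def _write_outputs(
    out, toy, reads_by_stage, truth, tags, filter_results, records, novel_results, named,
    counts, rpm, mirna_counts, mirna_rpm, spec_classes, iso_sets, iso_means, usage, bias,
    lengths, de_tables, stage_sets, overlaps, loci, clusters, fam_counts, aln, nj, support,
    cons, utrs, utr_truth, all_sites, manifest, tags_by_id,
):
    from .preprocess import DISCARD_RULES, write_tag_counts, write_tags_fasta

    io.write_fasta(toy.sequence, out / "genome.fa")
    io.write_gff3(toy.features, out / "features.gff3")
    io.write_fasta(toy.ncrna_refs, out / "ncrna_refs.fa")
    io.write_fasta(toy.mature_refs, out / "mature_refs.fa")
    io.write_fasta(toy.precursor_refs, out / "precursor_refs.fa")
    for stage, reads in reads_by_stage.items():
        io.write_fastq(reads, out / f"reads_{stage}.fastq", id_prefix=stage)
    io.write_tsv(truth, out / "truth.tsv")
    write_tags_fasta(tags, out / "tags.fa")
    write_tag_counts(tags, list(synthio.STAGES), out / "tag_counts.tsv")
    tally = pd.DataFrame(
        {s: [filter_results[s].tally[r] for r in DISCARD_RULES] for s in synthio.STAGES},
        index=list(DISCARD_RULES),
    )
    io.write_tsv(tally, out / "discard_tally.tsv", index=True, index_label="rule")
    io.write_tsv(
        pd.DataFrame(
            [
                {"tag_id": r.tag_id, "category": r.category, "evidence": r.evidence,
                 "mismatches": "" if r.mismatches is None else r.mismatches}
                for r in records
            ]
        ),
        out / "annotation.tsv",
    )
    io.write_tsv(
        ann.category_counts(records).rename("n_tags").to_frame(),
        out / "category_counts.tsv", index=True, index_label="category",
    )
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "reference": r.candidate.reference,
                    "start": r.candidate.start,
                    "end": r.candidate.end,
                    "strand": r.candidate.strand,
                    "accepted": r.accepted,
                    "reasons": ",".join(r.reasons),
                    "mature": r.candidate.mature_seq,
                    "arm": r.candidate.arm,
                    "delta_g": r.candidate.fold.delta_g,
                    "pairs": r.candidate.metrics.paired,
                    "bulge": r.candidate.metrics.bulge,
                    "asymmetry": r.candidate.metrics.asymmetry,
                    "loop_space": r.candidate.metrics.loop_space,
                    "cut_depth": r.candidate.cut_depth,
                    "copies": r.candidate.copy_count,
                    "representative_tag": r.representative_tag,
                }
                for r in novel_results
            ]
        ),
        out / "novel_candidates.tsv",
    )
    io.write_fasta({n: r.candidate.precursor for n, r in named}, out / "novel_precursors.fa")
    novel_feats = pd.DataFrame(
        [
            {"seqid": r.candidate.reference, "ftype": "miRNA_hairpin",
             "start": r.candidate.start, "end": r.candidate.end,
             "strand": r.candidate.strand, "feature_id": n, "parent": ""}
            for n, r in named
        ],
        columns=list(io.GFF_COLUMNS),
    )
    io.write_gff3(novel_feats, out / "novel.gff3")
    for stage in synthio.STAGES:
        seqs = sorted(stage_sets.get(stage, ()))
        io.write_fasta({f"pirna_{i + 1:06d}": s for i, s in enumerate(seqs)},
                       out / f"pirna_{stage}.fa")
    io.write_tsv(overlaps, out / "pirna_overlap.tsv")
    io.write_tsv(counts, out / "tag_count_matrix.tsv", index=True, index_label="tag_id")
    io.write_tsv(rpm, out / "tag_rpm.tsv", index=True, index_label="tag_id")
    io.write_tsv(mirna_counts, out / "mirna_counts.tsv", index=True, index_label="parent")
    io.write_tsv(mirna_rpm, out / "mirna_rpm.tsv", index=True, index_label="parent")
    io.write_tsv(spec_classes.to_frame(), out / "specificity.tsv", index=True,
                 index_label="parent")
    for (a, b), table in de_tables.items():
        io.write_tsv(table, out / f"de_{a}_vs_{b}.tsv", index=True, index_label="parent")
    iso_rows = []
    for parent in sorted(iso_sets):
        for m in sorted(iso_sets[parent].members, key=lambda m: m.tag_id):
            iso_rows.append(
                {"parent": parent, "tag_id": m.tag_id, "off5": m.off5, "off3": m.off3,
                 "nta": m.nta, **{s: m.counts.get(s, 0) for s in synthio.STAGES}}
            )
    io.write_tsv(pd.DataFrame(iso_rows), out / "isomirs.tsv")
    io.write_tsv(iso_means.to_frame().T, out / "isomir_means.tsv")
    io.write_tsv(usage, out / "arm_usage.tsv")
    for stage, df in bias.items():
        io.write_tsv(df, out / f"first_nt_bias_{stage}.tsv", index=True, index_label="length")
    io.write_tsv(lengths, out / "length_distribution.tsv", index=True, index_label="length")
    io.write_tsv(
        pd.DataFrame(
            [{"species": l.species, "name": l.name, "contig": l.contig, "start": l.start,
              "end": l.end, "strand": l.strand, "family": l.family} for l in loci]
        ),
        out / "mirna_loci.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            [
                {"contig": c.contig, "n_members": len(c.members), "span": c.span,
                 "members": ",".join(m.name for m in c.members)}
                for c in clusters
            ]
        ),
        out / "clusters.tsv",
    )
    io.write_tsv(fam_counts.rename("copies").to_frame(), out / "families.tsv", index=True,
                 index_label="family")
    io.write_fasta(aln, out / "homolog_alignment.fa")
    (out / "nj_tree.nwk").write_text(nj.newick() + "\n")
    io.write_tsv(
        pd.DataFrame(
            [{"bipartition": "|".join(sorted(s)), "support": v}
             for s, v in sorted(support.items(), key=lambda kv: sorted(kv[0]))]
        ),
        out / "bootstrap.tsv",
    )
    (out / "consensus.txt").write_text(cons + "\n")
    io.write_fasta(utrs, out / "utrs.fa")
    io.write_tsv(utr_truth, out / "utr_truth.tsv")
    targets.write_sites_tsv(all_sites, out / "target_sites.tsv")
    targets.write_sites_bed(all_sites, out / "target_sites.bed")

    files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest["outputs"] = {name: io.sha256_file(out / name) for name in files}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
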