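# Methods

This note documents the models, parameter choices and numerical
conventions behind `mirgonad`, and what the synthetic study conditions
do and do not establish about real data.

## Units, coordinates, alphabets

Coordinates are 0-based half-open in memory; GFF3 output is 1-based
inclusive, BED output 0-based half-open, and reported target-site spans
are 1-based inclusive. U and T are interchangeable on input; the
internal canonical alphabet is DNA, and RNA is emitted where the
molecule is RNA (folding, piRNA 5′ base reporting). Energies are
kcal/mol at 37 °C.

## Read cleanup

Raw reads are modelled as a ~18–32 nt insert followed by the 3′ adapter,
clipped to 50 nt. Cleanup applies six rules in a fixed order, tallying
the first that fires: mean Phred < 20 (`low_quality`); read begins with
a ≥ 6 nt suffix of the 5′ adapter (`adapter5_contamination`); no
detectable 3′ adapter (`adapter3_missing`) — detection is the leftmost
occurrence of the longest available adapter prefix (≥ 6 nt near the read
end, the full prefix elsewhere) at ≤ 1 mismatch, which makes accidental
in-insert matches vanishingly rare; insert longer than 32 nt
(`insert_too_long`, our operationalization of "inserted fragments");
≥ 80 % adenine (`poly_a`); and insert < 18 nt (`insert_too_short`). The
quality floor, poly(A) fraction, length bounds and adapter-match
parameters are all configurable, since published pipelines name these
filters without thresholds.

## Mapping

The mapper is exact-seed-and-verify with pigeonhole seeding: a query
with ≤ m mismatches is split into m + 1 chunks, one of which must match
exactly, so looking up the k-prefix of every chunk and verifying each
candidate diagonal by Hamming distance (both strands) is complete
whenever k ≤ ⌊L/(m+1)⌋. The default k = 6 keeps this guarantee for
18-nt tags at the 2-mismatch budget used for ncRNA annotation; k = 12 is
used for the 0-mismatch genome regime, where the whole tag is one chunk.
A k of 12 for the general case would silently lose 2-mismatch hits on
short tags, which is why completeness, not convention, fixed the
default. `N` counts as a mismatch everywhere; tags with > 2 Ns are
unmappable. All hits are reported sorted by (mismatches, reference,
start, strand), truncated at a cap with a flag — the cap is what feeds
the copy-number criterion of discovery.

## Annotation cascade

One category per tag, first match wins, order configurable. The default
order removes structural ncRNA (rRNA, tRNA, snRNA, snoRNA at ≤ 2
mismatches against the reference sets) before miRNA identification,
then conserved miRNA, repeat, exon/intron by genomic overlap and strand,
then novel miRNA, piRNA, unannotated. Conserved assignment requires
≥ 16 nt overlap with a reference mature, zero mismatches at mature
positions 2–8 (the seed), ≤ 2 mismatches elsewhere, and a verbatim
occurrence of the tag in a linked reference precursor; the best match
maximizes overlap, then minimizes mismatches, with a fixed lexicographic
tie-break so shuffling the reference set cannot change assignments.
Among isomiRs of one mature locus the representative is the
highest-count tag, ties broken to the lexicographically smaller
sequence.

piRNA calling is deliberately permissive per read: length within
24–32 nt and an intergenic locus. The 26–28 nt peak and the 5′-uridine
bias are population statistics reported downstream, not per-read
filters — a uridine requirement would bake the expected result into the
data. Whether repeat-derived loci count as piRNA territory is genuinely
ambiguous in practice, so both behaviours exist behind
`require_unannotated` (default: repeats allowed).

## Folding model

Discovery needs a folding engine whose optimum can be verified, so the
package carries a self-contained nearest-neighbour model: a 6 × 6
stacked-pair table over Watson–Crick plus G:U pairs, hairpin-loop
penalties tabulated to size 9 and extended logarithmically,
bulge/internal-loop penalties by size with a capped asymmetry term,
interior loops limited to 30 unpaired nt (the standard MAXLOOP
convention), hairpin loops ≥ 3, and no multiloops — precursor candidates
are single stem-loops, and excluding multiloops keeps exhaustive
enumeration exact. The dynamic program is the classical V/W recursion
restricted to this structure class; a numba-compiled kernel and a pure
Python twin implement the identical recurrence (same float64
arithmetic), and the test suite proves the DP equal to brute-force
enumeration over all structures for 200 random sequences ≤ 18 nt. The
parameter values are internal model constants, not fitted quantities;
an external folding backend can be substituted wherever a `FoldResult`
(sequence, dot-bracket, ΔG) is supplied.

## Novel miRNA discovery

Tag loci on one reference/strand merging within 50 nt form an expressed
locus; its mature is the representative tag, its cut-site depth is the
read support of the modal 5′ terminus (our operational reading of
"depth of the Drosha/Dicer cutting site"), and its copy number is the
representative's genome-wide hit count (hits truncated at the cap count
as cap + 1). The window is the mature locus ± 100 nt; the star arm is
inferred from the pairing partners of the mature with a 2-nt 3′
overhang (standard Dicer geometry) when no star reads exist; the
precursor is the duplex ± 10 nt, refolded. Duplex metrics are defined
operationally: paired = base pairs joining the arms; bulge = longest
unpaired run inside the duplex on either arm; asymmetry = |unpaired on
mature − unpaired on star| inside the duplex; loop space = bases
strictly between the arm intervals. Acceptance requires all eight
checks (mature length 18–26, depth ≥ 3, copies ≤ 20, ΔG ≤ −18, space
≤ 35, pairs ≥ 14, bulge ≤ 4, asymmetry ≤ 5); rejections list every
violated criterion by name. Tags up to 4 nt over the mature ceiling
still enter discovery so that over-long matures are rejected by name
rather than silently skipped. Relaxing any single threshold can only
grow the accepted set (tested property).

## Quantification

RPM = count × 10⁶ / library clean-read total; when the matrix covers all
clean reads each column sums to exactly 10⁶. The two-library
differential test conditions on the summed count: under a common rate,
a ~ Binomial(a + b, N₁/(N₁+N₂)), and the two-sided p-value sums all
outcomes no likelier than the observed one — the exact Poisson
two-sample test appropriate for count libraries without replicates (an
Audic–Claverie-type choice; the statistic is swappable). BH adjustment
runs across rows; up/down calls need |log₂ FC| ≥ 1 and adjusted
p < 0.05, with a 0.01-RPM pseudocount so stage-specific miRNAs give
finite fold changes. Stage-specificity uses a 1-RPM presence threshold.
IsomiRs are grouped per precursor arm within a 5′ offset ≤ 2 nt, 3′
offset ≤ 4 nt and ≤ 2 non-templated 3′ additions (mechanism-motivated
windows; no published thresholds exist), with templated parses
preferred; per-stage means divide distinct variants by parents observed
in that stage. Arm usage labels a precursor 5p/3p/both by which arms
carry reads; the guide is the more abundant arm, exact ties are
co-dominant.

## Evolution analyses

Family parsing strips the species prefix, a trailing numeric copy
suffix, and a trailing paralog letter run, case-insensitively
(mir-92a-1 → miR-92). Copy-number tables count loci per family per
species; a family is "conserved" when present in ≥ 2 species, and the
single/multi fractions are over conserved families. Cluster detection
is single-linkage chaining with a 10-kb default gap (published cluster
spans are sub-kilobase but the chaining window itself is a free choice;
the pipeline's toy-genome run uses 1 kb to match its compact layout).
Consensus takes the per-column modal base, uppercase at ≥ 0.9 modal
frequency, ties broken A < C < G < U. Distances are p-distances with
pairwise gap deletion (a zero-comparable-site pair is an error naming
the pair). Neighbour joining is the canonical agglomeration with the
three-point formula at the final star; on additive matrices it provably
returns the generating topology and branch lengths, which the tests
confirm on 100 random trees of 4–10 taxa and cross-check against an
independent implementation. Bootstrap resamples alignment columns with
replacement (default 1,000 replicates) and scores each original
internal bipartition by the fraction of replicate trees containing it;
fixed seed ⇒ identical supports. Multiple sequence alignment itself is
out of scope: the module consumes aligned FASTA.

## Target scanning

Sites are pure seed matches, typed most-stringent-first: 8mer
(complement of positions 2–8 plus A opposite position 1), 7mer-m8,
7mer-A1, 6mer; each 6mer-core window is reported once. No free-energy or
context scoring — site typing here is deliberately the seed-only
definition. Conservation maps a reference site's columns through an
alignment; a species retains the site only with the identical, gap-free
site string.

## Synthetic study conditions

The generator is the package's statement of the conditions under which
everything is tested, chosen once:

* genome 190 kb, one contig; every feature ≥ 200 nt from its neighbours
  (unambiguous genic/intergenic labels); non-cluster features isolated
  by ~2 kb so the single planted 6-member miRNA cluster is the only
  group within cluster-detection range;
* 20 planted novel hairpins (perfect 21–23-bp stems with two G:U
  wobbles so the star is not an exact reverse complement, 6–10 nt
  loops), verified at generation time to pass all discovery criteria
  through the discovery code itself;
* 10 decoy hairpins, each engineered to violate exactly one criterion
  (28-nt mature; 2-read depth; 21 genomic copies; A/U-only stem above
  −18 kcal/mol; 40-nt loop; 13-pair duplex; 5-nt bulge with asymmetry
  exactly 5; 6-nt asymmetry with bulges ≤ 4), re-drawn until the
  discovery code reports precisely the designated reason;
* 8 conserved hairpins (6 clustered, 2 singletons) with miRBase-style
  reference matures carrying up to 2 mismatches outside the seed and
  exact reference precursors; 6 express both arms at a 80/20
  guide/star split;
* 3 intergenic piRNA clusters, G-poor (4 % G) so random stems cannot
  reach the −18 kcal/mol acceptance bound, emitting 10,000 reads
  (2,500/3,000/4,500 per stage — testis-enriched) with lengths peaked
  at 26–28 nt within 24–32 and a 5′-U fraction of 0.8 enforced by
  sampling start positions whose genomic base matches, so reads still
  map perfectly;
* isomiR jitter (5′ offset 0 ±2 at 85/12/3 %, 3′ offset 0 ±2 at
  65/28/7 %, ≤ 2 non-templated 3′ U additions at 10 %) with
  non-templated bases chosen to differ from the templated genomic base,
  making every variant's classification unambiguous; variants are
  resampled into the 18–32 nt window so no generated miRNA read is lost
  to the length filter;
* structural ncRNA, exon/intron (both strands), repeat and
  uniform-random noise reads, plus small artifact classes (low-quality,
  adapter-less, poly(A), short) exercising each cleanup rule;
* conserved miRNAs mostly expressed in all three stages, novel miRNAs
  mostly stage-specific — the qualitative regime such gonad studies
  report.

All randomness flows through one seeded generator: identical spec and
seed give byte-identical genomes, libraries and downstream outputs.

What passing these conditions does **not** show: robustness to
sequencing error (only optional substitutions on ncRNA decoys are
modelled), to multi-mapping miRNA families sharing near-identical
matures, to ping-pong piRNA biogenesis signatures, to quality-score
structure, or to genome mis-assembly. The planted hairpins are cleaner
than real precursors; recovery rates here certify the machinery, not
expected sensitivity on tissue libraries.

## Problem sizes

Default runs use ~23,000 reads across the three libraries, a 190-kb
genome and ~12,500 unique tags; the full pipeline completes in well
under a minute on one CPU, and the acceptance script's oracle suites
(200 folding enumerations, 24 mapper comparisons on 30-kb references,
500 scanner pairs, 100 exact-test points, 100 NJ matrices) are sized to
keep exhaustive verification exact rather than sampled.

## Known limitations

* The energy model is internally consistent but not fitted to measured
  thermodynamics; absolute ΔG values are comparable only within the
  model (the −18 kcal/mol bound plays its role relative to that model).
* Star-arm inference assumes a single dominant duplex; precursors with
  branched alternative structures may get shifted star coordinates
  (isomiR offsets are therefore reported against annotated arms where
  annotations exist).
* Conserved-miRNA matching requires a verbatim precursor hit, so tags
  with non-templated additions fall out of the conserved category (they
  are still captured as isomiRs against the precursor).
* Family grouping is purely nomenclature-based; it cannot detect
  paralogy miRBase names do not encode.
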