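"""Seed-match target-site scanning and cross-species site conservation.

Plants sites of every canonical type (8mer, 7mer-m8, 7mer-A1, 6mer)
into toy 3'UTRs, scans them back, and checks the conservation of one
site across a small simulated UTR alignment.  Site types follow the
seed hierarchy: positions 2-7 are the core, position 8 and the A
opposite position 1 upgrade the match.
"""

from mirgonad.synthio import simulate_utrs
from mirgonad.targets import SeedSite, scan_seed_sites, site_conservation

matures = {
    "miR-17a-5p": "CAAAGTGCTTACAGTGCAGGTAG",
    "miR-19a-3p": "TGTGCAAATCTATGCAAAACTGA",
    "miR-92a-3p": "TATTGCACTTGTCCCGGCCTGT",
}
utrs, truth = simulate_utrs(matures, n_utrs=3, utr_length=400, seed=6)

print("planted sites:")
print(truth.to_string(index=False))
print("\nrecovered sites:")
for uid in sorted(utrs):
    for mid, mat in sorted(matures.items()):
        for s in scan_seed_sites(utrs[uid], mat, uid, mid):
            print(f"  {s.utr_id}:{s.start + 1}-{s.end}  {s.site_type:8s} {s.mirna_id}  {s.seed_match}")

# conservation of a 7mer site across a toy alignment: one species lost
# the site through a deletion
aln = {
    "zebrafish": "ACGTTTGCACTTTACGTACG",
    "medaka":    "ACGTTTGCACTTTACGAACG",
    "takifugu":  "ACGTTTGCACTTTACGTACG",
    "mouse":     "ACGT--GCACTTTACGTACG",
}
site = SeedSite("zebrafish", 3, 10, "7mer-m8", "miR-92a-3p", "TTTGCAC")
presence, frac, clades = site_conservation(
    aln, "zebrafish", site,
    clades={"teleosts": ["zebrafish", "medaka", "takifugu"], "mammals": ["mouse"]},
)
print("\nsite presence per species:", presence)
print(f"conserved fraction: {frac:.2f}; per clade: { {k: round(v, 2) for k, v in clades.items()} }")
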