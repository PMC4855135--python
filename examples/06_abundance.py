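"""Convert qPCR copy numbers into cell-based community percentages.

Marker-gene (ppk1) copies count clade cells directly (one copy per cell);
16S rRNA gene copies overcount cells because genomes carry 1-15 rrn
operons. The community-average copy number n_bar = 1/sum(f_i/n_i) converts
16S copies into cells before taking the ratio.
"""

from cladeqpcr import CommunityProfile, average_rrn_per_cell, build_profile

profile = CommunityProfile([("taxon-a", 0.5, 1.0), ("taxon-b", 0.5, 4.0)])
n_bar = average_rrn_per_cell(profile)
print(f"community-average rrn copies per cell: {n_bar:.2f}")

result = build_profile(
    "sample-1",
    ppk1_copies_by_clade={"IA": 1.0e5, "IIC": 5.0e4},
    s16_copies=1.6e7,
    profile=profile,
    total_acc_ppk1_copies=2.0e5,
)
for clade, pct in result.clade_pct.items():
    print(f"clade {clade}: {pct:.2f}% of total bacteria")
print(f"whole lineage: {result.total_acc_pct:.2f}%   "
      f"unclassified remainder: {result.unclassified_pct:.2f}%")
print("The unclassified remainder is lineage members amplified by the")
print("lineage-wide assay but by none of the clade-specific primer sets.")
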