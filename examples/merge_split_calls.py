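"""Show why split-call merging matters for carrier detection.

A ~3 Mb deletion split by the caller into two fragments leaves each
fragment below the 60% overlap threshold of the 1.5 Mb target region;
after merging, the reassembled call spans the region completely.
"""

from cnvburden import CnvCall, REGION_1_5MB, merge_calls, overlap_fraction, select_locus_carriers

left = CnvCall("patient1", "22", 18_800_000, 19_349_999, copy_number=1, num_snps=250)
right = CnvCall("patient1", "22", 19_905_001, 21_800_000, copy_number=1, num_snps=260)

for name, frag in (("left fragment ", left), ("right fragment", right)):
    print(f"{name}: {frag.chrom}:{frag.start}-{frag.end} "
          f"covers {overlap_fraction(frag, REGION_1_5MB):.1%} of the target region")

(merged,) = merge_calls([left, right])
gap = right.start - left.end - 1
print(f"\ngap between fragments: {gap:,} bp "
      f"(< 50% of the {merged.length_bp:,} bp merged span, so they merge)")
print(f"merged call: {merged.chrom}:{merged.start}-{merged.end} "
      f"({merged.num_snps} probes) covers "
      f"{overlap_fraction(merged, REGION_1_5MB):.1%} of the target region")

before = select_locus_carriers([left, right], REGION_1_5MB)
after = select_locus_carriers([merged], REGION_1_5MB)
print(f"carrier before merging: {'yes' if 'patient1' in before else 'no'}; "
      f"after merging: {'yes' if 'patient1' in after else 'no'}")
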