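"""Electronically digest a subtelomere reference into a nick map.

Builds a synthetic 15q-like subtelomere, scans it for the Nt.BspQI
recognition motif on both strands, and prints the strand-collapsed site
list plus any inverted nick pairs (INPs) -- close opposite-strand sites
that fragment molecules in real runs.
"""

import subtelomap as st

scenario = st.load_preset("three_haplotypes_15q")
sequence = scenario.reference_sequence

sites = st.in_silico_nick(sequence)
ref = st.build_reference_map("15q", sequence)
inps = st.detect_inp(sites, max_gap=1000)

print(f"reference length: {ref.length:,} bp")
print(f"stranded motif occurrences: {len(sites)}")
print(f"strand-collapsed map sites: {ref.n_sites}")
print(f"mean site spacing: {ref.length / ref.n_sites / 1000:.1f} kb")
print(f"first five sites (bp): {ref.sites[:5]}")
print(f"inverted nick pairs (<=1 kb apart): {len(inps)}")
for locus in inps:
    print(f"  INP at {locus.left_site.position:,}/{locus.right_site.position:,} "
          f"(gap {locus.gap} bp) -- molecules tend to break here")
# The site list is what a labeled molecule's fluorescent pattern is
# compared against; the spacing (~8-9 kb) sets how informative each
# matched interval is.
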