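"""Enumerate the editing variants and protein isoforms of the 5-HT2CR
editing region.

Five A-to-I sites (A, B, E, C, D) within a 15-nt window give 2^5 = 32 mRNA
variants; because A/B and E/C share codons, translation collapses them
onto 24 protein isoforms.
"""

from editnet import default_region, enumerate_isoforms, enumerate_variants

region = default_region()
variants = enumerate_variants(region)
isoforms = enumerate_isoforms(region)

print(f"editing sites: {', '.join(region.sites)} (transcript order)")
print(f"mRNA variants: {len(variants)}")
print(f"protein isoforms: {len(set(isoforms.values()))}")
print(f"unedited variant NONE encodes {isoforms['NONE']} (fully active receptor)")
print(f"AB encodes {isoforms['AB']}; ACD and ABCD both encode "
      f"{isoforms['ACD']} (low-activity receptor)")

# fibers of the variant -> isoform map: which isoforms have 2 encodings
fibers: dict[str, list[str]] = {}
for var, iso in isoforms.items():
    fibers.setdefault(iso, []).append(var)
shared = {iso: vs for iso, vs in fibers.items() if len(vs) > 1}
print(f"{len(shared)} isoforms are encoded by more than one variant, e.g. "
      f"VSV <- {', '.join(sorted(shared[isoforms['ACD']]))}")
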