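"""Kv1.1 (Kcna1) editing estimated from an MfeI restriction digest.

Editing destroys one of the two MfeI sites in the 390-bp amplicon:
unedited templates cut into 220+51+119 bp, edited ones into 220+170 bp.
The molar ratio of the ~170 bp to ~119 bp diagnostic fragments recovers
the edited fraction exactly in the noise-free case.
"""

from editnet import build_kcna1_amplicon, digest, estimate_editing, gen_digest_mixture

for edited in (False, True):
    prof = digest(build_kcna1_amplicon(edited))
    state = "edited" if edited else "unedited"
    print(f"{state:9s} amplicon -> fragments {sorted(prof.lengths)} "
          f"(sum {sum(prof.lengths)} bp)")

print("\nmixture recovery (truth -> estimate):")
for f in (0.0, 0.25, 0.5, 0.8, 1.0):
    est = estimate_editing(gen_digest_mixture(f))
    print(f"  {f:.2f} -> {est:.2f}")

noisy = estimate_editing(gen_digest_mixture(0.4, seed=1, molarity_cv=0.05))
print(f"with 5% molarity noise, truth 0.40 -> estimate {noisy:.3f}")
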