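# editnet

From amplicon reads to causal gene classification for A-to-I RNA editing
studies.

Serotonin 2C receptor (5-HT2CR) transcripts are edited by ADAR enzymes at
five closely spaced adenosines (sites A, B, E, C, D within a 15-nt
window). Because inosine is read as guanosine, the 2⁵ = 32 combinations
of edited sites define 32 mRNA variants that translate into 24 receptor
isoforms with very different signaling activity (unedited INI is highly
active; heavily edited VSV is not). `editnet` implements the
computational chain a spinal-cord injury (SCI) editing study needs:

1. **Variant quantification** — call each amplicon read's edited-site
   subset, tabulate the 32-variant frequency spectrum, derive per-site
   editing efficiencies, run PCA across samples and exact Mann–Whitney
   group tests with Benjamini–Hochberg control.
2. **Restriction assay** — simulate the MfeI digest of the 390-bp Kv1.1
   (*Kcna1*) amplicon (unedited → 220+51+119 bp, edited → 220+170 bp) and
   estimate the edited fraction from the diagnostic fragment molar ratio
   M₁₇₀/(M₁₇₀+M₁₁₉).
3. **Expression analysis** — gene filtering, median-of-ratios size
   factors, a log2 variance-stabilizing transform, per-gene Welch tests
   with the double DE threshold (fold change >1.2 or <0.8 **and** BH
   adjusted p < 0.05), and qPCR normalization to the geometric mean of
   endogenous controls.
4. **Trait signatures** — gene-wise Spearman correlation of expression
   with a per-sample trait (the ABCD variant frequency, or *Adarb1* qPCR),
   signed significant sets at FDR ≤ 0.1, and Fisher exact overlap tests
   (conditional-MLE odds ratio, exact 95% CI) between signatures on a
   shared gene universe.
5. **Co-expression modules** — WGCNA-style unsigned network
   (a_ij = |cor_ij|^β with β chosen for approximate scale-freeness),
   topological overlap matrix
   TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), average-linkage
   clustering with a deterministic static cut, grey for unassigned genes,
   and hypergeometric module enrichment.
6. **Per-gene Bayesian networks** — for every gene, the 12 admissible
   DAGs over {treatment T, gene G, hub A (*Adarb1* qPCR)} are scored with
   a conditional-Gaussian marginal likelihood (score-equivalent, so edge
   direction is inferred only through treatment-induced v-structures) and
   the gene is classified **upstream** (top DAG has G→A), **downstream**
   (A→G), **independent**, or **ambiguous** (runner-up relative score
   exp(Δ log score) > 0.9).

A synthetic-data module generates every input with planted ground truth
(multinomial variant mixtures with sequencing error, negative-binomial
counts with treatment effects, co-expression blocks, and a causal hub),
so every stage is testable end to end without external data.

## Worked example

Closed-loop variant quantification (`examples/02_amplicon_quantification.py`)
draws 100,000 reads from the spinal-cord mixture (ABD 36%, ABCD 18%,
AB 14%, unedited 3%, remainder uniform) with a 0.1% per-base error rate,
calls every read, and recovers the mixture:

```
100000 reads simulated, 1982 rejected
variant  truth    estimate
ABD       36.0%    35.99%
ABCD      18.0%    17.86%
AB        14.0%    13.99%
NONE       3.0%     3.06%

per-site editing efficiency (fraction of transcripts edited there):
  A=0.81  B=0.81  E=0.17  C=0.33  D=0.68
```

Each estimate sits within binomial sampling error of the truth; a site's
efficiency is the summed frequency of the 16 variants edited there.

Causal classification (`examples/07_network_classification.py`) on a
study with 20 planted hub-upstream genes, 20 hub-downstream genes and 40
independent genes (100 samples per group):

```
candidate networks per gene: 12
category tallies: {'upstream': 24, 'downstream': 29, 'independent': 245, 'ambiguous': 3}

recall per planted category (chance = 0.25):
  upstream     1.00  (n=20)
  downstream   0.85  (n=20)
  independent  0.93  (n=40)
```

The remaining scripts in `examples/` cover the combinatorics, the digest
assay, differential expression, trait signatures, module detection and
the one-call pipeline (`editnet run --out DIR --seed N` from the shell).

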