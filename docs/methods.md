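# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Editing region and variant calling

The coordinate system is an `EditingRegion`: a sense-strand reference
amplicon, 0-based offsets of the five editing sites (A, B, E, C, D in
transcript order, all within 15 nt), and the codon layout of residues
156/158/160. The packaged region uses a synthetic flanking sequence —
only the site/codon geometry carries scientific content. The codon
fixture (residue 156 = ATA with A and B at codon positions 1 and 3;
residue 158 = AAT with E at 1 and C at 2; residue 160 = ATT with D at 1)
is the unique layout consistent with the receptor's editing genetics:
unedited INI, VNI from the AB variant, VSV from both ACD and ABCD, and
32 variants collapsing onto exactly 24 isoforms when inosine is read as
guanosine.

Variant calling anchors a read by exact match of the two 8-nt flanks
immediately outside the editing window, on either strand. At each site,
A means unedited and G edited; any other base rejects the read, as do
more than 2 mismatches outside site positions (both choices are this
package's; amplicon protocols differ and the calling rule is
deliberately conservative and deterministic). Variant names concatenate
edited-site letters in A,B,C,D,E display order; the empty set is NONE.
Frequencies are per-sample counts over total assigned reads; a site's
efficiency is the summed frequency of variants containing it. PCA is the
SVD of the centered samples × 32 frequency matrix with the sign of each
component fixed by its largest-magnitude loading. Group comparison is
the exact two-sided Mann–Whitney U (exact when the pooled values are
untied, which small amplicon studies usually are), BH-adjusted across
the 32 variants or 5 sites. No named test accompanies the original
group comparisons; the exact rank test is this package's choice because
n = 8 per group makes full enumeration feasible.

## Restriction assay

The Kv1.1 amplicon is a constructed 390-nt sequence carrying two CAATTG
sites positioned so MfeI digestion (cut one base into the site) yields
220+51+119 for the unedited form and 220+170 for the edited form, in
which the editing-site adenosine is replaced by G and the second site
destroyed. The conventional diagnostic sizes (171/120) differ from the
constructed ones (170/119) by 1 nt; diagnostic matching therefore uses a
±2 nt tolerance, honoring both statements. The estimator works on molar
abundances — Bioanalyzer mass signal is converted by dividing by length,
exposed as an explicit flag (`DigestProfile.from_csv(mass_units=True)`)
because which currency the original assay used is not stated. The
estimator composed with the mixture generator is the identity on [0,1]
in the noise-free case and unbiased under multiplicative molarity noise.

## Expression analysis

Filtering keeps genes with at least one read in at least one sample;
when several transcript rows share a symbol, the row with the highest
standard deviation of normalized signal is kept. Size factors are
median-of-ratios to the gene-wise geometric mean, normalized to
geometric mean 1; the variance-stabilizing transform is the monotone
surrogate log2(count/size_factor + 1) (pseudocount 1). On NB
simulations the transform flattens the SD-vs-mean trend across genes by
more than an order of magnitude (a property test asserts a near-zero
slope). Differential expression is a per-gene Welch t-test on the
transformed values — an open substitution for the DESeq NB test, whose
internals are out of scope here; the reproducible contract is the
threshold rule: fold change (ratio of group means of size-factor-scaled
counts, control in the denominator) > 1.2 or < 0.8 AND BH-adjusted
p < 0.05. qPCR targets are normalized to the geometric mean of three
endogenous controls.

## Trait signatures and overlaps

Signatures are gene-wise Spearman correlations against a per-sample
trait. For n ≤ 9 untied samples the p-value is exact (the full n!
permutation null, cached per n); with ties or larger n the asymptotic t
approximation on average ranks is used. Signed significant sets are cut
at FDR ≤ 0.1, and lowering the cut can only shrink them (asserted as a
property). Overlap between two gene sets restricted to a shared,
case-normalized symbol universe is tested with the two-sided Fisher
exact test (summing all tables with probability ≤ observed). The
reported odds ratio is the conditional MLE of Fisher's noncentral
hypergeometric model, with an exact 95% CI by tail inversion
(`scipy.stats.nchypergeom_fisher`); degenerate tables report 0 or
infinity at the appropriate bound. The implementation is checked against
brute-force hypergeometric tail summation on random tables with
N ≤ 200.

## Co-expression modules

The network is unsigned: a_ij = |cor_ij|^β on Pearson correlations. β is
the smallest candidate whose connectivity distribution fits a power law
with R² ≥ 0.8 (log10 p(k) vs log10 k over 10 connectivity bins). When no
candidate reaches the threshold the fixed unsigned-network default β = 6
is used rather than the maximum-R² candidate: for non-scale-free inputs
the raw R² keeps rising toward extreme powers simply because the network
empties, which would annihilate the very structure the modules are built
from. The topological overlap matrix is the standard unsigned form
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij) with unit
diagonal; it is verified against a triple-loop oracle.

Module detection is average-linkage clustering on 1−TOM with a
deterministic static cut at the midpoint of the largest gap in the
sorted merge-height sequence. A fixed fraction of the maximum merge
height was tried first and discarded: with several planted modules the
between-module merges spread over 0.90–0.97 of the maximum, so any fixed
fraction either merges modules or splinters them, whereas the widest gap
reliably separates within-module from between-module merges and leaves
unstructured data (near-uniform merge heights) almost entirely grey.
Branches smaller than `min_module_size` (default 20) are grey; surviving
modules take WGCNA color names (turquoise, blue, brown, …) in decreasing
size order. Enrichment against user-supplied gene sets is the one-sided
hypergeometric upper tail, Bonferroni-corrected over all
(module, set) pairs.

## Per-gene Bayesian networks

For each gene, the 12 admissible DAGs over {T, G, A} — T parentless,
optional T→G and T→A, and none/G→A/A→G between gene and hub — are scored
and ranked. The score is a conditional-Gaussian marginal likelihood
built from normal–inverse-Wishart subset marginals: each continuous
family contributes log p(D_{node ∪ parents}) − log p(D_{parents}),
stratified over the discrete treatment parent when T is in the family;
T itself gets a Beta(1,1)–Bernoulli marginal. The prior is empirical
(mean and diagonal variance of the full data), with strength one
pseudo-observation and the degree-of-freedom adjustment that makes the
score structure-equivalent: Markov-equivalent DAGs tie exactly (asserted
to 1e-8), so edge direction can only ever be resolved through
treatment-induced v-structure asymmetry — exactly the semantics the
four-way classification assumes. This is a transparent stand-in for the
`deal` package's master-prior score, whose exact form the original
procedure does not pin down; recovery on planted data, not numerical
parity with `deal`, is the contract. The "relative score" of the
runner-up is exp(logscore₂ − logscore₁), on the likelihood scale (a 0.9
threshold on raw log scores would be scale-dependent). Classification:
ambiguous if that ratio exceeds 0.9; else upstream/downstream by the top
DAG's gene–hub edge; else independent. Constant regressors are dropped
with a warning; ranking ties break on the canonical DAG order (a tie at
the top is ambiguous anyway). The hub variable is the per-sample qPCR
value, log2-transformed by default since relative qPCR quantities are
ratio-scaled and the node model is Gaussian.

## Synthetic data: what it emulates, and the identifiability regime

Amplicon reads are single-end copies of the full region with G at the
drawn variant's sites and uniform substitution errors (no indels, no
quality model, no PCR duplicates — none of which the calling rule is
sensitive to). Counts are gamma-Poisson (NB) with a single dispersion
around 2^latent, scaled to a per-sample library size; per-gene latent
log2 expression is baseline + treatment effect + block factor +
(downstream genes) hub coupling + idiosyncratic noise. Random streams
are spawned per operation from the spec seed, so outputs are
reproducible byte-for-byte and generators do not perturb each other.

The hub ("Adarb1") is exported twice — as a count row through a log
link, and as positive per-sample qPCR metadata — mirroring a dual
RNA-seq/qPCR measurement of the same latent variable.

Direction recovery puts real constraints on the generating regime, and
the defaults encode them deliberately. For an upstream gene to be
recognized as upstream, conditioning on that single gene must screen the
treatment signal out of the hub; this fails when the hub aggregates many
independent inputs (each gene's edge becomes undetectable) and inverts
when the hub is a low-noise aggregate (the hub then screens every input
gene, which flips upstream calls to downstream — a genuine pathology of
measurement-noise asymmetry, not an implementation artifact). The
recovery conditions (`bna_recovery_spec`) therefore plant a tight
upstream module (within-module correlation 0.9) responding coherently to
treatment (log2FC −1), a hub integrating it with coefficient 0.1 plus
substantial intrinsic noise (sd 1.5 — the hub is more than its measured
inputs), downstream coupling ±0.7, low count dispersion (0.02), and 100
samples per group. Under these conditions per-category recall is far
above the 25% four-way chance level (the acceptance suite asserts > 0.5
per category; observed recall is typically 0.85–1.0). Passing these
tests shows the procedure recovers direction where direction is
identifiable; it does not show that real tissue data — with unmodeled
confounding, batch structure, and measurement noise on every node —
supports the same inference strength.

The default pipeline conditions (`default_expression_spec`: 2,000 genes
+ hub, 8 samples per group, dispersion 0.05, latent sd 0.5, ~10% of
genes with |log2FC| = 1.5, four treatment-responsive 50-gene blocks at
within-block correlation 0.7) are scaled-down study conditions chosen so
each stage has realistic signal at desk scale; the full run
(`editnet run`) completes in well under a minute on one CPU.

## Known limitations

- The calling rule requires exact flank matches; heavily degraded reads
  are rejected rather than rescued (counted, not silently dropped).
- The Welch-on-VST test is not DESeq and will not numerically reproduce
  DESeq output on real data; only the threshold contract is shared.
- The static largest-gap cut is a deterministic stand-in for dynamic
  tree cut; deeply nested module hierarchies will be cut at their
  widest level only.
- The three-node procedure inherits all caveats of observational causal
  scoring: hidden confounders between gene and hub are unmodeled, and
  the ambiguous category absorbs exactly the Markov-equivalent cases the
  data cannot resolve.
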