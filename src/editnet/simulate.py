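"""Synthetic-data generators with planted ground truth.

Every input the analysis consumes can be generated here: amplicon reads
drawn from a 32-variant multinomial mixture with uniform substitution
errors, negative-binomial RNA-seq counts with planted treatment effects,
co-expression blocks and a causal hub gene ("Adarb1"), and edited/unedited
restriction-digest mixtures.  Each generator records its planted truth in
a sidecar so recovery by the downstream stages is testable.

Random streams are per-operation: every generator derives its own
``numpy.random.Generator`` from its spec seed, so adding one generator
never perturbs another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CONTROL, TREATED, ExpressionStudy
from .region import EditingRegion, enumerate_variants
from .restriction import DigestProfile
from .restriction import gen_digest_mixture as _digest_mixture

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------


@dataclass
class AmpliconSimSpec:
    """Mixture of editing variants to draw reads from.

    ``variant_probabilities`` maps canonical variant labels to mixture
    weights (must sum to 1 within 1e-9; omitted variants get probability
    0).  Reads are single-end and span the full editing region.
    """

    variant_probabilities: dict[str, float]
    n_reads: int = 10_000
    per_base_error_rate: float = 0.0
    read_length: int | None = None
    seed: int = 0

    def __post_init__(self):
        total = sum(self.variant_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant probabilities sum to {total!r}, not 1")
        if any(p < 0 for p in self.variant_probabilities.values()):
            raise ValueError("variant probabilities must be non-negative")
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not 0.0 <= self.per_base_error_rate < 0.5:
            raise ValueError("per-base error rate must be in [0, 0.5)")


@dataclass
class AmpliconReads:
    """Simulated reads plus their truth sidecar."""

    sequences: list[str]
    truth_labels: list[str]
    region: EditingRegion

    @property
    def truth_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for lab in self.truth_labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts

    def to_fastq(self, path) -> None:
        """Sanger FASTQ (Phred+33, constant quality 'I' = Q40)."""
        with open(path, "w") as fh:
            for i, seq in enumerate(self.sequences):
                fh.write(f"@read_{i:07d}\n{seq}\n+\n{'I' * len(seq)}\n")

    def truth_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_reads": len(self.sequences), "counts": self.truth_counts}, fh)


def gen_amplicon_reads(spec: AmpliconSimSpec, region: EditingRegion) -> AmpliconReads:
    """Draw reads from the variant mixture and apply substitution errors.

    Each read is the region reference with G substituted at its variant's
    sites; sequencing errors are uniform substitutions over the three
    alternative bases at rate ``per_base_error_rate`` (no indels).
    """
    labels = enumerate_variants(region)
    unknown = set(spec.variant_probabilities) - set(labels)
    if unknown:
        raise ValueError(f"probabilities given for unknown variants: {sorted(unknown)}")
    read_len = spec.read_length or len(region.reference_sequence)
    if read_len < len(region.reference_sequence):
        raise ValueError("read_length shorter than the editing region")
    read_len = len(region.reference_sequence)  # single-end, full region

    probs = np.array([spec.variant_probabilities.get(l, 0.0) for l in labels])
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])

    templates = np.vstack(
        [
            np.frombuffer(region.sequence_for_variant(l).encode(), dtype=np.uint8)
            for l in labels
        ]
    )
    draws = rng.choice(len(labels), size=spec.n_reads, p=probs)
    reads = templates[draws].copy()

    if spec.per_base_error_rate > 0 and spec.n_reads > 0:
        err = rng.random(reads.shape) < spec.per_base_error_rate
        # uniform over the 3 non-original bases
        shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
        idx = np.searchsorted(_BASES, reads)  # A,C,G,T -> 0..3
        reads = np.where(err, _BASES[(idx + shift) % 4], reads)

    sequences = [r.tobytes().decode() for r in reads]
    truth = [labels[i] for i in draws]
    return AmpliconReads(sequences, truth, region)


def results_mixture(region: EditingRegion | None = None) -> dict[str, float]:
    """The observed spinal-cord variant mixture: the four named variants at
    their reported frequencies (ABD 36%, ABCD 18%, AB 14%, unedited 3%),
    remaining mass uniform over the other 28 variants."""
    from .region import default_region

    region = region or default_region()
    named = {"ABD": 0.36, "ABCD": 0.18, "AB": 0.14, "NONE": 0.03}
    labels = enumerate_variants(region)
    rest = [l for l in labels if l not in named]
    rest_p = (1.0 - sum(named.values())) / len(rest)
    return {l: named.get(l, rest_p) for l in labels}


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimSpec:
    """Negative-binomial count study with a planted causal hub.

    The hub ("Adarb1") is a linear combination of its upstream genes'
    latent (log-scale) deviations plus Gaussian noise; each downstream
    gene's latent mean is a linear function of the hub value.  The hub is
    exported both as a count row (log-link) and as the per-sample
    ``adarb1_qpcr`` metadata, mirroring a dual RNA-seq/qPCR measurement.

    Gene ids are integers ``1..n_genes``; the three causal sets must be
    disjoint.  ``treatment_effect_map`` gives per-gene log2 fold changes
    (treated vs control); ``module_blocks`` is a list of
    ``(gene id list, within-block correlation)`` pairs.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 8
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    dispersion: float = 0.1
    treatment_effect_map: dict[int, float] = field(default_factory=dict)
    upstream_gene_ids: list[int] = field(default_factory=list)
    downstream_gene_ids: list[int] = field(default_factory=list)
    independent_gene_ids: list[int] = field(default_factory=list)
    upstream_coefficients: dict[int, float] = field(default_factory=dict)
    downstream_coefficients: dict[int, float] = field(default_factory=dict)
    hub_noise_sd: float = 0.3
    module_blocks: list[tuple[list[int], float]] = field(default_factory=list)
    latent_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        sets = [
            set(self.upstream_gene_ids),
            set(self.downstream_gene_ids),
            set(self.independent_gene_ids),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("upstream/downstream/independent sets must be disjoint")
        all_ids = set().union(*sets, self.treatment_effect_map)
        for genes, _rho in self.module_blocks:
            all_ids |= set(genes)
        bad = [g for g in all_ids if not 1 <= g <= self.n_genes]
        if bad:
            raise ValueError(f"gene ids outside 1..n_genes: {sorted(bad)[:5]}")
        for _genes, rho in self.module_blocks:
            if not 0.0 <= rho < 1.0:
                raise ValueError("block correlation must be in [0, 1)")


def gene_name(i: int) -> str:
    return f"g{i:05d}"


HUB_GENE = "Adarb1"


def gen_expression_study(spec: ExpressionSimSpec) -> ExpressionStudy:
    """Generate counts, metadata and the truth sidecar.

    Per-gene latent log2 expression: baseline + treatment effect +
    block factor + (downstream genes) hub coupling + idiosyncratic noise;
    counts are gamma-Poisson (NB) around 2**latent scaled to the sample's
    library size.
    """
    n, m = spec.n_genes, 2 * spec.n_samples_per_group
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng_base = np.random.default_rng(ss[0])
    rng_latent = np.random.default_rng(ss[1])
    rng_counts = np.random.default_rng(ss[2])
    rng_hub = np.random.default_rng(ss[3])

    samples = [f"s{j + 1:03d}" for j in range(m)]
    treatment = np.array([1] * spec.n_samples_per_group + [0] * spec.n_samples_per_group)

    mu = rng_base.uniform(3.0, 9.0, size=n)  # baseline log2 mean
    beta = np.zeros(n)
    for g, lfc in spec.treatment_effect_map.items():
        beta[g - 1] = lfc

    # latent deviations: block factor + idiosyncratic, unit variance, scaled
    z = rng_latent.standard_normal((n, m))
    for genes, rho in spec.module_blocks:
        f = rng_latent.standard_normal(m)
        idx = np.array(genes) - 1
        z[idx] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * z[idx]
    latent = mu[:, None] + beta[:, None] * treatment[None, :] + spec.latent_sd * z

    # hub = linear combination of upstream latent deviations + noise
    hub = rng_hub.normal(0.0, spec.hub_noise_sd, size=m)
    for g in spec.upstream_gene_ids:
        c = spec.upstream_coefficients.get(g, 1.0)
        hub += c * (latent[g - 1] - mu[g - 1])
    for g in spec.downstream_gene_ids:
        c = spec.downstream_coefficients.get(g, 1.0)
        latent[g - 1] = latent[g - 1] + c * hub

    # hub exported as a gene row (log-link) and as qPCR metadata
    hub_mu = 7.0
    hub_latent = hub_mu + hub + 0.1 * rng_hub.standard_normal(m)
    latent_all = np.vstack([latent, hub_latent])
    genes = [gene_name(i + 1) for i in range(n)] + [HUB_GENE]

    base_mean = 2.0 ** latent_all
    lib = rng_counts.uniform(*spec.library_size_range, size=m)
    scale = lib / base_mean.sum(axis=0)
    mean = base_mean * scale[None, :]
    if spec.dispersion > 0:
        shape = 1.0 / spec.dispersion
        lam = rng_counts.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng_counts.poisson(lam)

    qpcr = 2.0 ** (hub + 0.05 * rng_hub.standard_normal(m))
    metadata = pd.DataFrame(
        {
            "group": np.where(treatment == 1, TREATED, CONTROL),
            "adarb1_qpcr": qpcr,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth = {
        "treatment_effects": {gene_name(g): lfc for g, lfc in spec.treatment_effect_map.items()},
        "upstream": [gene_name(g) for g in spec.upstream_gene_ids],
        "downstream": [gene_name(g) for g in spec.downstream_gene_ids],
        "independent": [gene_name(g) for g in spec.independent_gene_ids],
        "module_blocks": [
            {"genes": [gene_name(g) for g in genes_], "rho": rho}
            for genes_, rho in spec.module_blocks
        ],
        "hub_values": dict(zip(samples, hub.tolist())),
    }
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionStudy(counts=counts_df, metadata=metadata, truth=truth)


def default_expression_spec(seed: int = 0) -> ExpressionSimSpec:
    """Default study conditions: 2,000 genes, 8 samples per group.

    Planted structure scaled from the real study's proportions: ~10% of
    genes carry treatment effects (|log2FC| = 1), a tight 40-gene
    hub-upstream module (the "inflammatory" block that represses the
    editing enzyme), 80 hub-downstream genes, and four co-expression
    blocks of 50 genes at within-block correlation 0.7.  The hub's
    treatment shift is about -1 log2 unit, comparable to the ~2-fold
    enzyme downregulation the analysis is designed to detect.
    """
    n_genes = 2000
    de_genes = {g: (1.5 if g % 2 else -1.5) for g in range(1, 201)}
    upstream = list(range(301, 341))
    downstream = list(range(401, 481))
    independent = list(range(501, 701))
    for g in upstream:
        de_genes[g] = -1.0  # coherent module response drives the hub down
    blocks = [(list(range(1000 + 50 * b, 1050 + 50 * b)), 0.7) for b in range(4)]
    for b, (genes, _rho) in enumerate(blocks):
        for g in genes:  # blocks are treatment-responsive, like the real modules
            de_genes[g] = 1.5 if b % 2 else -1.5
    blocks.append((upstream, 0.9))
    return ExpressionSimSpec(
        n_genes=n_genes,
        n_samples_per_group=8,
        treatment_effect_map=de_genes,
        upstream_gene_ids=upstream,
        downstream_gene_ids=downstream,
        independent_gene_ids=independent,
        upstream_coefficients={g: 0.025 for g in upstream},
        downstream_coefficients={g: (0.7 if g % 2 else -0.7) for g in downstream},
        hub_noise_sd=0.75,
        module_blocks=blocks,
        latent_sd=0.5,
        dispersion=0.05,
        seed=seed,
    )


def bna_recovery_spec(
    seed: int = 0,
    n_samples_per_group: int = 100,
    n_upstream: int = 20,
    n_downstream: int = 20,
    n_independent: int = 40,
    n_genes: int = 300,
) -> ExpressionSimSpec:
    """Study conditions for causal-direction recovery experiments.

    Direction is identifiable only through the treatment node, so the
    regime matters: the upstream genes form a tight co-regulated module
    (within-module correlation 0.9) with a coherent treatment response
    (log2FC -1), the hub integrates them with substantial intrinsic noise
    (sd 1.5 -- the hub is more than its upstream inputs), and downstream
    genes follow the hub with coefficient +/-0.7.  Counts are
    low-dispersion (0.02) so measurement noise does not mask the latent
    conditional independencies.
    """
    up = list(range(1, n_upstream + 1))
    down = list(range(101, 101 + n_downstream))
    indep = list(range(201, 201 + n_independent))
    return ExpressionSimSpec(
        n_genes=n_genes,
        n_samples_per_group=n_samples_per_group,
        treatment_effect_map={g: -1.0 for g in up},
        upstream_gene_ids=up,
        downstream_gene_ids=down,
        independent_gene_ids=indep,
        upstream_coefficients={g: 0.1 for g in up},
        downstream_coefficients={g: (0.7 if g % 2 else -0.7) for g in down},
        hub_noise_sd=1.5,
        module_blocks=[(up, 0.9)],
        latent_sd=1.0,
        dispersion=0.02,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# digest mixtures
# ---------------------------------------------------------------------------


@dataclass
class DigestSimSpec:
    """Edited/unedited template mixture for the restriction assay."""

    fraction_edited: float = 0.5
    n_molecules: int = 1000
    molarity_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_edited <= 1.0:
            raise ValueError("fraction_edited must be within [0, 1]")


def gen_digest_profile(spec: DigestSimSpec) -> DigestProfile:
    return _digest_mixture(
        spec.fraction_edited,
        n_molecules=spec.n_molecules,
        seed=spec.seed,
        molarity_cv=spec.molarity_cv,
    )


def write_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))
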