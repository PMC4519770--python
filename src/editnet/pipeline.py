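"""End-to-end orchestration: simulate -> editing -> DE -> signatures ->
modules -> network classification, with a manifest for provenance.

All randomness flows from one root seed; per-stage seeds are spawned from
it so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .amplicon import compare_groups, pca_variants, site_efficiencies, tabulate_variants, VariantTable
from .bayesnet import classify_all, category_tallies, intersect_with_signature
from .coexpression import wgcna
from .expression import CONTROL, TREATED, differential_expression
from .region import default_region
from .simulate import (
    AmpliconSimSpec,
    default_expression_spec,
    gen_amplicon_reads,
    gen_expression_study,
    results_mixture,
)
from .trait import correlate_trait

log = logging.getLogger("editnet")


@dataclass
class RunConfig:
    """Parameters of a full synthetic run.

    Thresholds default to the analysis contract: DE fold change >1.2 or
    <0.8 at FDR 0.05, signature FDR 0.1, network ambiguity 0.9.
    """

    outdir: str = "editnet_run"
    seed: int = 0
    n_reads_per_sample: int = 20_000
    amplicon_error_rate: float = 0.001
    abcd_group_shift: float = 0.04  # ABCD decrease / AB increase in treated
    fc_high: float = 1.2
    fc_low: float = 0.8
    de_fdr: float = 0.05
    signature_fdr: float = 0.1
    ambiguity: float = 0.9
    min_module_size: int = 20
    candidate_betas: tuple = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)

    def __post_init__(self):
        if not (1.0 < self.fc_high and 0.0 < self.fc_low < 1.0):
            raise ValueError("fold-change thresholds must bracket 1")
        for name in ("de_fdr", "signature_fdr", "ambiguity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0.0 <= self.amplicon_error_rate < 0.5:
            raise ValueError("amplicon_error_rate must be in [0, 0.5)")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "candidate_betas" in data:
            data["candidate_betas"] = tuple(data["candidate_betas"])
        return cls(**data)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    tallies: dict = field(default_factory=dict)


def _sample_mixtures(config: RunConfig, groups: pd.Series, rng: np.random.Generator) -> dict[str, dict[str, float]]:
    """Per-sample variant mixtures: treated samples shift ABCD down and AB
    up by ``abcd_group_shift`` (plus small per-sample jitter)."""
    base = results_mixture()
    out = {}
    for sample, group in groups.items():
        shift = (config.abcd_group_shift if group == TREATED else 0.0) + 0.01 * rng.standard_normal()
        probs = dict(base)
        shift = float(np.clip(shift, -probs["AB"] + 1e-3, probs["ABCD"] - 1e-3))
        probs["ABCD"] -= shift
        probs["AB"] += shift
        out[sample] = probs
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in dependency order and write stage outputs.

    Outputs under ``config.outdir``: variant frequencies, site
    efficiencies, PCA scores, group comparisons, DE table, ABCD and hub
    signatures, module assignment, per-gene network classification and
    category tallies, plus ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = root.spawn(3)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "stages": {},
        "checksums": {},
    }

    def _stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = "ok"

    try:
        _stage("synthetic_data")
        expr_spec = default_expression_spec(seed=int(seeds[0].generate_state(1)[0] % 2**31))
        study = gen_expression_study(expr_spec).normalize()
        study.to_dir(outdir)
        (outdir / "truth.json").write_text(json.dumps(study.truth, indent=1))

        _stage("editing_amplicon")
        region = default_region()
        region.to_json(outdir / "region.json")
        rng = np.random.default_rng(seeds[1])
        mixtures = _sample_mixtures(config, study.groups, rng)
        tables = []
        for i, (sample, probs) in enumerate(mixtures.items()):
            spec = AmpliconSimSpec(
                probs,
                n_reads=config.n_reads_per_sample,
                per_base_error_rate=config.amplicon_error_rate,
                seed=int(seeds[2].generate_state(1)[0] % 2**31) + i,
            )
            reads = gen_amplicon_reads(spec, region)
            tables.append(tabulate_variants(reads.sequences, region, sample=sample))
        table = VariantTable.concat(tables)
        table.to_tsv(outdir / "variant_frequencies.tsv")
        eff = site_efficiencies(table, region)
        eff.to_csv(outdir / "site_efficiencies.tsv", sep="\t")
        scores, var_frac, _ = pca_variants(table)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.Series(
            var_frac, index=scores.columns[: len(var_frac)], name="variance_fraction"
        ).to_csv(outdir / "pca_variance.tsv", sep="\t")
        compare_groups(table.frequencies, study.groups).to_csv(outdir / "variant_group_test.tsv", sep="\t")
        compare_groups(eff, study.groups).to_csv(outdir / "site_group_test.tsv", sep="\t")

        _stage("expression_de")
        de = differential_expression(study, config.fc_high, config.fc_low, config.de_fdr)
        de.rename_axis("gene").to_csv(outdir / "de_table.tsv", sep="\t")

        _stage("trait_association")
        abcd = table.frequencies["ABCD"].reindex(study.normalized.columns)
        sig_abcd = correlate_trait(study.normalized, abcd, "ABCD", config.signature_fdr)
        sig_abcd.to_tsv(outdir / "signature_abcd.tsv")
        sig_hub = correlate_trait(
            study.normalized, study.adarb1_qpcr, "Adarb1", config.signature_fdr
        )
        sig_hub.to_tsv(outdir / "signature_adarb1.tsv")

        _stage("coexpression")
        de_genes = de.index[de["de"]]
        if len(de_genes) >= 30:
            modules, beta_choice, _ = wgcna(
                study.normalized.loc[de_genes],
                config.candidate_betas,
                config.min_module_size,
            )
            modules.rename_axis("gene").to_csv(outdir / "modules.tsv", sep="\t")
            beta_choice.fit_table.to_csv(outdir / "scale_free_fit.tsv", sep="\t", index=False)
        else:
            log.warning("coexpression skipped: only %d DE genes", len(de_genes))

        _stage("bayesnet")
        classification = classify_all(study, ambiguity=config.ambiguity)
        classification.to_csv(outdir / "gene_classification.tsv", sep="\t")
        tallies = category_tallies(classification)
        (outdir / "category_tallies.json").write_text(json.dumps(tallies, indent=1))
        sets = intersect_with_signature(classification, sig_hub)
        (outdir / "classified_signature_sets.json").write_text(
            json.dumps({k: sorted(v) for k, v in sets.items()}, indent=1)
        )
    except Exception as exc:
        stage_name = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline aborted in stage {stage_name!r}: {exc}") from exc

    for f in sorted(outdir.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["checksums"][f.name] = _checksum(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(outdir, manifest, tallies)
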