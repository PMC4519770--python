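"""Count normalization, differential expression, qPCR normalization.

Counts are filtered (all-zero rows dropped; one transcript per gene symbol
kept by highest signal SD), scaled by median-of-ratios size factors, and
variance-stabilized with a log2 transform.  Differential expression uses a
per-gene Welch t-test on the stabilized values with Benjamini-Hochberg
control, and the DE set is gated by both the fold change (>1.2 or <0.8,
treated vs control) and the adjusted p (<0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FC_HIGH = 1.2
FC_LOW = 0.8
DE_FDR = 0.05
VST_PSEUDOCOUNT = 1.0

TREATED = "treated"
CONTROL = "control"


@dataclass
class ExpressionStudy:
    """A gene x sample count matrix with its sample metadata.

    ``metadata`` is indexed by sample id with columns ``group``
    (``treated``/``control``) and ``adarb1_qpcr`` (positive real; the hub
    enzyme's qPCR quantification).  ``normalized`` is filled by
    :meth:`normalize`.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    normalized: pd.DataFrame | None = None
    size_factors_: pd.Series | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        counts = self.counts
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not counts.index.is_unique:
            raise ValueError("gene identifiers must be unique")
        missing = set(counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)}")
        self.metadata = self.metadata.loc[list(counts.columns)]

    @property
    def groups(self) -> pd.Series:
        return self.metadata["group"]

    @property
    def adarb1_qpcr(self) -> pd.Series:
        return self.metadata["adarb1_qpcr"].astype(float)

    def normalize(self) -> "ExpressionStudy":
        """Filter genes, compute size factors and the VST matrix in place."""
        self.counts = filter_genes(self.counts)
        self.size_factors_ = size_factors(self.counts)
        self.normalized = vst(self.counts, self.size_factors_)
        return self

    def scaled_counts(self) -> pd.DataFrame:
        """Counts divided by their per-sample size factors."""
        sf = self.size_factors_ if self.size_factors_ is not None else size_factors(self.counts)
        return self.counts.div(sf, axis=1)

    # -- I/O -----------------------------------------------------------

    def to_dir(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t")
        self.metadata.rename_axis("sample_id").to_csv(outdir / "metadata.tsv", sep="\t")
        if self.normalized is not None:
            self.normalized.to_csv(outdir / "normalized.tsv", sep="\t")

    @classmethod
    def from_files(cls, counts_path, metadata_path) -> "ExpressionStudy":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        return cls(counts=counts, metadata=meta)


def filter_genes(counts: pd.DataFrame, symbol_of: dict[str, str] | None = None) -> pd.DataFrame:
    """Drop all-zero rows; keep one transcript per gene symbol.

    When several rows map to the same symbol (``symbol_of`` row-id ->
    symbol; identity if omitted), the row whose normalized signal has the
    highest standard deviation is retained, and the surviving row is
    re-indexed by the symbol.
    """
    kept = counts.loc[counts.sum(axis=1) > 0]
    if kept.empty:
        raise ValueError("no genes left after removing all-zero rows")
    if symbol_of is None:
        return kept.copy()
    symbols = pd.Series({rid: symbol_of.get(rid, rid) for rid in kept.index})
    sf = size_factors(kept)
    signal_sd = vst(kept, sf).std(axis=1, ddof=1)
    order = signal_sd.sort_values(ascending=False).index
    seen: set[str] = set()
    keep_rows = []
    for rid in order:
        sym = symbols[rid]
        if sym not in seen:
            seen.add(sym)
            keep_rows.append(rid)
    out = kept.loc[[r for r in kept.index if r in set(keep_rows)]].copy()
    out.index = [symbols[r] for r in out.index]
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Each sample's factor is the median, over genes expressed in every
    sample, of its counts divided by the gene-wise geometric mean.
    """
    x = counts.values.astype(float)
    expressed = (x > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in all samples; size factors undefined")
    logx = np.log(x[expressed])
    log_ref = logx.mean(axis=1, keepdims=True)
    log_sf = np.median(logx - log_ref, axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def vst(counts: pd.DataFrame, sf: pd.Series, pseudocount: float = VST_PSEUDOCOUNT) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(count / size_factor + pseudocount)."""
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts.div(sf, axis=1) + pseudocount)


def differential_expression(
    study: ExpressionStudy,
    fc_high: float = FC_HIGH,
    fc_low: float = FC_LOW,
    fdr: float = DE_FDR,
) -> pd.DataFrame:
    """Per-gene Welch t-test (treated vs control) with the double threshold.

    Fold change is the ratio of group means of size-factor-scaled counts
    (control in the denominator); p-values are BH-adjusted genome-wide and
    a gene is DE iff (FC > ``fc_high`` or FC < ``fc_low``) and adjusted
    p < ``fdr``.  Returns a gene-indexed table (fc, p, padj, direction, de).
    """
    if study.normalized is None:
        study.normalize()
    groups = study.groups
    t_idx = (groups == TREATED).values
    c_idx = (groups == CONTROL).values
    if t_idx.sum() < 2 or c_idx.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    norm = study.normalized.values
    t_vals, c_vals = norm[:, t_idx], norm[:, c_idx]
    tstat, p = stats.ttest_ind(t_vals, c_vals, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)

    scaled = study.scaled_counts().values
    mean_t = scaled[:, t_idx].mean(axis=1)
    mean_c = scaled[:, c_idx].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_c > 0, mean_t / mean_c, np.inf)

    padj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "fc": fc,
            "t": tstat,
            "p": p,
            "padj": padj,
            "direction": np.where(fc >= 1.0, "up", "down"),
        },
        index=study.normalized.index,
    )
    out["de"] = ((out["fc"] > fc_high) | (out["fc"] < fc_low)) & (out["padj"] < fdr)
    return out


def qpcr_normalize(target_values: pd.Series, control_values: pd.DataFrame) -> pd.Series:
    """Normalize a qPCR target to the geometric mean of endogenous controls.

    ``control_values`` is samples x controls (typically 3 endogenous control
    genes); returns target / geomean(controls) per sample.  All inputs must
    be positive.
    """
    target = pd.Series(target_values, dtype=float)
    controls = pd.DataFrame(control_values).astype(float).loc[target.index]
    if (target <= 0).any() or (controls.values <= 0).any():
        raise ValueError("qPCR values must be positive")
    geomean = np.exp(np.log(controls).mean(axis=1))
    return target / geomean
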