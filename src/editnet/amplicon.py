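"""Quantification of combinatorial editing variants from amplicon reads.

Reads covering the five-site editing region are anchored to the reference
by exact 8-nt flank matches (forward or reverse complement), the base at
each site is read out (A = unedited, G = edited, anything else rejects the
read), and reads are tabulated into the 32-variant frequency spectrum.
Downstream summaries: per-site editing efficiencies, PCA across samples
and exact rank tests between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .region import (
    EditingRegion,
    SITE_TRANSCRIPT_ORDER,
    enumerate_variants,
    variant_label,
)

FLANK_LENGTH = 8
DEFAULT_MAX_MISMATCHES = 2

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantCall:
    """Outcome of calling a single read."""

    label: str | None
    reason: str | None = None  # set when the read is rejected

    @property
    def assigned(self) -> bool:
        return self.label is not None


def _anchor(read: str, region: EditingRegion) -> int | None:
    """Offset of the reference start within ``read``, or None.

    Anchoring requires exact matches of the two 8-nt flanks immediately
    outside the editing window (before the first site, after the last).
    """
    first = min(region.site_offsets.values())
    last = max(region.site_offsets.values())
    left = region.reference_sequence[first - FLANK_LENGTH : first]
    right = region.reference_sequence[last + 1 : last + 1 + FLANK_LENGTH]
    if len(left) < FLANK_LENGTH or len(right) < FLANK_LENGTH:
        raise ValueError("reference too short for 8-nt anchor flanks")
    pos = read.find(left)
    while pos != -1:
        start = pos - (first - FLANK_LENGTH)
        if start >= 0 and read[start + last + 1 : start + last + 1 + FLANK_LENGTH] == right:
            return start
        pos = read.find(left, pos + 1)
    return None


def call_variant(
    read: str,
    region: EditingRegion,
    max_mismatches_outside_sites: int = DEFAULT_MAX_MISMATCHES,
) -> VariantCall:
    """Assign a read to one of the ``2**k`` editing variants.

    The read is anchored on either strand; at each site offset A means
    unedited and G edited.  Rejection reasons: ``unanchorable`` (flanks not
    found), ``non_ag_at_site`` (C/T/N at a site), ``too_many_mismatches``
    (more than ``max_mismatches_outside_sites`` non-site mismatches within
    the aligned overlap).
    """
    read = read.upper()
    start = _anchor(read, region)
    if start is None:
        rc = reverse_complement(read)
        start = _anchor(rc, region)
        if start is None:
            return VariantCall(None, "unanchorable")
        read = rc

    ref = region.reference_sequence
    site_positions = set(region.site_offsets.values())
    edited: set[str] = set()
    for label, off in region.site_offsets.items():
        pos = start + off
        if pos >= len(read):
            return VariantCall(None, "unanchorable")
        base = read[pos]
        if base == "G":
            edited.add(label)
        elif base != "A":
            return VariantCall(None, "non_ag_at_site")

    mismatches = 0
    span = min(len(ref), len(read) - start)
    for i in range(span):
        if i in site_positions:
            continue
        if read[start + i] != ref[i]:
            mismatches += 1
            if mismatches > max_mismatches_outside_sites:
                return VariantCall(None, "too_many_mismatches")
    return VariantCall(variant_label(edited))


def tabulate_variants(
    reads,
    region: EditingRegion,
    sample: str = "sample",
    max_mismatches_outside_sites: int = DEFAULT_MAX_MISMATCHES,
) -> "VariantTable":
    """Call every read and tabulate counts over all variant labels.

    ``reads`` is an iterable of sequence strings (or Biopython SeqRecords).
    Raises ``ValueError`` if no read is assignable.
    """
    labels = enumerate_variants(region)
    counts = dict.fromkeys(labels, 0)
    n_rejected = 0
    for rec in reads:
        seq = str(rec.seq) if hasattr(rec, "seq") else str(rec)
        call = call_variant(seq, region, max_mismatches_outside_sites)
        if call.assigned:
            counts[call.label] += 1
        else:
            n_rejected += 1
    n_assigned = sum(counts.values())
    if n_assigned == 0:
        raise ValueError(f"sample {sample!r}: no assignable reads")
    frame = pd.DataFrame({sample: counts}).T.loc[:, labels]
    return VariantTable(frame, n_rejected={sample: n_rejected})


class VariantTable:
    """Per-sample read counts and frequencies over the variant labels.

    Wraps a samples x variants count DataFrame; frequencies are each
    sample's counts divided by its total assigned reads.
    """

    def __init__(self, counts: pd.DataFrame, n_rejected: dict[str, int] | None = None):
        if (counts.values < 0).any():
            raise ValueError("variant counts must be non-negative")
        self.counts = counts.astype(float)
        self.n_rejected = dict(n_rejected or {})

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_assigned(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def frequencies(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            empty = list(totals.index[totals == 0])
            raise ValueError(f"samples with zero assigned reads: {empty}")
        return self.counts.div(totals, axis=0)

    @classmethod
    def concat(cls, tables: list["VariantTable"]) -> "VariantTable":
        counts = pd.concat([t.counts for t in tables])
        rejected: dict[str, int] = {}
        for t in tables:
            rejected.update(t.n_rejected)
        return cls(counts, rejected)

    def to_tsv(self, path) -> None:
        self.frequencies.to_csv(path, sep="\t")


def site_efficiencies(table: VariantTable, region: EditingRegion) -> pd.DataFrame:
    """Per-sample editing efficiency of each site.

    Efficiency of a site is the summed frequency of all variants edited at
    that site -- the fraction of transcripts carrying that edit.
    """
    freq = table.frequencies
    sites = [s for s in SITE_TRANSCRIPT_ORDER if s in region.site_offsets]
    out = pd.DataFrame(0.0, index=freq.index, columns=sites)
    for label in freq.columns:
        for s in sites:
            if label != "NONE" and s in label:
                out[s] += freq[label]
    return out


def pca_variants(table: VariantTable) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Centered PCA of the samples x variants frequency matrix.

    Returns ``(scores, variance_fractions, loadings)``.  Sign convention:
    each component is flipped so its largest-magnitude loading is positive.
    Raises on a constant matrix (no variance to decompose).
    """
    freq = table.frequencies
    if len(freq) < 3:
        raise ValueError("PCA requires at least 3 samples")
    x = freq.values - freq.values.mean(axis=0)
    if np.allclose(x, 0):
        raise ValueError("constant frequency matrix: PCA undefined")
    # SVD of the centered matrix == eigen-decomposition of the covariance
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = int(np.sum(s > s[0] * 1e-12))
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for i in range(k):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = pd.DataFrame(
        u * s, index=freq.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    var_frac = s**2 / np.sum(s**2)
    loadings = pd.DataFrame(vt.T, index=freq.columns, columns=scores.columns)
    return scores, var_frac, loadings


def compare_groups(
    values: pd.DataFrame,
    groups: pd.Series,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Exact two-sided Mann-Whitney U per column, BH-adjusted across columns.

    ``values`` is samples x quantities (variant frequencies or site
    efficiencies); ``groups`` assigns each sample to one of exactly two
    group labels, each with at least 2 samples.
    """
    groups = groups.reindex(values.index)
    if groups.isna().any():
        raise ValueError("groups must cover every sample")
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a_idx = groups == levels[0]
    b_idx = groups == levels[1]
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    rows = []
    for col in values.columns:
        a = values.loc[a_idx, col].values
        b = values.loc[b_idx, col].values
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            stat, p = np.nan, 1.0
        else:
            method = "exact" if len(np.unique(np.r_[a, b])) == len(a) + len(b) else "auto"
            res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "quantity": col,
                "statistic": stat,
                f"median_{levels[0]}": float(np.median(a)),
                f"median_{levels[1]}": float(np.median(b)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("quantity")
    out["padj"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out
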