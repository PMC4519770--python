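"""Trait signatures and gene-set overlap tests.

A trait signature correlates one per-sample quantity (the ABCD variant
frequency, or the hub gene's qPCR level) with every gene's normalized
expression by Spearman rank correlation, BH-adjusts across genes, and
splits the significant genes by correlation sign.  Overlaps between
signatures (or between studies, restricted to the symbols detected in
both) are tested with the two-sided Fisher exact test, with a
conditional-MLE odds ratio and exact confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

SIGNATURE_FDR = 0.1
EXACT_P_MAX_N = 9


@lru_cache(maxsize=8)
def _exact_null_rho(n: int) -> np.ndarray:
    """Sorted null distribution of Spearman rho over all n! rank permutations."""
    perms = np.array(list(permutations(range(n))), dtype=float)
    ref = np.arange(n, dtype=float)
    d2 = ((perms - ref) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return np.sort(rho)


def _exact_two_sided_p(rho: float, n: int) -> float:
    null = _exact_null_rho(n)
    return float(np.mean(np.abs(null) >= abs(rho) - 1e-12))


@dataclass
class TraitSignature:
    """Gene-wise correlation table with signed significant sets."""

    trait: str
    table: pd.DataFrame  # columns rho, p, padj
    fdr_cut: float = SIGNATURE_FDR

    @property
    def positive(self) -> set[str]:
        t = self.table
        return set(t.index[(t["padj"] <= self.fdr_cut) & (t["rho"] > 0)])

    @property
    def negative(self) -> set[str]:
        t = self.table
        return set(t.index[(t["padj"] <= self.fdr_cut) & (t["rho"] < 0)])

    def at(self, fdr_cut: float) -> "TraitSignature":
        return TraitSignature(self.trait, self.table, fdr_cut)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["sign"] = np.select(
            [out.index.isin(self.positive), out.index.isin(self.negative)],
            ["positive", "negative"],
            default="ns",
        )
        out.rename_axis("gene").to_csv(path, sep="\t")


def correlate_trait(
    expression: pd.DataFrame,
    trait_values: pd.Series,
    trait_name: str = "trait",
    fdr_cut: float = SIGNATURE_FDR,
) -> TraitSignature:
    """Spearman-correlate a trait with every gene's expression.

    ``expression`` is genes x samples (normalized values); the trait must
    cover every sample with at least 4 samples.  For n <= 9 samples and
    untied data the p-value is exact (full permutation null); otherwise
    the asymptotic t approximation with average ranks is used.
    """
    trait = trait_values.reindex(expression.columns).astype(float)
    if trait.isna().any():
        raise ValueError("trait must be defined for every sample")
    n = len(trait)
    if n < 4:
        raise ValueError("need at least 4 samples")
    if trait.nunique() == 1:
        raise ValueError("constant trait: correlation undefined")

    trait_ranks = stats.rankdata(trait.values)
    gene_ranks = stats.rankdata(expression.values, axis=1)
    tr = trait_ranks - trait_ranks.mean()
    gr = gene_ranks - gene_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((gr**2).sum(axis=1) * (tr**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, gr @ tr / denom, 0.0)

    trait_tied = len(np.unique(trait.values)) < n
    pvals = np.empty(len(rho))
    for i, (r, row) in enumerate(zip(rho, expression.values)):
        tied = trait_tied or len(np.unique(row)) < n
        if denom[i] == 0:
            pvals[i] = 1.0
        elif n <= EXACT_P_MAX_N and not tied:
            pvals[i] = _exact_two_sided_p(r, n)
        else:
            # t approximation on the rank correlation
            t = r * np.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
            pvals[i] = 2.0 * stats.t.sf(abs(t), df=n - 2)
    pvals = np.clip(pvals, 0.0, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame({"rho": rho, "p": pvals, "padj": padj}, index=expression.index)
    return TraitSignature(trait_name, table, fdr_cut)


def shared_universe(gene_list_a, gene_list_b) -> list[str]:
    """Case-normalized symbol intersection of two detected-gene lists."""
    a = {str(g).upper() for g in gene_list_a}
    b = {str(g).upper() for g in gene_list_b}
    shared = sorted(a & b)
    if not shared:
        raise ValueError("no gene symbols shared between the two lists")
    return shared


@dataclass
class OverlapResult:
    universe_size: int
    size_a: int
    size_b: int
    intersection: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float

    def to_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "intersection": self.intersection,
            "odds_ratio": self.odds_ratio,
            "ci_95": [self.ci_low, self.ci_high],
            "p": self.p,
        }


def _cond_mle_or(N: int, K: int, n: int, x: int) -> float:
    """Conditional-MLE odds ratio of a 2x2 table with margins (K, n) in N."""
    lo, hi = max(0, K + n - N), min(K, n)
    if x <= lo:
        return 0.0
    if x >= hi:
        return np.inf

    def neg_logpmf(log_psi: float) -> float:
        return -stats.nchypergeom_fisher.logpmf(x, N, K, n, np.exp(log_psi))

    res = optimize.minimize_scalar(neg_logpmf, bounds=(-30, 30), method="bounded")
    return float(np.exp(res.x))


def _exact_ci(N: int, K: int, n: int, x: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (tail-inversion) CI for the noncentral hypergeometric odds."""
    alpha = 1.0 - level
    lo_supp, hi_supp = max(0, K + n - N), min(K, n)

    def sf_at(log_psi):  # P(X >= x | psi)
        return stats.nchypergeom_fisher.sf(x - 1, N, K, n, np.exp(log_psi))

    def cdf_at(log_psi):  # P(X <= x | psi)
        return stats.nchypergeom_fisher.cdf(x, N, K, n, np.exp(log_psi))

    if x <= lo_supp:
        lower = 0.0
    else:
        lower = float(np.exp(optimize.brentq(lambda t: sf_at(t) - alpha / 2, -35, 35)))
    if x >= hi_supp:
        upper = np.inf
    else:
        upper = float(np.exp(optimize.brentq(lambda t: cdf_at(t) - alpha / 2, -35, 35)))
    return lower, upper


def overlap_test(set_a, set_b, universe) -> OverlapResult:
    """Two-sided Fisher exact test of the overlap of two sets in a universe.

    Both sets are restricted to the universe before tabulation.  The odds
    ratio is the conditional MLE of the noncentral hypergeometric model,
    with an exact 95% CI by tail inversion (infinite upper bound when the
    table is degenerate).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    both = len(a & b)
    a_only = len(a) - both
    b_only = len(b) - both
    neither = len(universe) - both - a_only - b_only
    table = [[both, a_only], [b_only, neither]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    N, K, n, x = len(universe), len(a), len(b), both
    or_mle = _cond_mle_or(N, K, n, x)
    lo, hi = _exact_ci(N, K, n, x)
    return OverlapResult(N, len(a), len(b), both, or_mle, lo, hi, p)
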