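"""Weighted co-expression network construction and module detection.

The Pearson correlation matrix of the selected genes is soft-thresholded
into an unsigned weighted adjacency a_ij = |cor_ij|^beta, with beta chosen
as the smallest candidate whose connectivity distribution is approximately
scale-free (R^2 of the log-log degree fit >= 0.8).  The adjacency is
transformed into the topological overlap matrix (TOM); average-linkage
clustering on 1-TOM with a static cut defines modules, small branches fall
into the grey (unassigned) module, and modules are named by the WGCNA
color convention in decreasing size order.  Module membership is tested
against user-supplied gene sets with the one-sided hypergeometric test,
Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

SCALE_FREE_R2 = 0.8
DEFAULT_BETAS = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)
MIN_MODULE_SIZE = 20
CUT_HEIGHT_FRACTION = 0.99
GREY = "grey"

#: WGCNA color sequence: module labels in decreasing size order.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


def correlation_matrix(expression: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between genes (rows of ``expression``)."""
    cor = np.corrcoef(expression.values)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expression.index, columns=expression.index)


def adjacency(cor: pd.DataFrame, beta: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta."""
    return np.abs(cor) ** beta


def scale_free_fit(adj: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k linear fit over connectivity bins."""
    a = np.asarray(adj, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    k = k[k > 0]
    if len(k) < 3:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mask = counts > 0
    if mask.sum() < 3:
        return 0.0
    logk = np.log10(centers[mask])
    logp = np.log10(counts[mask] / counts.sum())
    r = np.corrcoef(logk, logp)[0, 1]
    return float(r**2)


@dataclass
class BetaChoice:
    beta: float
    fit_table: pd.DataFrame  # columns beta, r2

    def __float__(self):
        return float(self.beta)


#: Fallback power for unsigned networks when no candidate reaches the
#: scale-free fit threshold (the WGCNA convention for unsigned networks).
FALLBACK_BETA = 6.0


def pick_beta(cor: pd.DataFrame, candidate_betas=DEFAULT_BETAS) -> BetaChoice:
    """Smallest candidate power reaching scale-free fit R^2 >= 0.8.

    When no candidate reaches the threshold the fixed unsigned-network
    default (beta = 6) is used: non-scale-free inputs make the raw R^2
    increase toward extreme powers simply because the network empties, so
    chasing the maximum R^2 would destroy all structure.  Requires at
    least 30 genes for the degree distribution to be binnable.
    """
    if len(cor) < 30:
        raise ValueError("need at least 30 genes to assess scale-free fit")
    off = np.abs(cor.values.copy())
    np.fill_diagonal(off, 0.0)
    if np.allclose(off, 0.0):
        raise ValueError("all off-diagonal correlations are zero")
    rows = [
        {"beta": b, "r2": scale_free_fit(adjacency(cor, b).values)}
        for b in candidate_betas
    ]
    table = pd.DataFrame(rows)
    passing = table[table["r2"] >= SCALE_FREE_R2]
    beta = float(passing["beta"].iloc[0]) if len(passing) else FALLBACK_BETA
    return BetaChoice(beta, table)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Unsigned TOM: (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    The diagonal is set to 1; input must be symmetric with entries in
    [0, 1] (the diagonal is ignored internally).
    """
    a = np.asarray(adj, dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or (a - np.diag(np.diag(a))).max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return pd.DataFrame(tom)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = MIN_MODULE_SIZE,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering on 1-TOM with a deterministic static cut.

    Unless ``cut_height`` is given, the tree is cut at the midpoint of the
    largest gap in the sorted merge-height sequence: distinct modules
    merge into each other far above the heights at which their members
    join, so the widest gap separates within-module from between-module
    merges.  Branches smaller than ``min_module_size`` go to grey; with no
    modular structure the merge heights are nearly uniform, the cut lands
    between small chained clusters and (almost) everything is grey.
    Surviving modules get WGCNA color names in decreasing size order (ties
    broken by first gene).  Returns gene -> color.
    """
    genes = list(tom.index)
    if len(genes) < min_module_size:
        return pd.Series(GREY, index=genes, name="module")
    diss = 1.0 - tom.values
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    if cut_height is None:
        heights = link[:, 2]
        gaps = np.diff(heights)
        i = int(np.argmax(gaps)) if len(gaps) else 0
        cut_height = (heights[i] + heights[min(i + 1, len(heights) - 1)]) / 2.0
    labels = hierarchy.fcluster(link, t=cut_height, criterion="distance")

    sizes: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for pos, lab in enumerate(labels):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_pos.setdefault(lab, pos)
    keep = [lab for lab, s in sizes.items() if s >= min_module_size]
    keep.sort(key=lambda lab: (-sizes[lab], first_pos[lab]))
    color_of = {lab: MODULE_COLORS[i % len(MODULE_COLORS)] for i, lab in enumerate(keep)}
    assigned = [color_of.get(lab, GREY) for lab in labels]
    return pd.Series(assigned, index=genes, name="module")


def module_enrichment(
    assignment: pd.Series,
    gene_sets: dict[str, set],
    universe,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of each module in each gene set.

    Bonferroni correction spans all (non-grey module, set) pairs.  Gene
    sets are restricted to the universe; modules outside it never occur by
    construction (the assignment's genes define module membership).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    modules = [m for m in assignment.unique() if m != GREY]
    rows = []
    for mod in modules:
        members = set(assignment.index[assignment == mod]) & universe
        if not members:
            continue
        for set_name, genes in gene_sets.items():
            genes = set(genes) & universe
            k = len(members & genes)
            p = float(stats.hypergeom.sf(k - 1, N, len(genes), len(members)))
            rows.append(
                {
                    "module": mod,
                    "gene_set": set_name,
                    "module_size": len(members),
                    "set_size": len(genes),
                    "overlap": k,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def wgcna(
    expression: pd.DataFrame,
    candidate_betas=DEFAULT_BETAS,
    min_module_size: int = MIN_MODULE_SIZE,
) -> tuple[pd.Series, BetaChoice, pd.DataFrame]:
    """Correlation -> soft threshold -> TOM -> modules, in one call."""
    cor = correlation_matrix(expression)
    choice = pick_beta(cor, candidate_betas)
    tom = topological_overlap(adjacency(cor, choice.beta))
    modules = detect_modules(tom, min_module_size)
    return modules, choice, tom
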