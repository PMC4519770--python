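"""Per-gene three-node Bayesian-network classification against the hub.

For every gene, twelve admissible DAGs over {treatment T, gene expression
G, hub A (Adarb1 qPCR)} are enumerated: T is parentless, T may or may not
point at G and at A, and G and A may be unlinked or linked in either
direction.  Each DAG is scored by a conditional-Gaussian marginal
likelihood and the gene is classified from the top-scoring DAG:

* ambiguous   -- runner-up relative score exp(logscore2 - logscore1) > 0.9
* upstream    -- top DAG contains G -> A
* downstream  -- top DAG contains A -> G
* independent -- otherwise

The continuous score is a BGe-style normal-inverse-Wishart subset
marginal (empirical prior centered on the data mean/variance, one
pseudo-observation, Geiger-Heckerman degree-of-freedom adjustment),
stratified over the discrete treatment parent.  It is score-equivalent:
with no treatment edges the G->A and A->G structures tie exactly, so edge
direction is only ever inferred through treatment-induced v-structure
asymmetry.  The discrete node uses a Beta(1,1)-Bernoulli marginal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, multigammaln

AMBIGUITY_THRESHOLD = 0.9

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
INDEPENDENT = "independent"
AMBIGUOUS = "ambiguous"
CATEGORIES = (UPSTREAM, DOWNSTREAM, INDEPENDENT, AMBIGUOUS)


# ---------------------------------------------------------------------------
# DAG enumeration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateDag:
    """An admissible DAG over nodes T (treatment), G (gene), A (hub)."""

    edges: frozenset[tuple[str, str]]
    index: int = 0

    @property
    def name(self) -> str:
        return "+".join(f"{a}->{b}" for a, b in sorted(self.edges)) or "empty"

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(a for a, b in self.edges if b == node))

    @property
    def gene_to_hub(self) -> bool:
        return ("G", "A") in self.edges

    @property
    def hub_to_gene(self) -> bool:
        return ("A", "G") in self.edges

    def is_acyclic(self) -> bool:
        # 3 nodes; a cycle needs >= 2 edges between G and A or an edge into T
        if any(b == "T" for _, b in self.edges):
            return False
        return not (self.gene_to_hub and self.hub_to_gene)


def enumerate_dags() -> list[CandidateDag]:
    """The 12 admissible DAGs (3 G-A states x 2 T->G x 2 T->A), in a
    canonical deterministic order."""
    dags = []
    for ga in ((), (("G", "A"),), (("A", "G"),)):
        for tg in ((), (("T", "G"),)):
            for ta in ((), (("T", "A"),)):
                edges = frozenset(ga + tg + ta)
                dags.append(CandidateDag(edges, index=len(dags)))
    return dags


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneTriplet:
    """One gene's data: treatment indicator, expression, hub value."""

    treatment: np.ndarray  # 0/1 per sample
    gene_expression: np.ndarray
    adarb1: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.treatment, dtype=int)
        g = np.asarray(self.gene_expression, dtype=float)
        a = np.asarray(self.adarb1, dtype=float)
        if not len(t) == len(g) == len(a):
            raise ValueError("treatment, gene and hub vectors must align")
        if set(np.unique(t)) - {0, 1} or len(np.unique(t)) < 2:
            raise ValueError("treatment must be binary with both levels present")
        object.__setattr__(self, "treatment", t)
        object.__setattr__(self, "gene_expression", g)
        object.__setattr__(self, "adarb1", a)

    @property
    def n(self) -> int:
        return len(self.treatment)


@dataclass(frozen=True)
class ScorePrior:
    """Empirical normal-inverse-Wishart prior over the continuous pair.

    ``mu0``/``var0`` are the full-data mean and variance of (G, A);
    ``kappa0`` is the prior strength in pseudo-observations; the Wishart
    degrees of freedom for a d-dimensional subset are ``d + df_extra``
    (Geiger-Heckerman adjustment keeps the score structure-equivalent).
    """

    mu0: np.ndarray
    var0: np.ndarray
    kappa0: float = 1.0
    df_extra: float = 2.0

    @classmethod
    def from_data(cls, triplet: GeneTriplet, kappa0: float = 1.0) -> "ScorePrior":
        x = np.vstack([triplet.gene_expression, triplet.adarb1])
        var = x.var(axis=1, ddof=0)
        var = np.where(var > 0, var, 1.0)  # constant node: unit prior scale
        return cls(mu0=x.mean(axis=1), var0=var, kappa0=kappa0)


def _mvn_log_marginal(x: np.ndarray, mu0: np.ndarray, var0: np.ndarray, kappa0: float, df_extra: float) -> float:
    """Log marginal likelihood of n iid d-dim rows under the NIW prior."""
    n, d = x.shape
    if n == 0:
        return 0.0
    nu0 = d + df_extra
    t0 = np.diag(var0)
    xbar = x.mean(axis=0)
    dev = x - xbar
    s = dev.T @ dev
    dm = xbar - mu0
    kn = kappa0 + n
    tn = t0 + s + (kappa0 * n / kn) * np.outer(dm, dm)
    nun = nu0 + n
    sign0, logdet0 = np.linalg.slogdet(t0)
    signn, logdetn = np.linalg.slogdet(tn)
    return float(
        -0.5 * n * d * np.log(np.pi)
        + multigammaln(nun / 2.0, d)
        - multigammaln(nu0 / 2.0, d)
        + 0.5 * nu0 * logdet0
        - 0.5 * nun * logdetn
        + 0.5 * d * (np.log(kappa0) - np.log(kn))
    )


_CONT = {"G": 0, "A": 1}


class _FamilyScorer:
    """Caches subset marginals for one gene triplet under one prior."""

    def __init__(self, triplet: GeneTriplet, prior: ScorePrior):
        self.triplet = triplet
        self.prior = prior
        self._x = np.column_stack([triplet.gene_expression, triplet.adarb1])
        self._strata = {t: triplet.treatment == t for t in (0, 1)}
        self._cache: dict[tuple, float] = {}

    def _subset_logml(self, cols: tuple[int, ...], stratum: int | None) -> float:
        key = (cols, stratum)
        if key not in self._cache:
            rows = slice(None) if stratum is None else self._strata[stratum]
            x = self._x[rows][:, list(cols)]
            p = self.prior
            self._cache[key] = _mvn_log_marginal(
                x, p.mu0[list(cols)], p.var0[list(cols)], p.kappa0, p.df_extra
            )
        return self._cache[key]

    def node_score(self, node: str, parents: tuple[str, ...]) -> float:
        if node == "T":
            # Beta(1,1)-Bernoulli marginal; T never has parents
            t = self.triplet.treatment
            n, k = len(t), int(t.sum())
            return float(gammaln(k + 1) + gammaln(n - k + 1) - gammaln(n + 2))
        cont_parents = tuple(p for p in parents if p in _CONT)
        # drop constant continuous regressors (degenerate design)
        usable = []
        for p in cont_parents:
            vals = self._x[:, _CONT[p]]
            if np.ptp(vals) == 0:
                warnings.warn(
                    f"constant regressor {p} dropped from family of {node}",
                    stacklevel=3,
                )
            else:
                usable.append(p)
        fam = tuple(sorted({node, *usable}, key=lambda v: _CONT[v]))
        fam_cols = tuple(_CONT[v] for v in fam)
        par_cols = tuple(_CONT[v] for v in sorted(usable, key=lambda v: _CONT[v]))
        strata = (0, 1) if "T" in parents else (None,)
        total = 0.0
        for st in strata:
            total += self._subset_logml(fam_cols, st)
            if par_cols:
                total -= self._subset_logml(par_cols, st)
        return total

    def score(self, dag: CandidateDag) -> float:
        return sum(self.node_score(v, dag.parents(v)) for v in ("T", "G", "A"))


def score_network(dag: CandidateDag, data: GeneTriplet, prior: ScorePrior | None = None) -> float:
    """Log marginal likelihood of one candidate DAG for one gene."""
    prior = prior or ScorePrior.from_data(data)
    return _FamilyScorer(data, prior).score(dag)


def score_all_networks(data: GeneTriplet, prior: ScorePrior | None = None) -> "NetworkScoreSet":
    prior = prior or ScorePrior.from_data(data)
    scorer = _FamilyScorer(data, prior)
    dags = enumerate_dags()
    return NetworkScoreSet(dags, np.array([scorer.score(d) for d in dags]))


@dataclass
class NetworkScoreSet:
    """Scores of the 12 candidate DAGs, with deterministic ranking."""

    dags: list[CandidateDag]
    log_scores: np.ndarray

    def ranking(self) -> list[int]:
        """Indices by decreasing score; ties broken by canonical DAG order."""
        order = sorted(range(len(self.dags)), key=lambda i: (-self.log_scores[i], i))
        return order

    @property
    def top(self) -> CandidateDag:
        return self.dags[self.ranking()[0]]

    @property
    def relative_score(self) -> float:
        """Runner-up score on the likelihood scale: exp(logscore2 - logscore1)."""
        order = self.ranking()
        return float(np.exp(self.log_scores[order[1]] - self.log_scores[order[0]]))


@dataclass
class GeneClassification:
    category: str
    top_dag: CandidateDag
    log_score: float
    relative_score: float


def classify_gene(scores: NetworkScoreSet, ambiguity: float = AMBIGUITY_THRESHOLD) -> GeneClassification:
    """Apply the 4-way rule to a gene's score vector."""
    if len(scores.dags) != 12:
        raise ValueError("expected scores for all 12 candidate DAGs")
    top = scores.top
    rel = scores.relative_score
    if rel > ambiguity:
        cat = AMBIGUOUS
    elif top.gene_to_hub:
        cat = UPSTREAM
    elif top.hub_to_gene:
        cat = DOWNSTREAM
    else:
        cat = INDEPENDENT
    return GeneClassification(cat, top, float(scores.log_scores[scores.ranking()[0]]), rel)


# ---------------------------------------------------------------------------
# study-level driver
# ---------------------------------------------------------------------------


def classify_all(
    study,
    ambiguity: float = AMBIGUITY_THRESHOLD,
    prior_strength: float = 1.0,
    log_hub: bool = True,
) -> pd.DataFrame:
    """Classify every gene of an :class:`~editnet.expression.ExpressionStudy`.

    Expression is the study's normalized matrix (computed on demand); the
    hub variable is the per-sample Adarb1 qPCR value, log2-transformed by
    default since relative qPCR quantities are ratio-scaled.  Returns a
    gene-indexed table (category, top_dag, log_score, relative_score).
    """
    if "adarb1_qpcr" not in study.metadata.columns:
        raise ValueError("study metadata lacks the adarb1_qpcr column")
    if study.normalized is None:
        study.normalize()
    from .expression import TREATED

    treatment = (study.groups == TREATED).astype(int).values
    hub = study.adarb1_qpcr.values.astype(float)
    if log_hub:
        if (hub <= 0).any():
            raise ValueError("qPCR values must be positive for the log transform")
        hub = np.log2(hub)

    rows = {}
    for gene, expr in study.normalized.iterrows():
        triplet = GeneTriplet(treatment, expr.values, hub)
        prior = ScorePrior.from_data(triplet, kappa0=prior_strength)
        cls = classify_gene(score_all_networks(triplet, prior), ambiguity)
        rows[gene] = {
            "category": cls.category,
            "top_dag": cls.top_dag.name,
            "log_score": cls.log_score,
            "relative_score": cls.relative_score,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


def category_tallies(classification: pd.DataFrame) -> dict[str, int]:
    counts = classification["category"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CATEGORIES}


def intersect_with_signature(classification: pd.DataFrame, signature) -> dict[str, set]:
    """Intersect upstream/downstream calls with a trait signature's signed
    sets (e.g. the hub-correlated genes at FDR < 0.1)."""
    up = set(classification.index[classification["category"] == UPSTREAM])
    down = set(classification.index[classification["category"] == DOWNSTREAM])
    return {
        "upstream_positive": up & signature.positive,
        "upstream_negative": up & signature.negative,
        "downstream_positive": down & signature.positive,
        "downstream_negative": down & signature.negative,
    }
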