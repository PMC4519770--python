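"""DAG enumeration, conditional-Gaussian scoring, gene classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editnet.bayesnet import (
    AMBIGUOUS,
    DOWNSTREAM,
    INDEPENDENT,
    UPSTREAM,
    CandidateDag,
    GeneTriplet,
    NetworkScoreSet,
    ScorePrior,
    classify_all,
    classify_gene,
    enumerate_dags,
    intersect_with_signature,
    score_all_networks,
    score_network,
)
from editnet.simulate import bna_recovery_spec, gen_expression_study
from editnet.trait import TraitSignature


def dag_with(edges):
    return next(d for d in enumerate_dags() if d.edges == frozenset(edges))


class TestEnumerateDags:
    def test_exactly_twelve(self):
        dags = enumerate_dags()
        assert len(dags) == 12
        assert len({d.edges for d in dags}) == 12

    def test_structural_constraints(self):
        for d in enumerate_dags():
            assert not any(b == "T" for _, b in d.edges)  # T parentless
            assert not (d.gene_to_hub and d.hub_to_gene)

    def test_six_without_treatment_to_hub_edge(self):
        without = [d for d in enumerate_dags() if ("T", "A") not in d.edges]
        assert len(without) == 6

    def test_acyclicity_via_networkx_oracle(self):
        import networkx as nx

        for d in enumerate_dags():
            g = nx.DiGraph(list(d.edges))
            g.add_nodes_from(["T", "G", "A"])
            assert nx.is_directed_acyclic_graph(g)
            assert d.is_acyclic()

    def test_canonical_order_deterministic(self):
        assert [d.name for d in enumerate_dags()] == [
            d.name for d in enumerate_dags()
        ]


@pytest.fixture
def gaussian_triplet():
    rng = np.random.default_rng(20)
    t = np.array([0, 1] * 30)
    g = rng.standard_normal(60)
    a = 0.8 * g + 0.6 * rng.standard_normal(60)
    return GeneTriplet(t, g, a)


class TestScoreNetwork:
    def test_empty_dag_factorizes_into_marginals(self, gaussian_triplet):
        prior = ScorePrior.from_data(gaussian_triplet)
        from editnet.bayesnet import _FamilyScorer

        scorer = _FamilyScorer(gaussian_triplet, prior)
        total = score_network(dag_with([]), gaussian_triplet, prior)
        parts = sum(scorer.node_score(v, ()) for v in ("T", "G", "A"))
        assert total == pytest.approx(parts, abs=1e-10)

    def test_markov_equivalence_without_treatment_edges(self, gaussian_triplet):
        prior = ScorePrior.from_data(gaussian_triplet)
        s1 = score_network(dag_with([("G", "A")]), gaussian_triplet, prior)
        s2 = score_network(dag_with([("A", "G")]), gaussian_triplet, prior)
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_markov_equivalence_of_complete_dags(self, gaussian_triplet):
        prior = ScorePrior.from_data(gaussian_triplet)
        full = [("T", "G"), ("T", "A")]
        s1 = score_network(dag_with(full + [("G", "A")]), gaussian_triplet, prior)
        s2 = score_network(dag_with(full + [("A", "G")]), gaussian_triplet, prior)
        assert s1 == pytest.approx(s2, abs=1e-8)

    def test_generating_chain_wins_majority(self):
        rng = np.random.default_rng(21)
        wins = 0
        for _ in range(20):
            t = np.r_[np.zeros(100, int), np.ones(100, int)]
            g = 1.5 * t + rng.standard_normal(200)
            a = 1.0 * g + 0.7 * rng.standard_normal(200)
            ss = score_all_networks(GeneTriplet(t, g, a))
            wins += ss.top.edges == frozenset({("T", "G"), ("G", "A")})
        assert wins > 10

    def test_score_invariant_to_sample_reordering(self, gaussian_triplet):
        prior = ScorePrior.from_data(gaussian_triplet)
        perm = np.random.default_rng(1).permutation(gaussian_triplet.n)
        shuffled = GeneTriplet(
            gaussian_triplet.treatment[perm],
            gaussian_triplet.gene_expression[perm],
            gaussian_triplet.adarb1[perm],
        )
        for dag in enumerate_dags():
            assert score_network(dag, gaussian_triplet, prior) == pytest.approx(
                score_network(dag, shuffled, prior), abs=1e-8
            )

    def test_relative_scores_invariant_to_affine_rescaling(self, gaussian_triplet):
        base = score_all_networks(gaussian_triplet)
        scaled = GeneTriplet(
            gaussian_triplet.treatment,
            5.0 * gaussian_triplet.gene_expression - 3.0,
            gaussian_triplet.adarb1,
        )
        other = score_all_networks(scaled)
        d1 = base.log_scores - base.log_scores.max()
        d2 = other.log_scores - other.log_scores.max()
        assert np.allclose(d1, d2, atol=1e-6)

    def test_constant_regressor_dropped_with_warning(self):
        t = np.array([0, 1] * 10)
        g = np.random.default_rng(2).standard_normal(20)
        a = np.full(20, 3.0)
        trip = GeneTriplet(t, g, a)
        with pytest.warns(UserWarning, match="constant regressor"):
            score_network(dag_with([("A", "G")]), trip)


def rule_oracle(scores, dags, ambiguity=0.9):
    """Independent restatement of the 4-way classification rule."""
    order = sorted(range(12), key=lambda i: (-scores[i], i))
    top, second = order[0], order[1]
    if np.exp(scores[second] - scores[top]) > ambiguity:
        return AMBIGUOUS
    edges = dags[top].edges
    if ("G", "A") in edges:
        return UPSTREAM
    if ("A", "G") in edges:
        return DOWNSTREAM
    return INDEPENDENT


class TestClassifyGene:
    def test_exact_tie_is_ambiguous(self):
        dags = enumerate_dags()
        scores = np.zeros(12)
        cls = classify_gene(NetworkScoreSet(dags, scores))
        assert cls.category == AMBIGUOUS
        assert cls.relative_score == pytest.approx(1.0)

    def test_clear_upstream_dag(self):
        dags = enumerate_dags()
        scores = np.full(12, -100.0)
        i = next(j for j, d in enumerate(dags) if d.edges == frozenset({("T", "G"), ("G", "A")}))
        scores[i] = 0.0
        scores[(i + 1) % 12] = np.log(0.5)
        cls = classify_gene(NetworkScoreSet(dags, scores))
        assert cls.category == UPSTREAM
        assert cls.relative_score == pytest.approx(0.5)

    def test_no_hub_edge_is_independent(self):
        dags = enumerate_dags()
        scores = np.full(12, -100.0)
        i = next(j for j, d in enumerate(dags) if d.edges == frozenset({("T", "G")}))
        scores[i] = 0.0
        scores[(i + 2) % 12] = np.log(0.5)
        assert classify_gene(NetworkScoreSet(dags, scores)).category == INDEPENDENT

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 0), min_size=12, max_size=12))
    def test_matches_rule_oracle_on_random_score_vectors(self, raw):
        dags = enumerate_dags()
        scores = np.array(raw)
        cls = classify_gene(NetworkScoreSet(dags, scores))
        assert cls.category == rule_oracle(scores, dags)


class TestClassifyAll:
    @pytest.fixture(scope="class")
    def recovery(self):
        study = gen_expression_study(bna_recovery_spec(seed=2)).normalize()
        return study, classify_all(study)

    def test_planted_categories_recovered_above_chance(self, recovery):
        study, cls = recovery
        truth = study.truth
        correct = total = 0
        for cat in (UPSTREAM, DOWNSTREAM, INDEPENDENT):
            genes = [g for g in truth[cat] if g in cls.index]
            correct += (cls.loc[genes, "category"] == cat).sum()
            total += len(genes)
        assert correct / total > 0.25 * 2  # far above 4-way chance

    def test_upstream_recall_and_direction(self, recovery):
        study, cls = recovery
        up = [g for g in study.truth["upstream"] if g in cls.index]
        calls = cls.loc[up, "category"]
        assert (calls == UPSTREAM).mean() > 0.6
        # confusion with the opposite direction stays below chance
        assert (calls == DOWNSTREAM).mean() < 0.25

    def test_null_genes_mostly_independent_or_ambiguous(self, recovery):
        study, cls = recovery
        indep = [g for g in study.truth["independent"] if g in cls.index]
        frac = cls.loc[indep, "category"].isin([INDEPENDENT, AMBIGUOUS]).mean()
        assert frac > 0.8

    def test_permuting_hub_destroys_directional_calls(self, recovery):
        study, cls = recovery
        directional = (cls["category"].isin([UPSTREAM, DOWNSTREAM])).sum()
        shuffled = study.metadata.copy()
        rng = np.random.default_rng(3)
        shuffled["adarb1_qpcr"] = rng.permutation(shuffled["adarb1_qpcr"].values)
        from editnet.expression import ExpressionStudy

        broken = ExpressionStudy(study.counts, shuffled, normalized=study.normalized)
        cls2 = classify_all(broken)
        directional2 = (cls2["category"].isin([UPSTREAM, DOWNSTREAM])).sum()
        assert directional2 < directional / 3

    def test_missing_metadata_rejected(self, recovery):
        study, _ = recovery
        from editnet.expression import ExpressionStudy

        bad_meta = study.metadata.drop(columns=["adarb1_qpcr"]).assign(x=1)
        bad = ExpressionStudy(study.counts, bad_meta, normalized=study.normalized)
        with pytest.raises(ValueError, match="adarb1_qpcr"):
            classify_all(bad)


class TestIntersectWithSignature:
    @staticmethod
    def _signature(pos, neg, genes):
        table = pd.DataFrame(
            {
                "rho": [1.0 if g in pos else (-1.0 if g in neg else 0.0) for g in genes],
                "p": 0.001,
                "padj": [0.001 if g in pos | neg else 0.9 for g in genes],
            },
            index=genes,
        )
        return TraitSignature("hub", table, fdr_cut=0.1)

    def test_empty_signature_gives_empty_sets(self):
        genes = [f"g{i}" for i in range(10)]
        cls = pd.DataFrame({"category": [UPSTREAM] * 10}, index=genes)
        sig = self._signature(set(), set(), genes)
        sets = intersect_with_signature(cls, sig)
        assert all(len(v) == 0 for v in sets.values())

    def test_matches_brute_force_intersections(self):
        rng = np.random.default_rng(23)
        genes = [f"g{i}" for i in range(200)]
        cats = rng.choice([UPSTREAM, DOWNSTREAM, INDEPENDENT, AMBIGUOUS], 200)
        cls = pd.DataFrame({"category": cats}, index=genes)
        pos = set(rng.choice(genes, 40, replace=False))
        neg = set(rng.choice(sorted(set(genes) - pos), 40, replace=False))
        sets = intersect_with_signature(cls, self._signature(pos, neg, genes))
        up = {g for g, c in zip(genes, cats) if c == UPSTREAM}
        down = {g for g, c in zip(genes, cats) if c == DOWNSTREAM}
        assert sets["upstream_positive"] == up & pos
        assert sets["upstream_negative"] == up & neg
        assert sets["downstream_positive"] == down & pos
        assert sets["downstream_negative"] == down & neg
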