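"""Weighted voting, ranking, majority prediction and the Gibbs sampler."""

import numpy as np
import pytest

import netfunc as nf
from netfunc import AnnotationTable, ExperimentConfig, ProteinNetwork
from netfunc.inference import FunctionDistribution

from conftest import annotate_all


@pytest.fixture
def two_label_table():
    return AnnotationTable(
        {"e1": {"F1"}, "e2": {"F1"}, "i1": {"F2"}, "i2": {"F2"}},
        labels=("F1", "F2"),
    )


class TestVoteDistribution:
    def test_unanimous_single_layer(self, two_label_table):
        dist = nf.vote_distribution("q", [("e1", 1.0), ("e2", 1.0)], [], two_label_table)
        assert dist.probs.tolist() == [1.0, 0.0]
        assert not dist.uninformative

    def test_lambda_mixture(self, two_label_table):
        dist = nf.vote_distribution(
            "q", [("e1", 1.0), ("e2", 1.0)], [("i1", 5.0), ("i2", 2.0)],
            two_label_table, lam=0.7,
        )
        assert dist.probs == pytest.approx([0.7, 0.3])

    def test_multilabel_neighbor_full_weight_per_label(self):
        table = AnnotationTable({"n": {"F1", "F2"}}, labels=("F1", "F2"))
        dist = nf.vote_distribution("q", [("n", 5.0)], [], table)
        # the neighbor casts weight 5 for each of its labels; Z = 10
        assert dist.probs == pytest.approx([0.5, 0.5])

    def test_normalize_multilabel_flag_same_here(self):
        table = AnnotationTable({"n": {"F1", "F2"}, "o": {"F1"}}, labels=("F1", "F2"))
        plain = nf.vote_distribution("q", [("n", 1.0), ("o", 1.0)], [], table)
        norm = nf.vote_distribution(
            "q", [("n", 1.0), ("o", 1.0)], [], table, normalize_multilabel=True
        )
        assert plain.probs == pytest.approx([2 / 3, 1 / 3])
        assert norm.probs == pytest.approx([0.75, 0.25])

    def test_no_evidence_is_uninformative_uniform(self, two_label_table):
        dist = nf.vote_distribution("q", [], [], two_label_table)
        assert dist.uninformative
        assert dist.probs == pytest.approx([0.5, 0.5])

    def test_lambda_boundaries_reduce_to_single_layer(self, two_label_table):
        explicit = [("e1", 1.0)]
        inferred = [("i1", 1.0)]
        lam1 = nf.vote_distribution("q", explicit, inferred, two_label_table, lam=1.0)
        lam0 = nf.vote_distribution("q", explicit, inferred, two_label_table, lam=0.0)
        only_e = nf.vote_distribution("q", explicit, [], two_label_table)
        only_i = nf.vote_distribution("q", [], inferred, two_label_table)
        assert lam1.probs == pytest.approx(only_e.probs.tolist())
        assert lam0.probs == pytest.approx(only_i.probs.tolist())

    def test_lambda_out_of_range_rejected(self, two_label_table):
        with pytest.raises(nf.ValidationError):
            nf.vote_distribution("q", [("e1", 1.0)], [], two_label_table, lam=1.5)

    def test_monotone_interpolation_in_lambda(self, two_label_table):
        explicit = [("e1", 1.0)]
        inferred = [("i1", 1.0)]
        p_f1 = [
            nf.vote_distribution("q", explicit, inferred, two_label_table, lam=l).probs[0]
            for l in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a < b for a, b in zip(p_f1, p_f1[1:]))


class TestRankLabels:
    labels = ("F1", "F2", "F3")

    def test_descending_order(self):
        dist = FunctionDistribution(np.array([0.5, 0.3, 0.2]))
        assert nf.rank_labels(dist, self.labels, 2) == ("F1", "F2")

    def test_deterministic_tie_break(self):
        dist = FunctionDistribution(np.array([0.4, 0.4, 0.2]))
        assert nf.rank_labels(dist, self.labels, 3) == ("F1", "F2", "F3")

    def test_seeded_tie_shuffle_reproducible(self):
        dist = FunctionDistribution(np.array([1 / 3, 1 / 3, 1 / 3]))
        a = nf.rank_labels(dist, self.labels, 3, rng=np.random.default_rng(5))
        b = nf.rank_labels(dist, self.labels, 3, rng=np.random.default_rng(5))
        assert a == b
        seen = {
            nf.rank_labels(dist, self.labels, 3, rng=np.random.default_rng(s))
            for s in range(20)
        }
        assert len(seen) > 1  # ties really are shuffled


class TestMajority:
    def test_single_voter_path(self):
        net = ProteinNetwork.from_edges([("a", "b"), ("b", "c")])
        table = AnnotationTable({"b": {"F1"}}, labels=("F1", "F2"))
        pred = nf.majority_predict(net, table, "a")
        assert pred.labels[0] == "F1"
        assert not pred.uninformative

    def test_no_annotated_neighbors_flagged(self):
        net = ProteinNetwork.from_edges([("a", "b"), ("c", "d")])
        table = AnnotationTable({"d": {"F1"}}, labels=("F1",))
        assert nf.majority_predict(net, table, "a").uninformative

    def test_unknown_query_rejected(self, triangle):
        table = annotate_all(triangle)
        with pytest.raises(nf.ValidationError):
            nf.majority_predict(triangle, table, "zzz")

    def test_enriched_with_empty_inferred_equals_plain(self, triangle):
        table = AnnotationTable({"b": {"F1"}, "c": {"F2"}}, labels=("F1", "F2"))
        enr = nf.EnrichedNetwork(explicit=triangle, inferred={})
        assert nf.majority_predict(enr, table, "a") == nf.majority_predict(triangle, table, "a")


def unanimous_fixture():
    """Every unannotated protein's annotated neighbors all say F1."""
    net = ProteinNetwork.from_edges(
        [("a1", "q1"), ("q1", "q2"), ("q2", "a2"), ("a3", "q3"), ("a3", "q4")],
        nodes=["a4"],
    )
    table = AnnotationTable(
        {"a1": {"F1"}, "a2": {"F1"}, "a3": {"F1"}, "a4": {"F2"}},
        labels=("F1", "F2"),
    )
    return net, table


class TestGibbs:
    def test_requires_annotated_protein(self, triangle):
        table = AnnotationTable({"zzz": {"F1"}}, labels=("F1",))
        with pytest.raises(nf.ValidationError):
            nf.gibbs_classify(triangle, table)

    def test_deterministic_evidence_chain(self):
        net = ProteinNetwork.from_edges([("a1", "q"), ("q", "a2")])
        table = AnnotationTable({"a1": {"F1"}, "a2": {"F1"}}, labels=("F1", "F2"))
        for seed in (0, 1, 2):
            result = nf.gibbs_classify(net, table, ExperimentConfig(seed=seed, n_samples=20, burn_in=5))
            assert result["q"].labels[0] == "F1"
            # recorded rank-1 column is F1 in every sampling iteration
            assert np.all(result.samples["q"][:, 0] == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_majority_under_unanimous_neighborhoods(self, seed):
        net, table = unanimous_fixture()
        cfg = ExperimentConfig(seed=seed, burn_in=10, n_samples=30, n_ranks=2)
        result = nf.gibbs_classify(net, table, cfg)
        for q in ("q1", "q2", "q3", "q4"):
            assert result[q].labels == nf.majority_predict(net, table, q, cfg).labels

    def test_equal_seeds_identical_sample_matrices(self):
        net, table = unanimous_fixture()
        cfg = ExperimentConfig(seed=11, burn_in=5, n_samples=25)
        r1 = nf.gibbs_classify(net, table, cfg)
        r2 = nf.gibbs_classify(net, table, cfg)
        for q in r1:
            assert np.array_equal(r1.samples[q], r2.samples[q])
            assert np.array_equal(r1.sampled_counts[q], r2.sampled_counts[q])

    def test_unreachable_component_flagged_uninformative(self):
        net = ProteinNetwork.from_edges([("a1", "q1"), ("x1", "x2")])
        table = AnnotationTable({"a1": {"F1"}}, labels=("F1", "F2"))
        result = nf.gibbs_classify(net, table, ExperimentConfig(burn_in=2, n_samples=5))
        assert not result["q1"].uninformative
        assert result["x1"].uninformative and result["x2"].uninformative

    def test_star_sampler_calibration(self):
        # 4-leaf star: 3 leaves F1, 1 leaf F2, uniform weights; the center's
        # conditional is exactly (0.75, 0.25) in every iteration, so the
        # recorded rank-1 is F1 always and the sampled-state frequency of F1
        # is Binomial(s, 0.75)
        net = ProteinNetwork.from_edges([("c", f"l{i}") for i in range(4)])
        table = AnnotationTable(
            {"l0": {"F1"}, "l1": {"F1"}, "l2": {"F1"}, "l3": {"F2"}},
            labels=("F1", "F2"),
        )
        s = 200
        pooled_f1 = 0
        for seed in range(5):
            result = nf.gibbs_classify(net, table, ExperimentConfig(seed=seed, burn_in=10, n_samples=s))
            assert np.all(result.samples["c"][:, 0] == 0)  # rank-1 always F1
            pooled_f1 += int(result.sampled_counts["c"][0])
        n_total = 5 * s
        se = np.sqrt(0.75 * 0.25 / n_total)
        assert abs(pooled_f1 / n_total - 0.75) < 3 * se

    def test_relabeling_invariance_of_evidence(self):
        # renaming proteins (same structure, same seed stream order) keeps
        # the predicted label sets identical under unanimous evidence
        net, table = unanimous_fixture()
        mapping = {n: n.replace("q", "z") for n in net.nodes}
        import networkx as nx

        renamed = ProteinNetwork(nx.relabel_nodes(net.graph, mapping))
        cfg = ExperimentConfig(seed=3, burn_in=5, n_samples=10, n_ranks=1)
        r1 = nf.gibbs_classify(net, table, cfg)
        r2 = nf.gibbs_classify(renamed, table, cfg)
        for q in r1:
            assert r1[q].labels == r2[mapping.get(q, q)].labels
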