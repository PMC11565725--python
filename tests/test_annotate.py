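import networkx as nx
import numpy as np
import pytest

from funclust import annotate
from funclust.cluster import Cluster, Clustering
from funclust.graphio import AnnotationTable
from funclust.synthetic import SyntheticSpec, generate_annotations, generate_network
from conftest import clustering_of


class TestPairSimilarity:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ({"A", "B"}, {"A", "B"}, 1.0),
            ({"A"}, {"B"}, 0.0),
            ({"A", "B"}, {"B", "C"}, 1 / 3),
            (set(), {"A"}, 0.0),
        ],
    )
    def test_jaccard_values(self, u, v, expected):
        assert annotate.pair_similarity(u, v) == pytest.approx(expected)

    def test_empty_union_is_undefined(self):
        assert annotate.pair_similarity(set(), set()) is None


class TestClusterCoherence:
    def test_hand_enumerated_three_proteins(self):
        ann = AnnotationTable(
            terms={"u": {"A", "B"}, "v": {"B", "C"}, "w": {"B"}}
        )
        coh = annotate.cluster_coherence({"u", "v", "w"}, ann)
        assert coh == pytest.approx(4 / 9)

    def test_identical_annotations_score_one(self):
        ann = AnnotationTable(terms={x: {"A", "B"} for x in "abc"})
        assert annotate.cluster_coherence({"a", "b", "c"}, ann) == 1.0

    def test_unannotated_cluster_is_undefined(self):
        ann = AnnotationTable(terms={"a": set(), "b": set()})
        assert annotate.cluster_coherence({"a", "b"}, ann) is None

    def test_empty_pairs_skipped_not_zeroed(self):
        # one annotated pair at similarity 1, one pair with empty union
        ann = AnnotationTable(terms={"a": {"X"}, "b": {"X"}, "c": set()})
        # pairs: (a,b)=1, (a,c)=0 (union non-empty), (b,c)=0
        assert annotate.cluster_coherence({"a", "b", "c"}, ann) == pytest.approx(1 / 3)

    def test_invariant_under_term_relabeling(self):
        ann = AnnotationTable(terms={"a": {"X", "Y"}, "b": {"Y"}, "c": {"Z"}})
        relabeled = AnnotationTable(
            terms={"a": {"T1", "T2"}, "b": {"T2"}, "c": {"T3"}}
        )
        assert annotate.cluster_coherence({"a", "b", "c"}, ann) == pytest.approx(
            annotate.cluster_coherence({"a", "b", "c"}, relabeled)
        )


class TestShuffledNull:
    def test_permutation_preserves_annotation_multiset(self):
        ann = AnnotationTable(
            terms={f"p{i}": {f"GO:{i % 3}"} for i in range(12)}
        )
        clustering = clustering_of({"p0", "p1", "p2"}, {"p3", "p4", "p5"})
        rng_sets = []
        nulls = annotate.shuffled_null(clustering, ann, n_perm=3, seed=1)
        assert len(nulls) == 3
        # multiset preservation: rebuild one permutation explicitly
        universe = sorted(ann.terms)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(universe))
        shuffled = [sorted(ann.get(universe[i])) for i in perm]
        assert sorted(map(tuple, shuffled)) == sorted(
            tuple(sorted(ann.get(p))) for p in universe
        )

    def test_single_total_cluster_null_equals_real(self):
        ann = AnnotationTable(terms={"a": {"X"}, "b": {"Y"}, "c": {"X", "Y"}})
        clustering = clustering_of({"a", "b", "c"})
        real = annotate.coherence_profile(clustering, ann)
        nulls = annotate.shuffled_null(clustering, ann, n_perm=5, seed=0)
        for null in nulls:
            assert list(null.values()) == pytest.approx(list(real.values()))

    def test_same_number_of_observations_as_real(self, small_spec):
        net, labels = generate_network(small_spec)
        ann, _ = generate_annotations(labels, small_spec)
        blocks = {}
        for v, b in labels.items():
            if b >= 0:
                blocks.setdefault(b, set()).add(v)
        clustering = clustering_of(*blocks.values())
        real = annotate.coherence_profile(clustering, ann)
        nulls = annotate.shuffled_null(clustering, ann, n_perm=2, seed=0)
        for null in nulls:
            assert len(null) == len(real)

    def test_planted_signal_beats_null_across_seeds(self):
        wins = 0
        for seed in range(20):
            spec = SyntheticSpec(
                blocks=6, block_size_range=(8, 14), hub_count=0, seed=seed
            )
            net, labels = generate_network(spec)
            ann, _ = generate_annotations(labels, spec)
            blocks = {}
            for v, b in labels.items():
                blocks.setdefault(b, set()).add(v)
            clustering = clustering_of(*blocks.values())
            real = annotate.coherence_profile(clustering, ann)
            null = annotate.shuffled_null(clustering, ann, n_perm=1, seed=seed)[0]
            if np.mean(list(real.values())) > np.mean(list(null.values())):
                wins += 1
        assert wins >= 19


class TestCoherenceTest:
    def test_identical_samples_give_half(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        t, p = annotate.coherence_test(x, list(x))
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_clear_separation_rejects(self):
        rng = np.random.default_rng(0)
        real = rng.normal(1.0, 0.01, 30)
        null = rng.normal(0.0, 0.01, 30)
        _, p = annotate.coherence_test(real, null)
        assert p < 1e-20

    def test_agrees_with_permutation_oracle(self):
        """The t-test p matches a label-permutation p within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        real = rng.normal(0.35, 0.1, 12)
        null = rng.normal(0.25, 0.1, 12)
        _, p = annotate.coherence_test(real, null)
        pooled = np.concatenate([real, null])
        obs = real.mean() - null.mean()
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if perm[:12].mean() - perm[12:].mean() >= obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(p - p_perm) < 0.03


class TestCoherenceThreshold:
    def test_identical_distributions_have_no_crossing(self):
        x = list(np.linspace(0, 1, 50))
        res = annotate.coherence_threshold(x, list(x))
        assert res.threshold is None
        assert res.diagnostic is not None

    def test_two_gaussian_fixture_threshold_between_means(self):
        rng = np.random.default_rng(0)
        real = rng.normal(0.6, 0.05, 300)
        null = rng.normal(0.2, 0.05, 300)
        res = annotate.coherence_threshold(real, null)
        assert res.threshold is not None
        assert 0.2 < res.threshold < 0.6

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(1)
        real = rng.normal(0.5, 0.1, 100)
        null = rng.normal(0.3, 0.1, 100)
        a = annotate.coherence_threshold(real, null)
        b = annotate.coherence_threshold(real[::-1].copy(), null[::-1].copy())
        assert a.threshold == pytest.approx(b.threshold)


class TestFunctionAssignment:
    def make_cluster(self):
        ann = AnnotationTable(
            terms={
                "a": {"GO:1", "GO:2"},
                "b": {"GO:1"},
                "c": {"GO:1", "GO:3"},
                "d": {"GO:2"},
            }
        )
        return Cluster(members={"a", "b", "c", "d"}), ann

    def test_ranked_by_support_then_id(self):
        cluster, ann = self.make_cluster()
        ranked = annotate.assign_cluster_functions(cluster, ann)
        assert ranked[0] == ("GO:1", 3)
        assert ranked[1] == ("GO:2", 2)

    def test_recipe_added_counts_toward_support(self):
        cluster, ann = self.make_cluster()
        ann.terms["z"] = {"GO:3"}
        cluster.recipe_added = {"z"}
        ranked = dict(annotate.assign_cluster_functions(cluster, ann))
        assert ranked["GO:3"] == 2

    def test_slim_min_support_of_three(self):
        slim = {"GO:1": "GO:S1", "GO:2": "GO:S2", "GO:3": "GO:S1"}
        cluster, ann = self.make_cluster()
        # GO:S1 supported by a,b,c (4 via GO:1/GO:3); GO:S2 by a,d
        assert annotate.slim_label(cluster, ann, slim, min_support=3) == "GO:S1"

    def test_under_supported_slim_is_unassigned(self):
        slim = {"GO:2": "GO:S2"}
        cluster, ann = self.make_cluster()  # GO:S2 supported by only 2 proteins
        assert annotate.slim_label(cluster, ann, slim, min_support=3) == "unassigned"

    def test_slim_tie_broken_by_term_id(self):
        ann = AnnotationTable(
            terms={x: {"GO:1", "GO:2"} for x in ("a", "b", "c", "d")}
        )
        slim = {"GO:1": "GO:SB", "GO:2": "GO:SA"}
        cluster = Cluster(members={"a", "b", "c", "d"})
        assert annotate.slim_label(cluster, ann, slim) == "GO:SA"


class TestSummaryCard:
    def test_triangle_counts(self, triangle_net):
        ann = AnnotationTable(terms={v: {"GO:1"} for v in "abc"})
        cluster = Cluster(members={"a", "b", "c"}, id="C0")
        card = annotate.summary_card(cluster, triangle_net, ann)
        assert "edges: 3" in card
        assert "triangles: 1" in card

    def test_path_counts(self, path3_net):
        ann = AnnotationTable(terms={})
        cluster = Cluster(members={"a", "b", "c"}, id="C1")
        card = annotate.summary_card(cluster, path3_net, ann)
        assert "edges: 2" in card
        assert "triangles: 0" in card

    def test_card_and_prompt_deterministic(self, triangle_net):
        ann = AnnotationTable(terms={v: {"GO:1", "GO:2"} for v in "abc"})
        cluster = Cluster(members={"a", "b", "c"}, id="C0")
        a = annotate.summary_card(cluster, triangle_net, ann)
        b = annotate.summary_card(cluster, triangle_net, ann)
        assert a == b
        assert annotate.build_prompt(a) == annotate.build_prompt(b)
        assert "expert biologist" in annotate.build_prompt(a)
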