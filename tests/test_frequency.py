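import random

import pytest

from oncolex.annotate import PostAnnotation
from oncolex.frequency import (
    FrequencyError,
    FrequencyRow,
    FrequencyTable,
    compare_rankings,
    count_posts_by_concept,
    rank_top_n,
    read_registry,
    registry_top_n,
    relative_frequency,
    rollup_to_superclass,
    stratify_by_cancer_type,
)

from conftest import random_tree_ontology
from oracles import ancestor_chain


def ann(pid, concepts, cancer=True, ad=False):
    return PostAnnotation(pid, concepts=set(concepts), is_ad=ad,
                          is_cancer_post=cancer)


class TestRelativeFrequency:
    @pytest.mark.parametrize("n,total,expected", [
        (0, 100, 0.0),
        (254920, 754744, 33.8),
        (47940, 754744, 6.4),
        (1, 16, 6.3),     # 6.25 rounds half-UP to 6.3, not banker's 6.2
        (1, 8, 12.5),
        (3, 3, 100.0),
    ])
    def test_half_up_one_decimal(self, n, total, expected):
        assert relative_frequency(n, total) == expected

    def test_zero_total_is_undefined(self):
        with pytest.raises(FrequencyError):
            relative_frequency(0, 0)

    def test_count_above_total_rejected(self):
        with pytest.raises(FrequencyError):
            relative_frequency(5, 4)

    def test_raw_value_reconstructs_count(self, skeleton):
        annotations = [ann(f"p{i}", {"dwc_diet"} if i < 7 else {"colon_cancer"})
                       for i in range(20)]
        table = count_posts_by_concept(annotations, skeleton)
        for row in table.rows:
            assert round(row.pct_raw * table.total / 100) == row.n_posts


class TestBinaryCounting:
    def test_no_posts_gives_empty_table(self, skeleton):
        table = count_posts_by_concept([], skeleton)
        assert table.rows == [] and table.total == 0

    def test_post_counts_once_per_concept_regardless_of_mentions(self, skeleton):
        # concept sets are already deduplicated per post: two posts with
        # concept X give n_X = 2 however many spans each had
        annotations = [ann("p1", {"colon_cancer"}), ann("p2", {"colon_cancer"})]
        table = count_posts_by_concept(annotations, skeleton)
        assert table.get("colon_cancer").n_posts == 2
        assert table.total == 2

    def test_ads_and_non_cancer_posts_are_excluded(self, skeleton):
        annotations = [
            ann("p1", {"colon_cancer"}),
            ann("p2", {"colon_cancer"}, ad=True),
            ann("p3", {"dwc_diet"}, cancer=False),
        ]
        table = count_posts_by_concept(annotations, skeleton)
        assert table.total == 1

    def test_unknown_concept_is_a_consistency_error(self, skeleton):
        with pytest.raises(FrequencyError):
            count_posts_by_concept([ann("p1", {"mystery"})], skeleton)


class TestRollup:
    def test_two_siblings_count_once_toward_superclass(self, skeleton):
        annotations = [ann("p1", {"dwc_diet", "dwc_exercise", "colon_cancer"})]
        table = rollup_to_superclass(annotations, skeleton)
        assert table.get("dealing_with_cancer").n_posts == 1

    def test_superclass_own_mention_counts(self, skeleton):
        annotations = [ann("p1", {"treatment", "colon_cancer"})]
        table = rollup_to_superclass(annotations, skeleton)
        assert table.get("treatment").n_posts == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_per_post_ancestor_sets_on_random_trees(self, seed):
        ont = random_tree_ontology(seed, n_nodes=30)
        parents = {c: n.parent_id for c, n in ont.nodes.items()}
        rng = random.Random(seed)
        ids = sorted(ont.nodes)
        annotations = [
            ann(f"p{i}", rng.sample(ids, rng.randint(1, 5)))
            for i in range(100)
        ]
        table = rollup_to_superclass(annotations, ont)
        # oracle: per-post root-ancestor sets via explicit parent chains
        expected: dict[str, int] = {}
        for a in annotations:
            roots = set()
            for c in a.concepts:
                chain = ancestor_chain(parents, c)
                roots.add(chain[-1] if chain else c)
            for r in roots:
                expected[r] = expected.get(r, 0) + 1
        assert {r.concept_id: r.n_posts for r in table.rows} == expected


class TestStratification:
    def test_multi_type_post_appears_in_both_strata(self, skeleton):
        annotations = [ann("p1", {"colon_cancer", "stomach_cancer", "dwc_diet"})]
        tables = stratify_by_cancer_type(
            annotations, skeleton, ["colon_cancer", "stomach_cancer"])
        assert tables["colon_cancer"].total == 1
        assert tables["stomach_cancer"].total == 1

    def test_empty_stratum_reported_with_zero_total(self, skeleton):
        annotations = [ann("p1", {"colon_cancer"})]
        tables = stratify_by_cancer_type(annotations, skeleton, ["leukemia"])
        assert tables["leukemia"].total == 0 and tables["leukemia"].rows == []

    def test_unknown_type_raises(self, skeleton):
        with pytest.raises(KeyError):
            stratify_by_cancer_type([], skeleton, ["mystery_cancer"])

    def test_denominators_are_per_stratum(self, skeleton):
        annotations = [
            ann("p1", {"colon_cancer", "tx_surgery"}),
            ann("p2", {"colon_cancer"}),
            ann("p3", {"stomach_cancer", "tx_surgery"}),
        ]
        tables = stratify_by_cancer_type(
            annotations, skeleton, ["colon_cancer", "stomach_cancer"])
        colon = tables["colon_cancer"]
        assert colon.total == 2
        assert colon.get("treatment").pct == 50.0
        assert tables["stomach_cancer"].get("treatment").pct == 100.0

    def test_stratum_totals_at_least_posts_with_any_type(self, skeleton):
        rng = random.Random(9)
        types = ["colon_cancer", "stomach_cancer", "breast_cancer"]
        annotations = [
            ann(f"p{i}", set(rng.sample(types, rng.randint(1, 3))))
            for i in range(200)
        ]
        tables = stratify_by_cancer_type(annotations, skeleton, types)
        n_any = sum(1 for a in annotations if a.concepts & set(types))
        assert sum(t.total for t in tables.values()) >= n_any


class TestRanking:
    def _table(self, counts):
        total = 754744
        rows = [FrequencyRow(c, n, 100 * n / total, relative_frequency(n, total))
                for c, n in counts.items()]
        return FrequencyTable("ALL", "class", rows, total)

    def test_printed_counts_order(self):
        table = self._table({"colon_cancer": 47940, "breast_cancer": 47235,
                             "stomach_cancer": 37378})
        assert rank_top_n(table, 3) == ["colon_cancer", "breast_cancer",
                                        "stomach_cancer"]

    def test_equal_counts_fall_back_to_lexicographic(self):
        table = self._table({"b": 5, "a": 5, "c": 5})
        assert rank_top_n(table, 3) == ["a", "b", "c"]

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            rank_top_n(self._table({"a": 1}), 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_full_sort_oracle(self, seed):
        rng = random.Random(seed)
        counts = {f"c{i}": rng.randint(0, 20) for i in range(30)}
        table = self._table(counts)
        full = sorted(counts, key=lambda c: (-counts[c], c))
        for n in (1, 5, 30):
            assert rank_top_n(table, n) == full[:n]


class TestRankComparison:
    def test_identical_lists_have_empty_differences(self):
        cmp = compare_rankings(["a", "b"], ["a", "b"])
        assert cmp.social_only == set() and cmp.registry_only == set()
        assert cmp.shared == {"a", "b"}

    def test_social_only_types_detected(self):
        cmp = compare_rankings(["cervical_cancer", "colon_cancer"],
                               ["colon_cancer", "thyroid_cancer"])
        assert "cervical_cancer" in cmp.social_only
        assert "thyroid_cancer" in cmp.registry_only
        assert cmp.rank_pairs["cervical_cancer"] == (1, None)
        assert cmp.rank_pairs["colon_cancer"] == (2, 1)

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            compare_rankings(["a", "a"], ["b"])

    @pytest.mark.parametrize("seed", range(5))
    def test_set_algebra_matches_membership_oracle(self, seed):
        rng = random.Random(seed)
        pool = [f"t{i}" for i in range(15)]
        social = rng.sample(pool, 8)
        registry = rng.sample(pool, 8)
        cmp = compare_rankings(social, registry)
        assert cmp.shared == {t for t in social if t in registry}
        assert cmp.social_only == {t for t in social if t not in registry}
        assert cmp.registry_only == {t for t in registry if t not in social}
        assert cmp.shared | cmp.social_only == set(social)
        assert cmp.shared | cmp.registry_only == set(registry)


class TestRegistry:
    def test_read_and_top_n(self, registry_csv):
        df = read_registry(registry_csv)
        assert registry_top_n(df, 4) == [
            "stomach_cancer", "colon_cancer", "thyroid_cancer", "lung_cancer"]

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("cancer_type_label,incidence_rank\nx,1\n")
        with pytest.raises(ValueError):
            read_registry(p)
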