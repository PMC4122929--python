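import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import fisher_two_sided

from conftest import make_seq
from paralogkit.coding import CodingPotentialModel, coding_potential_score
from paralogkit.funcdiv import (
    HitCategory,
    build_control_different_isogroup,
    build_control_same_isogroup,
    chi_square_concordance,
    classify_hit_concordance,
    compare_jaccard_distributions,
    go_enrichment_fisher,
    jaccard_index,
    pairwise_score_difference,
    permutation_median_iqr_test,
)
from paralogkit.io import IsogroupMap


def iso_map(n_groups: int, per_group: int) -> IsogroupMap:
    return IsogroupMap(
        {
            f"t{g}_{i}": f"g{g}"
            for g in range(n_groups)
            for i in range(per_group)
        }
    )


class TestControlSets:
    def test_c1_distinct_isogroups(self):
        cs = build_control_same_isogroup(iso_map(5, 3), 3, seed=1)
        assert cs.n_realized == 3
        groups = {iso_map(5, 3).group_of(a) for a, _ in cs.pairs}
        assert len(groups) == 3
        for a, b in cs.pairs:
            assert iso_map(5, 3).group_of(a) == iso_map(5, 3).group_of(b)
            assert a != b

    def test_c1_capped_at_eligible_isogroups(self):
        cs = build_control_same_isogroup(iso_map(4, 2), 100, seed=1)
        assert cs.n_realized == 4

    def test_c1_deterministic(self):
        a = build_control_same_isogroup(iso_map(10, 3), 5, seed=9)
        b = build_control_same_isogroup(iso_map(10, 3), 5, seed=9)
        assert a.pairs == b.pairs

    def test_c1_no_eligible_isogroup_rejected(self):
        with pytest.raises(ValueError):
            build_control_same_isogroup(iso_map(4, 1), 2, seed=0)

    def test_c2_disjoint_cross_isogroup_pairs(self):
        m = iso_map(4, 1)
        cs = build_control_different_isogroup(m, 2, seed=3)
        assert cs.n_realized == 2
        used = [x for p in cs.pairs for x in p]
        assert len(used) == len(set(used))

    def test_c2_single_isogroup_rejected(self):
        with pytest.raises(ValueError):
            build_control_different_isogroup(iso_map(1, 4), 2, seed=0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_c2_never_reuses_a_sequence(self, seed):
        m = iso_map(8, 3)
        cs = build_control_different_isogroup(m, 12, seed=seed)
        used = [x for p in cs.pairs for x in p]
        assert len(used) == len(set(used))
        for a, b in cs.pairs:
            assert m.group_of(a) != m.group_of(b)


class TestConcordance:
    def test_category_semantics(self):
        hits = {"a1": "P1", "b1": "P1", "a2": "P1", "b2": "P2", "a3": "P1"}
        table = classify_hit_concordance(
            {"G": [("a1", "b1"), ("a2", "b2"), ("a3", "x"), ("y", "z")]}, hits
        )
        row = table.counts["G"]
        assert row[HitCategory.SAME_HIT] == 1
        assert row[HitCategory.DIFFERENT_HIT] == 2  # unequal + one-sided
        assert row[HitCategory.NO_HIT] == 1

    def test_rows_sum_to_group_sizes(self):
        pairs = {"A": [("x", "y")] * 0 + [(f"a{i}", f"b{i}") for i in range(7)],
                 "B": [(f"c{i}", f"d{i}") for i in range(4)]}
        table = classify_hit_concordance(pairs, {})
        assert table.row_total("A") == 7
        assert table.row_total("B") == 4

    def test_chi_square_identical_rows_is_zero(self):
        pairs = {"A": [("a", "b")] * 3, "B": [("c", "d")] * 3}
        table = classify_hit_concordance(pairs, {"a": "P", "b": "P", "c": "P", "d": "P"})
        with pytest.raises(ValueError):
            # two categories empty -> zero expected counts
            chi_square_concordance(table)

    def test_chi_square_hand_computed_value(self):
        from paralogkit.funcdiv import ConcordanceTable

        table = ConcordanceTable()
        data = {"A": (50, 50, 0), "B": (0, 50, 50), "C": (50, 0, 50)}
        for g, (s, d, n) in data.items():
            for _ in range(s):
                table.add(g, HitCategory.SAME_HIT)
            for _ in range(d):
                table.add(g, HitCategory.DIFFERENT_HIT)
            for _ in range(n):
                table.add(g, HitCategory.NO_HIT)
        stat, dof, p = chi_square_concordance(table)
        assert stat == pytest.approx(150.0)
        assert dof == 4


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [({"x"}, {"x"}, 1.0), ({"x"}, {"y"}, 0.0),
         ({"a", "b", "c"}, {"b", "c", "d"}, 0.5), (set(), set(), None)],
    )
    def test_values(self, a, b, expected):
        assert jaccard_index(a, b) == expected

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        a=st.sets(st.integers(0, 20)), b=st.sets(st.integers(0, 20))
    )
    def test_symmetry_and_identity(self, a, b):
        assert jaccard_index(a, b) == jaccard_index(b, a)
        if a or b:
            assert (jaccard_index(a, b) == 1.0) == (a == b)

    def test_identical_groups_kruskal_p_one(self):
        vals = [0.1, 0.5, 0.9, 0.3]
        rep = compare_jaccard_distributions({"A": vals, "B": vals, "C": vals})
        assert rep["kruskal_p"] == pytest.approx(1.0)

    def test_separated_beta_distributions(self):
        rng = np.random.default_rng(8)
        rep = compare_jaccard_distributions(
            {"A": list(rng.beta(5, 1, 200)), "B": list(rng.beta(1, 5, 200))}
        )
        assert rep["pairwise"][("A", "B")]["p_bonferroni"] < 1e-10

    def test_bonferroni_multiplies_by_test_count(self):
        rng = np.random.default_rng(9)
        groups = {k: list(rng.uniform(0, 1, 30)) for k in "ABC"}
        rep = compare_jaccard_distributions(groups)
        for stats in rep["pairwise"].values():
            assert stats["p_bonferroni"] == pytest.approx(
                min(1.0, stats["p_raw"] * 3)
            )


class TestScoreDifferences:
    def test_absolute_differences_and_drops(self):
        diffs, dropped = pairwise_score_difference(
            [("a", "b"), ("c", "d"), ("e", "f")],
            {"a": 0.9, "b": 0.9, "c": 0.9, "d": 0.2},
        )
        assert diffs == [0.0, pytest.approx(0.7)]
        assert dropped == 1


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        x = list(np.linspace(0, 1, 50))
        res = permutation_median_iqr_test(x, x, n_rounds=1000, seed=0)
        assert res.p_median == 1.0

    def test_spread_difference_detected_location_not(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 200)
        y = rng.normal(0, 3, 200)
        res = permutation_median_iqr_test(x, y, n_rounds=5000, seed=1)
        assert res.p_iqr < 0.001
        assert res.p_median > 0.05

    def test_label_exchange_symmetry(self):
        rng = np.random.default_rng(13)
        x, y = rng.uniform(0, 1, 80), rng.uniform(0, 1, 80)
        a = permutation_median_iqr_test(x, y, n_rounds=2000, seed=7)
        b = permutation_median_iqr_test(y, x, n_rounds=2000, seed=7)
        assert a.p_median == b.p_median and a.p_iqr == b.p_iqr

    def test_strict_variant_never_larger(self):
        rng = np.random.default_rng(14)
        x = rng.integers(0, 3, 40).astype(float)
        y = rng.integers(0, 3, 40).astype(float)
        loose = permutation_median_iqr_test(x, y, n_rounds=2000, seed=2)
        strict = permutation_median_iqr_test(x, y, n_rounds=2000, seed=2, strict=True)
        assert strict.p_median <= loose.p_median

    def test_bootstrap_variant_runs(self):
        rng = np.random.default_rng(15)
        res = permutation_median_iqr_test(
            rng.uniform(0, 1, 50), rng.uniform(0, 1, 50),
            n_rounds=1000, seed=3, method="bootstrap",
        )
        assert 0.0 <= res.p_median <= 1.0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            permutation_median_iqr_test([1, 2, 3], [1, 2, 3, 4, 5], n_rounds=1000)
        with pytest.raises(ValueError):
            permutation_median_iqr_test([1] * 10, [2] * 10, n_rounds=10)

    def test_zero_p_displayed_as_resolution_bound(self):
        from paralogkit.funcdiv import PermutationResult

        res = PermutationResult(1, 1, 0.0, 0.5, 1000, 0)
        assert res.display_p(res.p_median) == "< 0.001"


class TestEnrichment:
    def test_equal_rates_p_one(self):
        go = {f"s{i}": {"GO:0000001"} for i in range(40)}
        fg = {f"s{i}" for i in range(10)}
        res = go_enrichment_fisher(fg, set(go), go)
        assert res.table.loc["GO:0000001", "p"] == pytest.approx(1.0)

    def test_fisher_matches_hypergeometric_oracle(self):
        go = {}
        for i in range(10):
            go[f"f{i}"] = {"GO:0000001"} if i < 8 else set()
        for i in range(50):
            go[f"b{i}"] = {"GO:0000001"} if i < 10 else set()
        fg = {f"f{i}" for i in range(10)}
        bg = fg | {f"b{i}" for i in range(50)}
        res = go_enrichment_fisher(fg, bg, go)
        assert res.table.loc["GO:0000001", "p"] == pytest.approx(
            fisher_two_sided(8, 2, 10, 40), rel=1e-6
        )

    def test_bh_with_equal_pvalues(self):
        go = {}
        terms = [f"GO:{i + 1:07d}" for i in range(20)]
        # every term shows the same 2x2 table -> identical p, identical q
        for i in range(5):
            go[f"f{i}"] = set(terms)
        for i in range(45):
            go[f"b{i}"] = set()
        fg = {f"f{i}" for i in range(5)}
        bg = fg | {f"b{i}" for i in range(45)}
        res = go_enrichment_fisher(fg, bg, go)
        assert res.table["p"].nunique() == 1
        assert res.table["q"].nunique() == 1
        assert res.table["q"].iloc[0] == pytest.approx(res.table["p"].iloc[0])
        assert res.table["significant"].all()

    def test_q_never_below_p(self):
        rng = np.random.default_rng(17)
        go = {f"s{i}": {f"GO:{int(t) + 1:07d}" for t in rng.integers(0, 15, 3)}
              for i in range(60)}
        fg = {f"s{i}" for i in range(12)}
        res = go_enrichment_fisher(fg, set(go), go)
        assert (res.table["q"] >= res.table["p"] - 1e-12).all()

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment_fisher(set(), {"a"}, {})

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError):
            go_enrichment_fisher({"x"}, {"a"}, {})


class TestCodingPotential:
    @staticmethod
    def transcript_like(rng, n_codons=300, gc=0.50, disrupted=False):
        """ORF with UTR flanks, the shape of a real transcript."""
        orf = CodingPotentialModel._random_coding(rng, n_codons, gc)
        if disrupted:
            orf = CodingPotentialModel._disrupt(rng, orf)
        utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
        utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        return utr5 + orf + utr3

    def test_intact_transcript_scores_coding(self, coding_model):
        rng = np.random.default_rng(31)
        assert coding_model.score(self.transcript_like(rng)) > 0.5

    def test_disrupted_transcript_scores_noncoding(self, coding_model):
        rng = np.random.default_rng(31)
        assert coding_model.score(self.transcript_like(rng, disrupted=True)) < 0.5

    def test_external_table_passthrough(self, coding_model):
        seq = make_seq("t1", "ACGT" * 50)
        assert coding_potential_score(seq, coding_model, {"t1": 0.73}) == 0.73

    def test_short_sequence_undefined(self, coding_model):
        assert coding_model.score("ACGT" * 10) is None

    def test_deterministic_across_instances(self):
        a = CodingPotentialModel(corpus_size=60)
        b = CodingPotentialModel(corpus_size=60)
        seq = "ATGGCC" * 60
        assert a.score(seq) == b.score(seq)

    def test_scores_in_unit_interval(self, coding_model):
        rng = np.random.default_rng(33)
        for _ in range(5):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
            assert 0.0 <= coding_model.score(seq) <= 1.0
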