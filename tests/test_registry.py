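"""Deduplication, exact-key linkage, stratification and table arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from twolist.registry import (CaseRecord, ContingencyTable, RegistryError,
                              StratumScheme, dedupe, link_sources,
                              overlap_proportion, stratify, union_count)
from twolist.simulate import Scenario, generate

from conftest import make_records


class TestDedupe:
    def test_collapses_exact_duplicates(self):
        recs = make_records(["p1", "p1", "p2"], "A")
        assert sorted(r.person_id for r in dedupe(recs)) == ["p1", "p2"]

    def test_empty_input(self):
        assert dedupe([]) == []

    def test_injected_duplicates_against_unique_key_oracle(self):
        # 83 distinct persons, 17 extra copies scattered in: the deduped list
        # must match the brute-force set of unique keys.
        base = make_records([f"p{i}" for i in range(83)], "A")
        recs = base + [base[i % 83] for i in range(0, 51, 3)]  # 17 duplicates
        assert len(recs) == 100
        out = dedupe(recs)
        assert len(out) == 83
        assert {r.person_id for r in out} == {r.person_id for r in base}

    def test_idempotent(self):
        recs = make_records(["a", "b", "a", "c", "b"], "B")
        once = dedupe(recs)
        assert dedupe(once) == once

    def test_first_occurrence_wins_and_conflict_warns(self, caplog):
        recs = [CaseRecord("p1", "A", 80, "F"), CaseRecord("p1", "A", 90, "M")]
        with caplog.at_level("WARNING"):
            out = dedupe(recs)
        assert out[0].age == 80 and out[0].gender == "F"
        assert any("conflicting" in r.message for r in caplog.records)

    def test_conflict_raises_in_strict_mode(self):
        recs = [CaseRecord("p1", "A", 80, "F"), CaseRecord("p1", "A", 80, "M")]
        with pytest.raises(RegistryError, match="conflicting"):
            dedupe(recs, strict=True)

    def test_one_year_age_difference_is_tolerated(self, caplog):
        # Age at first capture may straddle a birthday within the window.
        recs = [CaseRecord("p1", "A", 80, "F"), CaseRecord("p1", "A", 81, "F")]
        with caplog.at_level("WARNING"):
            out = dedupe(recs, strict=True)
        assert len(out) == 1

    def test_mixed_sources_rejected(self):
        with pytest.raises(RegistryError, match="single source"):
            dedupe([CaseRecord("p1", "A"), CaseRecord("p2", "B")])


class TestLinkSources:
    def test_small_overlap(self):
        a = make_records([f"p{i}" for i in range(1, 6)], "A")
        b = make_records([f"p{i}" for i in range(4, 8)], "B")
        t = link_sources(a, b)
        assert (t.m, t.a_only, t.b_only) == (2, 3, 2)

    def test_published_counts_from_constructed_keys(self):
        shared = [f"s{i}" for i in range(856)]
        a = make_records(shared + [f"a{i}" for i in range(2968)], "A")
        b = make_records(shared + [f"b{i}" for i in range(1738)], "B")
        t = link_sources(a, b)
        assert (t.m, t.a_only, t.b_only) == (856, 2968, 1738)
        assert (t.n1, t.n2, t.union) == (3824, 2594, 5562)

    @settings(max_examples=50, deadline=None)
    @given(
        keys_a=st.sets(st.integers(0, 700), max_size=500),
        keys_b=st.sets(st.integers(0, 700), max_size=500),
    )
    def test_agrees_with_quadratic_comparison_oracle(self, keys_a, keys_b):
        a = make_records([f"k{i}" for i in keys_a], "A")
        b = make_records([f"k{i}" for i in keys_b], "B")
        t = link_sources(a, b)
        # O(n^2) oracle: count pairwise key matches explicitly.
        m_brute = sum(1 for ra in a for rb in b if ra.person_id == rb.person_id)
        assert t.m == m_brute
        assert t.a_only == len(a) - m_brute
        assert t.b_only == len(b) - m_brute

    @settings(max_examples=30, deadline=None)
    @given(
        keys_a=st.sets(st.integers(0, 100), max_size=60),
        keys_b=st.sets(st.integers(0, 100), max_size=60),
    )
    def test_symmetric_in_m_and_union(self, keys_a, keys_b):
        a = make_records([f"k{i}" for i in keys_a], "A")
        b = make_records([f"k{i}" for i in keys_b], "B")
        t_ab = link_sources(a, b)
        t_ba = link_sources(make_records([r.person_id for r in b], "A"),
                            make_records([r.person_id for r in a], "B"))
        assert t_ab.m == t_ba.m and t_ab.union == t_ba.union
        assert (t_ab.a_only, t_ab.b_only) == (t_ba.b_only, t_ba.a_only)

    def test_requires_deduplicated_input(self):
        a = make_records(["p1", "p1"], "A")
        with pytest.raises(RegistryError, match="dedup"):
            link_sources(a, make_records(["p2"], "B"))


class TestStratify:
    def test_age_class_boundaries(self):
        scheme = StratumScheme()
        assert [scheme.age_class(a) for a in (80, 84, 85, 89, 90, 95)] == [0, 0, 1, 1, 2, 2]
        assert scheme.labels() == ["F:<=84", "M:<=84", "F:85-89", "M:85-89",
                                   "F:>=90", "M:>=90"]

    def test_single_gender_input_leaves_half_the_strata_empty(self):
        a = [CaseRecord(f"p{i}", "A", age, "F") for i, age in enumerate((70, 86, 95))]
        tables = stratify(a, [], StratumScheme())
        nonempty = [t for t in tables if t.union > 0]
        assert len(tables) == 6 and len(nonempty) == 3
        assert all(t.label.startswith("F:") for t in nonempty)

    def test_stratum_tables_sum_to_overall(self):
        a, b, _ = generate(Scenario.homogeneous(800, 0.4, 0.3, seed=3))
        overall = link_sources(a, b)
        tables = stratify(a, b, StratumScheme(age_breaks=(80, 90)))
        assert sum(t.m for t in tables) == overall.m
        assert sum(t.a_only for t in tables) == overall.a_only
        assert sum(t.b_only for t in tables) == overall.b_only

    def test_counts_match_generator_ground_truth(self):
        from twolist.simulate import paper_marginals_scenario
        a, b, truth = generate(paper_marginals_scenario(seed=11))
        tables = {t.label: t for t in stratify(a, b, StratumScheme())}
        # Per stratum, observed union must equal the truth's captured count.
        observed = {}
        for pid, pat in truth.pattern.items():
            if pat != "neither":
                observed[truth.stratum[pid]] = observed.get(truth.stratum[pid], 0) + 1
        for lab, n_obs in observed.items():
            assert tables[lab].union == n_obs

    def test_missing_demographics_excluded_not_fatal(self, caplog):
        a = [CaseRecord("p1", "A", 80, "F"), CaseRecord("p2", "A", None, "F")]
        with caplog.at_level("WARNING"):
            tables = stratify(a, [], StratumScheme())
        assert sum(t.union for t in tables) == 1
        with pytest.raises(RegistryError, match="missing demographics"):
            stratify(a, [], StratumScheme(), strict=True)

    def test_cross_source_conflict_resolved_by_source_a(self):
        a = [CaseRecord("p1", "A", 80, "F")]
        b = [CaseRecord("p1", "B", 92, "F")]
        tables = {t.label: t for t in stratify(a, b, StratumScheme())}
        assert tables["F:<=84"].m == 1
        assert tables["F:>=90"].union == 0


class TestTableArithmetic:
    def test_union_and_overlap_of_published_table(self, table1):
        assert union_count(table1) == 5562
        assert overlap_proportion(table1, as_percent=True) == 15.4

    @pytest.mark.parametrize(
        "t, union, pct",
        [
            (ContingencyTable(0, 3, 4), 7, 0.0),
            (ContingencyTable(5, 0, 0), 5, 100.0),
        ],
    )
    def test_degenerate_tables(self, t, union, pct):
        assert union_count(t) == union
        assert overlap_proportion(t, as_percent=True) == pct

    def test_empty_table_rejected(self):
        with pytest.raises(RegistryError, match="empty"):
            overlap_proportion(ContingencyTable(0, 0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(RegistryError):
            ContingencyTable(-1, 0, 0)
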