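import pytest
from hypothesis import given, strategies as st

from lditrends.corpus_model import Corpus, Publication
from lditrends.enrichment_stats import (
    BackgroundRate,
    CooccurrenceRow,
    Substance,
    background_rate,
    build_cooccurrence_table,
    context_ratio,
    default_matrix_substances,
    default_nonmatrix_substances,
    excess_over_expected,
    expected_ratio,
    flag_enriched,
    load_reference_counts,
    pooled_weighted_average,
    substance_query,
    write_table,
)
from lditrends.query_engine import Term, count_matches, parse_query


def _pub(i, abstract="", methods=""):
    return Publication(pub_id=f"P{i}", abstract=abstract, methods_text=methods)


def _corpus_with_counts(substance, total, with_tech):
    """total pubs mentioning substance, with_tech of them also MALDI."""
    pubs = [
        _pub(i, abstract=f"about {substance} here",
             methods="MALDI run" if i < with_tech else "other run")
        for i in range(total)
    ]
    pubs += [_pub(1000 + i, methods="MALDI run") for i in range(5)]
    return Corpus(publications=pubs)


class TestCooccurrenceTable:
    def test_counts_match_published_table_structure(self):
        corpus = _corpus_with_counts("pyranylium", total=24, with_tech=20)
        rows = build_cooccurrence_table(
            corpus, [Substance("pyranylium")], parse_query("MALDI")
        )
        (row,) = rows
        assert (row.total, row.with_technique) == (24, 20)

    def test_absent_substance_has_undefined_ratios(self, hand_corpus):
        (row,) = build_cooccurrence_table(
            hand_corpus, [Substance("unobtainium")], parse_query("MALDI")
        )
        assert row.total == 0
        assert row.technique_fraction is None
        assert row.sm_pp is None and row.sm_op is None

    def test_synonyms_union_counts(self):
        pubs = [_pub(0, abstract="sinapic acid data"),
                _pub(1, abstract="sinapinic acid data"),
                _pub(2, abstract="unrelated")]
        corpus = Corpus(publications=pubs)
        substance = Substance("sinapic acid", synonyms=["sinapinic acid"])
        (row,) = build_cooccurrence_table(corpus, [substance], parse_query("MALDI"))
        # brute-force union of the two synonym matches
        brute = sum(
            any(count_matches(Corpus(publications=[p]), Term(s))
                for s in substance.all_terms())
            for p in pubs
        )
        assert row.total == brute == 2

    def test_rows_sorted_by_technique_cooccurrence(self, generated):
        config, corpus, _ = generated
        from lditrends.synthetic_corpus import config_substances

        matrices, _ = config_substances(config)
        rows = build_cooccurrence_table(corpus, matrices, parse_query("MALDI"))
        counts = [r.with_technique for r in rows]
        assert counts == sorted(counts, reverse=True)

    def test_empty_synonym_list_rejected(self):
        with pytest.raises(ValueError):
            substance_query(Substance(name="  "))


class TestBackgroundRate:
    def test_equal_fractions_zero_sd(self):
        pubs = []
        for name in ("alphaxide", "betaxide"):
            pubs += [
                _pub(f"{name}{i}", abstract=f"{name} sample",
                     methods="MALDI" if i == 0 else "none")
                for i in range(100)
            ]
        corpus = Corpus(publications=pubs)
        bg = background_rate(
            corpus, [Substance("alphaxide"), Substance("betaxide")],
            parse_query("MALDI"),
        )
        assert bg.mean_percent == pytest.approx(1.0)
        assert bg.sd_percent == pytest.approx(0.0)

    def test_hand_arithmetic_mean_and_sample_sd(self):
        # fractions 0.5%, 1.0%, 1.5% -> mean 1.0%, sd 0.5%
        pubs = []
        for name, hits in (("axx", 1), ("bxx", 2), ("cxx", 3)):
            pubs += [
                _pub(f"{name}{i}", abstract=f"{name} data",
                     methods="MALDI" if i < hits else "no")
                for i in range(200)
            ]
        bg = background_rate(
            Corpus(publications=pubs),
            [Substance("axx"), Substance("bxx"), Substance("cxx")],
            parse_query("MALDI"),
        )
        assert bg.mean_percent == pytest.approx(1.0)
        assert bg.sd_percent == pytest.approx(0.5)

    def test_unmatched_substance_excluded_with_warning(self):
        pubs = []
        for name in ("axx", "bxx"):
            pubs += [
                _pub(f"{name}{i}", abstract=f"{name} sample",
                     methods="MALDI" if i == 0 else "none")
                for i in range(50)
            ]
        with pytest.warns(UserWarning, match="matches no"):
            bg = background_rate(
                Corpus(publications=pubs),
                [Substance("axx"), Substance("bxx"), Substance("missing")],
                parse_query("MALDI"),
            )
        assert bg.n_substances == 2


class TestEnrichmentRule:
    BG = BackgroundRate(1.0, 0.39, 10, {})

    def _row(self, total, with_tech):
        return CooccurrenceRow("x", ["x"], total, with_tech, 0, 0, 0)

    def test_high_fraction_and_count_enriched(self):
        (row,) = flag_enriched([self._row(13, 13)], self.BG)
        assert row.enriched

    def test_below_min_count_not_enriched(self):
        (row,) = flag_enriched([self._row(18, 9)], self.BG)
        assert not row.enriched

    def test_below_fold_threshold_not_enriched(self):
        (row,) = flag_enriched([self._row(1000, 20)], self.BG)
        assert not row.enriched

    def test_monotone_in_with_technique(self):
        rows = [self._row(100, k) for k in range(101)]
        flagged = flag_enriched(rows, self.BG)
        states = [r.enriched for r in flagged]
        assert states == sorted(states)  # False...False True...True


class TestRatios:
    def test_published_discussion_fractions(self):
        assert round(100 * context_ratio(517, 4688)) == 11
        assert round(100 * context_ratio(459, 2183)) == 21

    def test_zero_numerator(self):
        assert context_ratio(0, 5) == 0

    def test_zero_denominator_is_undefined_not_error(self):
        assert context_ratio(3, 0) is None

    def test_expected_ratio_values(self):
        assert expected_ratio(10478, 80806) == 0.130
        assert expected_ratio(10478, 23288) == 0.450
        assert expected_ratio(7, 7) == 1.000
        assert expected_ratio(1, 0) is None

    def test_excess_over_expected(self):
        assert excess_over_expected(0.208, 0.130) == pytest.approx(60.0)
        assert excess_over_expected(0.45, 0.45) == 0.0
        assert round(excess_over_expected(0.548, 0.450), 1) == 21.8


def _rows(pairs):
    return [
        CooccurrenceRow(f"s{i}", [f"s{i}"], 10 * (sm + pp) + 10,
                        sm + pp, sm, pp, 0)
        for i, (sm, pp) in enumerate(pairs)
    ]


class TestPooledWeightedAverage:
    def test_hand_arithmetic(self):
        assert pooled_weighted_average(_rows([(1, 2), (3, 3)])) == pytest.approx(0.8)

    def test_single_row_identity(self):
        (row,) = _rows([(2, 5)])
        assert pooled_weighted_average([row]) == pytest.approx(row.sm_pp)

    def test_all_zero_denominators_undefined(self):
        assert pooled_weighted_average(_rows([(0, 0)])) is None

    def test_row_weighted_mode_differs_but_stays_in_range(self):
        rows = _rows([(1, 10), (5, 5)])
        ratios = [r.sm_pp for r in rows]
        for mode in ("pooled", "row_weighted"):
            value = pooled_weighted_average(rows, mode=mode)
            assert min(ratios) <= value <= max(ratios)

    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 20), st.integers(0, 20)), min_size=1, max_size=8
        ),
        seed=st.integers(0, 1000),
    )
    def test_invariant_to_order_and_row_splitting(self, pairs, seed):
        import numpy as np

        rows = _rows(pairs)
        base = pooled_weighted_average(rows)
        rng = np.random.default_rng(seed)
        perm = [rows[i] for i in rng.permutation(len(rows))]
        assert pooled_weighted_average(perm) == base
        # split the first row into two rows with the same summed counts
        # (both halves keep a nonzero denominator so each remains a
        # well-defined ratio row)
        sm, pp = pairs[0]
        if pp >= 2:
            a_sm = sm // 2
            a_pp = pp // 2
            split = _rows([(a_sm, a_pp), (sm - a_sm, pp - a_pp)] + pairs[1:])
            assert pooled_weighted_average(split) == pytest.approx(base)


class TestResources:
    def test_shipped_lists_match_study_design(self):
        matrices = default_matrix_substances()
        nonmatrix = default_nonmatrix_substances()
        assert len(matrices) == 19 and len(nonmatrix) == 10
        assert {s.name for s in nonmatrix} == {
            "adenosine", "alanine", "ascorbic acid", "chlorophyll",
            "cholesterol", "cisplatin", "cocaine", "glucose", "nicotine",
            "water",
        }
        assert sum(s.curated_matrix for s in matrices) == 8

    def test_reference_counts_ranked_by_cooccurrence(self):
        rows = load_reference_counts()
        assert len(rows) == 19
        counts = [r.with_technique for r in rows]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 9178 and counts[-1] == 13

    def test_write_table_round_half_formats(self, tmp_path):
        rows = flag_enriched(
            _rows([(1, 2)]), BackgroundRate(1.0, 0.0, 2, {})
        )
        out = tmp_path / "t.tsv"
        write_table(rows, out, decimals=2)
        lines = out.read_text("utf-8").splitlines()
        assert lines[0].startswith("substance\t")
        assert "0.50" in lines[1]
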