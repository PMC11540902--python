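"""Note parsing and the quota-cleaning chain."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quotawatch.ingest import (
    ALL,
    QuotaScope,
    RawQuotaRow,
    SplitEvent,
    clean_quotas,
    deduplicate,
    drop_backdated_split_quotas,
    filter_invalid,
    parse_quota_note,
    resolve_subspecies,
)


def row(party="ID", year=2005, taxon="Genus01 species001", rank="species", amount=100, notes="live"):
    return RawQuotaRow(party=party, year=year, taxon_name=taxon, rank=rank, amount=amount, notes=notes)


class TestParseQuotaNote:
    @pytest.mark.parametrize(
        "note, terms, sources, purposes",
        [
            ("live", frozenset({"live"}), frozenset({"wild"}), ALL),
            (None, ALL, frozenset({"wild"}), ALL),
            ("", ALL, frozenset({"wild"}), ALL),
            ("all", ALL, ALL, ALL),
            ("all, live", frozenset({"live"}), ALL, ALL),
            ("all, wild-taken", ALL, frozenset({"wild"}), ALL),
            ("live, wild-taken", frozenset({"live"}), frozenset({"wild"}), ALL),
            ("skins and meat", frozenset({"skins", "meat"}), frozenset({"wild"}), ALL),
        ],
    )
    def test_defaulting_rules(self, note, terms, sources, purposes):
        scope = parse_quota_note(note).scope
        assert scope.terms == terms
        assert scope.sources == sources
        assert scope.purposes == purposes

    def test_incomparable_term_mixture(self):
        # skins alone can be counted as animals; mixing with meat cannot
        assert parse_quota_note("live").scope.comparable
        assert parse_quota_note("skins").scope.comparable
        assert not parse_quota_note("skins and meat").scope.comparable
        assert not parse_quota_note("small leather pieces and skins").scope.comparable

    def test_unknown_token_preserved_with_warning(self):
        parsed = parse_quota_note("live, frobnicated widgets")
        assert parsed.unparsed == ("frobnicated widgets",)
        assert parsed.warnings
        assert parsed.scope.terms == frozenset({"live"})

    def test_region_tag_extracted(self):
        parsed = parse_quota_note("live (Sabah)")
        assert parsed.region == "sabah"
        assert parsed.scope.terms == frozenset({"live"})

    @given(st.text(max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_total_on_arbitrary_text(self, text):
        """Every note yields a scope; nothing raises, nothing is dropped."""
        parsed = parse_quota_note(text)
        for dim in (parsed.scope.terms, parsed.scope.sources, parsed.scope.purposes):
            assert dim == ALL or len(dim) > 0

    @pytest.mark.parametrize("note", ["live", "all, live", "skins and meat", "live, ranched", None])
    def test_scope_roundtrip_via_canonical_string(self, note):
        scope = parse_quota_note(note).scope
        assert QuotaScope.from_canonical(scope.canonical()) == scope


class TestScope:
    def test_covers_and_all_sentinel(self):
        scope = parse_quota_note("live").scope
        assert scope.covers("live", "wild", "commercial")
        assert not scope.covers("skins", "wild", "commercial")
        assert not scope.covers("live", "captive", "commercial")

    def test_intersects(self):
        live_wild = parse_quota_note("live").scope
        live_all = parse_quota_note("all, live").scope
        skins = parse_quota_note("skins").scope
        assert live_wild.intersects(live_all)
        assert not live_wild.intersects(skins)

    def test_empty_dimension_rejected(self):
        with pytest.raises(ValueError):
            QuotaScope(terms=frozenset())


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        rows = [row(), row()]
        assert deduplicate(rows) == [row()]

    def test_differing_amount_kept(self):
        rows = [row(amount=100), row(amount=200)]
        assert len(deduplicate(rows)) == 2

    def test_planted_duplicate_count(self):
        base = [row(year=2000 + i, amount=10 * i) for i in range(8)]
        rows = base + [base[2], base[5]]
        assert deduplicate(rows) == base

    @given(st.lists(st.integers(2000, 2005), max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_matches_set_semantics_order_stable(self, years):
        rows = [row(year=y) for y in years]
        out = deduplicate(rows)
        assert len(out) == len(set(rows))
        assert out == [r for i, r in enumerate(rows) if r not in rows[:i]]


class TestSplitRemoval:
    EVENT = SplitEvent("Genus01 parent", "Genus01 child", 2017)

    def test_backdated_duplicate_removed(self):
        parent = row(taxon="Genus01 parent", year=2015)
        child = row(taxon="Genus01 child", year=2015)
        assert drop_backdated_split_quotas([parent, child], [self.EVENT]) == [parent]

    def test_post_adoption_child_kept(self):
        parent = row(taxon="Genus01 parent", year=2018)
        child = row(taxon="Genus01 child", year=2018)
        assert len(drop_backdated_split_quotas([parent, child], [self.EVENT])) == 2

    def test_pre_adoption_child_without_parent_match_kept(self):
        child = row(taxon="Genus01 child", year=2015, amount=77)
        parent = row(taxon="Genus01 parent", year=2015, amount=99)
        out = drop_backdated_split_quotas([parent, child], [self.EVENT])
        assert child in out

    def test_unknown_taxon_warns(self):
        warn = []
        drop_backdated_split_quotas([row()], [SplitEvent("Nope a", "Nope b", 2010)], warn=warn)
        assert warn


class TestSubspeciesAndValidity:
    def test_trinomial_on_species_rank_collapsed(self):
        r = row(taxon="Genus01 species001 subsp", rank="species")
        assert resolve_subspecies([r])[0].taxon_name == "Genus01 species001"

    def test_explicit_subspecies_rank_unchanged(self):
        r = row(taxon="Genus01 species001 subsp", rank="subspecies")
        assert resolve_subspecies([r])[0] is r

    def test_binomial_identity(self):
        r = row()
        assert resolve_subspecies([r])[0] is r

    @pytest.mark.parametrize(
        "r, reason",
        [
            (row(amount=-1), "sentinel_amount"),
            (row(amount=None), "sentinel_amount"),
            (row(notes="March 2012 to March 2013"), "multi_year_span"),
            (row(notes="re-exports only"), "reexport_only"),
        ],
    )
    def test_invalid_reasons(self, r, reason):
        kept, removed = filter_invalid([r])
        assert kept == []
        assert removed == [(r, reason)]

    def test_ordinary_row_kept_and_partition(self):
        rows = [row(), row(amount=-1), row(year=2010)]
        kept, removed = filter_invalid(rows)
        assert len(kept) + len(removed) == len(rows)
        assert row() in kept

    def test_span_within_one_year_not_removed(self):
        kept, _ = filter_invalid([row(notes="January 2012 to November 2012")])
        assert len(kept) == 1


class TestCleanChain:
    def _rows(self):
        base = [row(year=2000 + i, amount=100 + i) for i in range(6)]
        dupes = [base[0], base[3]]
        invalid = [row(taxon="Genus02 bad", amount=-1), row(taxon="Genus02 span", notes="March 2001 to March 2002")]
        return base + dupes + invalid

    def test_stage_counts_sum(self):
        rows = self._rows()
        result = clean_quotas(rows)
        removed_total = sum(len(v) for v in result.removed.values())
        assert result.stage_counts["input"] - result.stage_counts["output"] == removed_total
        assert len(result.removed["duplicate"]) == 2
        assert len(result.removed["invalid"]) == 2

    def test_idempotent(self):
        rows = self._rows()
        once = clean_quotas(rows)
        again_rows = [
            RawQuotaRow(party=q.party, year=q.year, taxon_name=q.taxon, rank=q.rank, amount=q.amount, notes="live")
            for q in once.records
        ]
        twice = clean_quotas(again_rows)
        assert [(q.party, q.year, q.taxon, q.amount) for q in twice.records] == [
            (q.party, q.year, q.taxon, q.amount) for q in once.records
        ]

    def test_record_count_non_increasing_through_stages(self):
        counts = clean_quotas(self._rows()).stage_counts
        order = ["input", "after_dedup", "after_splits", "after_subspecies", "after_invalid", "output"]
        vals = [counts[k] for k in order]
        assert vals == sorted(vals, reverse=True)
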