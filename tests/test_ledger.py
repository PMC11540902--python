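"""Trade filtering, volume aggregation and quota-side preparation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quotawatch.ingest import ALL, QuotaRecord, QuotaScope, parse_quota_note
from quotawatch.ledger import (
    TradeRecord,
    aggregate_volumes,
    exclude_mixed_term_species,
    filter_live_direct,
    remove_overlapping_quotas,
    sum_malaysian_regions,
)


def trec(term="live", unit="", origin=None, source="wild", purpose="commercial",
         qty=100.0, reporter="exporter_reported", exporter="ID", year=2005,
         taxon="Genus01 species001"):
    return TradeRecord(
        year=year, taxon=taxon, exporter=exporter, importer="US", term=term,
        source=source, purpose=purpose, quantity=qty, unit=unit, reporter=reporter, origin=origin,
    )


def quota(id="q1", party="ID", year=2005, taxon="Genus01 species001", amount=100,
          note="live", region=None, rank="species"):
    parsed = parse_quota_note(note)
    return QuotaRecord(
        id=id, party=party, year=year, taxon=taxon, rank=rank, amount=amount,
        scope=parsed.scope, region=region or parsed.region,
    )


class TestFilterLiveDirect:
    def test_live_blank_unit_no_origin_kept(self):
        assert filter_live_direct([trec()]) == [trec()]

    def test_weight_unit_removed(self):
        assert filter_live_direct([trec(unit="kg")]) == []

    def test_reexport_removed_direct_kept(self):
        reexport = trec(origin="MG")
        direct = trec(origin="ID")
        assert filter_live_direct([reexport, direct]) == [direct]

    def test_idempotent(self):
        records = [trec(), trec(unit="kg"), trec(term="skins"), trec(origin="XX")]
        once = filter_live_direct(records)
        assert filter_live_direct(once) == once


class TestAggregateVolumes:
    KEY = ("Genus01 species001", "ID", 2005)

    def test_out_of_scope_source_zero(self):
        scope = parse_quota_note("live").scope  # wild only
        cell = aggregate_volumes([trec(source="captive")], scope, self.KEY)
        assert cell.exporter_volume == 0

    def test_additivity(self):
        scope = parse_quota_note("live").scope
        cell = aggregate_volumes([trec(qty=100), trec(qty=50)], scope, self.KEY)
        assert cell.exporter_volume == 150

    def test_reporters_summed_independently(self):
        scope = parse_quota_note("live").scope
        records = [trec(qty=100), trec(qty=70, reporter="importer_reported")]
        cell = aggregate_volumes(records, scope, self.KEY)
        assert (cell.exporter_volume, cell.importer_volume) == (100, 70)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["live", "skins", "meat"]),
                st.sampled_from(["wild", "captive", "ranched"]),
                st.sampled_from(["commercial", "hunting"]),
                st.integers(0, 500),
                st.sampled_from(["exporter_reported", "importer_reported"]),
            ),
            max_size=30,
        ),
        st.sampled_from(["live", "all, live", "all", "live, ranched", "skins"]),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_per_record_oracle(self, specs, note):
        """Aggregation equals a naive per-record loop for random scopes."""
        scope = parse_quota_note(note).scope
        records = [trec(term=t, source=s, purpose=p, qty=q, reporter=r) for t, s, p, q, r in specs]
        cell = aggregate_volumes(records, scope, self.KEY)
        exp = sum(
            q for t, s, p, q, r in specs
            if r == "exporter_reported"
            and (scope.terms == ALL or t in scope.terms)
            and (scope.sources == ALL or s in scope.sources)
            and (scope.purposes == ALL or p in scope.purposes)
        )
        imp = sum(
            q for t, s, p, q, r in specs
            if r == "importer_reported"
            and (scope.terms == ALL or t in scope.terms)
            and (scope.sources == ALL or s in scope.sources)
            and (scope.purposes == ALL or p in scope.purposes)
        )
        assert (cell.exporter_volume, cell.importer_volume) == (exp, imp)

    def test_monotone_in_scope_widening(self):
        records = [trec(source="wild", qty=10), trec(source="captive", qty=20), trec(term="skins", qty=40)]
        narrow = parse_quota_note("live").scope
        wider = parse_quota_note("all, live").scope
        widest = parse_quota_note("all").scope
        vols = [aggregate_volumes(records, s, self.KEY).exporter_volume for s in (narrow, wider, widest)]
        assert vols == sorted(vols)


class TestMalaysiaSumming:
    def test_three_regions_summed(self):
        quotas = [
            quota(id=f"q{i}", party="MY", amount=a, note=f"live ({r})")
            for i, (a, r) in enumerate([(10, "Sabah"), (20, "Sarawak"), (30, "Peninsular Malaysia")])
        ]
        out = sum_malaysian_regions(quotas)
        assert len(out) == 1
        assert out[0].amount == 60
        assert "region_summed" in out[0].provenance_flags
        assert out[0].region is None

    def test_national_quota_unchanged(self):
        q = quota()
        assert sum_malaysian_regions([q]) == [q]

    def test_two_of_three_regions_summed(self):
        quotas = [
            quota(id="q0", party="MY", amount=10, note="live (Sabah)"),
            quota(id="q1", party="MY", amount=20, note="live (Sarawak)"),
        ]
        out = sum_malaysian_regions(quotas)
        assert len(out) == 1 and out[0].amount == 30


class TestOverlapRemoval:
    def test_intersecting_scopes_both_removed(self):
        a = quota(id="qa", note="live")
        b = quota(id="qb", note="all, live", amount=500)
        audit = []
        assert remove_overlapping_quotas([a, b], audit=audit) == []
        assert {d["id"] for d in audit} == {"qa", "qb"}

    def test_disjoint_scopes_kept(self):
        a = quota(id="qa", note="live")
        b = quota(id="qb", note="skins")
        assert len(remove_overlapping_quotas([a, b])) == 2

    def test_different_years_not_overlapping(self):
        a = quota(id="qa", year=2005)
        b = quota(id="qb", year=2006)
        assert len(remove_overlapping_quotas([a, b])) == 2


class TestMixedTermExclusion:
    def test_live_with_skins_quota_excluded(self):
        live = quota(id="qa", note="live", year=2005)
        skins = quota(id="qb", note="skins", year=2006)
        out = exclude_mixed_term_species([live], all_quotas=[live, skins])
        assert out == []

    def test_pure_live_species_kept(self):
        live = quota(id="qa", note="live")
        assert exclude_mixed_term_species([live], all_quotas=[live]) == [live]

    def test_config_override(self):
        live = quota(id="qa", note="live")
        out = exclude_mixed_term_species([live], override_exclude=[("ID", "Genus01 species001")])
        assert out == []
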