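"""Percent-use arithmetic, breach flags and compliance summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quotawatch.compliance import (
    ComplianceResult,
    discrepancy_table,
    evaluate_quota,
    percent_use,
    round_half_up,
    summarize_compliance,
)
from quotawatch.ingest import QuotaRecord, parse_quota_note
from quotawatch.ledger import VolumeCell


def result(amount=100, exp=50, imp=None, quota_id="q1", party="GH", taxon="Genus01 species001", year=2009):
    return ComplianceResult(
        quota_id=quota_id, party=party, taxon=taxon, year=year,
        amount=amount, exporter_volume=exp, importer_volume=imp if imp is not None else exp,
    )


class TestPercentUse:
    def test_headline_one_decimal(self):
        assert percent_use(696, 63) == 1104.8

    @pytest.mark.parametrize("volume, amount, pct", [(1320, 200, 660), (0, 340, 0), (140, 200, 70)])
    def test_table_integer_rounding(self, volume, amount, pct):
        assert percent_use(volume, amount, ndigits=0) == pct

    def test_zero_quota_undefined(self):
        assert percent_use(5, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            percent_use(-1, 10)

    def test_half_up_not_bankers(self):
        assert round_half_up(0.5) == 1.0
        assert round_half_up(2.5) == 3.0
        assert percent_use(125, 1000, 0) == 13  # 12.5 rounds up

    @given(st.integers(0, 10_000), st.integers(1, 10_000), st.integers(1, 20))
    @settings(max_examples=100, deadline=None)
    def test_scale_equivariant(self, volume, amount, k):
        assert percent_use(volume, amount, ndigits=None) == pytest.approx(
            percent_use(k * volume, k * amount, ndigits=None)
        )


class TestEvaluateQuota:
    def _pair(self, amount, exp, imp):
        q = QuotaRecord(
            id="q1", party="GH", year=2009, taxon="Genus01 species001", rank="species",
            amount=amount, scope=parse_quota_note("live").scope,
        )
        cell = VolumeCell(taxon=q.taxon, exporter=q.party, year=q.year, scope=q.scope,
                          exporter_volume=exp, importer_volume=imp)
        return q, cell

    def test_importer_only_breach(self):
        r = evaluate_quota(*self._pair(200, 140, 1320))
        assert not r.breach_exporter
        assert r.breach_importer_only

    def test_zero_quota_subversion_importer_side(self):
        r = evaluate_quota(*self._pair(0, 0, 21))
        assert r.zero_breach
        assert r.pct_use_exporter is None

    def test_exact_use_is_compliant(self):
        r = evaluate_quota(*self._pair(100, 100, 100))
        assert not r.breach_exporter and not r.breach_importer_only and not r.zero_breach

    def test_key_mismatch_rejected(self):
        q, cell = self._pair(100, 10, 10)
        bad = VolumeCell(taxon="Other species", exporter="GH", year=2009, scope=q.scope)
        with pytest.raises(ValueError):
            evaluate_quota(q, bad)


class TestSummarize:
    def test_zero_quota_compliance_rate(self):
        results = [result(amount=0, exp=1 if i < 6 else 0, imp=1 if i < 6 else 0) for i in range(134)]
        s = summarize_compliance(results)
        assert s.n_zero_quotas == 134 and s.n_zero_breaches == 6
        assert s.zero_compliance_pct == 95.5

    def test_all_untraded(self):
        results = [result(exp=0) for _ in range(5)]
        s = summarize_compliance(results)
        assert s.mean_pct_use_all == 0.0
        assert s.mean_pct_use_traded is None

    def test_mean_use_ordering_with_zero_trade(self):
        results = [result(exp=0), result(exp=80), result(exp=40)]
        s = summarize_compliance(results)
        assert s.mean_pct_use_traded >= s.mean_pct_use_all

    def test_party_tallies_sum_to_global(self):
        results = [
            result(party="MG", amount=100, exp=150),
            result(party="MG", amount=100, exp=50),
            result(party="GH", amount=100, exp=200),
        ]
        s = summarize_compliance(results)
        assert sum(p["n_breaches"] for p in s.per_party.values()) == s.n_nonzero_breaches == 2


class TestDiscrepancyTable:
    def test_ranked_by_importer_pct_with_zero_quotas_first(self):
        results = [
            result(quota_id="a", amount=200, exp=130, imp=960),   # 480%
            result(quota_id="b", amount=200, exp=200, imp=770),   # 385%
            result(quota_id="c", amount=0, exp=0, imp=21),        # zero quota, "-"
            result(quota_id="d", amount=100, exp=150, imp=200),   # exporter breach: excluded
        ]
        df = discrepancy_table(results)
        assert list(df["importer_volume"]) == [21, 960, 770]
        assert list(df["importer_pct"])[1:] == [480, 385]
        assert df["importer_pct"].iloc[0] is None or df["importer_pct"].isna().iloc[0]

    def test_empty_when_no_importer_breaches(self):
        assert discrepancy_table([result(amount=100, exp=50, imp=50)]).empty

    def test_tie_broken_by_absolute_excess(self):
        results = [
            result(quota_id="small", amount=100, exp=90, imp=200),   # 200%, excess 100
            result(quota_id="big", amount=1000, exp=900, imp=2000),  # 200%, excess 1000
        ]
        df = discrepancy_table(results)
        assert list(df["quota"]) == [1000, 100]
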