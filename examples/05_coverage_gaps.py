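"""Quantify live wild-sourced trade occurring outside any quota.

A shipment is managed when a quota of its exporter covers its taxon,
year and scope; everything else is unmanaged.  Unmanaged volumes are
crossed with the IUCN category in force at the time of trade.
"""

from quotawatch import (
    QuotaRecord,
    ThreatRecord,
    ThreatTable,
    TradeRecord,
    gap_trends,
    parse_quota_note,
    split_managed,
)

scope = parse_quota_note("live").scope
quotas = [QuotaRecord(id=f"q{y}", party="ID", year=y, taxon="Python reticulatus",
                      rank="species", amount=1000, scope=scope) for y in (2014, 2015, 2016)]


def ship(taxon, year, qty, exporter="ID"):
    return TradeRecord(year=year, taxon=taxon, exporter=exporter, importer="US",
                       term="live", source="wild", purpose="commercial",
                       quantity=qty, unit="", reporter="exporter_reported")


trade = [
    ship("Python reticulatus", 2014, 800),   # covered by a quota
    ship("Python reticulatus", 2012, 600),   # before the first quota
    ship("Macrochelys temminckii", 2017, 30000, exporter="US"),  # never under quota
]
managed, unmanaged = split_managed(trade, quotas)
print(f"managed: {len(managed)} shipments, unmanaged: {len(unmanaged)}")

threats = ThreatTable([
    ThreatRecord("Python reticulatus", ((2000, "LC"),), False),
    ThreatRecord("Macrochelys temminckii", ((2000, "VU"),), True),
])
cells, summary = gap_trends(unmanaged, threats, era_split=2016)
for c in cells:
    print(f"{c.year} {c.category}: {c.volume} individuals "
          f"({c.n_species_exporter_combos} species-exporter combos)")
# The turtle shipment counts under both the globally-threatened and the
# trade-threatened categories; categories are deliberately non-exclusive.
print("\nera totals:", {era: {k: v["volume"] for k, v in cats.items() if v["volume"]}
                        for era, cats in summary["eras"].items()})
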