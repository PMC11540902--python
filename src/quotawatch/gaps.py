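"""Coverage gaps: live wild-sourced trade occurring outside any quota.

A shipment is "managed" when its exporter published, for that taxon and
year, a quota whose scope covers the shipment's term, source and
purpose; everything else is unmanaged trade.  Unmanaged volumes are
crossed with the species' IUCN Red List category *at the time of trade*
(the latest assessment preceding the trade year) and with a binary flag
for species likely threatened by international trade, yielding yearly
and era-level gap summaries.
"""

from __future__ import annotations

import csv
import json
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .ingest import QuotaRecord
from .ledger import TradeRecord

__all__ = [
    "ThreatRecord",
    "ThreatTable",
    "GapCell",
    "CATEGORIES",
    "split_managed",
    "unmanaged_trade",
    "gap_trends",
    "read_threat_csv",
]

IUCN_CATEGORIES = ("NE", "DD", "LC", "NT", "VU", "EN", "CR", "EW", "EX")
THREATENED = frozenset({"VU", "EN", "CR"})
CATEGORIES = ("dd_or_ne", "globally_threatened", "trade_threatened")


@dataclass(frozen=True)
class ThreatRecord:
    """A species' assessment timeline and trade-threat flag."""

    taxon: str
    iucn_timeline: tuple[tuple[int, str], ...]  # (year_from, category), year-ordered
    trade_threat_flag: bool

    def category_at(self, year: int) -> str:
        """Category in force at a trade year; NE before any assessment."""
        cat = "NE"
        for year_from, c in self.iucn_timeline:
            if year_from <= year:
                cat = c
            else:
                break
        return cat


class ThreatTable:
    """Lookup over ThreatRecords with NE fallback for unknown taxa."""

    def __init__(self, records: Sequence[ThreatRecord]):
        self._by_taxon = {r.taxon: r for r in records}
        self.warnings: list[str] = []

    def category_at(self, taxon: str, year: int) -> str:
        rec = self._by_taxon.get(taxon)
        if rec is None:
            self.warnings.append(f"taxon missing from threat table: {taxon}")
            return "NE"
        return rec.category_at(year)

    def trade_threatened(self, taxon: str) -> bool:
        rec = self._by_taxon.get(taxon)
        return bool(rec and rec.trade_threat_flag)


@dataclass(frozen=True)
class GapCell:
    """Unmanaged trade in one year for one concern category."""

    year: int
    category: str
    n_species_exporter_combos: int
    volume: int


def split_managed(
    trade: Sequence[TradeRecord],
    quotas: Sequence[QuotaRecord],
    include_higher_ranks: bool = False,
) -> tuple[list[TradeRecord], list[TradeRecord]]:
    """Partition trade records into (managed, unmanaged).

    ``trade`` should already be filtered to live, wild-sourced, direct,
    count-unit records.  Genus- and family-level quotas are ignored by
    default (species-level matching only).
    """
    by_key: dict[tuple[str, str, int], list[QuotaRecord]] = defaultdict(list)
    for q in quotas:
        if not include_higher_ranks and q.rank not in ("species", "subspecies"):
            continue
        by_key[(q.taxon, q.party, q.year)].append(q)
    managed, unmanaged = [], []
    for r in trade:
        candidates = by_key.get((r.taxon, r.exporter, r.year), ())
        if any(q.scope.covers(r.term, r.source, r.purpose) for q in candidates):
            managed.append(r)
        else:
            unmanaged.append(r)
    return managed, unmanaged


def unmanaged_trade(
    trade: Sequence[TradeRecord],
    quotas: Sequence[QuotaRecord],
    include_higher_ranks: bool = False,
) -> list[TradeRecord]:
    """Trade records not covered by any quota (see :func:`split_managed`)."""
    return split_managed(trade, quotas, include_higher_ranks)[1]


def _record_categories(r: TradeRecord, threats: ThreatTable) -> list[str]:
    """Concern categories a record contributes to (non-exclusive)."""
    cats = []
    iucn = threats.category_at(r.taxon, r.year)
    if iucn in ("DD", "NE"):
        cats.append("dd_or_ne")
    if iucn in THREATENED:
        cats.append("globally_threatened")
    if threats.trade_threatened(r.taxon):
        cats.append("trade_threatened")
    return cats


def gap_trends(
    unmanaged: Sequence[TradeRecord],
    threats: ThreatTable,
    era_split: int = 2016,
    reporter: str = "exporter_reported",
) -> tuple[list[GapCell], dict]:
    """Yearly gap cells and era-level summaries of unmanaged trade.

    Categories are non-exclusive: a critically endangered species also
    flagged as trade-threatened contributes to both.  Era summaries
    report volume, unique species-exporter combinations per era, and the
    sum of yearly combination counts (both countings).
    """
    records = [r for r in unmanaged if r.reporter == reporter]
    vol: dict[tuple[int, str], int] = defaultdict(int)
    combos: dict[tuple[int, str], set] = defaultdict(set)
    for r in records:
        for cat in _record_categories(r, threats):
            vol[(r.year, cat)] += int(r.quantity)
            combos[(r.year, cat)].add((r.taxon, r.exporter))

    cells = [
        GapCell(year=year, category=cat, n_species_exporter_combos=len(combos[(year, cat)]), volume=vol[(year, cat)])
        for (year, cat) in sorted(vol)
    ]

    eras: dict[str, dict] = {}
    for era_name, pred in (
        ("pre", lambda y: y < era_split),
        ("post", lambda y: y >= era_split),
    ):
        era: dict[str, dict] = {}
        for cat in CATEGORIES:
            cat_cells = [c for c in cells if c.category == cat and pred(c.year)]
            unique = set()
            species = set()
            exporters = set()
            for (year, c2), combo_set in combos.items():
                if c2 == cat and pred(year):
                    unique |= combo_set
            species = {t for t, _ in unique}
            exporters = {e for _, e in unique}
            era[cat] = {
                "volume": sum(c.volume for c in cat_cells),
                "combos_unique": len(unique),
                "combos_year_sum": sum(c.n_species_exporter_combos for c in cat_cells),
                "n_species": len(species),
                "n_exporters": len(exporters),
            }
        eras[era_name] = era
    summary = {"era_split": era_split, "eras": eras}
    return cells, summary


def read_threat_csv(path: str | Path) -> ThreatTable:
    """Read a threat table CSV (taxon, year_from, category, trade_threat_flag)."""
    timelines: dict[str, list[tuple[int, str]]] = defaultdict(list)
    flags: dict[str, bool] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            taxon = rec["taxon"].strip()
            timelines[taxon].append((int(rec["year_from"]), rec["category"].strip().upper()))
            flags[taxon] = str(rec.get("trade_threat_flag", "0")).strip().lower() in ("1", "true", "yes")
    records = [
        ThreatRecord(taxon=t, iucn_timeline=tuple(sorted(tl)), trade_threat_flag=flags[t])
        for t, tl in timelines.items()
    ]
    return ThreatTable(records)


def write_gap_outputs(cells: Sequence[GapCell], summary: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"year": c.year, "category": c.category, "n_combos": c.n_species_exporter_combos, "volume": c.volume}
            for c in cells
        ]
    ).to_csv(outdir / "gap_cells.csv", index=False)
    with open(outdir / "gap_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
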