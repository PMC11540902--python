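"""Trade-ledger handling: filtering, volume aggregation, quota matching prep.

Trade ledgers (CITES Trade Database comparative-tabulation dialect)
record shipments twice — once as reported by the exporting party and
once by the importer.  Compliance analysis needs both perspectives,
restricted to direct exports of live animals counted as individuals.
This module also hosts the quota-side preparation steps that depend on
trade semantics: summing Malaysia's regional quotas to national ones,
removing quotas whose scopes overlap for the same party/taxon/year, and
excluding species whose live quota coexists with quotas under other
terms (where live animals may move under e.g. a skins quota).
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .ingest import ALL, QuotaRecord, QuotaScope

__all__ = [
    "TradeRecord",
    "VolumeCell",
    "filter_live_direct",
    "aggregate_volumes",
    "sum_malaysian_regions",
    "remove_overlapping_quotas",
    "exclude_mixed_term_species",
    "read_trade_csv",
    "write_volume_cells",
]

Reporter = Literal["exporter_reported", "importer_reported"]

_COUNT_UNITS = {"", "specimens", "number of specimens"}


@dataclass(frozen=True)
class TradeRecord:
    """One directional shipment report (one reporter's view)."""

    year: int
    taxon: str
    exporter: str
    importer: str | None
    term: str
    source: str
    purpose: str
    quantity: float
    unit: str
    reporter: Reporter
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.quantity < 0:
            raise ValueError("quantity must be non-negative")


@dataclass(frozen=True)
class VolumeCell:
    """Traded volume for one quota key, split by reporter perspective."""

    taxon: str
    exporter: str
    year: int
    scope: QuotaScope
    exporter_volume: int = 0
    importer_volume: int = 0


def filter_live_direct(records: Sequence[TradeRecord]) -> list[TradeRecord]:
    """Keep direct exports of live animals counted as individuals.

    Direct means the stated origin is missing or equals the exporter
    (re-exports are removed); the unit must denote a count of specimens
    (blank or "specimens"), not a weight.
    """
    out = []
    for r in records:
        if r.term != "live":
            continue
        if r.unit.strip().lower() not in _COUNT_UNITS:
            continue
        if r.origin is not None and r.origin != r.exporter:
            continue
        out.append(r)
    return out


def aggregate_volumes(
    records: Iterable[TradeRecord],
    scope: QuotaScope,
    key: tuple[str, str, int],
) -> VolumeCell:
    """Sum reporter-specific quantities of the records falling in scope.

    ``key`` is (taxon, exporter, year); records are assumed pre-filtered
    to that key.  Exporter- and importer-reported sums are independent:
    they are two views of the same shipments, not double counting.
    """
    taxon, exporter, year = key
    exp = 0.0
    imp = 0.0
    for r in records:
        if not scope.covers(r.term, r.source, r.purpose):
            continue
        if r.reporter == "exporter_reported":
            exp += r.quantity
        else:
            imp += r.quantity
    return VolumeCell(
        taxon=taxon,
        exporter=exporter,
        year=year,
        scope=scope,
        exporter_volume=int(round(exp)),
        importer_volume=int(round(imp)),
    )


def sum_malaysian_regions(quotas: Sequence[QuotaRecord]) -> list[QuotaRecord]:
    """Collapse regionally specified quotas into one national quota.

    Quotas carrying a region tag (Sabah, Sarawak, Peninsular Malaysia)
    for the same (party, taxon, year, scope) are summed, because trade
    ledgers record only the national exporter.  The merged record is
    flagged ``region_summed``.
    """
    groups: dict[tuple, list[QuotaRecord]] = defaultdict(list)
    out: list[QuotaRecord] = []
    for q in quotas:
        if q.region is not None:
            groups[q.key()].append(q)
        else:
            out.append(q)
    for _, members in groups.items():
        members = sorted(members, key=lambda q: q.id)
        head = members[0]
        merged = replace(
            head,
            amount=sum(m.amount for m in members),
            region=None,
            provenance_flags=head.provenance_flags | {"region_summed"},
        )
        out.append(merged)
    out.sort(key=lambda q: q.id)
    return out


def remove_overlapping_quotas(
    quotas: Sequence[QuotaRecord],
    audit: list[dict] | None = None,
) -> list[QuotaRecord]:
    """Drop every member of a scope-overlapping quota set.

    Where one party published, for the same taxon and year, two quotas
    whose scopes intersect (e.g. live wild-sourced and live from all
    sources), the traded volume cannot be attributed to either quota, so
    the whole overlapping set is removed.
    """
    groups: dict[tuple, list[QuotaRecord]] = defaultdict(list)
    for q in quotas:
        groups[(q.party, q.taxon, q.year)].append(q)
    out: list[QuotaRecord] = []
    for _, members in groups.items():
        overlapping: set[str] = set()
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a.scope.intersects(b.scope):
                    overlapping.add(a.id)
                    overlapping.add(b.id)
        for q in members:
            if q.id in overlapping:
                if audit is not None:
                    audit.append(
                        {"id": q.id, "party": q.party, "taxon": q.taxon, "year": q.year, "reason": "overlapping_scope"}
                    )
            else:
                out.append(q)
    out.sort(key=lambda q: q.id)
    return out


def exclude_mixed_term_species(
    quotas: Sequence[QuotaRecord],
    all_quotas: Sequence[QuotaRecord] | None = None,
    override_exclude: Iterable[tuple[str, str]] = (),
    audit: list[dict] | None = None,
) -> list[QuotaRecord]:
    """Drop live quotas of species that also hold quotas under other terms.

    Where a (party, taxon) pairs a live quota with e.g. a skins or
    consumption quota, live animals may lawfully move under the other
    quota, so live-quota compliance cannot be assessed.  ``all_quotas``
    defaults to ``quotas``; ``override_exclude`` adds (party, taxon)
    pairs excluded by configuration.
    """
    pool = all_quotas if all_quotas is not None else quotas
    mixed: set[tuple[str, str]] = set(override_exclude)
    by_pair: dict[tuple[str, str], set[str]] = defaultdict(set)
    for q in pool:
        terms = "ALL" if q.scope.terms == ALL else "|".join(sorted(q.scope.terms))
        by_pair[(q.party, q.taxon)].add(terms)
    for pair, term_keys in by_pair.items():
        non_live = {t for t in term_keys if t not in ("live", "ALL")}
        if non_live and any(t in ("live", "ALL") or "live" in t.split("|") for t in term_keys):
            mixed.add(pair)
    out = []
    for q in quotas:
        if (q.party, q.taxon) in mixed:
            if audit is not None:
                audit.append(
                    {"id": q.id, "party": q.party, "taxon": q.taxon, "year": q.year, "reason": "mixed_term_species"}
                )
        else:
            out.append(q)
    return out


# ---------------------------------------------------------------------------
# I/O


_DEFAULT_HEADERS = {
    "year": "Year",
    "taxon": "Taxon",
    "term": "Term",
    "unit": "Unit",
    "importer": "Importer",
    "exporter": "Exporter",
    "origin": "Origin",
    "purpose": "Purpose",
    "source": "Source",
    "exporter_qty": "Exporter reported quantity",
    "importer_qty": "Importer reported quantity",
}


def read_trade_csv(
    path: str | Path,
    header_map: dict[str, str] | None = None,
    warn: list[str] | None = None,
) -> list[TradeRecord]:
    """Read a comparative-tabulation trade CSV into TradeRecords.

    Each CSV row yields up to two records, one per reporter column with
    a non-missing quantity.  Fractional counts are rounded to integers
    with a warning.
    """
    hm = dict(_DEFAULT_HEADERS)
    if header_map:
        hm.update(header_map)
    records: list[TradeRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            base = dict(
                year=int(rec[hm["year"]]),
                taxon=rec[hm["taxon"]].strip(),
                exporter=rec[hm["exporter"]].strip(),
                importer=(rec.get(hm["importer"]) or "").strip() or None,
                term=rec[hm["term"]].strip().lower(),
                source=(rec.get(hm["source"]) or "wild").strip().lower(),
                purpose=(rec.get(hm["purpose"]) or "commercial").strip().lower(),
                unit=(rec.get(hm["unit"]) or "").strip(),
                origin=(rec.get(hm["origin"]) or "").strip() or None,
            )
            for col, reporter in ((hm["exporter_qty"], "exporter_reported"), (hm["importer_qty"], "importer_reported")):
                raw = (rec.get(col) or "").strip()
                if not raw:
                    continue
                qty = float(raw)
                if qty != int(qty) and warn is not None:
                    warn.append(f"fractional count rounded: {qty} ({base['taxon']} {base['year']})")
                records.append(TradeRecord(quantity=float(round(qty)), reporter=reporter, **base))
    return records


def write_volume_cells(cells: Iterable[VolumeCell], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "exporter", "year", "scope", "exporter_volume", "importer_volume"])
        for c in cells:
            w.writerow([c.taxon, c.exporter, c.year, c.scope.canonical(), c.exporter_volume, c.importer_volume])
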