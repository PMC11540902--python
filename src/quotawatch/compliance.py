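"""Compliance statistics: percent-of-quota use, breaches and discrepancies.

A quota is breached when reported trade strictly exceeds the quota
amount; trading exactly the quota is compliant.  Zero quotas (bans) are
subverted by any reported trade.  Because exporters and importers report
the same shipments independently, a quota can look compliant from the
exporter's side while the importer's figures breach it — these
importer-only breaches are tabulated separately, ranked by severity.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ingest import QuotaRecord
from .ledger import VolumeCell

__all__ = [
    "ComplianceResult",
    "ComplianceSummary",
    "round_half_up",
    "percent_use",
    "evaluate_quota",
    "summarize_compliance",
    "discrepancy_table",
    "write_compliance_csv",
    "write_summary_json",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.5 -> 1), as in printed tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_use(volume: float, amount: float, ndigits: int | None = 1) -> float | None:
    """Traded volume as a percentage of the quota amount.

    Returns None (undefined) for zero quotas.  ``ndigits=1`` gives the
    headline one-decimal form, ``ndigits=0`` the integer table form,
    ``ndigits=None`` the exact value.  Half-up rounding throughout.
    """
    if volume < 0 or amount < 0:
        raise ValueError("volume and amount must be non-negative")
    if amount == 0:
        return None
    pct = 100.0 * volume / amount
    return pct if ndigits is None else round_half_up(pct, ndigits)


@dataclass(frozen=True)
class ComplianceResult:
    """One quota matched against both reporter perspectives."""

    quota_id: str
    party: str
    taxon: str
    year: int
    amount: int
    exporter_volume: int
    importer_volume: int

    @property
    def pct_use_exporter(self) -> float | None:
        return percent_use(self.exporter_volume, self.amount, ndigits=None)

    @property
    def pct_use_importer(self) -> float | None:
        return percent_use(self.importer_volume, self.amount, ndigits=None)

    @property
    def zero_breach(self) -> bool:
        return self.amount == 0 and (self.exporter_volume > 0 or self.importer_volume > 0)

    @property
    def breach_exporter(self) -> bool:
        return self.amount > 0 and self.exporter_volume > self.amount

    @property
    def breach_importer_only(self) -> bool:
        return not self.breach_exporter and self.amount > 0 and self.importer_volume > self.amount


def evaluate_quota(quota: QuotaRecord, cell: VolumeCell) -> ComplianceResult:
    """Match a quota to its volume cell and flag breaches.

    The cell must carry the quota's (taxon, exporter, year) key; both
    reporter perspectives are evaluated.
    """
    if (cell.taxon, cell.exporter, cell.year) != (quota.taxon, quota.party, quota.year):
        raise ValueError(
            f"volume cell key {(cell.taxon, cell.exporter, cell.year)} does not match "
            f"quota {(quota.taxon, quota.party, quota.year)}"
        )
    return ComplianceResult(
        quota_id=quota.id,
        party=quota.party,
        taxon=quota.taxon,
        year=quota.year,
        amount=quota.amount,
        exporter_volume=cell.exporter_volume,
        importer_volume=cell.importer_volume,
    )


@dataclass
class ComplianceSummary:
    """Aggregate compliance statistics over a set of evaluated quotas."""

    n_zero_quotas: int
    n_zero_breaches: int
    n_nonzero_quotas: int
    n_nonzero_breaches: int
    n_untraded_nonzero: int
    mean_pct_use_all: float | None
    mean_pct_use_traded: float | None
    per_party: dict[str, dict] = field(default_factory=dict)

    @property
    def zero_compliance_pct(self) -> float | None:
        """Percent of zero quotas complied with, one decimal."""
        if self.n_zero_quotas == 0:
            return None
        return round_half_up(100.0 * (self.n_zero_quotas - self.n_zero_breaches) / self.n_zero_quotas, 1)

    @property
    def nonzero_breach_pct(self) -> float | None:
        if self.n_nonzero_quotas == 0:
            return None
        return round_half_up(100.0 * self.n_nonzero_breaches / self.n_nonzero_quotas, 1)

    def to_dict(self) -> dict:
        return {
            "n_zero_quotas": self.n_zero_quotas,
            "n_zero_breaches": self.n_zero_breaches,
            "zero_compliance_pct": self.zero_compliance_pct,
            "n_nonzero_quotas": self.n_nonzero_quotas,
            "n_nonzero_breaches": self.n_nonzero_breaches,
            "nonzero_breach_pct": self.nonzero_breach_pct,
            "n_untraded_nonzero": self.n_untraded_nonzero,
            "mean_pct_use_all": self.mean_pct_use_all,
            "mean_pct_use_traded": self.mean_pct_use_traded,
            "per_party": self.per_party,
        }


def summarize_compliance(results: Sequence[ComplianceResult]) -> ComplianceSummary:
    """Tally breaches and mean percent use (exporter perspective).

    ``mean_pct_use_all`` averages percent use over all non-zero quotas,
    counting untraded quotas as 0%; ``mean_pct_use_traded`` excludes
    quotas with no exporter-reported trade.  Undefined percents (zero
    quotas) are excluded from both means.
    """
    zero = [r for r in results if r.amount == 0]
    nonzero = [r for r in results if r.amount > 0]
    pcts = [r.pct_use_exporter for r in nonzero]
    traded_pcts = [p for r, p in zip(nonzero, pcts) if r.exporter_volume > 0]

    per_party: dict[str, dict] = defaultdict(lambda: {"n_quotas": 0, "n_breaches": 0, "n_zero_breaches": 0})
    for r in results:
        p = per_party[r.party]
        p["n_quotas"] += 1
        if r.breach_exporter:
            p["n_breaches"] += 1
        if r.zero_breach:
            p["n_zero_breaches"] += 1

    return ComplianceSummary(
        n_zero_quotas=len(zero),
        n_zero_breaches=sum(r.zero_breach for r in zero),
        n_nonzero_quotas=len(nonzero),
        n_nonzero_breaches=sum(r.breach_exporter for r in nonzero),
        n_untraded_nonzero=sum(r.exporter_volume == 0 for r in nonzero),
        mean_pct_use_all=round_half_up(sum(pcts) / len(pcts), 1) if pcts else None,
        mean_pct_use_traded=round_half_up(sum(traded_pcts) / len(traded_pcts), 1) if traded_pcts else None,
        per_party=dict(per_party),
    )


def discrepancy_table(results: Sequence[ComplianceResult]) -> pd.DataFrame:
    """Quotas compliant by exporter figures but breached by importer figures.

    Includes zero quotas with importer-only trade.  Rows are ranked with
    zero quotas first (by importer volume), then by importer percent use
    descending; ties break by absolute excess volume, then by key order.
    Percent columns use the integer table form ("-" for zero quotas).
    """
    rows = []
    for r in results:
        zero_imp_only = r.amount == 0 and r.importer_volume > 0 and r.exporter_volume == 0
        if not (r.breach_importer_only or zero_imp_only):
            continue
        pe = percent_use(r.exporter_volume, r.amount, ndigits=0)
        pi = percent_use(r.importer_volume, r.amount, ndigits=0)
        rows.append(
            {
                "taxon": r.taxon,
                "party": r.party,
                "year": r.year,
                "quota": r.amount,
                "exporter_volume": r.exporter_volume,
                "exporter_pct": pe,
                "importer_volume": r.importer_volume,
                "importer_pct": pi,
                "_excess": r.importer_volume - r.amount,
                "_rank_pct": float("inf") if pi is None else pi,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "taxon", "party", "year", "quota",
            "exporter_volume", "exporter_pct", "importer_volume", "importer_pct",
            "_excess", "_rank_pct",
        ],
    )
    if df.empty:
        return df.drop(columns=["_excess", "_rank_pct"])
    df = df.sort_values(
        by=["_rank_pct", "_excess", "taxon", "party", "year"],
        ascending=[False, False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df.drop(columns=["_excess", "_rank_pct"])


def write_compliance_csv(results: Iterable[ComplianceResult], path: str | Path) -> None:
    rows = []
    for r in results:
        rows.append(
            {
                "quota_id": r.quota_id,
                "party": r.party,
                "taxon": r.taxon,
                "year": r.year,
                "amount": r.amount,
                "exporter_volume": r.exporter_volume,
                "importer_volume": r.importer_volume,
                "pct_use_exporter": "" if r.pct_use_exporter is None else round_half_up(r.pct_use_exporter, 1),
                "pct_use_importer": "" if r.pct_use_importer is None else round_half_up(r.pct_use_importer, 1),
                "zero_breach": int(r.zero_breach),
                "breach_exporter": int(r.breach_exporter),
                "breach_importer_only": int(r.breach_importer_only),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary_json(summary: ComplianceSummary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
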