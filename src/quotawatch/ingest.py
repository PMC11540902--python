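"""Quota-table ingest: note parsing, deduplication and validity filters.

Raw quota tables (Species+ CSV dialect) carry one row per published
export quota: the issuing party, calendar year, taxon, and an amount,
with the scope of the quota (commodity term, specimen source, trade
purpose) buried in a free-text "notes" column.  This module parses the
notes into a structured :class:`QuotaScope` and applies the cleaning
chain: exact-duplicate removal, removal of back-dated quotas created by
taxonomic splits, subspecies resolution, and validity filters (sentinel
amounts, multi-year spans, re-export-only quotas).
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .vocab import Vocabulary, default_vocabulary, normalize_token

__all__ = [
    "ALL",
    "RawQuotaRow",
    "QuotaScope",
    "ParsedNote",
    "QuotaRecord",
    "SplitEvent",
    "CleanResult",
    "parse_quota_note",
    "deduplicate",
    "drop_backdated_split_quotas",
    "resolve_subspecies",
    "filter_invalid",
    "clean_quotas",
    "read_quota_csv",
    "write_quota_records",
    "write_audit_log",
]

ALL = "ALL"
"""Sentinel meaning a scope dimension is unconstrained."""

Rank = Literal["family", "genus", "species", "subspecies"]


@dataclass(frozen=True)
class RawQuotaRow:
    """One row of a raw quota table, prior to any cleaning."""

    party: str
    year: int
    taxon_name: str
    rank: str
    amount: int | None  # None = missing; -1 = sentinel for permit issues
    notes: str | None = None


@dataclass(frozen=True)
class QuotaScope:
    """Structured scope of a quota: which trade it covers.

    Each dimension is either the sentinel :data:`ALL` or a non-empty
    frozenset of canonical codes.  ``comparable`` is True iff all terms
    are mutually convertible to whole-animal counts.
    """

    terms: frozenset[str] | str = ALL
    sources: frozenset[str] | str = ALL
    purposes: frozenset[str] | str = ALL
    comparable: bool = True

    def __post_init__(self) -> None:
        for dim in ("terms", "sources", "purposes"):
            v = getattr(self, dim)
            if v != ALL:
                if not isinstance(v, frozenset):
                    object.__setattr__(self, dim, frozenset(v))
                if not getattr(self, dim):
                    raise ValueError(f"scope dimension {dim} must be non-empty or ALL")

    @staticmethod
    def _dim_covers(dim: frozenset[str] | str, code: str) -> bool:
        return dim == ALL or code in dim

    def covers(self, term: str, source: str, purpose: str) -> bool:
        """True iff a shipment with these codes falls inside this scope."""
        return (
            self._dim_covers(self.terms, term)
            and self._dim_covers(self.sources, source)
            and self._dim_covers(self.purposes, purpose)
        )

    @staticmethod
    def _dim_intersects(a: frozenset[str] | str, b: frozenset[str] | str) -> bool:
        if a == ALL or b == ALL:
            return True
        return bool(a & b)

    def intersects(self, other: "QuotaScope") -> bool:
        """True iff some (term, source, purpose) lies in both scopes."""
        return (
            self._dim_intersects(self.terms, other.terms)
            and self._dim_intersects(self.sources, other.sources)
            and self._dim_intersects(self.purposes, other.purposes)
        )

    @staticmethod
    def _dim_str(dim: frozenset[str] | str) -> str:
        return ALL if dim == ALL else "|".join(sorted(dim))

    def canonical(self) -> str:
        """Stable string form, usable as a grouping key."""
        return ";".join(
            (self._dim_str(self.terms), self._dim_str(self.sources), self._dim_str(self.purposes))
        )

    @classmethod
    def from_canonical(cls, text: str, vocab: Vocabulary | None = None) -> "QuotaScope":
        vocab = vocab or default_vocabulary()
        parts = text.split(";")
        if len(parts) != 3:
            raise ValueError(f"malformed canonical scope: {text!r}")
        dims = [ALL if p == ALL else frozenset(p.split("|")) for p in parts]
        terms = dims[0]
        comparable = True if terms == ALL else vocab.comparable(terms)
        return cls(terms=dims[0], sources=dims[1], purposes=dims[2], comparable=comparable)


@dataclass(frozen=True)
class ParsedNote:
    """Result of parsing one note: scope plus parse metadata."""

    scope: QuotaScope
    region: str | None = None
    unparsed: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class QuotaRecord:
    """A cleaned quota with parsed scope, ready for matching."""

    id: str
    party: str
    year: int
    taxon: str
    rank: str
    amount: int
    scope: QuotaScope
    region: str | None = None
    provenance_flags: frozenset[str] = frozenset()
    unparsed: tuple[str, ...] = ()

    @property
    def is_zero(self) -> bool:
        return self.amount == 0

    def key(self) -> tuple:
        return (self.party, self.year, self.taxon, self.scope.canonical())


@dataclass(frozen=True)
class SplitEvent:
    """A taxonomic split adopted at a given year.

    Quotas published for ``child_taxon`` before ``adoption_year`` that
    duplicate a quota of ``parent_taxon`` are back-dated artefacts of the
    split and are removed.
    """

    parent_taxon: str
    child_taxon: str
    adoption_year: int


# ---------------------------------------------------------------------------
# Note parsing


_PAREN = re.compile(r"\(([^)]*)\)")
_SPLITTER = re.compile(r",|;|\band\b")


def parse_quota_note(note: str | None, vocab: Vocabulary | None = None) -> ParsedNote:
    """Parse a free-text quota note into a structured scope.

    The grammar splits the note on commas/semicolons/"and", classifies
    each token against the controlled vocabulary, and applies the
    defaulting rules: a missing or blank note covers wild-sourced trade
    of any term for any purpose; a bare "all" covers everything; "all"
    paired with detail widens only the dimensions the detail leaves
    unconstrained.  Unrecognized tokens are preserved in ``unparsed``
    with a warning, never silently dropped.
    """
    vocab = vocab or default_vocabulary()

    terms: set[str] = set()
    sources: set[str] = set()
    purposes: set[str] = set()
    region: str | None = None
    unparsed: list[str] = []
    warnings: list[str] = []
    saw_all = False

    if note is not None and note.strip():
        text = note
        # Region tags are conventionally parenthesised; check both forms.
        for m in _PAREN.finditer(text):
            tok = normalize_token(m.group(1))
            if tok in vocab.regions:
                region = vocab.regions[tok]
        text = _PAREN.sub(",", text)
        for raw_tok in _SPLITTER.split(text):
            tok = normalize_token(raw_tok)
            if not tok:
                continue
            hit = vocab.classify(tok)
            if hit is None:
                unparsed.append(raw_tok.strip())
                warnings.append(f"unrecognized note token: {raw_tok.strip()!r}")
                continue
            dim, code = hit
            if dim == "all":
                saw_all = True
            elif dim == "term":
                terms.add(code)
            elif dim == "source":
                sources.add(code)
            elif dim == "purpose":
                purposes.add(code)
            elif dim == "region":
                region = code

    terms_out: frozenset[str] | str = frozenset(terms) if terms else ALL
    purposes_out: frozenset[str] | str = frozenset(purposes) if purposes else ALL
    if sources:
        sources_out: frozenset[str] | str = frozenset(sources)
    elif saw_all:
        # "all" alone or paired with non-source detail: all sources.
        sources_out = ALL
    else:
        # Unspecified source defaults to wild-taken trade.
        sources_out = frozenset({"wild"})

    comparable = True if terms_out == ALL else vocab.comparable(terms_out)
    scope = QuotaScope(terms=terms_out, sources=sources_out, purposes=purposes_out, comparable=comparable)
    return ParsedNote(scope=scope, region=region, unparsed=tuple(unparsed), warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Cleaning chain


def deduplicate(rows: Sequence[RawQuotaRow]) -> list[RawQuotaRow]:
    """Drop rows whose every field matches an earlier row (order-stable)."""
    seen: set[RawQuotaRow] = set()
    out: list[RawQuotaRow] = []
    for row in rows:
        if row not in seen:
            seen.add(row)
            out.append(row)
    return out


def drop_backdated_split_quotas(
    rows: Sequence[RawQuotaRow],
    split_events: Sequence[SplitEvent],
    warn: list[str] | None = None,
) -> list[RawQuotaRow]:
    """Remove child-taxon quotas back-dated before the split's adoption.

    A quota for a child taxon, set in a year before the split was
    adopted, that duplicates a parent-taxon quota (same party, year,
    amount and notes) is a record-keeping artefact: the child taxon did
    not exist at the time.  Pre-adoption child quotas with no matching
    parent quota are kept.
    """
    parent_index: dict[str, set[tuple]] = {}
    names = {r.taxon_name for r in rows}
    events = []
    for ev in split_events:
        if ev.parent_taxon not in names and ev.child_taxon not in names:
            if warn is not None:
                warn.append(f"split event names taxa absent from table: {ev.parent_taxon} -> {ev.child_taxon}")
            continue
        events.append(ev)
    for ev in events:
        parent_index.setdefault(ev.parent_taxon, set())
    for r in rows:
        if r.taxon_name in parent_index:
            parent_index[r.taxon_name].add((r.party, r.year, r.amount, r.notes))

    by_child = {ev.child_taxon: ev for ev in events}
    out = []
    for r in rows:
        ev = by_child.get(r.taxon_name)
        if ev is not None and r.year < ev.adoption_year:
            if (r.party, r.year, r.amount, r.notes) in parent_index.get(ev.parent_taxon, set()):
                continue  # back-dated duplicate of the parent quota
        out.append(r)
    return out


_TRINOMIAL = re.compile(r"^\s*(\S+)\s+(\S+)\s+\S+\s*$")


def resolve_subspecies(rows: Sequence[RawQuotaRow]) -> list[RawQuotaRow]:
    """Collapse trinomial names carried on species-rank rows to binomials."""
    out = []
    for r in rows:
        m = _TRINOMIAL.match(r.taxon_name) if r.rank == "species" else None
        if m:
            out.append(replace(r, taxon_name=f"{m.group(1)} {m.group(2)}"))
        else:
            out.append(r)
    return out


_MONTHS = (
    "january|february|march|april|may|june|july|august|september|october|november|december"
)
_MULTI_YEAR = re.compile(
    rf"(?:{_MONTHS})\s+(\d{{4}})\s+(?:to|through|until|-|–)\s*(?:{_MONTHS})\s+(\d{{4}})",
    re.IGNORECASE,
)
_REEXPORT = re.compile(r"\bre-?exports?\b", re.IGNORECASE)


def filter_invalid(
    rows: Sequence[RawQuotaRow],
) -> tuple[list[RawQuotaRow], list[tuple[RawQuotaRow, str]]]:
    """Partition rows into usable quotas and removed rows with reasons.

    Removal reasons: ``sentinel_amount`` (amount −1 or missing, used for
    unverifiable permit issues), ``multi_year_span`` (the note names a
    month-to-month span crossing calendar years) and ``reexport_only``.
    """
    kept: list[RawQuotaRow] = []
    removed: list[tuple[RawQuotaRow, str]] = []
    for r in rows:
        note = r.notes or ""
        m = _MULTI_YEAR.search(note)
        if r.amount is None or r.amount < 0:
            removed.append((r, "sentinel_amount"))
        elif m and m.group(1) != m.group(2):
            removed.append((r, "multi_year_span"))
        elif _REEXPORT.search(note):
            removed.append((r, "reexport_only"))
        else:
            kept.append(r)
    return kept, removed


@dataclass
class CleanResult:
    """Outcome of the full cleaning chain, with per-stage audit."""

    records: list[QuotaRecord]
    removed: dict[str, list[dict]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    stage_counts: dict[str, int] = field(default_factory=dict)


def _row_dict(r: RawQuotaRow) -> dict:
    return {
        "party": r.party,
        "year": r.year,
        "taxon": r.taxon_name,
        "rank": r.rank,
        "amount": r.amount,
        "notes": r.notes,
    }


def clean_quotas(
    rows: Sequence[RawQuotaRow],
    split_events: Sequence[SplitEvent] = (),
    vocab: Vocabulary | None = None,
) -> CleanResult:
    """Run the full cleaning chain and parse notes into QuotaRecords.

    Stages, in order: exact-duplicate removal, back-dated split-quota
    removal, subspecies resolution, validity filtering, note parsing.
    The chain is idempotent and every removal is recorded with a reason.
    """
    vocab = vocab or default_vocabulary()
    result = CleanResult(records=[])
    result.stage_counts["input"] = len(rows)

    deduped = deduplicate(rows)
    dropped = len(rows) - len(deduped)
    result.removed["duplicate"] = []
    seen_counts: dict[RawQuotaRow, int] = {}
    for r in rows:
        seen_counts[r] = seen_counts.get(r, 0) + 1
    for r, n in seen_counts.items():
        for _ in range(n - 1):
            result.removed["duplicate"].append(_row_dict(r))
    assert len(result.removed["duplicate"]) == dropped
    result.stage_counts["after_dedup"] = len(deduped)

    warn: list[str] = []
    unsplit = drop_backdated_split_quotas(deduped, split_events, warn=warn)
    result.warnings.extend(warn)
    split_removed = [r for r in deduped if r not in set(unsplit)]
    # rows are hashable and unique post-dedup, so set subtraction is exact
    result.removed["backdated_split"] = [_row_dict(r) for r in split_removed]
    result.stage_counts["after_splits"] = len(unsplit)

    resolved = resolve_subspecies(unsplit)
    resolved_flags = {id(new) for old, new in zip(unsplit, resolved) if old.taxon_name != new.taxon_name}
    result.stage_counts["after_subspecies"] = len(resolved)

    kept, invalid = filter_invalid(resolved)
    result.removed["invalid"] = [dict(_row_dict(r), reason=reason) for r, reason in invalid]
    result.stage_counts["after_invalid"] = len(kept)

    records = []
    for i, r in enumerate(kept):
        parsed = parse_quota_note(r.notes, vocab)
        result.warnings.extend(f"{r.party}/{r.taxon_name}/{r.year}: {w}" for w in parsed.warnings)
        flags = set()
        if id(r) in resolved_flags:
            flags.add("subspecies_resolved")
        records.append(
            QuotaRecord(
                id=f"q{i:06d}",
                party=r.party,
                year=r.year,
                taxon=r.taxon_name,
                rank=r.rank,
                amount=int(r.amount),  # type: ignore[arg-type]
                scope=parsed.scope,
                region=parsed.region,
                provenance_flags=frozenset(flags),
                unparsed=parsed.unparsed,
            )
        )
    result.records = records
    result.stage_counts["output"] = len(records)
    return result


# ---------------------------------------------------------------------------
# I/O


_DEFAULT_HEADERS = {
    "party": "party",
    "year": "year",
    "taxon": "taxon",
    "rank": "rank",
    "quota": "quota",
    "notes": "notes",
}


def read_quota_csv(path: str | Path, header_map: dict[str, str] | None = None) -> list[RawQuotaRow]:
    """Read a Species+-style quota CSV into RawQuotaRows.

    ``header_map`` maps the logical names (party, year, taxon, rank,
    quota, notes) to the file's actual column headers.
    """
    hm = dict(_DEFAULT_HEADERS)
    if header_map:
        hm.update(header_map)
    rows: list[RawQuotaRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for rec in csv.DictReader(fh):
            raw_amount = (rec.get(hm["quota"]) or "").strip()
            amount: int | None
            if raw_amount in ("", "NA", "na", "NaN"):
                amount = None
            else:
                amount = int(float(raw_amount))
            notes = rec.get(hm["notes"])
            rows.append(
                RawQuotaRow(
                    party=(rec[hm["party"]] or "").strip(),
                    year=int(rec[hm["year"]]),
                    taxon_name=(rec[hm["taxon"]] or "").strip(),
                    rank=(rec.get(hm["rank"]) or "species").strip().lower(),
                    amount=amount,
                    notes=notes if notes and notes.strip() else None,
                )
            )
    return rows


def write_quota_records(records: Iterable[QuotaRecord], path: str | Path) -> None:
    """Write cleaned QuotaRecords as CSV (scope in canonical string form)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["id", "party", "year", "taxon", "rank", "amount", "scope", "comparable", "region", "flags"]
        )
        for r in records:
            w.writerow(
                [
                    r.id,
                    r.party,
                    r.year,
                    r.taxon,
                    r.rank,
                    r.amount,
                    r.scope.canonical(),
                    int(r.scope.comparable),
                    r.region or "",
                    "|".join(sorted(r.provenance_flags)),
                ]
            )


def write_audit_log(result: CleanResult, path: str | Path) -> None:
    """Write the removal audit as JSON lines (one record per removal)."""
    with open(path, "w", encoding="utf-8") as fh:
        for stage, removed in result.removed.items():
            for rec in removed:
                fh.write(json.dumps({"stage": stage, **rec}, sort_keys=True) + "\n")
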