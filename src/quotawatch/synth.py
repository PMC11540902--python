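"""Synthetic quota tables, trade ledgers and threat tables with known truth.

Every pipeline stage is testable without any download: the generator
plants exact duplicates, back-dated split quotas, sentinel amounts,
multi-year-span notes, Malaysian-style regional triplets, quota
breaches, importer-only discrepancies, managed/unmanaged trade splits
and pre/post trend structures — and records each planted artefact in a
machine-readable truth sidecar consumed by the test suite.

Default rates mirror the compliance regime of the global reptile-quota
system: ~6.3% of non-zero quotas breached, ~4.5% of zero quotas
subverted, a mean quota use around half the permitted offtake with a
quarter of quotas never traded, 624 update series of 2-27 years with a
hinge (slope 0.29/yr, stagnation near 17 years), and roughly half of
live wild-sourced volume traded outside quotas.

All randomness flows from a single seed through ``numpy.random.
SeedSequence`` spawning, so each sub-generator is independently
reproducible and identical configs give byte-identical CSV files.
"""

from __future__ import annotations

import itertools
import json
import string
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .changepoint import hinge_mean
from .ingest import ALL, RawQuotaRow, SplitEvent, parse_quota_note
from .prepost import PrePostSeries

__all__ = [
    "PlantedConfig",
    "ComplianceConfig",
    "ReportingConfig",
    "PrepostConfig",
    "UpdatesConfig",
    "GapsConfig",
    "ScenarioConfig",
    "gen_quota_table",
    "gen_trade_ledger",
    "gen_threat_table",
    "gen_prepost_series",
    "gen_update_series",
    "simulate_prepost_dataset",
    "simulate_update_series",
    "generate_scenario",
    "quota_rows_to_frame",
]


class PlantedConfig(BaseModel):
    """Counts of cleaning artefacts planted into the raw quota table."""

    n_duplicates: int = 5
    n_split_children: int = 3
    n_sentinel: int = 4
    n_multiyear: int = 3
    n_reexport: int = 2
    n_regional_triplet_years: int = 3
    n_overlap_pairs: int = 2


class ComplianceConfig(BaseModel):
    """Planted compliance regime for the trade ledger."""

    breach_prob: float = Field(0.063, ge=0, le=1)
    zero_breach_prob: float = Field(0.045, ge=0, le=1)
    zero_quota_share: float = Field(0.05, ge=0, le=1)
    no_trade_prob: float = Field(0.26, ge=0, le=1)
    use_alpha: float = 2.2  # Beta parameters of the traded fraction, mean ~0.69
    use_beta: float = 1.0
    excess_scale: float = 0.5  # exponential excess of breaches, as fraction of quota


class ReportingConfig(BaseModel):
    """Exporter/importer reporting-asymmetry model."""

    discrepancy_prob: float = Field(0.03, ge=0, le=1)
    multiplier_low: float = 1.5
    multiplier_high: float = 6.6


class PrepostConfig(BaseModel):
    """True trajectory structure for pre/post series generation."""

    n_series: int = 69
    n_exporters: int = 12
    pre_years: int = 10
    post_years: int = 10
    sigma: float = 0.3  # residual s.d. on the standardized scale
    slope_strong: float = 0.15  # per-year pre-trend, standardized scale
    step_strong: float = 1.5
    trend_change_strong: float = 0.3
    triples: list[tuple[float, float, float]] | None = None  # (pre_slope, step, trend_change)


class UpdatesConfig(BaseModel):
    """True hinge relating series length to number of updates."""

    n_series: int = 624
    intercept: float = -0.35
    slope_pre: float = 0.29
    slope_post: float = 0.0
    omega: float = 17.4
    length_min: int = 2
    length_max: int = 27
    length_decay: float = 0.88  # geometric weight on longer series
    dispersion: float = Field(1.0, ge=0, le=1)  # 1 = full binomial thinning, 0 = deterministic rounding


class GapsConfig(BaseModel):
    """Unmanaged-trade and threat-category mix."""

    n_unmanaged_species: int = 20
    unmanaged_records_per_species: int = 8
    unmanaged_volume_low: int = 10
    unmanaged_volume_high: int = 5000
    category_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "NE": 0.30, "DD": 0.10, "LC": 0.25, "NT": 0.10, "VU": 0.15, "EN": 0.07, "CR": 0.03,
        }
    )
    trade_threat_prob: float = 0.15


class ScenarioConfig(BaseModel):
    """Complete scenario: one seed drives every sub-generator."""

    n_parties: int = 20
    n_species: int = 60
    year_start: int = 1997
    year_end: int = 2021  # last year with usable trade records
    quota_year_end: int = 2023  # quotas are published beyond the trade horizon
    seed: int = 0
    planted: PlantedConfig = Field(default_factory=PlantedConfig)
    compliance: ComplianceConfig = Field(default_factory=ComplianceConfig)
    reporting: ReportingConfig = Field(default_factory=ReportingConfig)
    prepost: PrepostConfig = Field(default_factory=PrepostConfig)
    updates: UpdatesConfig = Field(default_factory=UpdatesConfig)
    gaps: GapsConfig = Field(default_factory=GapsConfig)


_STREAMS = ("quotas", "trade", "threats", "prepost", "updates")


def _rng_for(cfg: ScenarioConfig, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator derived from the scenario seed."""
    idx = _STREAMS.index(stream)
    children = np.random.SeedSequence(cfg.seed).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


def _party_codes(n: int) -> list[str]:
    codes = ["MY"]  # regional-quota party always present
    for a, b in itertools.product(string.ascii_uppercase, repeat=2):
        c = a + b
        if c not in ("MY", "NA"):  # "NA" would collide with CSV missing-value forms
            codes.append(c)
        if len(codes) >= n:
            break
    return codes[:n]


_NOTE_CHOICES = (
    (None, 0.38),
    ("live", 0.30),
    ("live, wild-taken", 0.10),
    ("all", 0.04),
    ("all, live", 0.05),
    ("skins", 0.05),
    ("live, ranched", 0.04),
    ("skins and meat", 0.04),
)


# ---------------------------------------------------------------------------
# Quota table


def gen_quota_table(cfg: ScenarioConfig) -> tuple[list[RawQuotaRow], dict]:
    """Generate a raw quota table with planted cleaning artefacts.

    Returns the rows plus a truth sidecar recording every planted
    artefact and the clean quota index the generator intended.
    """
    rng = _rng_for(cfg, "quotas")
    pl = cfg.planted
    comp = cfg.compliance
    parties = _party_codes(cfg.n_parties)
    rows: list[RawQuotaRow] = []
    clean_index: list[dict] = []

    taxa = [f"Genus{i // 10:02d} species{i:03d}" for i in range(cfg.n_species)]
    notes_pool = [n for n, _ in _NOTE_CHOICES]
    note_p = np.array([w for _, w in _NOTE_CHOICES])
    note_p = note_p / note_p.sum()

    for i, taxon in enumerate(taxa):
        party = parties[int(rng.integers(0, len(parties)))]
        note = notes_pool[int(rng.choice(len(notes_pool), p=note_p))]
        start = int(rng.integers(cfg.year_start, cfg.year_end - 4))
        length = int(rng.integers(3, min(12, cfg.year_end - start + 1) + 1))
        is_zero_series = rng.uniform() < comp.zero_quota_share
        base = 0 if is_zero_series else int(rng.integers(50, 20000))
        amount = base
        for year in range(start, start + length):
            if not is_zero_series and rng.uniform() < 0.3:
                amount = max(10, int(amount * rng.uniform(0.6, 1.5)))
            rows.append(RawQuotaRow(party=party, year=year, taxon_name=taxon, rank="species", amount=amount, notes=note))
            clean_index.append(
                {"party": party, "year": year, "taxon": taxon, "amount": amount, "note": note}
            )

    truth: dict = {"seed": cfg.seed}

    # --- overlapping scope pairs (same party/taxon/year, intersecting scopes)
    overlap_keys = []
    candidates = [c for c in clean_index if c["note"] == "live"]
    rng.shuffle(candidates)
    for c in candidates[: pl.n_overlap_pairs]:
        rows.append(
            RawQuotaRow(
                party=c["party"], year=c["year"], taxon_name=c["taxon"], rank="species",
                amount=int(rng.integers(50, 5000)), notes="all, live",
            )
        )
        overlap_keys.append([c["party"], c["taxon"], c["year"]])
    truth["overlap_keys"] = overlap_keys

    # --- Malaysian regional triplets
    regional = []
    for k in range(pl.n_regional_triplet_years):
        taxon = f"Genus90 regional{k:02d}"
        year = int(rng.integers(cfg.year_start, cfg.year_end + 1))
        amounts = [int(rng.integers(10, 500)) for _ in range(3)]
        for region, amt in zip(("Sabah", "Sarawak", "Peninsular Malaysia"), amounts):
            rows.append(
                RawQuotaRow(party="MY", year=year, taxon_name=taxon, rank="species", amount=amt, notes=f"live ({region})")
            )
        regional.append({"taxon": taxon, "year": year, "total": sum(amounts)})
    truth["regional_triplets"] = regional

    # --- back-dated split children
    split_events = []
    split_rows = 0
    parents = [t for t in taxa[: pl.n_split_children]]
    for k, parent in enumerate(parents):
        child = f"Genus91 split{k:02d}"
        adoption = int(rng.integers(cfg.year_start + 5, cfg.year_end))
        parent_rows = [r for r in rows if r.taxon_name == parent and r.year < adoption]
        for r in parent_rows[:3]:
            rows.append(RawQuotaRow(party=r.party, year=r.year, taxon_name=child, rank="species", amount=r.amount, notes=r.notes))
            split_rows += 1
        split_events.append({"parent_taxon": parent, "child_taxon": child, "adoption_year": adoption})
    truth["split_events"] = split_events
    truth["n_split_rows"] = split_rows

    # --- invalid rows: sentinels, multi-year spans, re-export-only
    inv_party = parties[0]
    for k in range(pl.n_sentinel):
        rows.append(
            RawQuotaRow(
                party=inv_party, year=int(rng.integers(cfg.year_start, cfg.year_end + 1)),
                taxon_name=f"Genus92 sentinel{k:02d}", rank="species",
                amount=(-1 if k % 2 == 0 else None), notes="live",
            )
        )
    for k in range(pl.n_multiyear):
        y = int(rng.integers(cfg.year_start, cfg.year_end))
        rows.append(
            RawQuotaRow(
                party=inv_party, year=y, taxon_name=f"Genus93 span{k:02d}", rank="species",
                amount=int(rng.integers(10, 1000)), notes=f"live, March {y} to March {y + 1}",
            )
        )
    for k in range(pl.n_reexport):
        rows.append(
            RawQuotaRow(
                party=inv_party, year=int(rng.integers(cfg.year_start, cfg.year_end + 1)),
                taxon_name=f"Genus94 reex{k:02d}", rank="species",
                amount=int(rng.integers(10, 1000)), notes="live, re-export only",
            )
        )
    truth["n_sentinel"] = pl.n_sentinel
    truth["n_multiyear"] = pl.n_multiyear
    truth["n_reexport"] = pl.n_reexport

    # --- exact duplicates (appended last; dedup keeps the first occurrence)
    dup_idx = rng.choice(len(rows), size=min(pl.n_duplicates, len(rows)), replace=False)
    for i in sorted(int(j) for j in dup_idx):
        r = rows[i]
        rows.append(RawQuotaRow(party=r.party, year=r.year, taxon_name=r.taxon_name, rank=r.rank, amount=r.amount, notes=r.notes))
    truth["n_duplicates"] = len(dup_idx)

    truth["clean_index"] = clean_index
    truth["zero_quota_keys"] = [
        [c["party"], c["taxon"], c["year"]] for c in clean_index if c["amount"] == 0
    ]
    return rows, truth


def quota_rows_to_frame(rows: list[RawQuotaRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "party": [r.party for r in rows],
            "year": [r.year for r in rows],
            "taxon": [r.taxon_name for r in rows],
            "rank": [r.rank for r in rows],
            "quota": ["" if r.amount is None else r.amount for r in rows],
            "notes": ["" if r.notes is None else r.notes for r in rows],
        }
    )


# ---------------------------------------------------------------------------
# Trade ledger


def _scope_codes(note: str | None) -> tuple[str, str, str]:
    """A concrete (term, source, purpose) inside the note's scope."""
    scope = parse_quota_note(note).scope
    term = "live" if scope.terms == ALL or "live" in scope.terms else sorted(scope.terms)[0]
    source = "wild" if scope.sources == ALL or "wild" in scope.sources else sorted(scope.sources)[0]
    purpose = "commercial" if scope.purposes == ALL else sorted(scope.purposes)[0]
    return term, source, purpose


def gen_trade_ledger(cfg: ScenarioConfig, quota_truth: dict) -> tuple[pd.DataFrame, dict]:
    """Generate a trade ledger realizing the planted compliance regime.

    One CSV row per shipment with exporter- and importer-reported
    quantity columns.  The truth sidecar lists every planted breach,
    zero-quota subversion and importer-only discrepancy, plus per-year
    managed/unmanaged live wild-sourced volumes.
    """
    rng = _rng_for(cfg, "trade")
    comp = cfg.compliance
    rep = cfg.reporting
    gaps = cfg.gaps

    ledger_rows: list[dict] = []
    breaches: list[list] = []
    zero_breaches: list[list] = []
    importer_only: list[list] = []
    managed_volume: dict[int, int] = {}
    unmanaged_volume: dict[int, int] = {}

    def add_row(year, taxon, exporter, term, source, purpose, unit, exp_qty, imp_qty, origin=""):
        ledger_rows.append(
            {
                "Year": year, "App.": "II", "Taxon": taxon, "Term": term, "Unit": unit,
                "Importer": "XX", "Exporter": exporter, "Origin": origin,
                "Purpose": purpose, "Source": source,
                "Exporter reported quantity": "" if exp_qty is None else exp_qty,
                "Importer reported quantity": "" if imp_qty is None else imp_qty,
            }
        )

    # --- trade under quotas
    for c in quota_truth["clean_index"]:
        term, source, purpose = _scope_codes(c["note"])
        if term != "live":
            continue  # only live trade is generated against live-term quotas
        year, taxon, party, amount = c["year"], c["taxon"], c["party"], c["amount"]
        if amount == 0:
            if rng.uniform() < comp.zero_breach_prob:
                qty = int(rng.integers(1, 50))
                if rng.uniform() < 0.5:
                    add_row(year, taxon, party, "live", source, purpose, "", qty, qty)
                    qty_exp = qty
                else:
                    add_row(year, taxon, party, "live", source, purpose, "", None, qty)
                    qty_exp = 0
                zero_breaches.append([party, taxon, year])
                if source == "wild":
                    managed_volume[year] = managed_volume.get(year, 0) + qty_exp
            continue
        if rng.uniform() < comp.breach_prob:
            excess = rng.exponential(comp.excess_scale)
            exp_qty = amount + max(1, int(round(amount * excess)))
            breaches.append([party, taxon, year, amount, exp_qty])
            imp_qty = exp_qty
        else:
            if rng.uniform() < comp.no_trade_prob:
                exp_qty = 0
            else:
                exp_qty = int(round(amount * rng.beta(comp.use_alpha, comp.use_beta)))
                exp_qty = min(exp_qty, amount)  # compliant by construction
            imp_qty = exp_qty
            if rng.uniform() < rep.discrepancy_prob:
                mult = rng.uniform(rep.multiplier_low, rep.multiplier_high)
                imp_qty = amount + max(1, int(round(amount * (mult - 1.0))))
                importer_only.append([party, taxon, year, amount, exp_qty, imp_qty])
        if exp_qty > 0 or imp_qty > 0:
            add_row(year, taxon, party, "live", source, purpose, "",
                    exp_qty if exp_qty > 0 else None, imp_qty if imp_qty > 0 else None)
            if source == "wild":
                managed_volume[year] = managed_volume.get(year, 0) + (exp_qty or 0)

    # --- unmanaged live wild trade (no quota at all for these taxa)
    parties = _party_codes(cfg.n_parties)
    for k in range(gaps.n_unmanaged_species):
        taxon = f"Gapus species{k:03d}"
        for _ in range(gaps.unmanaged_records_per_species):
            year = int(rng.integers(cfg.year_start, cfg.year_end + 1))
            exporter = parties[int(rng.integers(0, len(parties)))]
            qty = int(rng.integers(gaps.unmanaged_volume_low, gaps.unmanaged_volume_high))
            add_row(year, taxon, exporter, "live", "wild", "commercial", "", qty, qty)
            unmanaged_volume[year] = unmanaged_volume.get(year, 0) + qty

    # --- records the live/direct/count filter must reject
    filler_party = parties[1]
    noise = [
        dict(term="live", unit="kg", origin=""),
        dict(term="skins", unit="", origin=""),
        dict(term="live", unit="", origin=parties[2]),  # re-export
    ]
    for k, nz in enumerate(noise):
        add_row(
            cfg.year_start + k, f"Gapus species000", filler_party,
            nz["term"], "wild", "commercial", nz["unit"], 100, 100, origin=nz["origin"],
        )

    truth = {
        "breaches": breaches,
        "zero_breaches": zero_breaches,
        "importer_only": importer_only,
        "managed_volume_by_year": {str(k): v for k, v in sorted(managed_volume.items())},
        "unmanaged_volume_by_year": {str(k): v for k, v in sorted(unmanaged_volume.items())},
    }
    df = pd.DataFrame(ledger_rows)
    return df, truth


# ---------------------------------------------------------------------------
# Threat table


def gen_threat_table(cfg: ScenarioConfig, taxa: list[str]) -> tuple[pd.DataFrame, dict]:
    """Assessment timelines (possibly with one category change) per taxon."""
    rng = _rng_for(cfg, "threats")
    mix = cfg.gaps.category_mix
    cats = list(mix)
    probs = np.array([mix[c] for c in cats], dtype=float)
    probs /= probs.sum()
    rows = []
    truth = {}
    for taxon in sorted(taxa):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        flag = bool(rng.uniform() < cfg.gaps.trade_threat_prob)
        first = int(rng.integers(cfg.year_start - 5, cfg.year_start + 10))
        timeline = [(first, cat)]
        if rng.uniform() < 0.25:
            later = int(rng.integers(first + 3, cfg.year_end + 1))
            cat2 = cats[int(rng.choice(len(cats), p=probs))]
            timeline.append((later, cat2))
        for y, c in timeline:
            rows.append({"taxon": taxon, "year_from": y, "category": c, "trade_threat_flag": int(flag)})
        truth[taxon] = {"timeline": timeline, "trade_threat_flag": flag}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Pre/post series


def _default_triples(pp: PrepostConfig) -> list[tuple[float, float, float]]:
    s, st, tc = pp.slope_strong, pp.step_strong, pp.trend_change_strong
    menu = [
        (0.0, 0.0, 0.0),
        (0.0, st, 0.0),
        (s, st, 0.0),
        (s, -st, 0.0),
        (s, 0.0, -tc),
        (-s, st, tc),
        (0.0, -st, 0.0),
        (s, -st, -tc),
    ]
    return [menu[i % len(menu)] for i in range(pp.n_series)]


def gen_prepost_series(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Raw-scale volume and quota tables realizing known trend triples.

    Each series has ``pre_years`` of pre-quota trade and ``post_years``
    of post-quota trade plus quota levels, generated on the standardized
    scale from its (pre_slope, step, trend_change) triple and mapped to
    a randomized raw scale.  The truth sidecar stores the triples.
    """
    rng = _rng_for(cfg, "prepost")
    pp = cfg.prepost
    triples = pp.triples or _default_triples(pp)
    exporters = _party_codes(pp.n_exporters)
    vol_rows, quota_rows = [], []
    truth_series = []
    for i, (b3, step, tchange) in enumerate(triples):
        taxon = f"Trendus species{i:03d}"
        exporter = exporters[i % len(exporters)]
        q0 = int(rng.integers(cfg.year_start + pp.pre_years, cfg.year_end - pp.post_years + 2))
        centre = float(rng.uniform(500, 5000))
        scale = float(rng.uniform(100, 800))
        for t in range(-pp.pre_years, pp.post_years):
            year = q0 + t
            if t < 0:
                z = b3 * (t + 1) + rng.normal(0.0, pp.sigma)
                vol_rows.append(_pp_row(taxon, exporter, year, max(0, round(centre + scale * z))))
            else:
                z_act = b3 * (t + 1) + step + tchange * t + rng.normal(0.0, pp.sigma)
                vol_rows.append(_pp_row(taxon, exporter, year, max(0, round(centre + scale * z_act))))
                z_q = b3 * (t + 1) + step + tchange * t + rng.normal(0.0, pp.sigma / 2)
                quota_rows.append(_pp_row(taxon, exporter, year, max(0, round(centre + scale * z_q)), amount=True))
        truth_series.append(
            {"taxon": taxon, "exporter": exporter, "first_quota_year": q0,
             "pre_slope": b3, "step": step, "trend_change": tchange,
             "centre": centre, "scale": scale}
        )
    volumes = pd.DataFrame(vol_rows)
    quotas = pd.DataFrame(quota_rows)
    return volumes, quotas, {"series": truth_series, "sigma": pp.sigma}


def _pp_row(taxon, exporter, year, value, amount=False):
    row = {"taxon": taxon, "exporter": exporter, "purpose": "commercial", "source": "wild", "year": year}
    row["amount" if amount else "volume"] = int(value)
    return row


def simulate_prepost_dataset(
    beta: tuple[float, float, float, float, float],
    n_taxa: int = 16,
    n_exporters: int = 6,
    pre_years: int = 5,
    post_years: int = 5,
    taxon_sd: float = 0.2,
    exporter_sd: float = 0.2,
    year_sd: float = 0.1,
    sigma: float = 0.5,
    seed: int = 0,
    taxon_betas: np.ndarray | None = None,
) -> list[PrePostSeries]:
    """Simulate standardized series directly from the hierarchical model.

    Used for parameter-recovery calibration: the population-level
    coefficients are exactly ``beta`` and the series are emitted on the
    standardized scale (centre 0, scale 1), bypassing re-standardization
    so planted values stay on the fitted scale.  ``taxon_betas`` (shape
    (n_taxa, 5)) plants exact per-taxon coefficients instead of drawing
    them around ``beta``; used for trajectory-classification tests.
    """
    rng = np.random.default_rng(seed)
    beta_arr = np.asarray(beta, dtype=float)
    exporters = [f"E{k:02d}" for k in range(n_exporters)]
    year_effects: dict[int, float] = {}
    exp_effects = {e: rng.normal(0, exporter_sd) for e in exporters}
    series = []
    for j in range(n_taxa):
        if taxon_betas is not None:
            bj = np.asarray(taxon_betas, dtype=float)[j]
        else:
            bj = beta_arr + rng.normal(0, taxon_sd, size=5)
        taxon = f"Simux species{j:03d}"
        exporter = exporters[j % n_exporters]
        q0 = 2005 + (j % 4)
        cal, tt, state, v = [], [], [], []
        for t in range(-pre_years, post_years):
            year = q0 + t
            if year not in year_effects:
                year_effects[year] = rng.normal(0, year_sd)
            shared = exp_effects[exporter] + year_effects[year]
            mu_pre = bj[2] * (t + 1)
            if t < 0:
                cal.append(year); tt.append(t); state.append("pre")
                v.append(mu_pre + shared + rng.normal(0, sigma))
            else:
                cal.append(year); tt.append(t); state.append("post_actual")
                v.append(mu_pre + bj[0] + bj[3] * t + shared + rng.normal(0, sigma))
                cal.append(year); tt.append(t); state.append("post_quota")
                v.append(mu_pre + bj[1] + bj[4] * t + shared + rng.normal(0, sigma))
        series.append(
            PrePostSeries(
                taxon=taxon, exporter=exporter, purpose="commercial", source="wild",
                calendar_year=np.array(cal), year_centred=np.array(tt),
                state=np.array(state), volume_std=np.array(v), centre=0.0, scale=1.0,
            )
        )
    return series


# ---------------------------------------------------------------------------
# Update series


def gen_update_series(cfg: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Quota-amount paths whose update counts follow the configured hinge.

    The expected number of changes at length L is the hinge mean clipped
    to [0, L-1]; realized counts are binomial-thinned around it, keeping
    counts integer and bounded.  Returns (series table, per-year amounts
    table, truth).
    """
    rng = _rng_for(cfg, "updates")
    up = cfg.updates
    lengths = np.arange(up.length_min, up.length_max + 1)
    weights = up.length_decay ** lengths
    weights = weights / weights.sum()
    parties = _party_codes(cfg.n_parties)

    series_rows, amount_rows, truth_series = [], [], []
    for i in range(up.n_series):
        L = int(rng.choice(lengths, p=weights))
        m = float(np.clip(hinge_mean(L, up.intercept, up.slope_pre, up.slope_post, up.omega), 0.0, L - 1))
        p = m / (L - 1)
        if rng.uniform() < up.dispersion:
            n_changes = int(rng.binomial(L - 1, p))
        else:
            # stochastic rounding keeps the mean while shrinking dispersion
            frac = m - np.floor(m)
            n_changes = int(np.floor(m) + (rng.uniform() < frac))
        taxon = f"Updatus species{i:03d}"
        exporter = parties[int(rng.integers(0, len(parties)))]
        last_start = cfg.quota_year_end - L + 1
        start = int(rng.integers(cfg.year_start, last_start + 1)) if last_start > cfg.year_start else cfg.year_start
        change_at = set(int(x) for x in rng.choice(L - 1, size=n_changes, replace=False))
        amount = int(rng.integers(50, 10000))
        amounts = [amount]
        for t in range(L - 1):
            if t in change_at:
                new = max(10, int(amount * rng.uniform(0.5, 1.6)))
                amount = new if new != amount else amount + 10
            amounts.append(amount)
        for k, a in enumerate(amounts):
            amount_rows.append(
                {"taxon": taxon, "exporter": exporter, "purpose": "commercial",
                 "term": "live", "source": "wild", "year": start + k, "amount": a}
            )
        series_rows.append(
            {"taxon": taxon, "exporter": exporter, "purpose": "commercial",
             "term": "live", "source": "wild", "length": L, "n_changes": n_changes}
        )
        truth_series.append({"taxon": taxon, "length": L, "n_changes": n_changes})

    truth = {
        "hinge": {"intercept": up.intercept, "slope_pre": up.slope_pre,
                  "slope_post": up.slope_post, "omega": up.omega},
        "series": truth_series,
        "n_never_changed": sum(1 for s in truth_series if s["n_changes"] == 0),
        "n_changed_every_year": sum(1 for s in truth_series if s["n_changes"] == s["length"] - 1),
    }
    return pd.DataFrame(series_rows), pd.DataFrame(amount_rows), truth


def simulate_update_series(
    n_series: int = 600,
    omega: float = 17.0,
    slope_pre: float = 0.3,
    slope_post: float = 0.0,
    intercept: float = -0.35,
    sigma: float = 1.0,
    length_decay: float = 0.88,
    length_range: tuple[int, int] = (2, 27),
    seed: int = 0,
) -> list:
    """Simulate update series directly from the hinge + normal-error model.

    Used for parameter-recovery calibration of the change-point fit:
    counts are the hinge mean plus Gaussian noise, rounded and clipped
    to the feasible [0, length - 1] range.  The pipeline-level
    :func:`gen_update_series` (binomial thinning) remains the source of
    count-structured fixtures; this model-level simulator matches the
    fitted error family so interval calibration is interpretable.
    """
    from .changepoint import UpdateSeries  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    lengths = np.arange(length_range[0], length_range[1] + 1)
    w = length_decay ** lengths
    w = w / w.sum()
    L = rng.choice(lengths, p=w, size=n_series)
    m = hinge_mean(L, intercept, slope_pre, slope_post, omega)
    n = np.clip(np.round(m + rng.normal(0.0, sigma, n_series)), 0, L - 1).astype(int)
    return [
        UpdateSeries(
            taxon=f"Simup species{i:03d}", exporter="AA", purpose="commercial",
            term="live", source="wild", length=int(l), n_changes=int(c),
        )
        for i, (l, c) in enumerate(zip(L, n))
    ]


# ---------------------------------------------------------------------------
# Scenario driver


def generate_scenario(cfg: ScenarioConfig, outdir: str | Path) -> dict:
    """Write every synthetic input CSV plus the truth sidecar to outdir.

    Files: quotas.csv, splits.csv, trade.csv, threats.csv,
    prepost_volumes.csv, prepost_quotas.csv, update_series.csv,
    update_amounts.csv, truth.json.  Byte-identical for identical cfg.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    quota_rows, quota_truth = gen_quota_table(cfg)
    trade_df, trade_truth = gen_trade_ledger(cfg, quota_truth)
    quota_taxa = sorted({c["taxon"] for c in quota_truth["clean_index"]})
    gap_taxa = sorted({t for t in trade_df["Taxon"].unique()})
    threats_df, threat_truth = gen_threat_table(cfg, sorted(set(quota_taxa) | set(gap_taxa)))
    pp_vol, pp_quota, pp_truth = gen_prepost_series(cfg)
    upd_series, upd_amounts, upd_truth = gen_update_series(cfg)

    quota_rows_to_frame(quota_rows).to_csv(outdir / "quotas.csv", index=False)
    pd.DataFrame(quota_truth["split_events"]).to_csv(outdir / "splits.csv", index=False)
    trade_df.to_csv(outdir / "trade.csv", index=False)
    threats_df.to_csv(outdir / "threats.csv", index=False)
    pp_vol.to_csv(outdir / "prepost_volumes.csv", index=False)
    pp_quota.to_csv(outdir / "prepost_quotas.csv", index=False)
    upd_series.to_csv(outdir / "update_series.csv", index=False)
    upd_amounts.to_csv(outdir / "update_amounts.csv", index=False)

    truth = {
        "config": json.loads(cfg.model_dump_json()),
        "quotas": {k: v for k, v in quota_truth.items() if k != "clean_index"},
        "n_clean_quotas": len(quota_truth["clean_index"]),
        "trade": trade_truth,
        "threats": {t: {"timeline": [list(x) for x in v["timeline"]], "trade_threat_flag": v["trade_threat_flag"]}
                    for t, v in threat_truth.items()},
        "prepost": pp_truth,
        "updates": upd_truth,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return truth
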