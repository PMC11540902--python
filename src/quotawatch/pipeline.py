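"""End-to-end orchestration: ingest -> ledger -> compliance -> models -> gaps.

Drives the whole analysis from a single config, against either real
CSV exports or a generated synthetic scenario, and writes one JSON +
Markdown report.  Every stage logs input/output record counts; a stage
failure raises a :class:`StageError` naming the stage.  Reports carry
no timestamps, so identical configs (including the seed) produce
byte-identical output.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import changepoint as cp
from . import compliance as comp
from . import gaps as gp
from . import ingest as ing
from . import ledger as led
from . import prepost as pp
from ._mcmc import McmcSettings
from .synth import ScenarioConfig, generate_scenario
from .vocab import default_vocabulary, load_vocabulary

__all__ = ["RunConfig", "StageError", "run_all"]

log = logging.getLogger("quotawatch")


class McmcConfig(BaseModel):
    chains: int = 4
    warmup: int = 500
    samples: int = 500
    seed: int = 0

    def settings(self) -> McmcSettings:
        return McmcSettings(chains=self.chains, warmup=self.warmup, samples=self.samples, seed=self.seed)


class RunConfig(BaseModel):
    """Paths or scenario, stage toggles, sampler settings, output dir."""

    scenario: ScenarioConfig | None = None
    quotas_path: str | None = None
    splits_path: str | None = None
    trade_path: str | None = None
    threats_path: str | None = None
    prepost_volumes_path: str | None = None
    prepost_quotas_path: str | None = None
    update_amounts_path: str | None = None
    vocab_path: str | None = None
    outdir: str = "quotawatch_out"
    era_split: int = 2016
    trade_year_end: int = 2021
    run_prepost: bool = True
    run_changepoint: bool = True
    run_gaps: bool = True
    mcmc: McmcConfig = Field(default_factory=McmcConfig)

    @model_validator(mode="after")
    def _inputs_present(self) -> "RunConfig":
        if self.scenario is None and (self.quotas_path is None or self.trade_path is None):
            raise ValueError("either a synthetic scenario or real quota+trade paths must be given")
        return self


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending detail."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001 - wrap with stage context
                raise StageError(name, str(e)) from e

        return wrapped

    return deco


@_stage("ingest")
def _run_ingest(cfg: RunConfig, vocab) -> ing.CleanResult:
    rows = ing.read_quota_csv(cfg.quotas_path)
    splits = []
    if cfg.splits_path and Path(cfg.splits_path).exists():
        sdf = pd.read_csv(cfg.splits_path)
        if len(sdf):
            splits = [
                ing.SplitEvent(r.parent_taxon, r.child_taxon, int(r.adoption_year))
                for r in sdf.itertuples()
            ]
    result = ing.clean_quotas(rows, splits, vocab)
    log.info("ingest: %d raw rows -> %d clean quotas", len(rows), len(result.records))
    return result


@_stage("compliance")
def _run_compliance(cfg: RunConfig, records, trade):
    live = [q for q in records if q.scope.terms == ing.ALL or "live" in q.scope.terms]
    live = [q for q in live if q.year <= cfg.trade_year_end]
    audit: list[dict] = []
    live = led.sum_malaysian_regions(live)
    live = led.remove_overlapping_quotas(live, audit=audit)
    live = led.exclude_mixed_term_species(live, all_quotas=records, audit=audit)
    filtered = led.filter_live_direct(trade)
    by_key: dict[tuple, list] = {}
    for r in filtered:
        by_key.setdefault((r.taxon, r.exporter, r.year), []).append(r)
    results = []
    for q in live:
        cell = led.aggregate_volumes(by_key.get((q.taxon, q.party, q.year), []), q.scope, (q.taxon, q.party, q.year))
        results.append(comp.evaluate_quota(q, cell))
    summary = comp.summarize_compliance(results)
    table = comp.discrepancy_table(results)
    log.info("compliance: %d live quotas evaluated, %d breaches", len(results), summary.n_nonzero_breaches)
    return live, results, summary, table, audit


@_stage("prepost")
def _run_prepost(cfg: RunConfig, settings: McmcSettings):
    volumes = pd.read_csv(cfg.prepost_volumes_path)
    quotas = pd.read_csv(cfg.prepost_quotas_path)
    audit: list[dict] = []
    series = pp.build_series(volumes, quotas, audit=audit)
    fit = pp.fit_prepost(series, settings)
    panels = pp.classify_all(fit) if fit.converged else []
    return series, fit, panels, audit


@_stage("changepoint")
def _run_changepoint(cfg: RunConfig, records, settings: McmcSettings):
    if cfg.update_amounts_path:
        adf = pd.read_csv(cfg.update_amounts_path)
        qrecs = [
            ing.QuotaRecord(
                id=f"u{i:06d}", party=r.exporter, year=int(r.year), taxon=r.taxon, rank="species",
                amount=int(r.amount),
                scope=ing.QuotaScope(
                    terms=frozenset({r.term}), sources=frozenset({r.source}), purposes=frozenset({r.purpose}),
                ),
            )
            for i, r in enumerate(adf.itertuples())
        ]
    else:
        qrecs = records
    modelled, excluded = cp.build_update_series(qrecs)
    fit = cp.fit_changepoint(modelled, settings)
    return modelled, excluded, fit


@_stage("gaps")
def _run_gaps(cfg: RunConfig, records, trade):
    threats = gp.read_threat_csv(cfg.threats_path) if cfg.threats_path else gp.ThreatTable([])
    filtered = [r for r in led.filter_live_direct(trade) if r.source == "wild" and r.year <= cfg.trade_year_end]
    managed, unmanaged = gp.split_managed(filtered, records)
    cells, summary = gp.gap_trends(unmanaged, threats, era_split=cfg.era_split)
    managed_by_year: dict[int, int] = {}
    total_by_year: dict[int, int] = {}
    for r in filtered:
        if r.reporter != "exporter_reported":
            continue
        total_by_year[r.year] = total_by_year.get(r.year, 0) + int(r.quantity)
    for r in managed:
        if r.reporter != "exporter_reported":
            continue
        managed_by_year[r.year] = managed_by_year.get(r.year, 0) + int(r.quantity)
    summary["managed_volume_by_year"] = {str(k): v for k, v in sorted(managed_by_year.items())}
    summary["total_volume_by_year"] = {str(k): v for k, v in sorted(total_by_year.items())}
    return cells, summary


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages and write report.json / report.md.

    Returns the report dict.  With a synthetic scenario, the generated
    input CSVs are written under ``<outdir>/inputs`` and then read back
    through the ordinary readers, exercising the full I/O path.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}

    if cfg.scenario is not None:
        inputs = outdir / "inputs"
        generate_scenario(cfg.scenario, inputs)
        cfg = cfg.model_copy(
            update={
                "quotas_path": str(inputs / "quotas.csv"),
                "splits_path": str(inputs / "splits.csv"),
                "trade_path": str(inputs / "trade.csv"),
                "threats_path": str(inputs / "threats.csv"),
                "prepost_volumes_path": str(inputs / "prepost_volumes.csv"),
                "prepost_quotas_path": str(inputs / "prepost_quotas.csv"),
                "update_amounts_path": str(inputs / "update_amounts.csv"),
            }
        )

    vocab = load_vocabulary(cfg.vocab_path) if cfg.vocab_path else default_vocabulary()
    settings = cfg.mcmc.settings()

    clean = _run_ingest(cfg, vocab)
    report["stages"]["ingest"] = dict(clean.stage_counts)
    ing.write_quota_records(clean.records, outdir / "quotas_clean.csv")
    ing.write_audit_log(clean, outdir / "ingest_audit.jsonl")

    trade = led.read_trade_csv(cfg.trade_path)
    report["stages"]["ledger"] = {"input": len(trade), "live_direct": len(led.filter_live_direct(trade))}

    live, results, summary, table, audit = _run_compliance(cfg, clean.records, trade)
    report["stages"]["compliance"] = {"live_quotas": len(live), "evaluated": len(results)}
    report["compliance"] = summary.to_dict()
    report["compliance"]["n_importer_only_breaches"] = int(sum(r.breach_importer_only for r in results))
    comp.write_compliance_csv(results, outdir / "compliance.csv")
    comp.write_summary_json(summary, outdir / "compliance_summary.json")
    table.to_csv(outdir / "discrepancy_table.csv", index=False)
    report["discrepancy_top10"] = table.head(10).to_dict(orient="records")

    if cfg.run_prepost and cfg.prepost_volumes_path:
        series, fit, panels, pp_audit = _run_prepost(cfg, settings)
        report["stages"]["prepost"] = {"series": len(series), "excluded": len(pp_audit)}
        pop = fit.summaries[fit.summaries["level"] == "population"]
        report["prepost"] = {
            "converged": fit.converged,
            "rhat_max": round(fit.rhat_max, 4),
            "coefficients": {
                r["coefficient"]: {
                    "median": round(r["median"], 3),
                    "hdi90": [round(r["hdi_low"], 3), round(r["hdi_high"], 3)],
                    "pd": round(r["pd"], 2),
                }
                for _, r in pop.iterrows()
            },
            "panel_counts_quota": _tally(p.quota_panel for p in panels),
            "panel_counts_volume": _tally(p.volume_panel for p in panels),
        }
        pp.write_fit_outputs(fit, outdir / "prepost")
    else:
        report["prepost"] = {"skipped": True}

    if cfg.run_changepoint:
        modelled, excluded, cfit = _run_changepoint(cfg, clean.records, settings)
        report["stages"]["changepoint"] = {"series": len(modelled), "excluded_zero_quota": len(excluded)}
        cp.write_update_series(modelled + excluded, outdir / "update_series.csv")
        cp.write_fit_json(cfit, outdir / "changepoint_summary.json")
        entry = {
            "converged": cfit.converged,
            "rhat_max": round(cfit.rhat_max, 4),
            "parameters": {
                r["parameter"]: {
                    "median": round(r["median"], 3),
                    "ci90": [round(r["hdi_low"], 3), round(r["hdi_high"], 3)],
                    "pd": round(r["pd"], 2),
                }
                for _, r in cfit.summaries.iterrows()
            },
        }
        if cfit.converged:
            e15 = cp.expected_changes(cfit, 15)
            e25 = cp.expected_changes(cfit, 25)
            entry["expected_changes"] = {
                "15yr": {"median": round(e15.median, 2), "rate_per_year": cp.per_year_rate(e15.median, 15)},
                "25yr": {"median": round(e25.median, 2), "rate_per_year": cp.per_year_rate(e25.median, 25)},
            }
        report["changepoint"] = entry
    else:
        report["changepoint"] = {"skipped": True}

    if cfg.run_gaps and cfg.threats_path:
        cells, gsummary = _run_gaps(cfg, clean.records, trade)
        report["stages"]["gaps"] = {"cells": len(cells)}
        report["gaps"] = gsummary
        gp.write_gap_outputs(cells, gsummary, outdir / "gaps")
    else:
        report["gaps"] = {"skipped": True}

    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (outdir / "report.md").write_text(_render_markdown(report), encoding="utf-8")
    return report


def _tally(values) -> dict[str, int]:
    out: dict[str, int] = {}
    for v in values:
        out[str(v)] = out.get(str(v), 0) + 1
    return dict(sorted(out.items(), key=lambda kv: int(kv[0])))


def _render_markdown(report: dict) -> str:
    lines = ["# Quota analysis report", ""]
    c = report.get("compliance", {})
    if c:
        lines += [
            "## Compliance",
            "",
            f"- zero quotas: {c['n_zero_quotas']} ({c['n_zero_breaches']} subverted; "
            f"{c['zero_compliance_pct']}% complied)" if c.get("n_zero_quotas") else "- zero quotas: 0",
            f"- non-zero quotas: {c['n_nonzero_quotas']} ({c['n_nonzero_breaches']} breached, "
            f"{c['nonzero_breach_pct']}%)",
            f"- mean quota use: {c['mean_pct_use_all']}% (all), {c['mean_pct_use_traded']}% (traded only)",
            "",
        ]
    ppr = report.get("prepost", {})
    lines += ["## Pre/post-quota model", ""]
    if ppr.get("skipped"):
        lines += ["- skipped", ""]
    else:
        for name, v in ppr.get("coefficients", {}).items():
            lines.append(f"- {name}: median {v['median']} (90% HDI {v['hdi90'][0]} to {v['hdi90'][1]}, pd {v['pd']}%)")
        lines.append("")
    cpr = report.get("changepoint", {})
    lines += ["## Quota-update change point", ""]
    if cpr.get("skipped"):
        lines += ["- skipped", ""]
    else:
        for name, v in cpr.get("parameters", {}).items():
            lines.append(f"- {name}: median {v['median']} (90% CI {v['ci90'][0]} to {v['ci90'][1]})")
        if "expected_changes" in cpr:
            e = cpr["expected_changes"]
            lines.append(
                f"- expected updates: {e['15yr']['median']} at 15 yr ({e['15yr']['rate_per_year']}/yr), "
                f"{e['25yr']['median']} at 25 yr ({e['25yr']['rate_per_year']}/yr)"
            )
        lines.append("")
    g = report.get("gaps", {})
    lines += ["## Coverage gaps", ""]
    if g.get("skipped"):
        lines += ["- skipped", ""]
    else:
        for era, cats in g.get("eras", {}).items():
            for cat, v in cats.items():
                lines.append(f"- {era}-era {cat}: volume {v['volume']}, combos {v['combos_unique']}")
        lines.append("")
    return "\n".join(lines) + "\n"
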