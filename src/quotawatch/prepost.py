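"""Counterfactual pre/post-quota trade model and trajectory classification.

For each species-exporter quota series we compare traded volumes before
the first quota with (a) traded volumes after it and (b) the quota
levels themselves, on a per-series standardized scale (volumes centred
on the last pre-quota year, scaled by the series standard deviation).

The model is a hierarchical Gaussian regression

    volume_std ~ N(mu, sigma^2)
    mu = alpha[j,k,l] + b1[j]*post_actual + b2[j]*post_quota + b3[j]*year
         + b4[j]*post_actual*year + b5[j]*post_quota*year

with varying intercepts by taxon j, exporter k and calendar year l
(crossed), and all five slopes varying by taxon.  b1/b2 are the
counterfactual step of post-quota volumes / quota levels above the
extrapolated pre-quota trend at year 0; b4/b5 are the corresponding
changes in trend.  Priors are zero-centred and diffuse.

Each series' posterior is classified onto an 18-panel taxonomy of
pre-to-post trajectories: a 3x3 grid of (pre-quota trend x step) for
series with no clear trend change (panels 1-9) and the same grid with a
clear trend change (panels 10-18).  A direction is "clear" when >= 97.5%
of the posterior shares the median's sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._mcmc import (
    CoefSummary,
    McmcSettings,
    RHAT_LIMIT,
    max_rhat,
    sample_hierarchical_gaussian,
    summarize_draws,
)

__all__ = [
    "PrePostSeries",
    "PrePostFit",
    "PanelCall",
    "PanelClass",
    "PANEL_GRID",
    "CLEAR_PD",
    "build_series",
    "series_to_frame",
    "fit_prepost",
    "summarize_coefficient",
    "classify_panel",
    "classify_all",
]

State = Literal["pre", "post_actual", "post_quota"]

CLEAR_PD = 97.5
"""Posterior share (percent) required to call a direction clear."""

#: Base grid of the panel taxonomy: (pre_trend, step) -> panel 1-9.
#: A clear trend change adds 9.  Config-replaceable.
PANEL_GRID: dict[tuple[str, str], int] = {
    ("flat", "none"): 1,
    ("flat", "up"): 2,
    ("flat", "down"): 3,
    ("up", "none"): 4,
    ("up", "up"): 5,
    ("up", "down"): 6,
    ("down", "none"): 7,
    ("down", "up"): 8,
    ("down", "down"): 9,
}


@dataclass
class PrePostSeries:
    """One standardized species-exporter series (pre + post + quota rows)."""

    taxon: str
    exporter: str
    purpose: str
    source: str
    calendar_year: np.ndarray  # per row
    year_centred: np.ndarray  # 0 = first post-quota year
    state: np.ndarray  # "pre" | "post_actual" | "post_quota"
    volume_std: np.ndarray
    centre: float  # raw volume of the last pre-quota year
    scale: float  # s.d. of raw actual volumes across the series

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.taxon, self.exporter, self.purpose, self.source)

    def destandardize(self) -> np.ndarray:
        """Recover raw volumes from the standardized values exactly."""
        return self.volume_std * self.scale + self.centre


def series_to_frame(series: Sequence[PrePostSeries]) -> pd.DataFrame:
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "taxon": s.taxon,
                    "exporter": s.exporter,
                    "purpose": s.purpose,
                    "source": s.source,
                    "calendar_year": s.calendar_year,
                    "year_centred": s.year_centred,
                    "state": s.state,
                    "volume_std": s.volume_std,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def build_series(
    volumes: pd.DataFrame,
    quotas: pd.DataFrame,
    min_pre: int = 5,
    min_post: int = 5,
    max_pre: int = 10,
    listing: pd.DataFrame | None = None,
    audit: list[dict] | None = None,
) -> list[PrePostSeries]:
    """Assemble standardized pre/post series from volume and quota tables.

    ``volumes`` has columns (taxon, exporter, purpose, source, year,
    volume); ``quotas`` the same with ``amount``.  A series needs at
    least ``min_post`` contiguous quota years and ``min_pre`` pre-quota
    years (years with no trade record count as zero trade); ``listing``,
    if given, must show (party, taxon) listed at least ``min_pre`` years
    before the first quota.  Series with zero standard deviation are
    excluded with an audit reason.
    """
    key_cols = ["taxon", "exporter", "purpose", "source"]
    vol_idx = volumes.set_index(key_cols + ["year"])["volume"].to_dict()
    listed: dict[tuple[str, str], int] = {}
    if listing is not None:
        listed = {(r.party, r.taxon): int(r.listed_year) for r in listing.itertuples()}

    out: list[PrePostSeries] = []
    for key, grp in quotas.groupby(key_cols, sort=True):
        taxon, exporter, purpose, source = key
        grp = grp.sort_values("year")
        q_years = grp["year"].to_numpy()
        q_amounts = dict(zip(grp["year"], grp["amount"]))
        # first contiguous run of quota years
        q0 = int(q_years[0])
        run = [q0]
        for y in q_years[1:]:
            if y == run[-1] + 1:
                run.append(int(y))
            else:
                break
        if len(run) < min_post:
            _audit(audit, key, "too_few_post_years")
            continue
        pre_years = list(range(q0 - max_pre, q0))
        if listing is not None:
            ly = listed.get((exporter, taxon))
            if ly is None or q0 - ly < min_pre:
                _audit(audit, key, "listed_too_recently")
                continue
            pre_years = [y for y in pre_years if y >= ly]
        if len(pre_years) < min_pre:
            _audit(audit, key, "too_few_pre_years")
            continue

        def vol(year: int) -> float:
            return float(vol_idx.get((taxon, exporter, purpose, source, year), 0.0))

        actual_years = pre_years + run
        actual = np.array([vol(y) for y in actual_years])
        centre = vol(q0 - 1)
        scale = float(np.std(actual, ddof=1))
        if scale == 0.0:
            _audit(audit, key, "zero_sd")
            continue

        cal, t, state, v = [], [], [], []
        for y in pre_years:
            cal.append(y); t.append(y - q0); state.append("pre"); v.append((vol(y) - centre) / scale)
        for y in run:
            cal.append(y); t.append(y - q0); state.append("post_actual"); v.append((vol(y) - centre) / scale)
        for y in run:
            cal.append(y); t.append(y - q0); state.append("post_quota"); v.append((q_amounts[y] - centre) / scale)
        out.append(
            PrePostSeries(
                taxon=taxon,
                exporter=exporter,
                purpose=purpose,
                source=source,
                calendar_year=np.array(cal),
                year_centred=np.array(t),
                state=np.array(state),
                volume_std=np.array(v),
                centre=centre,
                scale=scale,
            )
        )
    return out


def _audit(audit: list[dict] | None, key: tuple, reason: str) -> None:
    if audit is not None:
        audit.append({"series_key": list(key), "reason": reason})


COEF_NAMES = ("beta1", "beta2", "beta3", "beta4", "beta5")


@dataclass
class PrePostFit:
    """Posterior draws and summaries of the counterfactual model."""

    taxa: list[str]
    exporters: list[str]
    years: list[int]
    series_keys: list[tuple[str, str, str, str]]
    series_taxon: dict[tuple[str, str, str, str], str]
    alpha: np.ndarray  # (chains, draws)
    beta: np.ndarray  # (chains, draws, 5) population-level slopes
    taxon_beta: np.ndarray  # (chains, draws, 5, J) taxon-level slopes
    sigma: np.ndarray  # (chains, draws)
    rhat_max: float
    settings: McmcSettings
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def converged(self) -> bool:
        return self.rhat_max < RHAT_LIMIT

    def coefficient_draws(self, name: str, taxon: str | None = None) -> np.ndarray:
        """Flat draws for a population or taxon-level coefficient."""
        m = COEF_NAMES.index(name)
        if taxon is None:
            return self.beta[:, :, m].ravel()
        j = self.taxa.index(taxon)
        return self.taxon_beta[:, :, m, j].ravel()


def summarize_coefficient(draws: np.ndarray, hdi_prob: float = 0.90) -> CoefSummary:
    """Median, 90% HDI and probability of direction for a draw vector."""
    return summarize_draws(draws, hdi_prob=hdi_prob)


def fit_prepost(
    series: Sequence[PrePostSeries],
    settings: McmcSettings | None = None,
    fixed_sd: float = 2.5,
    group_sd_scale: float = 2.0,
    hdi_prob: float = 0.90,
) -> PrePostFit:
    """Fit the hierarchical counterfactual model to standardized series."""
    if len(series) < 2:
        raise ValueError("need at least 2 series to fit the hierarchical model")
    settings = settings or McmcSettings()

    taxa = sorted({s.taxon for s in series})
    exporters = sorted({s.exporter for s in series})
    years = sorted({int(y) for s in series for y in s.calendar_year})
    J, K, L = len(taxa), len(exporters), len(years)
    jdx = {t: i for i, t in enumerate(taxa)}
    kdx = {e: i for i, e in enumerate(exporters)}
    ldx = {y: i for i, y in enumerate(years)}

    rows_y: list[float] = []
    design: list[np.ndarray] = []
    p = 6 + J + K + L + 5 * J
    for s in series:
        j, k = jdx[s.taxon], kdx[s.exporter]
        for cy, t, st, v in zip(s.calendar_year, s.year_centred, s.state, s.volume_std):
            sa = 1.0 if st == "post_actual" else 0.0
            sq = 1.0 if st == "post_quota" else 0.0
            x = np.zeros(p)
            x[0] = 1.0
            x[1], x[2], x[3], x[4], x[5] = sa, sq, t, sa * t, sq * t
            base = 6
            x[base + j] = 1.0
            x[base + J + k] = 1.0
            x[base + J + K + ldx[int(cy)]] = 1.0
            rb = base + J + K + L
            covs = (sa, sq, t, sa * t, sq * t)
            for m in range(5):
                x[rb + m * J + j] = covs[m]
            design.append(x)
            rows_y.append(float(v))
    X = np.vstack(design)
    y = np.asarray(rows_y)

    base = 6
    rb = base + J + K + L
    blocks = [
        ("taxon", np.arange(base, base + J)),
        ("exporter", np.arange(base + J, base + J + K)),
        ("year", np.arange(base + J + K, base + J + K + L)),
    ] + [(f"b{m+1}", np.arange(rb + m * J, rb + (m + 1) * J)) for m in range(5)]

    draws = sample_hierarchical_gaussian(
        X, y, fixed_idx=np.arange(6), blocks=blocks, settings=settings,
        fixed_sd=fixed_sd, group_sd_scale=group_sd_scale,
    )
    theta = draws["theta"]  # (c, s, p)
    alpha = theta[:, :, 0]
    beta = theta[:, :, 1:6]
    taxon_dev = np.stack(
        [theta[:, :, rb + m * J : rb + (m + 1) * J] for m in range(5)], axis=2
    )  # (c, s, 5, J)
    taxon_beta = beta[:, :, :, None] + taxon_dev

    diag = {
        "alpha": alpha,
        "beta": beta,
        "sigma": draws["sigma"],
    }
    rhat = max_rhat(diag)

    fit = PrePostFit(
        taxa=taxa,
        exporters=exporters,
        years=years,
        series_keys=[s.key for s in series],
        series_taxon={s.key: s.taxon for s in series},
        alpha=alpha,
        beta=beta,
        taxon_beta=taxon_beta,
        sigma=draws["sigma"],
        rhat_max=rhat,
        settings=settings,
    )

    rows = []
    for m, name in enumerate(COEF_NAMES):
        s = summarize_draws(beta[:, :, m], hdi_prob=hdi_prob)
        rows.append({"coefficient": name, "level": "population", **s._asdict()})
    s = summarize_draws(alpha, hdi_prob=hdi_prob)
    rows.append({"coefficient": "alpha", "level": "population", **s._asdict()})
    s = summarize_draws(draws["sigma"], hdi_prob=hdi_prob)
    rows.append({"coefficient": "sigma", "level": "population", **s._asdict()})
    for j, taxon in enumerate(taxa):
        for m, name in enumerate(COEF_NAMES):
            s = summarize_draws(taxon_beta[:, :, m, j], hdi_prob=hdi_prob)
            rows.append({"coefficient": name, "level": taxon, **s._asdict()})
    fit.summaries = pd.DataFrame(rows)
    return fit


@dataclass(frozen=True)
class PanelCall:
    """Classification of one series for one contrast (quota or volume)."""

    series_key: tuple[str, str, str, str]
    which: str  # "quota_level" | "actual_volume"
    panel: int
    pre_trend: str  # down | flat | up
    step: str  # down | none | up
    trend_change: str  # down | none | up


@dataclass(frozen=True)
class PanelClass:
    """Both contrasts for one series."""

    series_key: tuple[str, str, str, str]
    quota_panel: int
    volume_panel: int
    quota_call: PanelCall
    volume_call: PanelCall


def _direction(draws: np.ndarray, neutral: str) -> str:
    s = summarize_draws(draws)
    if s.pd >= CLEAR_PD:
        return "up" if s.median > 0 else "down"
    return neutral


def classify_panel(
    fit: PrePostFit,
    series_key: tuple[str, str, str, str],
    which: str = "quota_level",
    grid: dict[tuple[str, str], int] | None = None,
) -> PanelCall:
    """Map a series' taxon-level posterior onto the 18-panel taxonomy.

    ``which`` selects the contrast: "quota_level" uses the quota step and
    trend-change coefficients (b2, b5), "actual_volume" uses b1 and b4;
    the pre-quota trend is b3 in both.  Requires a converged fit.
    """
    if not fit.converged:
        raise ValueError(f"fit has not converged (max R-hat {fit.rhat_max:.3f}); classification blocked")
    if which not in ("quota_level", "actual_volume"):
        raise ValueError(f"unknown contrast: {which!r}")
    grid = grid or PANEL_GRID
    taxon = fit.series_taxon[series_key]
    step_coef, trend_coef = ("beta2", "beta5") if which == "quota_level" else ("beta1", "beta4")
    pre_trend = _direction(fit.coefficient_draws("beta3", taxon), "flat")
    step = _direction(fit.coefficient_draws(step_coef, taxon), "none")
    trend_change = _direction(fit.coefficient_draws(trend_coef, taxon), "none")
    base = grid[(pre_trend, step)]
    panel = base + (9 if trend_change != "none" else 0)
    return PanelCall(
        series_key=series_key, which=which, panel=panel,
        pre_trend=pre_trend, step=step, trend_change=trend_change,
    )


def classify_all(fit: PrePostFit, grid: dict[tuple[str, str], int] | None = None) -> list[PanelClass]:
    """Classify every fitted series for both contrasts."""
    out = []
    for key in fit.series_keys:
        q = classify_panel(fit, key, "quota_level", grid)
        v = classify_panel(fit, key, "actual_volume", grid)
        out.append(PanelClass(series_key=key, quota_panel=q.panel, volume_panel=v.panel, quota_call=q, volume_call=v))
    return out


def write_fit_outputs(fit: PrePostFit, outdir: str | Path) -> None:
    """Write coefficient summaries, panel calls and draws under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fit.summaries.to_csv(outdir / "coefficients.csv", index=False)
    if fit.converged:
        panels = classify_all(fit)
        pd.DataFrame(
            [
                {
                    "taxon": p.series_key[0],
                    "exporter": p.series_key[1],
                    "purpose": p.series_key[2],
                    "source": p.series_key[3],
                    "quota_panel": p.quota_panel,
                    "volume_panel": p.volume_panel,
                }
                for p in panels
            ]
        ).to_csv(outdir / "panels.csv", index=False)
    c, s, _ = fit.beta.shape
    draw_df = pd.DataFrame(
        {
            "chain": np.repeat(np.arange(c), s),
            "draw": np.tile(np.arange(s), c),
            "alpha": fit.alpha.ravel(),
            "sigma": fit.sigma.ravel(),
            **{name: fit.beta[:, :, m].ravel() for m, name in enumerate(COEF_NAMES)},
        }
    )
    draw_df.to_csv(outdir / "draws.csv", index=False)
    with open(outdir / "convergence.json", "w", encoding="utf-8") as fh:
        import json

        json.dump({"rhat_max": fit.rhat_max, "converged": fit.converged}, fh, indent=2)
        fh.write("\n")
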