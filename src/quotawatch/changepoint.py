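"""Adaptive-management analysis: quota-update counts and stagnation point.

Quotas that are adjusted as populations and threats change are a
hallmark of adaptive management.  We count, for every quota time series
(grouped by taxon, exporter, purpose, term, source), how many times the
amount changed relative to the preceding year, and relate the number of
changes to series length with a continuous piecewise-linear (hinge)
Bayesian model:

    n_changes ~ N(a + s_pre * min(L, omega) + s_post * max(L - omega, 0), sigma^2)

The hinge location omega is the stagnation point: beyond it, extra
years of quota length no longer bring extra updates.  Slope priors are
N(1, 2) — a 1:1 update-per-year relationship being the a-priori ideal
of adaptive management — and omega has a broad N(10, 5) prior truncated
to the feasible length range.  The posterior is explored with an
affine-invariant ensemble sampler.
"""

from __future__ import annotations

import json
import warnings as _warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import emcee
import numpy as np
import pandas as pd

from ._mcmc import CoefSummary, McmcSettings, RHAT_LIMIT, max_rhat, summarize_draws
from .ingest import QuotaRecord

__all__ = [
    "UpdateSeries",
    "ChangePointFit",
    "ChangePointPriors",
    "count_changes",
    "build_update_series",
    "fit_changepoint",
    "expected_changes",
    "per_year_rate",
    "write_update_series",
]


@dataclass(frozen=True)
class UpdateSeries:
    """One uninterrupted quota time series and its update count."""

    taxon: str
    exporter: str
    purpose: str
    term: str
    source: str
    length: int
    n_changes: int
    contains_zero_quota: bool = False
    first_year: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_changes <= self.length - 1:
            raise ValueError("n_changes must lie in [0, length - 1]")


def count_changes(amounts: Sequence[float]) -> int:
    """Number of year-on-year changes in a gap-free amount sequence."""
    if len(amounts) < 2:
        raise ValueError("need at least 2 years to count changes")
    a = list(amounts)
    return sum(a[t] != a[t - 1] for t in range(1, len(a)))


def build_update_series(
    quotas: Sequence[QuotaRecord],
    min_length: int = 2,
) -> tuple[list[UpdateSeries], list[UpdateSeries]]:
    """Group quotas into series, split at year gaps, count changes.

    Series are keyed by (taxon, exporter, purpose, term, source); a year
    with no published quota ends the series and starts a new one, since
    splicing across gaps would conflate "unchanged" with "re-issued".
    Returns ``(modelled, excluded)``: series containing any zero quota
    (bans) are excluded from modelling, as are series shorter than
    ``min_length`` years.
    """
    groups: dict[tuple, dict[int, int]] = defaultdict(dict)
    for q in quotas:
        scope = q.scope
        tkey = "ALL" if scope.terms == "ALL" else "|".join(sorted(scope.terms))
        skey = "ALL" if scope.sources == "ALL" else "|".join(sorted(scope.sources))
        pkey = "ALL" if scope.purposes == "ALL" else "|".join(sorted(scope.purposes))
        groups[(q.taxon, q.party, pkey, tkey, skey)][q.year] = q.amount

    modelled: list[UpdateSeries] = []
    excluded: list[UpdateSeries] = []
    for (taxon, party, pkey, tkey, skey), by_year in sorted(groups.items()):
        years = sorted(by_year)
        runs: list[list[int]] = [[years[0]]]
        for y in years[1:]:
            if y == runs[-1][-1] + 1:
                runs[-1].append(y)
            else:
                runs.append([y])
        for run in runs:
            if len(run) < min_length:
                continue
            amounts = [by_year[y] for y in run]
            s = UpdateSeries(
                taxon=taxon, exporter=party, purpose=pkey, term=tkey, source=skey,
                length=len(run), n_changes=count_changes(amounts),
                contains_zero_quota=any(a == 0 for a in amounts),
                first_year=run[0],
            )
            (excluded if s.contains_zero_quota else modelled).append(s)
    return modelled, excluded


@dataclass(frozen=True)
class ChangePointPriors:
    """Prior settings for the hinge model."""

    slope_mean: float = 1.0
    slope_sd: float = 2.0
    omega_mean: float = 10.0
    omega_sd: float = 5.0
    omega_bounds: tuple[float, float] = (2.0, 27.0)
    intercept_sd: float = 5.0
    sigma_scale: float = 2.0


def hinge_mean(length, intercept, slope_pre, slope_post, omega):
    """Continuous two-segment mean: slope_pre below omega, slope_post above."""
    L = np.asarray(length, dtype=float)
    return intercept + slope_pre * np.minimum(L, omega) + slope_post * np.maximum(L - omega, 0.0)


@dataclass
class ChangePointFit:
    """Posterior draws and summaries for the hinge change-point model."""

    intercept: np.ndarray  # (chains, draws)
    slope_pre: np.ndarray
    slope_post: np.ndarray
    omega: np.ndarray
    sigma: np.ndarray
    rhat_max: float
    settings: McmcSettings
    lengths_observed: tuple[int, int] = (2, 27)
    summaries: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def converged(self) -> bool:
        return self.rhat_max < RHAT_LIMIT

    def summary(self, name: str, hdi_prob: float = 0.90) -> CoefSummary:
        """Equal-tailed 90% credible interval (the conventional "CI")."""
        return summarize_draws(getattr(self, name), hdi_prob=hdi_prob, interval="quantile")


def _log_posterior(params: np.ndarray, L: np.ndarray, n: np.ndarray, pr: ChangePointPriors) -> np.ndarray:
    """Vectorized log posterior over an ensemble of parameter vectors."""
    a, s_pre, s_post, omega, sigma = params.T
    lp = np.full(a.shape, -np.inf)
    lo, hi = pr.omega_bounds
    ok = (sigma > 0) & (omega >= lo) & (omega <= hi)
    if not np.any(ok):
        return lp
    mu = (
        a[ok, None]
        + s_pre[ok, None] * np.minimum(L[None, :], omega[ok, None])
        + s_post[ok, None] * np.maximum(L[None, :] - omega[ok, None], 0.0)
    )
    loglik = -n.size * np.log(sigma[ok]) - 0.5 * np.sum((n[None, :] - mu) ** 2, axis=1) / sigma[ok] ** 2
    logprior = (
        -0.5 * (a[ok] / pr.intercept_sd) ** 2
        - 0.5 * ((s_pre[ok] - pr.slope_mean) / pr.slope_sd) ** 2
        - 0.5 * ((s_post[ok] - pr.slope_mean) / pr.slope_sd) ** 2
        - 0.5 * ((omega[ok] - pr.omega_mean) / pr.omega_sd) ** 2
        - 0.5 * (sigma[ok] / pr.sigma_scale) ** 2
    )
    lp[ok] = loglik + logprior
    return lp


def fit_changepoint(
    series: Sequence[UpdateSeries],
    settings: McmcSettings | None = None,
    priors: ChangePointPriors | None = None,
    walkers_per_chain: int = 16,
    hdi_prob: float = 0.90,
) -> ChangePointFit:
    """Sample the hinge model posterior over (length, n_changes) pairs.

    Runs ``settings.chains`` independent walker ensembles; draws from
    each ensemble form one diagnostic chain.
    """
    settings = settings or McmcSettings()
    priors = priors or ChangePointPriors()
    if len(series) < 30:
        _warnings.warn(f"only {len(series)} series; the change point may be weakly identified")
    L = np.array([s.length for s in series], dtype=float)
    n = np.array([s.n_changes for s in series], dtype=float)
    lo, hi = max(priors.omega_bounds[0], L.min()), min(priors.omega_bounds[1], L.max())
    pr = ChangePointPriors(
        slope_mean=priors.slope_mean, slope_sd=priors.slope_sd,
        omega_mean=priors.omega_mean, omega_sd=priors.omega_sd,
        omega_bounds=(lo, hi), intercept_sd=priors.intercept_sd,
        sigma_scale=priors.sigma_scale,
    )

    # coarse profile fit over omega to seed all walkers in the dominant mode
    best = None
    for om in np.arange(lo, hi + 1e-9, 0.5):
        A = np.column_stack([np.ones_like(L), np.minimum(L, om), np.maximum(L - om, 0.0)])
        coef, res, *_ = np.linalg.lstsq(A, n, rcond=None)
        sse = float(np.sum((n - A @ coef) ** 2))
        if best is None or sse < best[0]:
            best = (sse, coef, om)
    sse0, coef0, om0 = best
    sigma0 = max(np.sqrt(sse0 / max(len(n) - 4, 1)), 0.05)
    centre = np.array([coef0[0], coef0[1], coef0[2], om0, sigma0])

    ndim = 5
    names = ("intercept", "slope_pre", "slope_post", "omega", "sigma")
    chain_draws: dict[str, list[np.ndarray]] = {k: [] for k in names}
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    for c in range(settings.chains):
        rng = np.random.default_rng(seeds[c])
        p0 = centre[None, :] + rng.normal(0.0, 0.02, size=(walkers_per_chain, ndim)) * np.maximum(np.abs(centre), 1.0)
        p0[:, 3] = np.clip(p0[:, 3], lo + 1e-3, hi - 1e-3)
        p0[:, 4] = np.abs(p0[:, 4]) + 0.01
        sampler = emcee.EnsembleSampler(
            walkers_per_chain, ndim, _log_posterior, args=(L, n, pr), vectorize=True,
        )
        sampler.random_state = np.random.RandomState(int(seeds[c].generate_state(1)[0] >> 1)).get_state()
        state = sampler.run_mcmc(p0, settings.warmup, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, settings.samples, progress=False)
        flat = sampler.get_chain()  # (samples, walkers, ndim)
        for i, k in enumerate(names):
            # interleave walkers into one diagnostic chain per ensemble
            chain_draws[k].append(flat[:, :, i].reshape(-1))

    draws = {k: np.vstack(v) for k, v in chain_draws.items()}  # (chains, samples*walkers)
    rhat = max_rhat(draws)
    fit = ChangePointFit(
        intercept=draws["intercept"],
        slope_pre=draws["slope_pre"],
        slope_post=draws["slope_post"],
        omega=draws["omega"],
        sigma=draws["sigma"],
        rhat_max=rhat,
        settings=settings,
        lengths_observed=(int(L.min()), int(L.max())),
    )
    fit.summaries = pd.DataFrame(
        [
            {"parameter": k, **summarize_draws(draws[k], hdi_prob=hdi_prob, interval="quantile")._asdict()}
            for k in names
        ]
    )
    return fit


def expected_changes(
    fit: ChangePointFit,
    length: float,
    hdi_prob: float = 0.90,
) -> CoefSummary:
    """Posterior of the expected number of updates at a given length."""
    if not fit.converged:
        raise ValueError(f"fit has not converged (max R-hat {fit.rhat_max:.3f})")
    lo, hi = fit.lengths_observed
    if not lo <= length <= hi:
        _warnings.warn(f"length {length} outside observed support [{lo}, {hi}]")
    m = hinge_mean(length, fit.intercept, fit.slope_pre, fit.slope_post, fit.omega)
    return summarize_draws(m, hdi_prob=hdi_prob, interval="quantile")


def per_year_rate(n_changes: float, length: float, ndigits: int = 2) -> float:
    """Updates per year of series length, rounded for reporting."""
    if length <= 0:
        raise ValueError("length must be positive")
    return round(n_changes / length, ndigits)


def write_update_series(series: Sequence[UpdateSeries], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "taxon": s.taxon, "exporter": s.exporter, "purpose": s.purpose,
                "term": s.term, "source": s.source, "first_year": s.first_year,
                "length": s.length, "n_changes": s.n_changes,
                "contains_zero_quota": int(s.contains_zero_quota),
            }
            for s in series
        ]
    ).to_csv(path, index=False)


def write_fit_json(fit: ChangePointFit, path: str | Path) -> None:
    out = {
        row["parameter"]: {k: row[k] for k in ("median", "hdi_low", "hdi_high", "pd")}
        for _, row in fit.summaries.iterrows()
    }
    out["rhat_max"] = fit.rhat_max
    out["converged"] = fit.converged
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
        fh.write("\n")
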