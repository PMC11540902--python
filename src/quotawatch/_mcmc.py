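"""Posterior sampling machinery shared by the Bayesian modules.

The hierarchical Gaussian regression is sampled with a two-block Gibbs
scheme: given the variance components, all location parameters (fixed
effects plus every random-effect level) are jointly Gaussian and are
drawn exactly via a sparse-free Cholesky solve; given the locations,
each group standard deviation and the residual standard deviation are
updated by univariate slice sampling in log space.  Joint draws of the
location block avoid the slow mixing of one-at-a-time updates.

Convergence is checked with split-R-hat (threshold 1.02) across
independent chains; interval summaries use highest-density intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import arviz as az
import numpy as np

__all__ = [
    "McmcSettings",
    "CoefSummary",
    "summarize_draws",
    "probability_of_direction",
    "max_rhat",
    "slice_sample",
    "sample_hierarchical_gaussian",
]

RHAT_LIMIT = 1.02


@dataclass(frozen=True)
class McmcSettings:
    """Chain configuration: defaults are 4 chains of 500 warmup + 500 draws."""

    chains: int = 4
    warmup: int = 500
    samples: int = 500
    seed: int = 0


class CoefSummary(NamedTuple):
    """Posterior summary: median, 90% HDI bounds, probability of direction."""

    median: float
    hdi_low: float
    hdi_high: float
    pd: float


def probability_of_direction(draws: np.ndarray) -> float:
    """Share of draws (percent, >= 50) on the median's side of zero.

    Exactly-zero draws count half to each side, so symmetric posteriors
    report ~50% and one-signed posteriors 100%.
    """
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty draws")
    med = np.median(d)
    sign = 1.0 if med >= 0 else -1.0
    share = np.mean(np.sign(d) * sign > 0) + 0.5 * np.mean(d == 0)
    return float(max(share, 1.0 - share) * 100.0)


def summarize_draws(
    draws: np.ndarray, hdi_prob: float = 0.90, interval: str = "hdi"
) -> CoefSummary:
    """Median, 90% interval and probability of direction for one parameter.

    ``interval`` selects the highest-density interval ("hdi") or the
    equal-tailed quantile interval ("quantile", the usual "CI").
    """
    d = np.asarray(draws, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty draws")
    if interval == "hdi":
        lo, hi = az.hdi(d, hdi_prob=hdi_prob)
    elif interval == "quantile":
        tail = (1.0 - hdi_prob) / 2.0
        lo, hi = np.quantile(d, [tail, 1.0 - tail])
    else:
        raise ValueError(f"unknown interval type: {interval!r}")
    return CoefSummary(
        median=float(np.median(d)),
        hdi_low=float(lo),
        hdi_high=float(hi),
        pd=probability_of_direction(d),
    )


def max_rhat(chain_draws: dict[str, np.ndarray]) -> float:
    """Largest split-R-hat over a dict of (chains, draws[, ...]) arrays."""
    worst = 1.0
    for name, arr in chain_draws.items():
        arr = np.asarray(arr)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
        r = az.rhat(az.convert_to_dataset(flat))
        worst = max(worst, float(np.nanmax(r["x"].values)))
    return worst


def slice_sample(
    x0: float,
    logf: Callable[[float], float],
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> float:
    """One univariate slice-sampling update (stepping-out procedure)."""
    logy = logf(x0) + np.log(rng.uniform())
    u = rng.uniform()
    left = x0 - w * u
    right = left + w
    j = int(np.floor(max_steps * rng.uniform()))
    k = max_steps - 1 - j
    while j > 0 and logf(left) > logy:
        left -= w
        j -= 1
    while k > 0 and logf(right) > logy:
        right += w
        k -= 1
    for _ in range(200):
        x1 = rng.uniform(left, right)
        if logf(x1) > logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pathological shrinkage; keep current value


def _log_halfnormal_sd(log_s: float, scale: float, n: int, ssq: float) -> float:
    """Log conditional of a scale parameter in log space.

    ``n`` values with sum of squares ``ssq`` are iid N(0, s^2); the
    prior on s is half-normal(scale); includes the log-space Jacobian.
    """
    s2 = np.exp(2.0 * log_s)
    return -n * log_s - 0.5 * ssq / s2 - 0.5 * s2 / scale**2 + log_s


def sample_hierarchical_gaussian(
    X: np.ndarray,
    y: np.ndarray,
    fixed_idx: np.ndarray,
    blocks: Sequence[tuple[str, np.ndarray]],
    settings: McmcSettings,
    fixed_sd: float = 2.5,
    group_sd_scale: float = 2.0,
    sigma_scale: float = 2.0,
) -> dict[str, np.ndarray]:
    """Gibbs-sample theta, sigma and group s.d.s of a Gaussian regression.

    ``y ~ N(X theta, sigma^2)``; columns in ``fixed_idx`` get independent
    N(0, fixed_sd^2) priors, and each ``(name, idx)`` block in ``blocks``
    shares a N(0, tau_name^2) prior with tau_name ~ half-normal.

    Returns draws with a leading (chains, samples) shape: ``"theta"`` of
    shape (chains, samples, p), ``"sigma"`` and one ``"tau_<name>"`` per
    block.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y

    theta_draws = np.empty((settings.chains, settings.samples, p))
    sigma_draws = np.empty((settings.chains, settings.samples))
    tau_draws = {name: np.empty((settings.chains, settings.samples)) for name, _ in blocks}

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    for c in range(settings.chains):
        rng = np.random.default_rng(seeds[c])
        theta = np.zeros(p)
        sigma = 1.0
        taus = {name: 1.0 for name, _ in blocks}
        total = settings.warmup + settings.samples
        for it in range(total):
            # --- exact Gaussian draw of the full location block
            prior_prec = np.zeros(p)
            prior_prec[fixed_idx] = 1.0 / fixed_sd**2
            for name, idx in blocks:
                prior_prec[idx] = 1.0 / taus[name] ** 2
            Q = XtX / sigma**2 + np.diag(prior_prec)
            L = np.linalg.cholesky(Q)
            mean = np.linalg.solve(L.T, np.linalg.solve(L, Xty / sigma**2))
            z = rng.standard_normal(p)
            theta = mean + np.linalg.solve(L.T, z)

            # --- residual s.d. via slice sampling in log space
            resid = y - X @ theta
            rss = float(resid @ resid)
            log_sigma = slice_sample(
                np.log(sigma),
                lambda ls: _log_halfnormal_sd(ls, sigma_scale, n, rss),
                rng,
            )
            sigma = float(np.exp(log_sigma))

            # --- group s.d.s
            for name, idx in blocks:
                u = theta[idx]
                ssq = float(u @ u)
                log_tau = slice_sample(
                    np.log(taus[name]),
                    lambda lt: _log_halfnormal_sd(lt, group_sd_scale, len(idx), ssq),
                    rng,
                )
                taus[name] = float(np.exp(log_tau))

            if it >= settings.warmup:
                j = it - settings.warmup
                theta_draws[c, j] = theta
                sigma_draws[c, j] = sigma
                for name in taus:
                    tau_draws[name][c, j] = taus[name]

    out: dict[str, np.ndarray] = {"theta": theta_draws, "sigma": sigma_draws}
    for name, arr in tau_draws.items():
        out[f"tau_{name}"] = arr
    return out
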