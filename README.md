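# quotawatch

Compliance, trend and coverage analysis for wildlife-trade export quotas.

Many range states manage international trade in protected species by
publishing annual export quotas: a maximum number of individuals (or
derived products) that may leave the country in a calendar year, with a
zero quota acting as a ban. Whether this system works hinges on three
testable properties — quotas are complied with, they relate sensibly to
the trade that preceded them, and they are updated as conditions change.
`quotawatch` is a library for testing all three against quota registries
and trade ledgers in the CSV dialects used by the CITES ecosystem
(Species+ quota exports; CITES Trade Database comparative tabulations),
for conservation scientists and trade analysts.

## What it computes

**Cleaning and scope parsing.** Quota rows carry their scope — commodity
*term* (live, skins, meat…), specimen *source* (wild, captive-bred,
ranched…) and trade *purpose* — as a free-text note. A token grammar over
a bundled controlled vocabulary turns each note into a structured scope,
applying the registry conventions: an unspecified source means
wild-sourced; a bare `all` covers everything; `all, live` covers live
individuals from all sources for all purposes. The cleaning chain
removes exact duplicates, back-dated quotas created by taxonomic splits,
sentinel amounts (−1/NA) and multi-year or re-export-only quotas, with a
full removal audit.

**Compliance.** For each live quota, traded volume is assembled from
both reporter perspectives (exporter- and importer-reported) and the
percent use computed as `100 × volume / quota`. Use ≤ 100% is compliant;
strict excess is a breach; any trade under a zero quota is a subversion.
Quotas whose scopes overlap for the same party/taxon/year, and species
whose live quota coexists with quotas under other terms, are excluded
from the compliance set (with audit reasons). A ranked table surfaces
quotas compliant in the exporter's figures but breached in the
importer's.

**Pre/post counterfactual model.** For series with ≥5 years of trade
before and after the first quota, volumes are standardized per series
(centred on the last pre-quota year, scaled by the series s.d.) and fit
with a hierarchical Gaussian regression

    volume ~ N(mu, sigma^2)
    mu = alpha[j,k,l] + b1[j]*post_actual + b2[j]*post_quota + b3[j]*year
         + b4[j]*post_actual*year + b5[j]*post_quota*year

with varying intercepts by taxon *j*, exporter *k* and calendar year *l*,
and all slopes varying by taxon. `b1`/`b2` are the counterfactual steps
of post-quota volumes / quota levels above the extrapolated pre-quota
trend; `b4`/`b5` the changes in trend. Posteriors are summarized by
median, 90% highest-density interval and probability of direction (pd),
and each series is classified onto an 18-panel taxonomy of
pre-to-post trajectories (3 pre-trends × 3 steps, with and without a
clear trend change; a direction is *clear* when pd ≥ 97.5%).

**Update stagnation.** Quota series are grouped by taxon, exporter,
purpose, term and source; the number of year-on-year changes is related
to series length with a continuous hinge model
`E[n_changes] = a + s_pre·min(L, ω) + s_post·max(L − ω, 0)`, whose
change point ω is the length beyond which updating stagnates.

**Coverage gaps.** Live wild-sourced trade not covered by any quota is
quantified per year, crossed with the IUCN Red List category in force at
the time of trade and with a flag for species likely threatened by
international trade.

**Synthetic data.** A fully truth-tracked generator emulates all three
input tables with controllable compliance rates, reporter discrepancies,
trend structures and update regimes, so the entire pipeline is testable
without any download; every planted artefact is recorded in a JSON truth
sidecar.

All Bayesian fitting is self-contained: a blocked Gibbs sampler (exact
joint Gaussian updates for all location parameters, slice sampling for
variance components) for the hierarchical model, and an affine-invariant
ensemble sampler for the nonlinear hinge, with split-R-hat < 1.02 as the
convergence bar.

## Worked example

```sh
python examples/04_update_stagnation.py
```

```
changes in [100, 200, 200, 150]: 2
slope_pre: median 0.28 [90% CI 0.27, 0.30]
slope_post: median 0.03 [90% CI -0.06, 0.10]
omega: median 17.18 [90% CI 15.68, 18.78]
a 15-year quota is updated ~4.1 times (0.27/yr)
a 25-year quota is updated ~4.9 times (0.2/yr)
```

Six hundred series were simulated with updates stagnating after 17
years (0.3 changes per year before, none after). The fit recovers the
pre-stagnation slope (0.28/yr), finds no post-stagnation association,
and places the change point at 17.2 years with a 90% CI of about ±1.5
years — so a 25-year quota accrues barely more revisions than a 15-year
one, the signature of non-adaptive management.

The other scripts in `examples/` walk through note parsing and cleaning
(01), compliance and the importer-discrepancy table (02), the
counterfactual model and panel classification (03), coverage gaps (05)
and the full pipeline (06). The pipeline is also scriptable from a
shell:

```sh
quotawatch synth --config scenario.yaml --out inputs/
quotawatch run --config run.yaml
```

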