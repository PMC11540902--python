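# Methods

This note records the models, conventions and design choices behind
`quotawatch`, at the level a maintainer or reviewer needs to judge what
the package does and what its tests do and do not demonstrate.

## Quota cleaning and note parsing

Quota registries store a quota's scope as a free-text note. We parse
notes with a token grammar rather than a lookup of literal strings: the
note is split on commas, semicolons and the word "and", each token is
matched (case-, whitespace- and Unicode-NFC-insensitively) against a
controlled vocabulary of term, source and purpose surface forms, and
unmatched tokens are preserved in an `unparsed` bucket with a warning —
never silently dropped. Defaulting follows registry convention: an
unspecified source means wild-sourced trade; unspecified terms or
purposes are unconstrained; a bare `all` widens every dimension, and
`all` paired with detail widens only the dimensions the detail leaves
open. The vocabulary ships as an editable YAML file; region tags
(Sabah, Sarawak, Peninsular Malaysia) are recognized for the regional
quota summing step.

Comparability — whether a quota's terms can be expressed as a count of
whole animals — is a property of the term set: the scope is comparable
iff every term is in the vocabulary's `countable_terms` list. A quota
mixing skins with meat is therefore incomparable, while live or skins
alone are countable. The list is configuration, not inference, because
no formal convertibility rule exists.

The cleaning chain (exact-duplicate removal → back-dated split-quota
removal → subspecies resolution → validity filter → note parsing) is
idempotent, order-stable, and logs every removal with a reason
(`sentinel_amount`, `multi_year_span`, `reexport_only`, …). Taxonomic
split events are supplied as configuration (parent, child, adoption
year): a pre-adoption child quota is removed only when it duplicates a
parent quota in party, year, amount and notes. Multi-year spans are
detected by a month-year-to-month-year pattern crossing calendar years.

## Compliance conventions

* Percent use is `100 × volume / quota`; undefined for zero quotas.
* The compliance boundary is strict: volume = quota is compliant, only
  strict excess breaches. Any reported trade under a zero quota is a
  subversion, from either reporter's perspective.
* Rounding is half-up (away from zero): one decimal for headline
  figures, nearest integer for table cells. One published table cell
  prints 82% where 1222/1500 = 81.47% rounds to 81%; we follow
  arithmetic and note the single-cell divergence rather than
  reverse-engineering an undocumented rounding rule.
* Mean percent use is reported both including untraded quotas (as 0%)
  and excluding them; undefined percents (zero quotas) are excluded
  from both means. The traded-only mean can only be ≥ the all-quota
  mean.
* Importer-reported quantities are attributed to the ledger's stated
  year; the reporting lag between exporter and importer years is not
  reconciled.
* Overlapping quotas (same party/taxon/year, intersecting scopes) are
  all removed, since volume cannot be attributed among them. Species
  holding a live quota alongside quotas under other terms are excluded
  from the compliance set, because live animals may lawfully move under
  the other quota; a config override list supplements the automatic
  rule. Family- and genus-level quotas are excluded from species-level
  matching by default (policy switch `include_higher_ranks`).
* The discrepancy table ranks zero-quota subversions first (by importer
  volume), then importer-only breaches by integer percent use, with
  ties broken by absolute excess volume and then key order.

## The pre/post counterfactual model

Series construction: for each (taxon, exporter, purpose, source) with at
least 5 contiguous quota years and 5 pre-quota years (10-year pre window
by default; years with no trade record count as zero trade), volumes are
centred on the final pre-quota year and scaled by the series standard
deviation (ddof = 1, computed over pre and post actual volumes).
Per-series ("group-level") standardization is what makes volumes
comparable across species whose trade differs by orders of magnitude;
series with zero variance are excluded with an audit reason. Quota
levels are standardized with the same centre and scale so the two
post-quota states are directly contrastable. De-standardization with
the stored centre/scale recovers raw volumes exactly (tested).

The model is the hierarchical Gaussian regression given in the README:
varying intercepts by taxon, exporter and calendar-year factor
(implemented as crossed, not nested), with all five slopes varying by
taxon. A single homoscedastic residual s.d. is used. Priors are
zero-centred and diffuse: N(0, 2.5²) for fixed effects, half-normal(2)
for the group standard deviations and residual s.d.; all are
configurable. Defaults are 4 chains × 500 warmup + 500 sampling
iterations.

Sampling is a two-block Gibbs scheme written for this package: given
variances, all location parameters are jointly Gaussian and drawn
exactly via one Cholesky solve per iteration (avoiding the slow mixing
of coordinate-wise updates); given locations, each s.d. is updated by
univariate slice sampling in log space. Convergence requires split-
R-hat < 1.02 over independent chains; an unconverged fit is flagged and
blocks panel classification.

Identifiability caveat: the continuous centred-year covariate lies in
the span of the calendar-year factor plus the taxon intercepts, so the
trend coefficients are separated from temporal shocks only through the
hierarchical shrinkage priors. With few series this leaves a visible
wobble (±0.1–0.3 s.d.) in individual fits; across replicates the
posteriors remain approximately calibrated (90% HDIs cover planted
coefficients at ≈ 90% over 20-replicate batches, tested).

### Panel taxonomy

Each series is classified, separately for quota levels (b2, b5) and
actual volumes (b1, b4), by three component calls: pre-quota trend
(b3), step, and trend change. A direction is *clear* when ≥ 97.5% of
the posterior shares the median's sign; otherwise the component is
flat/none. The 18 panels are an explicit 3 × 3 × 2 grid — pre-trend
(flat, up, down) × step (none, up, down) as panels 1–9 with no clear
trend change, and the same grid shifted by 9 when a trend change is
clear. Panel 1 is "no clear change anywhere", panel 2 "step increase
with no trend change". The mapping ships as a replaceable module
constant (`PANEL_GRID`); published panel numberings that distinguish
post-change slope magnitudes (not just directions) cannot be fully
reproduced by a direction-only grid, and the mapping here should be
treated as this package's own documented convention.

## The update-stagnation model

Update series group quotas by taxon, exporter, purpose, term and source.
A calendar-year gap ends a series and starts a new one — splicing across
gaps would conflate "unchanged" with "re-issued". Series containing any
zero quota (bans) are excluded from modelling but returned flagged;
minimum modelled length is 2 years. The update count is the number of
year-on-year amount changes, so a 10-year series changed every year
counts 9.

The hinge model `E[n] = a + s_pre·min(L, ω) + s_post·max(L − ω, 0)` is
continuous at ω by construction (a discontinuous switch would contradict
reporting a single stagnation point with pre/post slopes). Priors:
slopes N(1, 2) — a 1:1 update-per-year relationship being the a-priori
ideal of adaptive management — ω N(10, 5) truncated to the feasible
length range intersected with the observed range, intercept N(0, 5),
residual s.d. half-normal(2). The posterior is sampled with emcee
(affine-invariant ensemble, 16 walkers per chain, 4 independent
ensembles as diagnostic chains); walkers are initialized from a coarse
profile-least-squares hinge fit to avoid a degenerate reflected mode
(ω at the boundary with the slope roles exchanged) that traps a few
walkers under dispersed initialization. Summaries use equal-tailed
quantile intervals (the conventional "CI") rather than HDIs. When the
truth has no change point, ω is weakly identified (wide or multimodal
posterior) and the convergence flag correctly trips; the fitted mean
function still tracks the data (tested).

## Synthetic data

The generator emulates the statistical structure of a real quota system
with every artefact planted and recorded in a JSON truth sidecar:

* **Quota table** — per-species quota series with notes drawn from the
  vocabulary grammar (≈ 38% blank, live-dominated otherwise, matching
  the published composition); planted exact duplicates, back-dated
  split children, −1/NA sentinels, multi-year-span notes,
  re-export-only notes, Malaysian regional triplets and
  overlapping-scope pairs, with exact counts in the sidecar.
* **Trade ledger** — exporter-reported use drawn as a zero-inflated
  fraction of quota (point mass at zero ≈ 0.26, Beta(2.2, 1) otherwise,
  reproducing the observed "about half the permitted offtake used,
  ~70% among traded quotas" regime); breaches planted at 6.3% of
  non-zero quotas with exponential excess; zero-quota subversions at
  4.5%; importer-reported volumes equal exporter volumes except under a
  configurable discrepancy model that produces importer-only breaches;
  plus records the live/direct/count filter must reject and unmanaged
  trade for the gap analysis.
* **Pre/post series** — raw-scale volume and quota tables realized from
  per-series (pre-slope, step, trend-change) triples on the
  standardized scale, mapped to randomized raw centres and scales.
* **Update series** — lengths 2–27 drawn with geometric weight 0.88 per
  extra year, counts binomial-thinned around the hinge mean (clipped to
  [0, L−1]); a `dispersion` knob interpolates to mean-preserving
  stochastic rounding. Defaults mirror the published regime: 624
  series, slope 0.29/yr before stagnation at 17.4 years, none after.

All randomness derives from a single seed through `SeedSequence`
spawning (one stream per sub-generator), so identical configs give
byte-identical CSVs.

### Model-level simulators and what the tests show

Parameter-recovery calibration uses model-level simulators
(`simulate_prepost_dataset`, `simulate_update_series`) that generate
directly from the fitted model families: the pre/post simulator emits
standardized series (centre 0, scale 1), because re-standardizing
generated raw volumes by the realized series s.d. would rescale the
planted coefficients; the update simulator uses hinge-plus-normal noise
(σ = 1, rounded and clipped to the feasible count range), because
binomial thinning is heteroscedastic in length and the homoscedastic
normal model's intervals are then honestly but unhelpfully miscalibrated
for a recovery experiment (the point estimate stays unbiased; the
20-replicate CI coverage drops to ≈ 60–65%). Calibration results
(≈ 90% HDI coverage for the hierarchical model over 100
coefficient-replicates; ≈ 85–90% CI coverage for ω over 20 replicates at
n = 600) therefore demonstrate correctness of the samplers and
summaries under their own assumptions. They do not demonstrate interval
calibration under count-valued, heteroscedastic real data — there the
intervals should be read as approximate, exactly as for the original
normal-error formulation.

The pipeline-level generators likewise emulate structure, not realism:
species names and party codes are synthetic, trade volumes have no
seasonal or market dynamics, reporter discrepancies are a simple
multiplier model, and threat timelines have at most one category
change. Passing tests show the pipeline's bookkeeping, matching,
arithmetic and inference machinery are correct under known truth; they
say nothing about taxonomy reconciliation or reporting quirks in real
registry exports.

## Problem sizes and runtime conventions

Desk-scale defaults were chosen so the full test suite and the
acceptance script each run in a few minutes on one CPU: calibration
batches use 20 replicate fits (16-taxon, 5+5-year series for the
hierarchical model; 600 update series for the hinge), the compliance
oracle runs on a ledger of several thousand records, and pipeline
determinism checks use reduced chains (2 × 150/150). Full-scale runs
(69 series, 4 × 500/500; 624 update series) are the library defaults
and remain available through configuration.

## Known limitations

* No unit conversion between derived products and individuals; no
  re-export chain reconstruction; no taxonomy reconciliation against
  external checklists.
* Importer/exporter year attribution is taken from the ledger as-is.
* The panel grid encodes directions only; trajectory shapes that differ
  in post-change slope magnitude share a panel.
* The trend/year-factor identifiability wobble above grows as the
  number of series shrinks; fits on a handful of series should be read
  with the HDIs, not the medians.
* Zero-quota (ban) effectiveness is tallied but not modelled.
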