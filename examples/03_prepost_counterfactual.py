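"""Fit the counterfactual pre/post-quota model on simulated series.

Series are simulated with quota levels set 0.9 s.d. above the
extrapolated pre-quota trend (b2 = 0.9) and no other effects; the
hierarchical fit should recover that step and classify the series onto
the step-change panel of the trajectory taxonomy.
"""

from quotawatch import (
    McmcSettings,
    classify_all,
    fit_prepost,
    simulate_prepost_dataset,
    summarize_coefficient,
)

series = simulate_prepost_dataset(beta=(0.0, 0.9, 0.0, 0.0, 0.0), seed=5)
print(f"simulated {len(series)} standardized series "
      f"({len({s.taxon for s in series})} taxa)")

fit = fit_prepost(series, McmcSettings(chains=4, warmup=500, samples=500, seed=3))
print(f"max split-R-hat: {fit.rhat_max:.3f} (converged: {fit.converged})\n")

names = {"beta1": "post-quota volume step", "beta2": "quota-level step",
         "beta3": "pre-quota trend", "beta4": "volume trend change",
         "beta5": "quota trend change"}
for m, (key, label) in enumerate(names.items()):
    s = summarize_coefficient(fit.beta[:, :, m])
    print(f"{key} ({label}): median {s.median:+.2f} "
          f"[90% HDI {s.hdi_low:+.2f}, {s.hdi_high:+.2f}] pd {s.pd:.1f}%")
# beta2 should sit near +0.9 with pd ~100%: quota levels were planted
# 0.9 s.d. above the trend.  The others stay near zero.

calls = classify_all(fit)
tally: dict[int, int] = {}
for c in calls:
    tally[c.quota_panel] = tally.get(c.quota_panel, 0) + 1
print("\nquota-contrast panel tally:", dict(sorted(tally.items())))
# Panel 2 (clear step increase, no trend change) dominates.  The
# simulator jitters coefficients per taxon (s.d. 0.2), so some taxa have
# genuine small pre-trends and land on neighbouring panels, and a step
# that misses the 97.5% posterior bar falls back to panel 1.
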