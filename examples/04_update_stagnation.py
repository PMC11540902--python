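"""Quota-update stagnation: counting changes and the hinge model.

Adaptively managed quotas should keep being updated as they age.  The
hinge (change-point) model estimates the series length beyond which
updates stop accruing.
"""

from quotawatch import (
    McmcSettings,
    count_changes,
    expected_changes,
    fit_changepoint,
    per_year_rate,
    simulate_update_series,
)

print("changes in [100, 200, 200, 150]:", count_changes([100, 200, 200, 150]))

# 600 series whose update counts stagnate after 17 years
series = simulate_update_series(n_series=600, omega=17.0, slope_pre=0.3,
                                slope_post=0.0, seed=11)
fit = fit_changepoint(series, McmcSettings(seed=7))
for name in ("slope_pre", "slope_post", "omega"):
    s = fit.summary(name)
    print(f"{name}: median {s.median:.2f} [90% CI {s.hdi_low:.2f}, {s.hdi_high:.2f}]")

for years in (15, 25):
    e = expected_changes(fit, years)
    print(f"a {years}-year quota is updated ~{e.median:.1f} times "
          f"({per_year_rate(e.median, years)}/yr)")
# The per-year update rate falls beyond the stagnation point: long-lived
# quotas are proportionately the least revised.
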