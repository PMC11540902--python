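"""Evaluate quota compliance from both reporter perspectives.

Trading exactly the quota is compliant; strict excess is a breach.  A
quota can look compliant in the exporter's figures while the importer's
figures breach it — those importer-only cases are ranked separately.
"""

from quotawatch import (
    QuotaRecord,
    VolumeCell,
    discrepancy_table,
    evaluate_quota,
    parse_quota_note,
    percent_use,
    summarize_compliance,
)

print("696 exported against a quota of 63 ->", percent_use(696, 63), "% use")

scope = parse_quota_note("live").scope
cases = [  # (quota amount, exporter-reported, importer-reported)
    (200, 140, 1320),   # exporter compliant, importer-side breach
    (340, 119, 1109),   # same pattern
    (500, 500, 500),    # exactly on quota: compliant
    (0, 0, 21),         # zero quota (ban) subverted on the importer side
    (1000, 250, 250),   # ordinary partial use
]
results = []
for i, (amount, exp, imp) in enumerate(cases):
    q = QuotaRecord(id=f"q{i}", party="GH", year=2009, taxon=f"Genus sp{i:02d}",
                    rank="species", amount=amount, scope=scope)
    cell = VolumeCell(taxon=q.taxon, exporter=q.party, year=q.year, scope=scope,
                      exporter_volume=exp, importer_volume=imp)
    results.append(evaluate_quota(q, cell))

summary = summarize_compliance(results)
print(f"zero quotas: {summary.n_zero_quotas}, subverted: {summary.n_zero_breaches}")
print(f"mean quota use: {summary.mean_pct_use_all}% over all non-zero quotas")

print("\nimporter-only breach table (ranked by importer percent use):")
print(discrepancy_table(results).to_string(index=False))
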