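"""Parse free-text quota notes and run the cleaning chain.

A quota's scope (commodity term, specimen source, trade purpose) arrives
as a free-text note.  This example parses a few notes, then cleans a
small quota table containing a duplicate and a sentinel amount.
"""

from quotawatch import RawQuotaRow, clean_quotas, parse_quota_note

for note in ["live", None, "all, live", "skins and meat"]:
    scope = parse_quota_note(note).scope
    print(f"note={note!r:<18} -> terms={scope.terms} sources={scope.sources} "
          f"purposes={scope.purposes} comparable={scope.comparable}")

rows = [
    RawQuotaRow("ID", 2005, "Varanus salvator", "species", 450, "live"),
    RawQuotaRow("ID", 2005, "Varanus salvator", "species", 450, "live"),  # exact duplicate
    RawQuotaRow("ID", 2006, "Varanus salvator", "species", 450, "live"),
    RawQuotaRow("MG", 2006, "Furcifer pardalis", "species", -1, "live"),  # sentinel: unverifiable
    RawQuotaRow("MG", 2007, "Furcifer pardalis", "species", 2000, None),
]
result = clean_quotas(rows)
print("\nstage counts:", result.stage_counts)
for stage, removed in result.removed.items():
    for r in removed:
        print(f"removed at {stage}: {r}")
# The duplicate and the -1 sentinel are removed; the blank note defaults
# to wild-sourced trade of any term for any purpose.
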