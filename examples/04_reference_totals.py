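"""Worked example on the packaged reference count table.

The package ships an 11-row per-category count table for core-metabolism
proteins of cellobiose-grown C. thermocellum batch cultures (shotgun and
iTRAQ 4-plex acquisition).  This script feeds those rows through the same
totals and percentage logic the pipeline uses for its own summaries.
"""

from proteoquant import headline_percents, load_reference_counts, totals_row

counts = load_reference_counts()
totals = totals_row(counts)

print(counts.to_string(index=False))
print("\nTotals:", totals.to_dict())

pct = headline_percents(int(totals["increased"]), int(totals["decreased"]),
                        int(totals["detected_4plex"]))
print(f"\nOf {totals['detected_4plex']} proteins detected by 4-plex acquisition, "
      f"{pct.pct_changed}% changed ({pct.pct_increased}% increased, "
      f"{pct.pct_decreased}% decreased in stationary phase).")
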