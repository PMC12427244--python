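"""Peak-table curation: rounding, merging, consolidation, imputation.

Builds three tiny per-sample peak tables the way chromatography exports
look, rounds retention times to one decimal (merging redundant peaks),
consolidates them on the union of retention times, and imputes the gaps.
"""

from sweatvoc import PeakTable, consolidate, drop_empty_features, impute_moving_average, round_and_merge

raw = [
    PeakTable("CO001", [(10.68, 100.0), (10.74, 50.0), (12.02, 7.0)]),
    PeakTable("CO002", [(10.71, 120.0), (24.38, 3.0)]),
    PeakTable("CRC001", [(10.66, 40.0), (12.04, 9.0), (24.41, 5.0)]),
]

rounded = [round_and_merge(t) for t in raw]
print("after rounding to one decimal:")
for t in rounded:
    print(f"  {t.sample_id}: {t.peaks}")

matrix = consolidate(rounded, ["CO", "CO", "CRC"])
print("\nconsolidated matrix (NaN = peak absent in that sample):")
print(matrix.values)

complete = impute_moving_average(drop_empty_features(matrix))
print("\nafter windowed-mean imputation:")
print(complete.values)

print(
    "\nNote that CO001's two peaks at 10.68 and 10.74 min merged into one"
    "\n10.7-min feature with the summed area (abundance is conserved), and"
    "\nthat an absent peak is missing data — not a zero area."
)
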