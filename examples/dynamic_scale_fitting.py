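"""Fit a corpus-specific (dynamic) quality scale and compare it to the
static one.

Uses a 14-version sequence of hierarchy-depth (DITOnto) values in which the
depth drifts between 11 and 14.  The static scale maps every depth above 8
to the worst score, so it sees no evolution at all; the dynamic scale,
fitted by exact 1-D k-means on the observed values, resolves the drift into
distinct quality levels.
"""

from oquare import dynamic_score, fit_dynamic_scale, static_score

depths = [11, 11, 11, 11, 13, 13, 14, 13, 13, 13, 13, 12, 12, 12]

scale = fit_dynamic_scale({"DITOnto": depths})
print("fitted intervals (score -> [low, high]):")
for score, (lo, hi) in sorted(scale.intervals["DITOnto"].items(), reverse=True):
    print(f"  {score}: [{lo}, {hi}]")
print("  1: empty (only 4 distinct values observed, low scores stay empty)")

print("\nversion-by-version scores:")
print("  depth   static  dynamic")
for d in depths:
    print(f"  {d:5d}   {static_score('DITOnto', d):6d}  {dynamic_score(scale, 'DITOnto', d):7d}")

print(
    "\nThe static column is constant at 1 (all depths exceed its worst "
    "threshold) while the dynamic column starts at 5, dips to 2 when the "
    "depth peaks, and ends at 4 — the drift becomes visible."
)
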