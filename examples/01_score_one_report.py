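"""Score a single coronary CTA report.

Builds a small English report for a patient with moderate coronary
calcification (CAC 215.3 AU) and a moderate stenosis (CAD-RADS 3),
parses it back, and composes the biological cardiovascular age with the
itemized rule ledger.
"""

from cardioage import KeyMetrics, compose_bioage, parse_report, render_report

metrics = KeyMetrics(cac_au=215.3, cadrads="3", lvef_percent=77.0)
text = render_report(metrics, locale="en", style_seed=0)
print(text)
print("-" * 60)

result = parse_report(text, locale="en")
estimate = compose_bioage(result.metrics, chrono_age=66.0)

print(f"base (39 + 0.1 x CAC): {estimate.base_years:.2f} y")
for rule, years in estimate.increment_ledger:
    print(f"  + {rule}: {years:.1f} y")
print(f"total BioAGE:          {estimate.total_years:.2f} y")
print(f"displayed:             {estimate.display_years:.0f} y")
print(f"deviation vs chrono:   {estimate.deviation_years:+.2f} y")

# The total is the calcium base age plus the CAD-RADS 3 increment;
# displayed ages are rounded to whole years.  A positive deviation means
# the coronary findings make the heart "older" than the calendar.
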