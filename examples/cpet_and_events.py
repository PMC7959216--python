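"""Reduce a CPET breath series and follow-up records to outcome variables.

Shows the maximal-effort gate (peak VO2 is reported only when the
respiratory exchange ratio reaches 1.05) and the first-qualifying-event rule
of the composite endpoint.
"""

import pandas as pd

import fontanstress as fs

# maximal test: RER reaches 1.12
series = fs.generate_cpet_series(peak_vo2=34.0, rer_max=1.12, ve_vco2_slope=31.0)
res = fs.process_cpet(series, predicted_peak_vo2=41.5)
print(f"maximal test:    peak VO2 {res.peak_vo2:.1f} mL/kg/min "
      f"({res.pct_predicted:.0f}% predicted), RERmax {res.rer_max:.2f}, "
      f"VE/VCO2 slope {res.ve_vco2_slope:.1f}")

# submaximal test: RER tops out at 1.04, peak VO2 is withheld
sub = fs.process_cpet(fs.generate_cpet_series(peak_vo2=34.0, rer_max=1.04))
print(f"submaximal test: peak VO2 withheld (RERmax {sub.rer_max:.2f} < 1.05), "
      f"VE/VCO2 slope {sub.ve_vco2_slope:.1f} still reported\n")

records = pd.DataFrame(
    [
        ("P1", 420.0, "reintervention_catheter", 1),
        ("P1", 900.0, "death", 1),
        ("P1", 150.0, "arrhythmia", 0),  # no medication/intervention: excluded
    ],
    columns=["patient_id", "offset_days", "category", "qualifying"],
)
out = fs.build_composite(records, follow_up_days=2600.0)
print(f"composite endpoint: event={out.event} at day {out.time_days:.0f} "
      f"({out.first_category})")
print("the non-qualifying arrhythmia at day 150 does not count; the first")
print("qualifying event (catheter reintervention, day 420) sets the time.")
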