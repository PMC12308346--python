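"""Generate a synthetic exposure series and run it through QC.

Simulates the second concentration series (vehicle control plus 5e-12 to
5e-14 M, 12 males each), converts water concentrations to release rates,
and applies the exclusion rules.  The printed audit shows which males were
discarded and why.
"""

from countersignal import apply_qc_filters, series_2, simulate_experiment

cfg = series_2(seed=42)
samples, truth = simulate_experiment(cfg)
print(f"simulated {samples.male_id.nunique()} males "
      f"({len(samples)} water samples)")

records, audit = apply_qc_filters(samples)
n_inc = (records.qc_status == "included").sum()
print(f"{n_inc} males survive QC; exclusions by reason:")
print(audit.to_text())

print("first included records (rates in mg/h):")
print(records[records.qc_status == "included"].head()
      [["male_id", "baseline_rate_mg_per_h", "post_rate_mg_per_h", "fold_change"]]
      .to_string(index=False))
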