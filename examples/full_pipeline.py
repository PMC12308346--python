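"""The complete three-series experiment, end to end.

Simulates all three concentration series, quantifies and QC-filters every
male, runs the per-series rank-based tests (with the Wilcoxon-first cascade
for the series whose control collapsed), pools responders for the
baseline-coupling test, and prints the report.
"""

from countersignal import default_pipeline_config, render_report, run_pipeline

cfg = default_pipeline_config(seed=11, n_perm=1000)
result = run_pipeline(cfg)
print(render_report(result))
print(f"pooled males for the coupling analysis: {len(result.pooled_ids)}")
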