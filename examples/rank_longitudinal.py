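"""Rank-based treatment x time inference on a simulated series.

A significant treatment x time interaction means the treatments changed
release rates between the baseline and post windows by different amounts --
the signature of a pheromone response.  Post hoc pairwise comparisons are
BH-adjusted.
"""

from countersignal import (apply_qc_filters, ats_test,
                           longitudinal_from_records, pairwise_posthoc,
                           permutation_interaction_test,
                           relative_treatment_effects, series_2,
                           simulate_experiment)

samples, _ = simulate_experiment(series_2(seed=7))
records, _ = apply_qc_filters(samples)
data = longitudinal_from_records(records)
data["group"] = ["C" if g == 0 else f"{g:.0e}" for g in data["group"]]

print("relative treatment effects (probability-scale, 0.5 = typical):")
print(relative_treatment_effects(data).round(3))

for effect in ("treatment", "time", "interaction"):
    res = ats_test(data, effect)
    print(f"{effect:12s} ATS = {res.statistic:6.2f}  "
          f"df = ({res.df_numerator:.2f}, {res.df_denominator:.1f})  "
          f"p = {res.p_value:.2g}")

obs, p_perm = permutation_interaction_test(data[data.group.isin(["C", "5e-12"])],
                                           n_perm=2000, seed=1)
print(f"two-group permutation oracle (C vs 5e-12): p = {p_perm:.4f}")

print("post hoc pairwise interaction tests (BH-adjusted):")
print(pairwise_posthoc(data).round(4).to_string(index=False))
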