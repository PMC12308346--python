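"""Exact Wilcoxon signed-rank test at bioassay sample sizes.

With 13 or fewer males per treatment the exact enumeration of all sign
assignments matters: p-values are computed from the true permutation
distribution, including tied absolute differences.
"""

import numpy as np

from countersignal import wilcoxon_signed_rank

baseline = np.array([0.011, 0.092, 0.018, 0.150, 0.052, 0.029, 0.008, 0.065])
post = np.array([0.041, 0.280, 0.042, 0.310, 0.160, 0.081, 0.020, 0.190])

res = wilcoxon_signed_rank(baseline, post)
print(f"n = {res.n}, W+ = {res.statistic}, two-sided p = {res.p_value:.6f}")
print("all 8 males increased release, so W+ is maximal and p = 2/2^8")

res_g = wilcoxon_signed_rank(baseline, post, alternative="greater")
print(f"one-sided (post > baseline): p = {res_g.p_value:.6f}")
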