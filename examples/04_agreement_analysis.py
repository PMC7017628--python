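"""Agreement statistics on a paired questionnaire-vs-accelerometer sample.

Demonstrates the analysis battery: mean difference (bias), Bland-Altman
limits of agreement (bias +/- 1.96 SD of the differences), the Wilcoxon
signed-rank test, and Spearman correlation with interpretation bands
(none < 0.10 <= poor < 0.30 <= fair < 0.60 <= moderately strong < 0.80 <=
very strong < 1 = perfect).
"""

import numpy as np

from paq_agree import PairedSample, bland_altman, spearman, wilcoxon_signed_rank

rng = np.random.default_rng(0)
n = 54
accel = rng.gamma(4, 3.5, n)                   # accelerometer vigorous min/day
gpaq = accel * 3.0 * rng.lognormal(-0.045, 0.3, n)  # 3x over-reported, noisy

sample = PairedSample("vigorous", "with_cards",
                      [f"P{i:02d}" for i in range(n)], gpaq, accel)

ba = bland_altman(sample)
print(f"n = {ba.n}")
print(f"bias (questionnaire - accelerometer): {ba.bias:.1f} min/day")
print(f"limits of agreement: [{ba.loa_lower:.1f}, {ba.loa_upper:.1f}] min/day")
# ~95% of individual differences are expected inside the limits

w = wilcoxon_signed_rank(sample.questionnaire, sample.accelerometer)
print(f"Wilcoxon signed-rank: W+ = {w.statistic:.1f}, p = {w.p_value:.2g} ({w.method})")

c = spearman(sample)
print(f"Spearman rho = {c.rho:.2f} (p = {c.p_value:.2g}) -> {c.band} correlation")
# A large systematic bias can coexist with a decent rank correlation:
# the questionnaire overstates the level but preserves the ordering.
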