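"""The economic Model Benefit statistic, step by step.

A screening model that tells some patients they can skip the HbA1c test
saves one test fee per avoided test (true negative) but incurs the
therapeutic-inertia cost for every poorly controlled patient it misses
(false negative).  MB compares model-guided testing with testing everyone.
"""

import numpy as np

import glycobench as gb

costs = gb.CostModel()  # 73 yuan per test, 786.77 yuan per missed patient
counts = gb.ConfusionCounts(tp=100, fp=11, fn=3, tn=82)

report = gb.model_benefit(counts, costs)
print(f"N = {counts.n} patients")
print(f"TC (test everyone)   = {report.tc:>9.2f} {report.currency}")
print(f"MC (model-guided)    = {report.mc:>9.2f} {report.currency}")
print(f"MB = TC - MC         = {report.mb:>9.2f} {report.currency}")

# MB depends only on TN and FN: each averted test is worth 2*fee, each
# missed patient costs (miss_cost - fee).
closed = 2 * costs.test_fee * counts.tn - (costs.miss_cost - costs.test_fee) * counts.fn
print(f"closed form 146*TN - 713.77*FN = {closed:.2f}")

# Full evaluation of predicted probabilities, including decision curves:
rng = np.random.default_rng(0)
labels = rng.integers(0, 2, 500)
scores = np.clip(0.6 * labels + rng.normal(0.2, 0.18, 500), 0, 1)
ev = gb.evaluate_scores(scores, labels, costs)
print(f"\nsimulated classifier: AUC {ev.auc:.3f}, AUPRC {ev.auprc:.3f}, "
      f"accuracy {ev.accuracy:.3f}, MB {ev.benefit.mb:.2f} {costs.currency}")
t = gb.optimal_mb_threshold(scores, labels, costs)
best = gb.model_benefit(gb.confusion_at_threshold(scores, labels, t), costs)
print(f"MB-optimal threshold {t:.3f} -> MB {best.mb:.2f} {costs.currency}")
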