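"""Validate scores against measured residual enzyme activity (ACADM panel).

Loads the packaged table of 14 ACADM mutation pairs (compound heterozygotes;
each score is the average of the two variants' scores), applies the 2-SD
outlier rule, computes Pearson's r with a one-tailed t p-value, then fits a
least-squares trendline on the kept K329E-carrying pairs (the near-null
variant, so residual activity is attributable to the partner allele) and
predicts the activity of the remaining pairs.
"""

from modict import (
    exclude_outliers,
    fit_trendline,
    packaged_table,
    pearson,
    predict_activity,
    prediction_error,
    read_activity_table,
)

points = read_activity_table(str(packaged_table("acadm_table2")))
kept, excluded = exclude_outliers(points, k=2.0)
print(f"loaded {len(points)} pairs; excluded {len(excluded)}: "
      f"{[(p.label, p.activity, p.score) for p in excluded]}")

result = pearson(kept)
print(f"Pearson r = {result.r:.3f} on n = {result.n_used}, "
      f"one-tailed p = {result.p_one_tailed:.3f}")

# train on the K329E-carrying pairs, predict the rest
training = [p for p in kept if "K329E" in p.label]
held_out = [p for p in kept if p not in training]
trend = fit_trendline(training)
print(f"\ntrendline on {len(training)} training pairs: "
      f"activity = {trend.slope:.2f} * score + {trend.intercept:.1f}")
predicted = [predict_activity(p.score, trend) for p in held_out]
summary = prediction_error(predicted, [p.activity for p in held_out])
print(f"held-out prediction over {summary.n} pairs: "
      f"MAE = {summary.mae:.1f} activity-%, accuracy = {summary.accuracy_pct:.0f}%")
print("\n(accuracy here is 100*(1 - MAE/mean observed activity))")
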