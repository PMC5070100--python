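"""Classify a test score against control-derived thresholds.

Score interpretation is relative: a negative control S_C (wildtype vs refined
wildtype) anchors the benign end and a known deleterious variant score S_K the
other.  A stringency K in [0, 100] widens the classification band.  The
published tubulin example is used: scores 1.843 (wildtype control), 2.003
(known deleterious R380L) and the test variant A248V at 1.984, classified
against the published threshold T1 = 1.945.
"""

from modict import ControlSet, ThresholdBracket, classify, compute_threshold

# published threshold, supplied directly
bracket = ThresholdBracket(t1=1.945, band_halfwidth=0.05)
for score, name in [(1.984, "A248V (test)"), (1.843, "wildtype control")]:
    print(f"{name}: score {score:.3f} -> {classify(score, bracket)}")

# the same controls through the threshold formula (additive reading, K = 55)
controls = ControlSet(s_negative=1.843, s_known=2.003, s_intermediate=2.003,
                      stringency_K=55.0)
derived = compute_threshold(controls)
print(f"\nformula-derived T1 at stringency 55: {derived.t1:.3f}")
print(f"A248V under the derived bracket:     {classify(1.984, derived)}")
print("\nA score above T1 is called deleterious; ties resolve to the lower")
print("(less deleterious) category.")
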