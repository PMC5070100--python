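"""Find which residue pairs drive a score (the iterator workflow).

Builds a profile with a strong localized displacement, then reports each
consecutive residue pair's contribution (observed displacement term minus its
background term, floored at zero) rescaled to an attained weight in [0, 10].
Pairs with weight 10 dominate the score.
"""

import numpy as np

from modict import DomainSet, RmsdProfile, iterate_contributions

dev = np.full(20, 0.8)
dev[8:12] = 3.0   # displaced block: residues 9-12
profile = RmsdProfile.from_deviations(dev)

result = iterate_contributions(profile, DomainSet(((1, 20),)))
print("pair  contribution  attained_weight")
for start, contribution, weight in result.pair_scores:
    marker = " <-- displaced block" if weight == 10.0 else ""
    print(f"{start:>2}-{min(start + 1, 20):<3} {contribution:>10.4f} {weight:>12.2f}{marker}")
print("\nAttained weights are invariant under uniform rescaling of the")
print("profile; consecutive high-weight pairs mark structurally affected regions.")
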