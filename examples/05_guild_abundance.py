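"""Guild relative abundance from trap counts.

Computes per-woodland species proportions from the published burying-beetle
trap totals: N. vespilloides dominates both woods, but the Gamlingay guild
is more finely subdivided among congeners.
"""

import pandas as pd

from nichescan import relative_abundance

traps = pd.DataFrame({
    "woodland": ["gamlingay"] * 2 + ["waresley"] * 2,
    "species": ["N. vespilloides", "other Nicrophorus"] * 2,
    "count": [1811, 2219 - 1811, 1963, 2096 - 1963],
})

out = relative_abundance(traps)
print(out.to_string(index=False))
# 81.6% of Gamlingay's 2219 trapped Nicrophorus are N. vespilloides vs.
# 93.7% of Waresley's 2096 — Waresley is nearly a one-competitor guild.
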