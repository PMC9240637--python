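"""Screen features by the four methods and compare their picks.

Each method scores every feature against yield; scores are min-max
normalised to a [0, 1] screening probability, and fusion mode keeps the
top-3 vegetation indices plus the top-3 texture features.
"""

from canopy_yield import simulate_feature_table
from canopy_yield.feature_selection import METHODS, run_selector

table = simulate_feature_table(315, seed=0)

for method in METHODS:
    res = run_selector(method, table, k=3, fusion=True, seed=0)
    probs = ", ".join(f"{c}={res.probabilities[c]:.2f}" for c in res.selected)
    print(f"{method:3s} -> {probs}")

# Different screeners disagree on exact ranks but all should surface strong
# members of each family; screening probability 1.0 marks a method's top pick.
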