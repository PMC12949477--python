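"""Independent brute-force oracles shared by the test modules."""

from itertools import permutations

import numpy as np


def brute_force_perm_p(x, y):
    """Enumerate every ordering of y and count slopes <= observed."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def slope(v):
        return np.polyfit(x, np.asarray(v, float), 1)[0]

    obs = slope(y)
    all_orderings = list(permutations(y))
    count = sum(slope(p) <= obs + 1e-12 for p in all_orderings)
    return (1 + count) / (1 + len(all_orderings))
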