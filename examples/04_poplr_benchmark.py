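"""Benchmark PoPLR progression detection on a progressing/stable pair.

Generates matched progressing and stable bundles under the Reliable
condition and sweeps the PoPLR p-value cutoff into ROC curves at visit
horizons 6 and 10, for the visual-field and OCT series separately.
"""

import warnings

import numpy as np

import sfsim
from sfsim.io import ReservedSeedWarning

warnings.simplefilter("ignore", ReservedSeedWarning)

cfg = sfsim.SeedConfig(n_eyes=30, rng_seed=15)
truths, persons = sfsim.truth_population(cfg)
stable = [sfsim.make_stable(t) for t in truths]
prog = sfsim.measure_bundle(truths, "Reliable", 1, "progressing", persons)
stab = sfsim.measure_bundle(stable, "Reliable", 5, "stable", persons)

rng = np.random.default_rng(0)
grid = sfsim.benchmark_bundles(prog, stab, visits_list=(6, 10),
                               n_perm=500, rng=rng)

print("PoPLR separation of progressing from stable eyes (30 eyes each):")
print(f"{'data':>5} {'visits':>6} {'AUC %':>7} {'pAUC %':>7}")
for (mod, v), s in sorted(grid.items()):
    print(f"{mod:>5} {v:>6} {s.auc:>7.1f} {s.pauc:>7.1f}")
print("pAUC is the area over false-positive rate <= 0.1 as a percentage")
print("of its 0.1 maximum (chance level 5%); more visits -> better")
print("separation.")
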