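"""Trace cross-validated AUC as the second-order elimination strength
varies over (-1, 0].

The weight matrix does not depend on alpha, so each fold is fitted once
and merely rescored per alpha; alpha = 0 is the plain weighted two-round
allocation.
"""

import numpy as np

from ibnra.evaluation import alpha_sweep, make_folds
from ibnra.synthetic import PlantedBlockSpec, generate_dataset

net, expr, ppi, _ = generate_dataset(PlantedBlockSpec(seed=7))
plan = make_folds(net, "kfold", k=10, seed=7)
alphas = np.round(np.arange(-0.9, 0.01, 0.1), 10)

print("alpha    AUC")
for alpha, auc in alpha_sweep(net, plan, alphas, expr, ppi):
    print(f"{alpha:5.1f}  {auc:.4f}")
# the curve is smooth in alpha; how much (and whether) elimination helps
# depends on the redundancy structure of the network at hand
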