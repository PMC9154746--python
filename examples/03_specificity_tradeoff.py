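"""The optimal level of enzyme specificity.

Scans the optimized fidelity Dbar(sigma) over a grid of specificities
for a wide-peaked (3-component) and a narrow-peaked (20-component)
target: promiscuous enzymes (sigma -> 0) synthesize broad profiles well,
narrow multi-peak profiles need more specific enzymes, and beyond a
critical sigma the reaction chain can no longer bridge the gaps between
enzyme shapes, so fidelity collapses — hence an interior optimum.
"""

import numpy as np

import golgicode as gc

grid = [0.0, 0.1, 0.25, 0.5]

wide = gc.make_gmm_target(gc.random_mixture_spec(3, Ns=100, seed=5))
scan_w = gc.scan_sigma(gc.GolgiSystem(NC=3, NE=3, Ns=100), wide, grid,
                       n_starts=4, seed=13, maxiter=120)

narrow = gc.make_gmm_target(gc.random_mixture_spec(20, Ns=200, seed=7))
scan_n = gc.scan_sigma(gc.GolgiSystem(NC=3, NE=3, Ns=200), narrow, grid,
                       n_starts=4, seed=13, maxiter=120)

print("sigma grid:           ", grid)
print("Dbar, wide 3-peak:    ", np.round(scan_w.Dbar, 4))
print("Dbar, narrow 20-peak: ", np.round(scan_n.Dbar, 4))
print(f"sigma_min wide = {scan_w.sigma_min}, narrow = {scan_n.sigma_min}")

# The narrow-peaked target's optimal specificity is at least as large as
# the wide-peaked target's: sharp peaks cannot be carved out by
# promiscuous enzymes, which spread reaction flux over many glycan
# indices.
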