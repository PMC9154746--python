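"""Stiff and sloppy directions, degeneracy, and the enzyme-swap probe.

Optimizes a (3, 3) machinery to a 3-peak target, then (i) computes the
Hessian of the fidelity at the optimum over all box-normalized
coordinates (mu, R, L, sigma) and groups its eigenvectors by dominant
parameter block, and (ii) exchanges the enzyme complements of two
cisternae to show that cisternal partitioning carries information.
"""

import numpy as np

import golgicode as gc

target = gc.make_gmm_target(gc.random_mixture_spec(3, Ns=100, seed=5))
system = gc.GolgiSystem(NC=3, NE=3, Ns=100)

scan = gc.scan_sigma(system, target, [0.1, 0.25, 0.5], n_starts=6, seed=3,
                     maxiter=150)
best = scan.results[int(np.nanargmin(scan.Dbar))]
params = gc.ParameterSet(mu=best.best_params.mu, R=best.best_params.R,
                         L=best.best_params.L, sigma=scan.sigma_min)

analysis = gc.hessian_at(system, target, params)
print(f"coordinate dimension: {analysis.dim}")
print("average stiffness ln<lambda> by parameter block:")
for block, stiff in sorted(analysis.group_stiffness.items(),
                           key=lambda kv: -kv[1]):
    print(f"  {block:>5}: {stiff:8.3f}")

report = gc.probe_degeneracy(best, eigenvalues=analysis.eigenvalues)
print(f"near-best starts: {report.fraction_near_best:.0%} in "
      f"{report.n_clusters} distinct cluster(s); "
      f"{report.n_flat_directions} flat direction(s)")

d0 = gc.steady_state_linear(system, best.best_params).displayed
d1 = gc.steady_state_linear(system,
                            gc.swap_cisternae(best.best_params, 1, 3)).displayed
print(f"KL(original || cisternae 1<->3 swapped) = "
      f"{gc.kl_divergence(d0, d1):.4g} nats")

# Specificity is the stiffest direction — the cell must control sigma
# tightly — while most reaction-rate directions are sloppy.  Swapping
# the enzymes of two cisternae degrades the displayed code: WHERE along
# the stack an enzyme sits matters, not just which enzymes exist.
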