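"""Calling the complexity of a glycan profile.

Generates a noisy MSMS-like spectrum from a 5-component mixture (Poisson
counting noise plus a 2% uniform chemical baseline), fits Gaussian
mixtures of growing size by weighted EM, and calls the profile's
complexity as the component count where the KL divergence saturates.
"""

import numpy as np

import golgicode as gc
from golgicode.synthetic import separated_mixture_spec

spec = separated_mixture_spec(5, Ns=200, seed=3)
clean = gc.make_gmm_target(spec)
raw = gc.make_msms_like(clean, gc.MsmsNoiseSpec(total_counts=10**5,
                                                baseline=0.02, seed=3))
profile = raw.normalize()

call = gc.complexity(profile, m_max=8, restarts=6, seed=0)

print("m    D(profile || GMM_m)")
for m, kl in enumerate(call.curve, start=1):
    marker = "  <- saturation" if m == call.m_star else ""
    print(f"{m:<4} {kl:.5f}{marker}")
print(f"complexity call: m* = {call.m_star} (generating mixture had "
      f"{len(spec.components)} components)")

# The KL curve drops steeply while components still capture real peaks
# and flattens once only noise remains; the saturation point recovers
# the generating component count despite the counting noise.
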