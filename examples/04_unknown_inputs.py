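"""Recover sparse unknown stimulus drivers and their spatial map.

Simulates stimulus runs driven by sparse inputs through a planted spatial
map B, holds the (rest-derived) coupling matrix A fixed, and alternates
l1-penalised estimation of the input time courses U and of B.
"""

import numpy as np
from scipy.linalg import subspace_angles

from neuromodes import fit_unknown_inputs, make_sparse_inputs, make_stable_system, simulate_run
from neuromodes.experiments import random_stable_spec
from neuromodes.sysid import input_support

rng = np.random.default_rng(0)
n, p, T = 30, 3, 154
system = make_stable_system(n, random_stable_spec(n, rng), seed=1)
B_true = rng.standard_normal((n, p))
B_true /= np.linalg.norm(B_true, axis=0)

panels, U_true = [], []
for i in range(4):
    U = make_sparse_inputs(p, T, density=0.05, amplitude=1.0, seed=10 + i)
    U_true.append(U)
    panels.append(simulate_run(system, T, B_true=B_true, U=U, noise_sd=0.02, seed=20 + i))

# (i) input timing with the true model given: channel-wise support recovery
from neuromodes import estimate_inputs

U_hat, _ = estimate_inputs(panels[0], system.A_true, B_true, reg_weight=0.5)
est = input_support(U_hat)
tru = U_true[0] != 0
tp = (est & tru).sum()
f1 = 2 * tp / (2 * tp + (est & ~tru).sum() + (~est & tru).sum())
print(f"input-support F1 with the true map given = {f1:.2f} "
      "(timing/channel of the sparse drivers)")

# (ii) spatial map unknown: the alternating fit recovers its column span
# (individual columns are only identified up to permutation and scale)
result = fit_unknown_inputs(panels, system.A_true, p=p, reg_weight=0.5,
                            max_iter=30, seed=0)
angle = np.degrees(subspace_angles(result.model.B, B_true).max())
trace = result.objective_trace
print(f"alternating fit: objective {trace[0]:.1f} -> {trace[-1]:.1f} "
      f"over {result.n_iterations} alternations (never increases)")
print(f"span(B) recovered to {angle:.1f} deg principal angle "
      "(<10 deg means the planted input subspace was found)")
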