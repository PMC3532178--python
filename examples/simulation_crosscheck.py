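"""Validating the reductions against exact stochastic simulation.

Runs the Gillespie SSA on the full elementary enzyme network and on its
coarse-grained heuristic counterpart (k1 = 5e-3, half saturation, volume
100), plus the slow-scale Langevin equation, and compares stationary
substrate statistics with the analytic predictions.  The full-network SSA
lands on the slow-scale value; the heuristic SSA lands on the heuristic
value - roughly half of the true variance at these rates.
"""

import numpy as np

from sslna import (
    heuristic_lna,
    langevin_sslna,
    slow_scale_lna,
    ssa_simulate,
    steady_state,
    trajectory_statistics,
)
from sslna.models import EnzymeParams, enzyme_coarse_network, enzyme_full_network

p = EnzymeParams(k1=5e-3).at_theta(0.5)
net = enzyme_full_network(p)
ss = steady_state(net)
red = slow_scale_lna(net, ss.concentrations)
coarse = enzyme_coarse_network(p)
red_h = heuristic_lna(coarse, steady_state(coarse).concentrations)

print(f"analytic substrate variance   ssLNA: {red.covariance[0, 0]:.3f}   "
      f"hLNA: {red_h.covariance[0, 0]:.3f}")

traj = ssa_simulate(net, t_max=40_000.0, seed=101, n_grid=100_000)
st = trajectory_statistics(traj)
print(f"full-network SSA:      var = {st.variance[0]:.3f} +- {st.variance_se[0]:.3f}")

traj_h = ssa_simulate(coarse, t_max=40_000.0, seed=101, n_grid=100_000)
st_h = trajectory_statistics(traj_h)
print(f"heuristic SSA:         var = {st_h.variance[0]:.3f} +- {st_h.variance_se[0]:.3f}")

lv = langevin_sslna(red, dt=0.1, t_max=20_000.0, seed=1)
st_l = trajectory_statistics(lv)
print(f"slow-scale Langevin:   var = {st_l.variance[0]:.3f} +- {st_l.variance_se[0]:.3f}")
print()
print("The Langevin route reproduces the full-network noise at a cost")
print("independent of the molecule numbers - the practical alternative to")
print("simulating heuristic propensities.")
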