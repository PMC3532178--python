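"""Substrate noise in a two-subunit enzyme network: slow-scale vs heuristic.

Builds the full seven-reaction elementary network at slow binding
(k1 = 5e-7) and half enzyme saturation, reduces it both ways and compares
the predicted substrate fluctuations.  The heuristic route (extrapolating
the coarse-grained Hill rate law into propensities) misses the noise of the
reversible binding steps and underestimates the coefficient of variation
~11-fold and the Fano factor ~112-fold.
"""

import numpy as np

from sslna import heuristic_lna, slow_scale_lna, steady_state
from sslna.models import EnzymeParams, enzyme_coarse_network, enzyme_full_network

p = EnzymeParams(k1=5e-7).at_theta(0.5)
net = enzyme_full_network(p)          # species (S; EES, SEES), EE eliminated
ss = steady_state(net, require_stable=True)
red = slow_scale_lna(net, ss.concentrations)

coarse = enzyme_coarse_network(p)     # 0 -> S -> P with effective rate k'(S)
ssc = steady_state(coarse)
red_h = heuristic_lna(coarse, ssc.concentrations)

S = ss.concentrations[0]
var_ss, var_h = red.covariance[0, 0], red_h.covariance[0, 0]
print(f"steady-state substrate concentration [S] = {S:.1f}  (Km = {p.Km:.1f})")
print(f"effective stoichiometry S' = {np.round(red.effective_stoichiometry, 4)}")
print(f"reduced master equation exists: {red.reduced_cme_exists}")
print(f"substrate variance   ssLNA: {var_ss:.1f}   hLNA: {var_h:.1f}")
print(f"Omega*Fano factor    ssLNA: {p.omega * var_ss / S:.1f}   "
      f"hLNA: {p.omega * var_h / S:.3f}")
print(f"Fano-factor ratio ssLNA/hLNA = {var_ss / var_h:.1f}   "
      f"CV ratio = {np.sqrt(var_ss / var_h):.1f}")
print()
print("The ssLNA Omega*FF >> 1 marks super-Poissonian molecule-number")
print("fluctuations; the heuristic route predicts ~Poissonian noise and is")
print("wrong by two orders of magnitude in the Fano factor here.")
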