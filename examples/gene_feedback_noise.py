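"""Protein noise in a negative-feedback gene circuit.

Evaluates the reduced two-variable (mRNA, protein) description of the
11-reaction feedback circuit at strong repression (k0 = 100, one gene copy
at volume 100) and compares the slow-scale and heuristic protein Fano
factors.  The rate-limiting repressor-gene binding contributes noise that
the heuristic reduction silently discards, costing it about three orders
of magnitude.
"""

import numpy as np

from sslna import solve_lyapunov
from sslna.models import GeneParams, gene_reduced_model

p = GeneParams(k3=1.0, k0=100.0)
m = gene_reduced_model(p)

H_ss = solve_lyapunov(m.jacobian, m.diffusion_sslna)
H_h = solve_lyapunov(m.jacobian, m.diffusion_hlna)

print(f"steady state: [M] = {m.M:.3f}, [P] = {m.P:.1f}")
print(f"QSS weights: p1 = {m.p1:.1f}, q = {m.q:.3f}")
print(f"diffusion D_M  ssLNA: {m.diffusion_sslna[0, 0]:.3g}   "
      f"hLNA: {m.diffusion_hlna[0, 0]:.3g}")
print(f"protein Fano factor  ssLNA: {H_ss[1, 1] / m.P:.2f}   "
      f"hLNA: {H_h[1, 1] / m.P:.4f}")
print(f"log10 Fano-factor ratio = {np.log10(H_ss[1, 1] / H_h[1, 1]):.2f}")
print()
print("p1 measures the noise injected by the slow binding of repressor to")
print("the gene; setting p1 = 0 and q = 1 (the heuristic assumption that")
print("fast-species reactions are silent) recovers the hLNA diffusion and")
print("loses ~3 decades of protein noise.")
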