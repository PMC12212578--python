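"""Simulate one draw of the varying-coefficient spatial model and fit it.

The model is Y = GWY + Xbeta + eps with G = diag{sin(u'alpha)}: each unit's
spatial autocorrelation strength depends on its location through the index
u'alpha.  The fit recovers the index direction alpha, the regression
coefficients beta, the spline approximation of g, and the residual variance.
"""

import numpy as np

import ssivcar as sv

design = sv.SimulationDesign()          # 15x15 grid, Rook, alpha=(1/2, sqrt3/2)
data = sv.simulate(design, seed=3)
fit = sv.fit(data)

print("true alpha:", np.round(design.alpha, 4), " estimated:", np.round(fit.alpha, 4))
print("true beta: ", np.round(design.beta, 4), " estimated:", np.round(fit.beta, 4))
print(f"sigma2 estimate: {fit.sigma2:.4f}  (truth {design.sigma2})")
print(f"converged after {fit.iterations} outer iteration(s); "
      f"profile loss {fit.loss:.2f}")
g_err = np.sqrt(np.mean((fit.g_hat - data.true_g) ** 2))
print(f"rms error of fitted g over the 225 units: {g_err:.3f}")
# On a single draw the index direction lands within a few hundredths of the
# truth while beta scatters with a standard error of roughly 0.15-0.25 —
# consistent with the Monte Carlo dispersion reported by the full study.
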