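"""Why a constant-rho SAR model fails under heterogeneous spatial dependence.

Data are generated with a per-unit autocorrelation field rho_i =
0.8*sin(u_i1 + u_i2) on a 15x15 grid and covariates uniform on [0, 1]; the
homogeneous SAR model is then fit by quasi-maximum likelihood.  Compare with
the near-homogeneous limit (amplitude ~ 0), where the same fit is unbiased.
"""

import ssivcar as sv

het = sv.misspecification_experiment(amplitude=0.8, nmc=30, seed=0)
hom = sv.misspecification_experiment(amplitude=1e-9, nmc=30, seed=0)

print("heterogeneous rho field (amplitude 0.8):")
print(het.round(4).to_string(index=False))
print("\nnear-homogeneous control (amplitude ~0):")
print(hom.round(4).to_string(index=False))
# Under heterogeneity the single rho-hat settles on an uninterpretable
# compromise, the beta estimates are strongly biased and sigma2 is inflated
# severalfold; the control shows the same fit is fine when its assumption
# holds. This motivates letting the autocorrelation vary with unit traits.
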