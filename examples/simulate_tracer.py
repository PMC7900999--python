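"""Solve one tracer-transport realization and report the output functionals.

Uses the capillary-filtration velocity model (Model 2) with full-scale
coefficients: gadobutrol diffusivity 1.2e-10 m^2/s, RMS inflow speed
0.17 um/s and an interior sink r = 1e-5 1/s, driven by the
conservation-constrained SAS concentration.
"""

import numpy as np

from tracermc import GeometrySpec, TransportSampler, build_surrogate_hierarchy

spec = GeometrySpec(dimension=2, n_levels=3)
hierarchy = build_surrogate_hierarchy(spec)
sampler = TransportSampler(hierarchy, model="model2")

drive = sampler.drive
print(f"c_CSF(0) = {drive.c_csf[0]:.3f} mol/m^3, "
      f"c_CSF(24 h) = {drive.c_csf[-1]:.3f} mol/m^3")
print(f"tracer balance check: max deviation "
      f"{np.abs(drive.balance - drive.params.n0).max() / drive.params.n0:.2e} "
      "(relative to the injected 0.5 mmol)")

rng = np.random.default_rng(7)
q = sampler.sample_qoi(3, rng).reshape(4, -1)
tau_h = sampler.tau / 3600.0
for name, row in zip(("Q_g", "Q_w", "q_g", "q_w"), q):
    print(f"{name}: 6 h = {np.interp(6, tau_h, row):.4g}, "
          f"24 h = {row[-1]:.4g}")
# Q_g/Q_w are total amounts (mol) in gray and white matter; q_g/q_w are
# average concentrations (mol/m^3) in the probe subregions.  Tracer reaches
# the gray shell within hours while the white core lags, and the SAS
# concentration declines as the parenchyma takes tracer up.
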