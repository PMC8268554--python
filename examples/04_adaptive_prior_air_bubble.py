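"""Adaptive prior regions rescue reconstruction from a reference-model error.

Adds a 50 mm air bubble (sigma = 0) outside the heated region — emulating
organ shift or bowel gas during the treatment — and compares the fixed
prior region (which becomes unusable) with the adaptive 1+1+3 scheme that
re-derives the prior mask from an unconstrained first pass.
"""

import numpy as np
from dataclasses import replace

from eitherm import (adaptive_prior_reconstruct, apply_gaussian_heating,
                     insert_spherical_anomaly, iterative_reconstruct,
                     scenario_fixture, solve_forward)
from eitherm.inverse import ReconConfig
from eitherm.pipeline import build_setup

setup = build_setup(frequencies=("lf",))
mesh, sigma = setup.mesh, setup.sigma_ref["lf"]
spec, table = setup.spec, setup.table

heat = scenario_fixture("P1", spec)
air = scenario_fixture("air", spec)
truth = apply_gaussian_heating(sigma, heat, mesh)
truth = insert_spherical_anomaly(truth, mesh, air.anomaly["center_mm"],
                                 air.anomaly["diameter_mm"], 0.0)
true_pct = 100 * (truth.values - sigma.values) / np.maximum(sigma.values, 1e-300)

vref = solve_forward(mesh, sigma, setup.pattern)
v = solve_forward(mesh, truth, setup.pattern)
mask = np.linalg.norm(mesh.centroids - heat.center, axis=1) <= heat.radius

cfg = ReconConfig(hyperparameter=0.01, penalty_mode="tissue_dependent",
                  penalty_value=0.001, prior_mask=mask, n_iterations=3)
fixed = iterative_reconstruct(mesh, vref, v, sigma, cfg,
                              table["muscle"].sigma_lf)
adaptive = adaptive_prior_reconstruct(mesh, vref, v, sigma,
                                      replace(cfg, prior_mask=None),
                                      table["muscle"].sigma_lf)

for name, res in (("fixed prior", fixed), ("adaptive prior", adaptive)):
    err = res.delta_sigma_percent - true_pct
    print(f"{name:15s}: heated-region error {err[mask].mean():+7.1f} "
          f"+- {err[mask].std():6.1f} %  ({res.n_inverse_solves} inverse solves)")
# the fixed prior forces the bubble's impedance signature into the heated
# sphere; the adaptive masks recover both change regions simultaneously
m2 = adaptive.masks[1]
print(f"refined adaptive mask: {m2.sum()} elements, covering the heated "
      f"sphere and the air bubble")
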