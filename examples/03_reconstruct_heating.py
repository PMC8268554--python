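"""Reconstruct a spherical Gaussian heating pattern (scenario P1 analog).

Applies the 40 %-peak Gaussian conductivity increase to a liver-region
sphere, solves the forward problem before and after heating, reconstructs
the change with three Gauss-Newton iterations (tissue-dependent penalty,
lambda = 0.01, known prior region) and reports the binned error
statistics after the 1.2 cm averaging filter.
"""

from eitherm.pipeline import build_setup, run_spherical_case

setup = build_setup()
print(f"phantom: {setup.mesh.n_elements} elements, "
      f"{setup.pattern.n_measurements} voltage measurements")

res = run_spherical_case(setup, scenario_id="P1")
print("per-iteration voltage residual |dv| (uV, mean +- std):")
for i, (m, s) in enumerate(res.recon.residuals, 1):
    print(f"  iteration {i}: {m*1e6:8.2f} +- {s*1e6:.2f}")
# the residual collapsing by orders of magnitude shows the iterative
# reference update converging on the measured state

mean, std = res.metrics.overall
print(f"reconstruction error in the heated sphere: "
      f"{mean:+.2f} +- {std:.2f} % of baseline conductivity")
print("sliding histogram (per 1 % of true change):")
print(res.metrics.bins.to_string(index=False,
                                 formatters={"mean": "{:+.2f}".format,
                                             "std": "{:.2f}".format}))
print(f"worst bin: |mean| {res.metrics.max_abs_bin_mean:.2f} %, "
      f"std {res.metrics.max_bin_std:.2f} % (feasibility bound: 10 %)")
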