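# eitherm

Electrical impedance tomography (EIT) for monitoring hyperthermia cancer
therapy: can boundary-voltage measurements track the conductivity changes
that heating induces in deep tissue, and can those changes be mapped back
to temperature and perfusion?

`eitherm` is a simulation and reconstruction toolkit that answers this
end to end, entirely from synthetic data:

* a **layered torso phantom** (elliptic cylinder with skin/fat shells,
  muscle bulk, bone, a liver-like organ, a urine-filled bladder and a
  tumor) whose conductivity spans ~0 S/m to 3 S/m — the heterogeneity
  that makes quantitative EIT hard;
* a **P1 finite-element forward solver** for the quasi-static conduction
  problem with point electrodes (two interleaved rings of eight), pairwise
  current injection (offset 7, 1 mA) and adjacent-pair voltage
  measurement (192 channels), with an exact adjoint Jacobian;
* a **regularized one-step Gauss–Newton inverse solver** for difference
  imaging, iterated with reference-model updates, plus tissue-dependent
  penalties, adaptive prior regions (1+1+3 scheme), a positivity
  constraint, measurement-based voltage rescaling and thermal-length
  smoothing;
* a **Pennes bioheat solver** with temperature-dependent perfusion
  (optimistic vs pessimistic vasodilation) and the conductivity-change
  model linking temperature and perfusion to conductivity at two
  frequencies;
* **two-frequency separation** of the direct temperature contribution
  from the perfusion contribution.

## The model in brief

Difference imaging solves the linearized problem `y = J x + n` by the
one-step Gauss–Newton estimate

    x̂ = (JᵀJ + λ²R)⁻¹ Jᵀ y,      R_ii = √((JᵀJ)_ii) · Penalty_i,

computed in the equivalent form `x̂ = R⁻¹Jᵀ (J R⁻¹Jᵀ + λ²I)⁻¹ y` that
inverts only a 192×192 system.  The penalty (< 1 inside the prior region)
raises the permitted change where heating is expected; the
tissue-dependent variant scales it per tissue as `σ_muscle/σ_ref`,
removing the systematic over/under-estimation of low/high-conductivity
tissues.  Heating changes conductivity both directly and through
vasodilation:

    Δσ/σ_ref = Tc·ΔT + α(√ω − 1)(1 + Tc·ΔT)

with temperature coefficient `Tc = 2 %/°C`, plasma fraction
`α = 24 %` (LF) / `8 %` (HF) and relative perfusion `ω(T)`.  Measuring at
two frequencies isolates the temperature term,

    Δσ_LF − (α_LF/α_HF)·Δσ_HF = (1 − α_LF/α_HF)·Tc·ΔT,

and the perfusion term from the plain difference.

## Worked example

```bash
python examples/03_reconstruct_heating.py
```

builds the default phantom (~25k tetrahedra), applies the 40 %-peak
Gaussian conductivity increase of scenario P1 (a 60 mm sphere in the
liver region), reconstructs it noise-free with three iterations and
prints:

```
phantom: 24576 elements, 192 voltage measurements
per-iteration voltage residual |dv| (uV, mean +- std):
  iteration 1:    34.46 +- 44.79
  iteration 2:     1.62 +- 2.08
  iteration 3:     0.01 +- 0.01
reconstruction error in the heated sphere: -0.14 +- 1.63 % of baseline conductivity
worst bin: |mean| 2.97 %, std 2.10 % (feasibility bound: 10 %)
```

The residual collapsing by three orders of magnitude shows the iterative
reference update converging on the measured state; the binned error
statistics (sliding histogram every 1 % of true change, after the 1.2 cm
averaging filter) stay well inside the 10 % feasibility bound.  The other
examples cover phantom construction, forward solving, the adaptive prior
region under a reference-model error (air bubble), full treatment
monitoring with two-frequency temperature mapping, and the separation
algebra.

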