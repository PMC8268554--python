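# Methods

This note records the models implemented in `eitherm`, the assumptions
behind them, the defaults that matter, and what the synthetic study does
and does not demonstrate.

## Phantom

The torso section is an elliptic cylinder (half-axes 15 cm × 10 cm,
height 20 cm, volume 9.42 L) meshed deterministically: concentric-ring
nodes on the unit disk, 2-D Delaunay triangulation, affine map to the
ellipse, extrusion to prisms and minimal-index prism splitting (which
guarantees a conforming, positive-volume tetrahedralization).  The
default target is 3·10⁴ elements (realized ~2.5·10⁴); mesh volume matches
the analytic value to ≲0.3 %.  Tissue labels are assigned by element
centroid: skin and fat shells by normalized elliptic radius, then
inclusions in order (bone cylinder, liver-like ellipsoid, urine sphere,
tumor sphere; later wins).  Coordinates are metres internally and
millimetres at the configuration surface, z along the torso axis.

The tissue table is a compact stand-in for a full dielectric/thermal
database.  Low-frequency conductivities anchor to the values that define
the phantom's dynamic range (muscle 0.36, urine 3.0, internal air 0 S/m);
high-frequency values are scaled up per tissue.  `Tc = 2 %/°C` and
`α_LF = 24 %`, `α_HF = 8 %` are uniform across tissues.  Every value is
overridable.

The five heated-region fixtures (P1–P5) and the 50 mm air object use
positions stated in a reference torso frame and mapped into the phantom
by linear per-axis scaling of the frame half-extents (170, 110, 100 mm)
onto the phantom's — preserving deep vs shallow and left vs right
placement.  The heating multiplier `1 + 0.4·exp(−r²/2R²)` is applied
inside the heated sphere only (R = region radius); the truncation at the
sphere boundary is deliberate: the prior region in the reconstruction
studies is that same sphere, so all true change lies inside it.

## Forward model

Linear P1 FEM for `∇·(σ∇u) = 0` with point electrodes at single boundary
nodes (two rings of eight, interleaved, at the quarter heights, 45°
spacing per ring, 22.5° offset between rings).  Contact impedance and
extended electrode models are out of scope; difference imaging is
insensitive to electrode modelling shared between the two states.  The
system is grounded at one interior node (choice verified immaterial for
differential voltages) and factorized once per conductivity (SuperLU);
all drive and measurement fields reuse the factorization.  Nodes whose
every incident element has σ = 0 (inside air inclusions) are pinned;
a floating *electrode* raises instead.

The protocol injects 1 mA through electrode pairs `(i, i+7 mod 16)` and
measures all adjacent pairs not touching the injection electrodes:
16 × 12 = 192 channels.  The adjoint Jacobian
`J[m,e] = −V_e ∇u_drive·∇u_meas` is the exact derivative of the discrete
system (verified against central finite differences to <10⁻⁴ relative).

Measurement noise is zero-mean Gaussian with standard deviation
`rms(v − v_ref)/10^(SNR/20)` — SNR referenced to the heating-induced
voltage change, added to the heated frame only.

## Inverse solver

One-step Gauss–Newton with the sensitivity-scaled diagonal prior
`R_ii = √((JᵀJ)_ii)·Penalty_i`, solved through the push-through identity
so only the measurement-space system is inverted.  Zero-sensitivity
diagonal entries are floored at 10⁻¹²·max(R).

**Scaling.**  The solver works in dimensionless variables chosen once:
conductivity changes normalized by muscle conductivity
(`x = Δσ/σ_muscle`) and per-channel relative voltage differences
(`y_m = Δv_m/|v_ref,m|`, with the channel magnitude floored at 10⁻³ of
the median).  This keeps the hyperparameter `λ = 0.01` independent of
units, mesh scale and injection current while preserving the
absolute-variable behaviour of standard one-step Gauss–Newton EIT — in
particular the constant-penalty failure mode (percentage-scale changes
overestimated in low-σ tissue, underestimated in high-σ tissue) that the
tissue-dependent penalty corrects.

**Penalties.**  Outside the prior region the penalty is 1; inside it is
the configured value (strict default 0.001, relaxed 0.1).  The
tissue-dependent variant multiplies the base by `σ_muscle/σ_ref,i`,
clipped to `[base/10, base·100]` (the cap also catches σ = 0 elements).
The functional form was chosen to equalize percentage-scale sensitivity
across tissues; its constants are exposed in the configuration.

**Iteration.**  Each iteration re-solves the forward problem at the
current conductivity, recomputes the Jacobian there (full Gauss–Newton)
and records mean ± std of |Δv|; updated conductivities are floored at
10⁻⁶·σ_ref to keep the FEM system connected.  Divergence (residual
growing twice in a row) stops the iteration with a flag.  The optional
positivity constraint zeroes negative changes before each iteration.

**Adaptive prior (1+1+3).**  One unconstrained reconstruction, smoothed
(1 cm Gaussian over centroids, volume-weighted) and thresholded at 25 %
of the peak |change| (fraction unspecified upstream; exposed in
configuration) → mask 1; one reconstruction with mask 1 at penalty 0.1 →
mask 2; three iterations with mask 2 at the strict penalty.  Exactly five
inverse solves.  Empty masks fall back to the whole domain with a
warning.

Smoothing is applied to masks and final maps only, not between
iterations (configurable).

## Thermal model

Pennes bioheat on a rectilinear voxel grid (default spacing 4 mm for
field work, 5–6 mm in the orchestrated pipelines) masked to the phantom:

    ρc ∂T/∂t = ∇·(k∇T) + w_b c_b (T_a − T) + q_m + q_ext

with `w_b` a blood mass flow per tissue volume (kg/(s·m³)), so the sink
coefficient is `w_b·c_b` (~2400 W/(m³·K) for baseline muscle; quoting a
volumetric rate folds ρ_b into the same product).  The outer surface is
fixed at T_a = 37 °C (water-bolus-cooled skin stand-in; body-core drift
out of scope).  Metabolic heat defaults to zero — the uniform 37 °C
baseline is taken as the equilibrium in which q_m is already balanced;
the field exists for non-equilibrium studies.

Time stepping is semi-implicit: diffusion implicit through one sparse LU
factorization, perfusion sink and sources explicit, default dt = 5 s
(10 s in the treatment pipeline).  The explicit term is stable for dt
well below the perfusion time constant ρc/(w_b c_b) (~120 s for muscle at
maximal vasodilation); a per-tissue check rejects unstable steps.  A
fully implicit alternative would refactorize every step because the
perfusion diagonal is temperature-dependent.  A steady-state solver
(fixed-point in ω(T)) supports the analytic validation cases.  The
characteristic thermal length √(k/(w_b c_b)) in baseline muscle is
~1.1 cm — the basis for the 1 cm smoothing radius.

**Perfusion curves.**  ω(T) is piecewise linear: 1 up to a vasodilation
onset, rising to ω_max at a plateau temperature.  Defaults: optimistic —
muscle ×12, fat ×4 (onset 39 °C, plateau 45 °C), tumor ×2 (onset 37 °C,
plateau 43 °C); pessimistic — muscle ×3, fat ×1.5, tumor ×1.  The onset
matters structurally: it confines the optimistic/pessimistic mismatch to
the meaningfully heated volume, which is what makes a planning-based
reference with a 39 °C mask threshold a *closer* starting point rather
than a mis-specified one.  Only muscle, fat and tumor are
perfusion-responsive for conductivity purposes.  The exact curves carry
the largest physiological uncertainty in this domain; conclusions here
rely on their general magnitude and monotone shape, not their details.

**Conductivity coupling.**  `Δσ/σ_ref = Tc·ΔT + α(√ω−1)(1+Tc·ΔT)`.  The
square root reflects the vessel cross-section/perfusion relation under
constant pressure drive and laminar flow; a flag selects the literal
`ω−1` reading.  The inverse map (used to convert reconstructed
conductivity to temperature) is a monotone table inversion at 10⁻³ °C
resolution over ΔT ∈ [0, 15] °C, exact to ≪10⁻⁵ °C; out-of-range inputs
are clipped and flagged.

**Applicator stand-in.**  Power deposition is an isotropic Gaussian at
the tumor centre (default peak 2.5·10⁴ W/m³, spread 4 cm, one hour).
These values put the planned treatment in the clinical window (optimistic
peak ≈45 °C) with the pessimistic truth ~1.5–2.5 °C hotter — the
perfusion-uncertainty gap the monitoring problem exists to close.  A
focused multi-antenna field pattern is out of scope.

## Treatment pipeline and metrics

Scenario 1 reconstructs against the 37 °C conductivity with no prior
region; Scenario 2 against σ(T_optimistic) with the prior region
T_opt > 39 °C.  Truth is always σ(T_pessimistic).  Reconstructions use
λ = 0.01, tissue-dependent penalty, 3 iterations, noise-free unless a
noise sweep is requested.

Analysis follows one chain for every map: per-element fractional change →
nearest-centroid rasterization to the grid → 1.2 cm cubic averaging
filter → model inversion (single frequency, with the true perfusion
curves) or two-frequency separation → 1 cm Gaussian smoothing.  Error
statistics (overall, per tissue, and a sliding histogram every 1 % of
the true change, bins with ≥5 samples) compare reconstruction and truth
after the *identical* chain, so they measure reconstruction fidelity
rather than the filter's deliberate resolution limit.  Headline
statistics are evaluated over the prior-region mask.

Grid-to-mesh transfer uses trilinear interpolation (temperatures at
element centroids); mesh-to-grid uses nearest element centroid.

## Problem sizes

Default pipeline scale, chosen as the package's standard configuration:
~2.5·10⁴ tetrahedra, 192 measurement channels, thermal grids of 4–6 mm
spacing (~4–8·10⁴ interior voxels), 360 time steps per one-hour
simulation.  A spherical-scenario reconstruction takes a few seconds; the
full two-frequency treatment pipeline a few minutes on one CPU.

## What the synthetic study shows — and does not

The phantom reproduces the *structure* of the problem (heterogeneous
conductivity spanning two orders of magnitude, deep targets, realistic
electrode counts and voltage scales — baseline channels ~5 mV at 1 mA,
heating signatures tens to hundreds of µV) but not anatomical geometry:
organ shapes are idealized, there is no inter-subject variability, and
electrode placement is exact.  Passing results therefore demonstrate the
soundness of the reconstruction machinery and the multifrequency
algebra under the stated physics, not clinical performance.  Known
limitations shared with the underlying physics: distributed-perfusion
Pennes (no discrete-vessel cooling), fixed body-core temperature, real
conductivities only (no capacitive effects), point electrodes, and
perfusion curves known only in broad outline.

Frequency orderings are partly composition-dependent.  HF reconstruction
errors are smaller than LF's in the conductivity domain (smaller change
range to reconstruct) in both scenarios here.  Converting to temperature
divides by the slope dσ/dT, which in vasodilating muscle is 2–3× steeper
at LF; when the evaluation mask is muscle-dominated, this division can
hand LF the smaller *temperature* error despite its larger conductivity
error (observed in Scenario 1 on this phantom).  In the planning-based
Scenario 2 — the configuration the monitoring pipeline targets — HF is
better in both domains.

On error weighting in the separation: the weighted temperature equation
amplifies *independent* LF/HF noise more than the perfusion equation in
general; the perfusion estimate is relatively worse (per unit of change)
when perfusion changes are modest (ω ≲ 2 at ΔT ≈ 4 °C) — the regime of
the treatment pipeline — and when LF/HF reconstruction errors are
correlated underestimation, which is what iterative regularized
reconstruction produces.  The property tests target those regimes.
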