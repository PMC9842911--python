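# Methods

## Model overview and assumptions

`cortivasc` is a steady-state, lumped (per-depth) description of one
vascular unit of human V1 and of the gradient-echo MR signal it
produces at 7 T. It deliberately omits temporal dynamics (no HRF,
no transients), pial vessels, orientation-dependent frequency offsets,
diffusion narrowing, and any field strength other than 7 T. The cortex
is 2.5 mm thick, discretised into 10 voxels of 0.75 × 0.75 × 0.25 mm³;
depths 1–2 map to layer VI, 3–4 to V, 5–6 to IV, 7–8 to II/III, 9–10
to I (the grid is configurable; this 2-voxels-per-layer assignment is a
modelling choice, since equal-thickness voxels and five layer labels
admit no unique mapping). Depth groups are deep = 1–4, middle = 5–6,
superficial = 7–10.

### Vessel tree

Mass conservation at steady state makes trunk flux purely cumulative:
in each layer a vein carries the capillary flux drained in that layer
plus everything from deeper layers. Capillary flux uses d = 8 μm,
v = 1.6 mm/s; flux-to-geometry conversion uses p = d³α/4 with
α = v/d = 160 s⁻¹ (post-capillary) and 320 s⁻¹ (pre-capillary), both
anchored at d = 12.5 μm. π is dropped from p = r²v everywhere,
consistently, so it cancels in all derived quantities. Each vein is
paired with two arteries that split its flux, hence
d_a = d_v·(α_post/2α_pre)^⅓ ≈ 0.63 d_v and the cube law
d_a³·α_pre = d_v³·α_post/2 holds identically.

The per-layer capillary counts are not taken from capillary-density
literature; they are obtained by inverting the reference table of vein
diameters (n = round(Δ(d³)·α/4p_cap)), which guarantees the one
checkable output — the diameter table itself — is reproduced (to
< 0.1 μm; the guaranteed bound used in tests is 0.5 μm, the coarseness
of the rounded inputs). One count is an exact half-integer (V1,
layer I: 12.5); round-half-to-even applies, and the resulting 19.7 μm
vs 20 μm discrepancy is within that bound.

### Baseline blood volume

The laminar (arteriole + capillary + venule) baseline CBV profile is a
**packaged synthetic stand-in** for the histology-derived microvascular
density curve of macaque V1, which is published only graphically. It
is smooth and mid-peaked with minimum 2.0% at the white-matter border,
maximum 2.7% at a middle depth, and mean exactly 2.3%; the constant
scenario replaces it by that 2.3% average. The compartment split is
43% arterioles / 36% capillaries / 21% venules as a volume-weighted
average (a reversed 21/36/43 split is available as a configuration for
rodent-like composition).

The split is not applied as a constant factor at every depth: the
venular share rises linearly toward the surface by ±0.04 (arteriolar
share falls correspondingly; capillary share constant), centred so the
volume-weighted means equal 43/36/21 exactly. Physiologically this
reflects venous drainage converging toward the intracortical veins.
Structurally it is load-bearing: with exactly proportional compartment
profiles the VASO responses of the arteriole+capillary pool and of the
venule pool are collinear (only 0.79·ΔCBV_ac + 0.21·ΔCBV_ven would be
identifiable), and noiseless self-consistency fits would tie between
distinct integer tuples. The tilt makes the four fitted parameters
jointly identifiable in the noiseless limit while leaving every
printed aggregate unchanged.

Intracortical baseline CBV per depth is Σ multiplicity·(πd²/4)/l²
over the vessels present. The census is one vein of each class
(V1–V4) and, for arteries, the unit's 2× pairing for A3/A4 with more
numerous small arteries (A2 ×3, A1 ×4) — small diving arteries
outnumber large ones, and these counts (together with one per-class
scale) are the calibration that sets the across-depth maxima to the
published 1.4% (veins) and 1.2% (arteries). The non-uniform A1/A2
counts also break the exact proportionality of the ICA and ICV
baseline shapes that would otherwise follow from d_a = 0.63 d_v, again
a prerequisite for separate identifiability of ICA and ICV volume
changes. The per-class scales come out at ≈ 1.10–1.12 (fractional
vessel counts per footprint are legitimate: the unit cell need not be
centred in a voxel). Resulting deep-layer minima are ≈ 0.23–0.30%,
and the mean total baseline CBV is 3.85%, within the 3.5–4.0% band
that brackets the published 3.7% (exact reproduction is not claimed:
the laminar curve and census are fixture-calibrated).

### Signal model

Blood: R2*_IV = 67 + 536.48·(1−Y)² s⁻¹. Tissue:
R2*_EV = 34 + Σᵢ (e·Δν_s,i + f·CBVᵢ[%]) with e = 0.0453, f = −0.19.
Two documented ambiguities are resolved by explicit switches, both
defaulting to the form exactly as printed in the source tables:

* **Frequency convention** — Δν_s enters in angular units
  (rad s⁻¹; Y = 0.70 gives 49.43 s⁻¹); `frequency_convention="hz"`
  divides by 2π. The fitted e-coefficient presumably absorbed one
  convention or the other.
* **EV Hb form** — the printed `e·Δν + f·CBV` summed per compartment,
  vs `ev_hb_form="cbv_scaled"` which uses `(e·Δν + f)·CBV`.

With the default (printed, angular) combination the simulated BOLD
changes are large (≈ 14% for the best-fit parameters, vs ≈ 6% measured
group means); the alternatives bracket the measurement. Every
recovery-based result in this package is invariant to the choice
because generation and fitting share one forward model — only the
absolute BOLD scale moves.

Spin densities of blood and tissue are set equal (S₀ = 1); only
relative changes matter. T1_tissue (1.8 s) is used only for absolute
blood-nulled signal levels, never for percent changes, since the VASO
percent change is an exact ratio identity independent of TI/TR/T1/ε.

### Activation and profiles

CBV_act = CBV_base·(1 + (β(z)/β_mid)·ΔCBV_mid/100) with β = 1.5 in
middle layers (laminar) and middle+superficial layers (intracortical),
β = 1 elsewhere; an equal-activation mode sets β ≡ 1. ΔCBV is applied
as a volume scaling directly (vessel cross-sections are not
re-derived). Group-level reporting rounds mid/1.5 for deep layers
(56 → 37, ICA 21 → 14, ICV 5 → 3). Profiles are smoothed by a
normalised (0.2, 0.6, 0.2) zero-padded kernel — the point-spread of
depth sampling is cited in the literature but never printed, so a
one-voxel-support kernel is the package default and is configurable or
removable; recovery results are kernel-invariant because both
directions share it. The two zero-padded edges are dropped, leaving 8
points. VASO is displayed activation-positive (the physical change is
negative).

Without smoothing, the best-fit parameter set yields a single
mid-cortical VASO peak on this fixture; a qualitative double peak
(local maxima mid-cortex and near-surface) emerges for parameter sets
with strong diving-vessel dilation, because the true sub-laminar dip
at the stria of Gennari is below the 250 μm depth resolution of the
packaged laminar curve.

## Fitting

RMSE over the 8 retained points, unweighted (a per-depth SEM column is
read but ignored by the objective; a weighted option exists, off by
default). The VASO search is exhaustive over 0–90% in 1% steps on four
axes (91⁴ ≈ 6.9 × 10⁷ points): VASO linearity lets each candidate be a
dot product with four basis profiles, and the quadratic form is
evaluated in vectorised chunks over the leading axis (≈ 0.5 s on one
core). The best point's RMSE is re-evaluated directly from the basis
(the quadratic-form route loses ~8 digits to cancellation near exact
fits). Ties break to the lexicographically smallest tuple in the
order arterioles/capillaries, venules, ICAs, ICVs — deterministic and
documented. The BOLD search is a 16 × 16 double loop of full forward
simulations.

The 20%-RMSE envelope is the set {RMSE ≤ 1.2·min}; it is reported as
per-parameter min/max over the joint member set (not per-parameter 1-D
profiles) and as a per-depth min/max band of member profiles. A
guard of +1e-12·(1+‖y‖²) on the SSE threshold keeps the best point a
member under floating-point cancellation when the minimum is ~0.

## Synthetic data

The measured group profiles that motivated the model exist only as
figures, so the generator produces stand-ins from the forward model:
n_subjects = 7 (the analysed group size), per-subject i.i.d. Gaussian
noise of 0.1% signal change per depth by default (consistent with the
published per-depth standard errors at n = 7), seeded; the group mean
and SEM are derived per depth. With zero noise the mean reproduces the
forward model exactly (bit-identical, special-cased to avoid 1-ulp
averaging drift). The generator does **not** emulate inter-subject
parameter variability, depth-correlated noise, vascular anatomy
variation, or registration/laminar-extraction errors — so recovery
results characterise the estimator under the model's own assumptions,
not performance on real group data.

## Known limitations

* **Ill-conditioned noisy inversion.** The venule direction is nearly
  collinear with the arteriole+capillary direction (broken only by the
  ±0.04 share tilt), and ICA/ICV separation rests on modest shape
  differences. Per grid step the VASO response moves by only ≈ 0.02%
  signal change, so at 0.1% per-depth noise the marginal uncertainty
  of the arteriole/capillary estimate spans tens of grid steps; a
  recovery-within-one-step criterion at that noise level fails by a
  wide margin (measured ≈ 6/50 replicates). This is the package-level
  counterpart of the very wide published 20%-RMSE envelopes (venules
  0–73%) and is intrinsic to the model class, not to the search, which
  is exact by construction (brute-force-verified).
* The BOLD absolute scale depends on the EV-Hb/frequency convention
  (above).
* Table-derived capillary counts are not reconciled with laminar
  capillary CBV; the inversion prioritises the printed diameter table.
* One printed artery diameter (A4, layer II/III: 43 μm) is
  inconsistent with the 2:1 flux rule applied to its printed vein
  (67 μm → 42.2); the model reports 42.

## Problem sizes and runtimes (single core)

Full VASO fit: 91⁴ grid, ≈ 0.5 s (envelope pass included). BOLD fit:
256 forward simulations, < 0.2 s. The complete test suite, including
two full-grid recoveries, brute-force cross-checks on downsampled
grids, and a 50-replicate noisy-recovery experiment, runs in ≈ 15 s;
`scripts/acceptance.py` in ≈ 2 s.
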