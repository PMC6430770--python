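# Methods

This note documents the models, numerical choices and validation strategy
behind `spatialflux`, in the order data flows through the pipeline.

## Natural-abundance correction

A measured MID is the convolution of the tracer-labeling distribution with
natural ¹³C occurrence on the non-tracer carbons: C[i, j] = Binom(n−j, a)
evaluated at i−j, with a the ¹³C abundance (default 0.0107). C is lower
triangular with positive diagonal, so the exact inverse exists; we use it
diagnostically (a component below −0.01 means the data are inconsistent
with the convolution model and an error is raised) and return the
non-negative least-squares solution, renormalized, so noisy inputs always
yield a valid MID. Tracer impurity and non-carbon isotopes are not
modeled. The correction is an exact left inverse of the forward
convolution for abundances below 0.2 (property-tested round trip < 1e-8).

## Isotope-ratio pool quantification

With R1 the labeled/unlabeled intensity ratio in the internal-standard-only
extract and R2 the same ratio in a fraction mixed with standard, the
relative pool size is (1 − R2/R1)/(R2 + R2/R1); values below 0 (possible
only through noise) are clipped with a warning. Measurements are taken at
several standard dilutions (1:1, 1:5, 1:10) because the dynamic range is
best when R2 ≈ 1; the combination rule — take the point estimate from the
pair with minimal |ln R2| and the SD from the spread of all per-pair
estimates — is this package's choice, since no canonical aggregation rule
exists for this design.

## Contamination deconvolution

The mixing model P_c = X_c + β·X_m, P_m = α·X_c + X_m (X per unit marker
signal) inverts in closed form; the implementation is property-tested
against a direct 2×2 linear solve and conserves the measured total exactly
(an algebraic identity). Defaults α = 0.13, β = 0.11, SD 0.03. Nuclear
content is treated as cytosolic (small molecules equilibrate through
nuclear pores); α and β enter as configuration, not as estimated
quantities.

Uncertainty propagation draws (P_m, P_c, α, β) from independent Gaussians,
rejecting negative pools or coefficients and αβ ≥ 1 — pool sizes are
physically non-negative, so truncation-by-resampling is preferred over raw
Gaussians; a rejection rate above 50% aborts, as the noise model then
contradicts the data. Default 10,000 draws; the seed is mandatory.

MIDs are deconvolved per isotopomer on pool-size scale (Ī·P), then clipped
at zero and renormalized. Small negative components are expected noise;
components below −0.25 of the compartment total raise an error, and
anything below −0.01 warns. (The warn/error split exists because
moderately negative components arise already for noiseless but strongly
asymmetric compositions, which should deconvolve-and-clip rather than
fail.)

## Thermodynamic bounds

For each IDH isozyme, Δ_rG′ = Δ_rG′° + RT·ln Q in the oxidative direction,
with Q built exclusively from within-compartment ratios — the analysis is
therefore independent of compartment volumes. Because the measured species
is citrate rather than isocitrate, the reactions are lumped with aconitase
(near equilibrium), shifting Δ_rG′° without affecting conclusions; this is
an explicit model assumption. Δ_rG′° values are configuration inputs with
Gaussian uncertainty (group-contribution estimation is out of scope).
Cofactor assumptions: mitochondrial NADH:NAD⁺ measured-style point values
(e.g. 0.015), mitochondrial NADPH:NADP⁺ Gaussian around 100 with 30% CV,
cytosolic NADPH:NADP⁺ uniform on [30, 100], CO₂ fixed at 1.2 mM. R =
8.314e-3 kJ mol⁻¹ K⁻¹ and T = 310.15 K, overridable.

The flux-force relationship Δ_rG′ = −RT·ln(J⁺/J⁻) converts each Gibbs draw
to a backward/forward ratio; b and σ_b are the mean and SD of
exp(Δ_rG′/RT) over draws, and the fit constrains (b − 2σ)·v_O ≤ v_R ≤
(b + 2σ)·v_O with the lower bound clipped at 0.

## The kinetic flux model

Ten non-negative fluxes (mM h⁻¹) under two equality constraints (mass
balance of mitochondrial and cytosolic citrate). Two citrate isotopomers
are tracked per compartment: m+5 (reductive route from αKG m+5) and m+4
(oxidative route via malate m+4) — m+3 for the SDH-knockout variant, where
the oxidative cycle is blocked and malate m+3 takes that role. Mitochondrial
acetyl-CoA is treated as unlabeled (citrate m+6 is negligible in the data
this model targets), and citrate m+6 is not modeled.

Forcings (αKG m+5 in both compartments, malate m+4/m+3 in mitochondria)
enter as measured deconvolved points, interpolated piecewise-linearly with
value 0 at t = 0 and constant extrapolation beyond the last point; no
smoothing is applied, so the model consumes the data as measured. Because
the ODEs are linear and the forcings piecewise linear, each isotopomer's
(mitochondrial, cytosolic) pair is integrated *exactly* segment by segment
via the matrix exponential of a 4×4 augmented system — there is no
integration-tolerance parameter to tune. An explicit-Euler integrator
(dt = 0.001 min) serves as an independent brute-force cross-check and
agrees to ~1e-5 absolute.

Units: fluxes are reported in mM h⁻¹ and converted once (÷60) for internal
integration in minutes. Fit times default to {2, 5, 10, 20, 30, 60, 180}
min.

### Fitting

The objective is the variance-weighted SSR over fit times × two isotopomers
× two compartments, with per-point σ floored at 0.002 (absolute MID
fraction) to avoid division by near-zero replicate SDs. Optimization uses
SLSQP from random feasible starts: all ten fluxes uniform on
[0, 5 mM h⁻¹], projected onto the equality constraints by least squares
with alternating clipping at 0 (resampled if projection fails). Defaults:
50 starts (fewer suffice for the well-conditioned synthetic studies and are
used there), constraint tolerance 1e-8 (SLSQP internal), objective
tolerance 1e-10, 500 iterations per start. Fits are bit-reproducible for a
fixed (data, config, seed).

Identifiability: the labeling kinetics constrain v_CS, v_CIT_F, v_CIT_B,
v_IDH1_R and the *sum* v_IDH2_R + v_IDH3_R; the 2/3 split, the oxidative
IDH fluxes and v_AcCoA are constrained only through mass balance and the
thermodynamic ratio intervals, and are reported but not individually
identified. Parameter-recovery tests therefore assert on the identifiable
combinations.

### Profile-likelihood intervals

Each bound walks the flux in steps of 5% of its MLE (5% of v_CS when the
MLE is at zero), re-optimizing all remaining fluxes at each step with warm
starts, until the profile SSR first crosses SSR_min + 3.841459 (χ²₁, 95%);
the bound is linearly interpolated between the bracketing steps. Failed
re-optimizations are retried from the MLE and from random feasible starts;
if only near-feasible unconverged iterates exist, their best value is used
as an upper bound on the profile and the interval is flagged. Non-monotone
profiles and bounds pinned at a constraint are also flagged rather than
hidden. Empirical coverage of the v_CS interval on the default synthetic
study is ~95% over 100 noise replicates (recomputed by the acceptance
script).

## ISA of palmitate

Palmitate = 8 acetyl units; a traced molecule carries 2k heavy carbons,
k ~ Binomial(8, p) with p the acetyl-CoA m+2 enrichment; a fraction 1 − g
of the pool predates the trace and stays at m+0. Both p and g are co-fit by
box-constrained least squares (21×21 grid seed + L-BFGS-B), because at
finite tracing times turnover is partial and a fixed g would bias p. Odd
masses are exactly zero and the mean label count is 16·g·p (both
property-tested). A pure-m+0 input leaves g unidentifiable and is flagged.
Natural abundance is assumed corrected upstream.

## Synthetic-study generator

The generator emulates the data shapes of a fractionation time course:
saturating-exponential forcings A(1 − e^(−kt)), ODE-derived citrate
labeling, forward contamination mixing with the same (α, β) model the
deconvolution inverts, and per-replicate Gaussian noise — pools with
CV 5% (resampled if negative), MID fractions with absolute SD 0.005
(clipped to [0, 1] and renormalized), 3 replicates, sampled at
{2, 5, 10, 20, 30, 60, 180} min. The generator's forcing curves are
sampled at the study timepoints and interpolated linearly — the synthetic
world's forcings are by construction exactly what the model consumes, so
noiseless recovery is exact rather than interpolation-biased.

Default true fluxes (mM h⁻¹): CS 0.48, CIT_F 0.61, CIT_B 0.60, IDH1_R
0.06, IDH1_O 0.05, IDH2_R 0.08, IDH2_O 0.01, IDH3_R 0.01, IDH3_O 0.55,
AcCoA 0.02 — a normoxia-like regime (oxidative IDH3 dominant, small
reductive NADP-dependent fluxes, fast bidirectional citrate exchange) with
synthetic pool sizes (citrate 0.12/0.35 mM mito/cyto) chosen so labeling
turnover spans the sampling window. Ratio-bound intervals consistent with
the truth (IDH1 [0.8, 1.6], IDH2 [5, 11], IDH3 [0, 0.05]) stand in for the
thermodynamics stage.

What the generator does *not* emulate: chromatographic/instrument
artifacts, natural-abundance convolution (generated MIDs are tracer-pure),
correlated replicate noise, forcing-curve model mismatch (real αKG/malate
kinetics need not be saturating exponentials), and volume heterogeneity
(relative pools equal mM ratios). Passing recovery tests therefore
demonstrates correctness of the inference chain under its own assumptions,
not robustness to all real-data pathologies.

In recovery experiments the objective's σ is the pooled replicate SD of
the deconvolved tracked-citrate entries (the generator's noise is
homoscedastic) scaled to the SD of the replicate mean; pooling across all
entries stabilizes the variance estimate, keeping the SSR approximately χ²
and the profile intervals calibrated. The file-based pipeline, which sees
only mean ± SD tables, instead propagates the per-entry SDs through the
deconvolution by the delta method.

## Degenerate inputs and tie-breaks

MIDs normalize on construction and reject components below −1e-9; all-zero
MIDs are errors. Equal R2 distances to 1 resolve to the first-listed
dilution. Fluxes violating mass balance beyond 1e-6·|v| are rejected by
the simulator (the optimizer itself evaluates intermediate infeasible
iterates without this check). Ratio bounds with lower > upper raise before
any optimization. MID table rows are silently renormalized within 5% of
sum 1, renormalized with a logged warning beyond that, and rejected as
schema errors beyond ±0.5.

## Problem sizes used in validation

Deconvolution oracle: 1,000 random instances. ODE cross-check: 20 random
feasible flux vectors (10 per variant), Euler dt = 0.001 min over 60 min.
Recovery: one noiseless fit with 10 starts; coverage: 100 independent noisy
studies with 5 starts each and a profile walk for v_CS. These sizes give
stable results while keeping the full validation run to a few minutes.
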