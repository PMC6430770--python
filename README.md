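# spatialflux

Compartment-resolved isotope-tracing fluxomics: from fraction-level
mass-isotopomer and pool-size measurements to mitochondrial vs cytosolic
metabolic fluxes with confidence intervals.

## The problem

Rapid subcellular fractionation followed by LC-MS yields, for each
metabolite, a pool size and a mass-isotopomer distribution (MID — the
fractions of the pool carrying 0..n heavy carbons) in a
mitochondrial-enriched fraction and a cytosolic fraction. Two obstacles
stand between those measurements and compartment-specific fluxes:

1. **Cross-contamination.** Each fraction carries a known admixture of the
   other compartment (α = fraction of cytosolic signal in the mitochondrial
   fraction, β = the converse). With measured fraction pools (P_m, P_c) the
   compartment pools follow the closed form

       P'_c = (P_c − β·P_m)(1 + α) / (1 − αβ)
       P'_m = (P_m − α·P_c)(1 + β) / (1 − αβ)

   which conserves P'_m + P'_c = P_m + P_c identically. MIDs are
   deconvolved component-wise on per-isotopomer pool sizes; uncertainty is
   propagated by Monte Carlo over Gaussian noise in pools and (α, β).

2. **Flux inference.** After a switch to [U-¹³C]-glutamine, the transient
   labeling kinetics of citrate m+5 (reductive IDH route) and m+4 (oxidative
   TCA route; m+3 in SDH-knockout cells) in both compartments constrain ten
   fluxes of a compartmentalized citrate model (citrate synthase, forward /
   backward mitochondrial citrate transport, oxidative and reductive fluxes
   of IDH1/2/3, cytosolic acetyl-CoA demand). Labeling fractions Y obey
   linear ODEs, e.g. for mitochondrial citrate m+5:

       dY⁵ₘ/dt = (1/uₘ)[(v_IDH2R + v_IDH3R)·X⁵ₐKG,ₘ(t) + v_CITB·Y⁵꜀
                        − (v_CS + v_IDH2R + v_IDH3R + v_CITB)·Y⁵ₘ]

   driven by measured α-ketoglutarate and malate labeling ("forcings").
   Fluxes are estimated by minimizing the variance-weighted SSR between
   measured and simulated kinetics under citrate mass balance, v ≥ 0, and
   thermodynamic bounds (b − 2σ)·v_O ≤ v_R ≤ (b + 2σ)·v_O, where
   b = exp(Δ_rG′/RT) comes from the flux-force relationship
   Δ_rG′ = −RT·ln(J⁺/J⁻) applied to Monte-Carlo Gibbs-energy distributions.
   Confidence intervals are profile likelihoods against the χ²(1) 95%
   threshold.

The package also includes isotopomer spectral analysis (ISA) of palmitate —
a binomial-precursor model recovering the lipogenic acetyl-CoA m+2
enrichment p and the fraction of newly synthesized palmitate g — plus
natural-abundance correction, isotope-ratio pool quantification, and a
synthetic-study generator so the entire chain is verifiable by parameter
recovery against known ground truth.

## Worked example

Generate a synthetic study (known fluxes, contamination α = 0.13 /
β = 0.11, replicate noise), run the full deconvolution → fit → profile-CI
chain, and compare to the generating truth:

```python
import spatialflux as sf

result = sf.recover_fluxes(seed=7, n_starts=10, profile=("v_CS", "v_IDH1_R"))
fit = result["fit"]
print(f"SSR = {fit.ssr:.2f}  ({fit.n_converged}/{fit.n_starts} starts converged)")
for name in ("v_CS", "v_CIT_F", "v_CIT_B", "v_IDH1_R"):
    true, est = getattr(result["truth"], name), getattr(fit.best, name)
    line = f"{name:9s} true {true:.3f}  est {est:.3f}"
    if name in result["intervals"]:
        lo, hi = result["intervals"][name]
        line += f"  95% CI [{lo:.3f}, {hi:.3f}]"
    print(line)
```

prints

```
SSR = 22.75  (10/10 starts converged)
v_CS      true 0.480  est 0.476  95% CI [0.396, 0.496]
v_CIT_F   true 0.610  est 0.646
v_CIT_B   true 0.600  est 0.666
v_IDH1_R  true 0.060  est 0.056  95% CI [0.046, 0.067]
```

All fluxes are in mM h⁻¹. The SSR near the number of fitted residuals (28)
indicates a well-calibrated noise model; the citrate-synthase flux and the
reductive IDH1 flux are recovered within their 95% profile intervals.

A command-line interface mirrors the library:
`spatialflux simulate | deconvolve | thermo | fit | isa | run`
(see `spatialflux --help`); `run` executes the whole pipeline from one YAML
config and writes `fluxes.json`, intermediate tables and a reproducibility
manifest.

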