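# Methods

`domfit` implements a complete dominance-and-DFE analysis for coding
variation: expected site frequency spectra (SFS) under selection with
arbitrary dominance, Poisson random field (PRF) inference of the
distribution of fitness effects (DFE) and per-bin dominance coefficients
conditional on an inferred demography, Akaike-weight model averaging, and
individual-based Wright–Fisher forward simulation of genetic load and
inbreeding load under a two-population out-of-Africa history.

## Model and conventions

Inference convention: a deleterious mutation has selection coefficient
`s ∈ [0, 0.5]` with mutant-homozygote fitness `1 − 2s` and heterozygote
`1 − 2sh`; `s = 0.5` is lethal. The population-scaled coefficient is
`γ = 2 N_anc s`. The stationary allele-frequency density is

    f(q; γ, h) = e^{A(q)} / (q(1−q)) · ∫_q^1 e^{−A(ε)} dε / ∫_0^1 e^{−A(ε)} dε,
    A(ε) = 4γ̃hε + 2γ̃(1−2h)ε²,

where `γ̃` is the signed drift coefficient. The formula's orientation is
such that deleterious mutations carry `γ̃ < 0` (at `γ̃ → +∞` the density
piles mass at high frequency); the package therefore negates the positive
deleterious `γ` internally, and the orientation is locked by a test
asserting that deleterious parameters lower the mean sample frequency.
At `h = 0.5` the density reduces to the classical genic-selection flux
density, which the test suite verifies to 1e-8 relative.

The expected SFS entry for a sample of `n` chromosomes is
`E[x_i] = θ · ∫ C(n,i) q^i (1−q)^{n−i} f(q) dq`; under the PRF assumption
each unmasked entry is an independent Poisson count, giving the
log-likelihood `Σ x_i ln m_i − m_i − ln x_i!`. θ enters multiplicatively
and has the closed-form MLE `θ̂ = Σx_i / Σm_i`, used to profile θ out of
the demographic fit. `N_anc = θ̂_S / (4 μ L_S)` with `μ = 1.5e-8` per site
per generation, and `θ_NS = 2.31 θ_S` (the assumed nonsynonymous :
synonymous length ratio).

## Numerics of the diffusion engine

* Frequency grid: geometric crowding toward both boundaries, 2200 interior
  points spanning `[1e-8, 1−1e-8]` by default.
* The demographic transient solves the 1-D forward diffusion
  `∂φ/∂τ = ½ ∂²(q(1−q)φ/ν)/∂q² − ∂(M φ)/∂q` with
  `M = 2γ̃ q(1−q)(h+(1−2h)q)`, time in `2N_anc` generations, per-epoch
  relative size `ν` (constant or exponential). The flux is discretized
  Scharfetter–Gummel style in the variable `ψ = Dφ`
  (`J = (M/D)ψ − ψ'`), which makes the neutral stationary profile `1/q` an
  **exact** fixed point of the discrete operator (verified to ~1e-13) and
  keeps the scheme positivity-preserving at strong selection. Implicit
  Euler steps of `dt = 1e-3` (in `2N_anc` units) with a Thomas solve per
  step; mutational influx enters at the first interior node at mass rate
  `θ/(2 x_0)`, which yields the correct ν-independent flux `θ/2`.
* Binomial sampling uses composite 3-point Gauss–Legendre quadrature on the
  grid cells with the `1/q(1−q)` endpoint factors handled analytically
  (`g = φ q (1−q)` is finite at both boundaries). Constant-size histories
  bypass the PDE and evaluate the analytic equilibrium directly at the
  quadrature nodes, reproducing `θ/i` under neutrality to better than 1e-8.
* The selection grid cache holds 1000 log-spaced values of `s` spanning
  exactly `[1e-5, 0.25]`; mutations with `s > 0.25` are treated as not
  segregating, and DFE mass below `1e-5` contributes the neutral spectrum.
* Validation oracle: a dense Wright–Fisher transition matrix (binomial
  resampling around the linearized post-selection frequency
  `q' = q − 2sq(1−q)(h+(1−2h)q)`, influx `θν/2` per generation, feasible
  for `2N ≤ 1000`). When comparing the continuum density against the
  finite-N chain, the density is first binned onto the `2N+1` frequency
  atoms (mass below half a copy cannot exist in the chain). Agreement is
  within 2% per entry for moderate `γ` (≲ 10) at `2N ∈ {200, 400}`,
  including bottleneck + recovery and growth histories. At `γ ≈ 50` and
  these small `2N`, `s = γ/2N` is no longer small and the diffusion's
  boundary-injection approximation deviates by ~`γ/2N` on the singleton
  class — a limitation of the small-N comparison, not of the engine at the
  study's `N_anc ~ 1e4`.

## DFE families and the h-s sweep

The gamma DFE has shape/scale parameters (scale in unscaled `s` units); the
discrete DFE is a mixture of uniform distributions over five `|s|` bins
(neutral `≤1e-5`, nearly neutral, weakly, moderately, strongly deleterious
`1e-2–0.5`), with four free proportions (the fifth by complement through an
unconstrained softmax transform, so `k = 4` for AIC). Mixture spectra are
assembled from per-h caches with uniform-in-s mass per grid cell (gamma
mass via incomplete-gamma differences). The h-s sweep fixes the neutral bin
at `h = 0.5` and enumerates all combinations of
`{0, 0.05, 0.1, 0.15, 0.25, 0.35, 0.45, 0.5}` over the four other bins
(4096 models, 5 optimizer starts each, per-model seeds derived from the
global seed). Filters: plausibility retains models within 1.92
log-likelihood units of the best (boundary inclusive); the monotonic filter
keeps non-strict decay of h from the neutral to the strong bin (published
retained sets contain tied h values, so ties are allowed). Model averaging
uses Akaike weights `∝ exp(−ΔAIC/2)`.

Identifiability: `h` and `s` trade off (heterozygotes carry most
information, constraining `hs`), so the profile likelihood in a single
global `h` is nearly flat above ~0.15 while strongly rejecting more
recessive values; the test suite asserts exactly this structure at the
study scale rather than a sharp peak. On constant-size data the three-epoch
demographic template has an exact scale ridge (a deep short bottleneck
reproduces the neutral shape with θ rescaled), so absolute sizes are
unidentified there; recovery of sizes is verified on an informative
bottleneck + growth history.

## Forward simulation

Individual-based Wright–Fisher simulation of 1340-bp genes (22,500 genes
over 22 autosomes for the full genome; a 2-chromosome subset of 2046 genes
for desk runs, with results projected ×11). Fitness is multiplicative
across sites in the simulation convention (heterozygote `1 − sh`,
homozygote `1 − s`, `s ∈ [0, 1]`, bins at twice the inference edges).
Recombination: probability 1e-3 per gene boundary per meiosis within
chromosomes (the between-element convention of the precedent simulations,
not per-bp), independent assortment between chromosomes, none within
genes. Deleterious mutations arise at `1.05e-8 = 1.5e-8 × 2.31/3.31` per
site per generation with `s` uniform within the sampled bin (matching the
inference mixture; the source text does not state the within-bin law).

Demography (diploids, generations): ancestral 7,310 with a 10·N/λ
generation burn-in; African growth to 14,474 at 5,920 generations BP (the
divergence time of the source two-population model; the text gives no
explicit time); European split 2,040 BP at the bottleneck size 1,861, held
until exponential growth over the last 204 generations to 424,000 (Africa)
and 512,000 (Europe). The text's bottleneck duration (1,120 generations)
leaves 716 generations unspecified before growth; they are spent at the
bottleneck size. No migration.

Rescaling by λ divides sizes and durations by λ and multiplies `s` (capped
at 1), μ and the gene-boundary recombination probability (capped at 0.5)
by λ, preserving θ, γ and ρ; a rescaling that drives any deme below 50
diploids is refused. Output metrics use the simulated coefficients divided
by λ (frequencies are λ-invariant), which makes load and B comparable
across λ — verified by a λ=2 vs λ=4 invariance test. The s-cap affects
only the reported per-site `s` of would-be `s > 1/λ` lethals and leaves
their B and load contributions unbiased (both are `∝ μ/h` at balance).

Implementation: haplotypes are CSR arrays of (mutation id, float32
position, `ln(1−sh)`) compacted every 32 generations (fixed mutations move
to per-population lists; globally lost ones are dropped so attribute
tables stay cache-resident). Per-individual fitness is a vectorized sum of
`ln(1−sh)` over both haplotypes plus an exact homozygosity correction
restricted to sites where `|ln(1−s) − 2 ln(1−sh)| > 1e-5`; for the
remaining quasi-neutral sites the correction is `O(s²) < 1e-6` per site
and omitting it perturbs log fitness by well under 1e-3 per genome.
Offspring are exchangeable, so parent pairs are processed in sorted order
for memory locality and the final 100-individual sample is drawn at random
indices. All randomness flows through one seeded generator per replicate;
runs are bit-reproducible.

Replicate ensembles share a small number of independently equilibrated
ancestral histories and fork with distinct seeds at the population split,
so the post-divergence dynamics — the part that differentiates the two
populations — are independent across replicates. Means over replicates are
unbiased; the across-replicate spread understates the (small)
pre-divergence component of variance. The packaged study runs use 20 replicates per model at λ=10 on 2
chromosomes (one to two ancestral histories, configurable).

## Load metrics

Genetic load is `1 − mean_individuals Π_sites w` from the 100-individual
sample, with population-fixed sites multiplying every individual's fitness
by `1 − s`; projection to the genome exponentiates relative fitness by the
chromosome factor (11 for 2 of 22). The inbreeding load B (haploid lethal
equivalents) is reported in the concealed-heterozygous-effect convention

    B = Σ_sites s q (1 − q) (1 − h),

i.e. half the expected per-individual sum of unexpressed heterozygous
effects `s − hs`. This is the definition consistent with the published
verbal description and it reproduces the published per-model values: the
per-bin deterministic approximation `Σ_b U_b (1 − h_b)/h_b` gives
0.54 / 0.92 / 2.2 for the three dominance models where the alternative
Morton-style slope form `Σ s q(1−q)(1−2h)` (the derivative of `−ln w̄`
with respect to F, zero for additive sites) gives 0.34 / 0.73 / 2.0.
Both are available (`inbreeding_load(..., kind="concealed" | "slope")`).
Derived-allele counts per individual count fixed sites twice and are
summed across chromosomes (projection multiplies by the factor).

## Synthetic data

The generator Poisson-samples every unmasked entry of the expected folded
spectra: synonymous from the neutral expectation at `θ_S` under the chosen
demography, nonsynonymous from the DFE/dominance mixture at
`θ_NS = 2.31 θ_S`; defaults are `n = 864` chromosomes (432 diploids),
`θ_S = 20,000` and a three-epoch out-of-Africa-style history
(bottleneck ν=0.15 for 0.05, recovery at 1.0 for 0.04, exponential growth
to 25 over 0.012, in `2N_anc` units, `N_anc = 10,000`) — round numbers of
the magnitude inferred for European-ancestry samples. Because sites are
independent under the PRF, this sampling is exact, so passing recovery
tests validates the estimator; it does not probe real-data complications
(linkage, ancestral misidentification, variable mutation rate, annotation
error), which are out of scope.

## Problem sizes used by the packaged checks

Test-suite and acceptance runs use: 20 replicates per dominance model at
λ=10 over 2 chromosomes for the inbreeding loads; 50 replicates at λ=25 on
one chromosome for the sign of the out-of-Africa load difference (the 1–2%
magnitudes require the unrescaled sizes and ~100 replicates to resolve and
are not reproduced at desk scale); 20 seeds for end-to-end recovery at
`θ_S = 20,000`, asserting across-seed mean recovery (single seeds scatter
a few percent along the demography–θ ridge); and the reduced 16-model
sweep for pipeline structure. These are the package's standard reduced
configurations; the full 4096-model sweep and 100-replicate simulations
run through the same code paths.

## Known limitations

* The diffusion engine covers a single population; the two-population
  joint SFS is out of scope (simulation handles the two-population side).
* Beneficial mutations, linkage in the inference model, and lognormal or
  point-mass DFE families are not implemented.
* Real-data log-likelihoods depend on the exact filtered input spectra and
  are not reproducible from this package alone; the pipeline accepts any
  dadi-style SFS pair and reports its own likelihoods.
* The h–s identifiability ceiling is intrinsic: many dominance models fit
  equally well, which is why model averaging and plausibility filtering,
  not point selection, are the primary outputs.
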