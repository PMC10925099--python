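# domfit

Dominance and selection inference for coding variation, from site frequency
spectra to genetic load.

How recessive are deleterious mutations? The dominance coefficient *h*
(heterozygote fitness effect relative to the homozygote) controls how
demography shapes deleterious variation and how severe inbreeding
depression is, yet *h* is nearly unidentifiable from polymorphism data
because segregating mutations are mostly heterozygous and constrain only
the product *hs*. `domfit` addresses this the way the human population
genetics literature does: instead of estimating one *h*, it maps the set of
dominance models consistent with the data and propagates that whole set
into forward simulations of genetic load.

The package provides:

* **Expected SFS under selection with dominance.** The stationary density
  f(q; γ, h) (γ = 2N₍anc₎s) is propagated through a piecewise demographic
  history with an implicit finite-volume diffusion solver and binomially
  sampled into expected spectra, cached on a 1000-point log-spaced grid of
  s ∈ [1e-5, 0.25] per dominance value. A dense Wright–Fisher
  transition-matrix oracle validates the engine at small N.
* **Poisson random field inference.** A three-epoch demography is fit to
  the folded synonymous SFS (θ profiled out in closed form,
  N₍anc₎ = θ_S/4μL_S); gamma or five-bin discrete DFEs with per-bin
  dominance are then fit to the nonsynonymous SFS with θ_NS = 2.31·θ_S
  held fixed. The per-bin sweep covers all 8⁴ = 4096 dominance maps
  (neutral bin fixed additive), filtered by a 1.92 log-likelihood
  plausibility rule and a monotonic h-s decay rule, and model-averaged
  with Akaike weights (AIC = 2k − 2 ln L).
* **Forward Wright–Fisher simulation.** Individual-based simulation of
  22,500 coding genes (1340 bp) on 22 autosomes under a two-population
  out-of-Africa history (ancestral 7,310; African growth to 14,474;
  European split 2,040 generations ago with a 1,861 bottleneck; recent
  exponential growth to 424,000/512,000), with population rescaling for
  desk-scale runs, reporting genetic load, inbreeding load B (haploid
  lethal equivalents) and derived-allele counts per individual.
* **Synthetic data.** Poisson sampling of observed spectra around the model
  expectations, so the whole inference chain is testable end to end.

## Worked example

Simulate the three published DFE/dominance models (weakly / moderately /
strongly recessive; average h = 0.40 / 0.34 / 0.26) at rescale factor 10 on
two chromosomes and project to the genome:

```python
import numpy as np
from domfit import (GenomeModel, TwoPopDemography, PUBLISHED_MODELS,
                    simulate_ensemble, project_to_genome)

genome, demo = GenomeModel(chromosomes=2), TwoPopDemography()
for name, model in PUBLISHED_MODELS.items():
    runs = [project_to_genome(r) for r in simulate_ensemble(
        genome, demo, model, rescale=10, n_reps=20, seed=1)]
    B = np.mean([(r.populations["AF"].inbreeding_load
                  + r.populations["EU"].inbreeding_load) / 2 for r in runs])
    ratio = np.mean([r.populations["EU"].genetic_load
                     / r.populations["AF"].genetic_load for r in runs])
    print(f"{name:22s} h̄={model.average_h():.2f}  B={B:.2f}  EU/AF load={ratio:.3f}")
```

prints (a few minutes per model):

```
weakly_recessive       h̄=0.40  B=0.57  EU/AF load=1.027
moderately_recessive   h̄=0.34  B=0.92  EU/AF load=1.004
strongly_recessive     h̄=0.26  B=2.02  EU/AF load=0.981
```

The inbreeding load rises steeply as strongly deleterious mutations become
more recessive — more selection hidden in heterozygotes — spanning the
range of empirical human estimates (~0.7–2.5 lethal equivalents), and the
sign of the out-of-Africa load difference flips: the European bottleneck
slightly *increases* load under weakly recessive models but *purges* it
under strongly recessive ones.

The inference side runs from two dadi-style SFS files:

```bash
domfit run --config run.yaml        # demography → caches → fits → averages
domfit simulate --model strongly_recessive --chroms 2 --reps 20 --rescale 10 --seed 1
```

with a YAML config naming the synonymous/nonsynonymous spectra, μ, L_S and
grid/optimizer settings (see `domfit.pipeline.RunConfig`).

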