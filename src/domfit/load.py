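"""Genetic load, inbreeding load and allele-count metrics from samples.

Genetic load is the proportional reduction in mean fitness from segregating
and fixed deleterious alleles, with fitness multiplicative across sites
(simulation convention: heterozygote 1-sh, mutant homozygote 1-s).  The
inbreeding load B, in haploid lethal equivalents, sums the selective effects
concealed in heterozygotes.  Two conventions are standard and both are
offered:

* ``kind="concealed"`` (default): each heterozygous site hides an effect
  s - hs, so per individual the concealed load is sum over het sites of
  s (1 - h); its expectation per haploid genome is

      B = sum_sites s q (1 - q) (1 - h).

* ``kind="slope"``: the Morton-style derivative of -ln(mean fitness) with
  respect to the inbreeding coefficient F,

      B = sum_sites s q (1 - q) (1 - 2h),

  which equals the difference in expected (additively composed) load
  between a fully inbred (F = 1) and a random-mating (F = 0) genotype
  distribution; fully additive sites (h = 0.5) then contribute nothing.

Fixed sites contribute to neither.  The allele count is the mean number of
derived deleterious alleles carried per individual, counting fixed sites
twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SampleGenotypes",
    "PopMetrics",
    "SimResult",
    "genetic_load",
    "inbreeding_load",
    "derived_allele_count",
    "project_to_genome",
    "results_frame",
]


@dataclass
class SampleGenotypes:
    """Genotypes (0/1/2 copies) of sampled individuals at segregating sites.

    ``s`` and ``h`` are per-site simulation-convention coefficients (after
    any rescaling has been divided back out); ``fixed_s``/``fixed_h`` list
    sites fixed in the population the sample came from.
    """

    genotypes: np.ndarray
    s: np.ndarray
    h: np.ndarray
    fixed_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    fixed_h: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be (individuals, sites)")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0, 1 or 2")
        for name in ("s", "h", "fixed_s", "fixed_h"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.s.size != self.genotypes.shape[1] or self.h.size != self.s.size:
            raise ValueError("per-site s/h must match the genotype matrix")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    def frequencies(self) -> np.ndarray:
        """Sample allele frequencies q at the segregating sites."""
        return self.genotypes.sum(axis=0) / (2.0 * self.n_individuals)


@dataclass
class PopMetrics:
    """Per-population summary: load in [0,1], B >= 0, mean allele count."""

    genetic_load: float
    inbreeding_load: float
    allele_count: float


@dataclass
class SimResult:
    """Per-replicate simulation output."""

    populations: dict
    rescale: float
    seed: int
    sample_size: int
    chromosomes: int
    projection: float = 1.0


def genetic_load(sample: SampleGenotypes) -> float:
    """1 - mean multiplicative fitness over the sampled individuals.

    Heterozygous sites contribute (1-sh), homozygous (1-s); sites fixed in
    the population multiply every individual's fitness by (1-s).
    """
    G = sample.genotypes
    with np.errstate(divide="ignore"):
        lw_het = np.log(np.clip(1.0 - sample.s * sample.h, 0.0, None))
        lw_hom = np.log(np.clip(1.0 - sample.s, 0.0, None))
        lw_fixed = np.sum(np.log(np.clip(1.0 - sample.fixed_s, 0.0, None)))
    log_w = (G == 1) @ lw_het + (G == 2) @ lw_hom + lw_fixed
    return float(1.0 - np.exp(log_w).mean())


def inbreeding_load(sample: SampleGenotypes, kind: str = "concealed") -> float:
    """Haploid lethal equivalents B over segregating sites.

    ``kind="concealed"``: B = sum s q (1-q) (1-h), the expected per-haploid
    sum of unexpressed heterozygous effects.  ``kind="slope"``: the
    d(-ln w)/dF form with (1-2h), zero for additive sites.
    """
    q = sample.frequencies()
    if kind == "concealed":
        dom = 1.0 - sample.h
    elif kind == "slope":
        dom = 1.0 - 2.0 * sample.h
    else:
        raise ValueError("kind must be 'concealed' or 'slope'")
    return float(np.sum(sample.s * q * (1.0 - q) * dom))


def derived_allele_count(sample: SampleGenotypes) -> float:
    """Mean derived deleterious alleles per individual (fixed sites count 2)."""
    return float(sample.genotypes.sum(axis=1).mean() + 2.0 * sample.fixed_s.size)


def project_to_genome(result: SimResult, factor: float | None = None) -> SimResult:
    """Scale chromosome-subset results to the 22-autosome genome.

    load' = 1 - (1-load)^factor (fitness values exponentiated by the factor),
    B and allele counts multiply by it.  The factor defaults to
    22 / chromosomes simulated and must be a whole number of chromosome
    copies (11 when 2 chromosomes were run).
    """
    if factor is None:
        if 22 % result.chromosomes != 0:
            raise ValueError(
                f"{result.chromosomes} chromosomes do not divide 22 evenly; "
                "pass an explicit factor"
            )
        factor = 22 // result.chromosomes
    if factor != int(factor):
        raise ValueError("projection factor must be an integer")
    factor = float(factor)
    pops = {
        name: PopMetrics(
            genetic_load=1.0 - (1.0 - m.genetic_load) ** factor,
            inbreeding_load=m.inbreeding_load * factor,
            allele_count=m.allele_count * factor,
        )
        for name, m in result.populations.items()
    }
    return replace(result, populations=pops, projection=factor)


def results_frame(results: list[SimResult]) -> "pd.DataFrame":
    """Tidy per-replicate, per-population table of the three metrics."""
    import pandas as pd

    rows = []
    for r in results:
        for name, m in r.populations.items():
            rows.append(
                {
                    "seed": r.seed,
                    "population": name,
                    "load": m.genetic_load,
                    "inbreeding_load": m.inbreeding_load,
                    "allele_count": m.allele_count,
                    "projected": r.projection != 1.0,
                    "rescale": r.rescale,
                }
            )
    return pd.DataFrame(rows)
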