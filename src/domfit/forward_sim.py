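"""Forward Wright-Fisher simulation of deleterious coding variation.

Simulates 1340-bp genes spread over autosomes (22,500 genes over 22
autosomes for the full genome), free recombination between chromosomes, a
per-gene-boundary crossover probability within them, and no recombination
within genes.  Deleterious mutations arise at 1.05e-8 per site per
generation with selection and dominance drawn from a discrete DFE/dominance
model; fitness is multiplicative across sites with the simulation
convention: mutant homozygote 1-s, heterozygote 1-sh, s in [0, 1].

Population rescaling by a factor lambda divides population sizes and epoch
durations by lambda and multiplies s (capped at 1), the mutation rate and
the gene-boundary recombination probability (capped at 0.5) by lambda,
preserving the population-scaled parameters theta = 4Nu, gamma = 2Ns and
rho.  Output metrics are computed with the simulated selection coefficients
divided by lambda, which makes load and inbreeding load comparable across
rescaling factors (allele frequencies are invariant under the rescaling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _simcore as core
from .dfe import DiscreteDFE, DominanceMap
from .load import PopMetrics, SampleGenotypes, SimResult, derived_allele_count, genetic_load, inbreeding_load

__all__ = [
    "GenomeModel",
    "TwoPopDemography",
    "SimDominanceModel",
    "simulate",
    "simulate_ensemble",
    "simulate_constant",
    "draw_mutation_effect",
    "WEAKLY_RECESSIVE",
    "MODERATELY_RECESSIVE",
    "STRONGLY_RECESSIVE",
    "PUBLISHED_MODELS",
]

#: simulation-convention bin edges over |s| (twice the inference edges)
SIM_BIN_EDGES = (0.0, 2e-5, 2e-4, 2e-3, 2e-2, 1.0)

_FULL_GENES = 22_500
_FULL_CHROMS = 22


def _gene_partition(n_chrom: int = _FULL_CHROMS, total: int = _FULL_GENES) -> np.ndarray:
    base = total // n_chrom
    rem = total - base * n_chrom
    return np.array([base + (1 if c < rem else 0) for c in range(n_chrom)], dtype=np.int64)


@dataclass
class GenomeModel:
    """Coding-genome layout and mutational/recombination parameters."""

    chromosomes: int = _FULL_CHROMS
    gene_length: int = 1340
    recomb_between_genes: float = 1e-3
    mu_deleterious: float = 1.05e-8

    def __post_init__(self) -> None:
        if not 1 <= self.chromosomes <= _FULL_CHROMS:
            raise ValueError("chromosomes must be between 1 and 22")
        full = _gene_partition()
        self.genes_per_chrom = full[: self.chromosomes].copy()

    @property
    def total_genes(self) -> int:
        return int(self.genes_per_chrom.sum())

    @property
    def total_bp(self) -> int:
        return self.total_genes * self.gene_length

    @property
    def chrom_starts(self) -> np.ndarray:
        """Cumulative gene offsets (length chromosomes+1), in gene units."""
        return np.concatenate([[0.0], np.cumsum(self.genes_per_chrom)]).astype(float)


@dataclass
class TwoPopDemography:
    """Two-population out-of-Africa history (sizes in diploids, times in
    generations before present)."""

    N_anc: int = 7_310
    N_afr: int = 14_474
    T_afr_growth: int = 5_920
    T_split: int = 2_040
    N_eu_bottleneck: int = 1_861
    bottleneck_duration: int = 1_120
    T_growth: int = 204
    N_afr_final: int = 424_000
    N_eu_final: int = 512_000

    def __post_init__(self) -> None:
        sizes = (
            self.N_anc,
            self.N_afr,
            self.N_eu_bottleneck,
            self.N_afr_final,
            self.N_eu_final,
        )
        if any(s <= 0 for s in sizes):
            raise ValueError("population sizes must be positive")
        if not (self.T_afr_growth > self.T_split > self.T_growth > 0):
            raise ValueError("time schedule must satisfy T_afr_growth > T_split > T_growth")
        if self.bottleneck_duration + self.T_growth > self.T_split:
            raise ValueError("bottleneck plus growth cannot exceed the time since the split")


@dataclass
class SimDominanceModel:
    """Discrete DFE proportions with per-bin h, simulation convention."""

    proportions: tuple
    h_per_bin: tuple
    name: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        h = np.asarray(self.h_per_bin, dtype=float)
        if p.shape != (5,) or h.shape != (5,):
            raise ValueError("need 5 proportions and 5 h values")
        # published tables carry 3-decimal rounding (sums can be 1.001)
        if abs(p.sum() - 1.0) > 5e-3:
            raise ValueError("proportions must sum to 1")
        if np.any(p < 0) or np.any(h < 0) or np.any(h > 1):
            raise ValueError("invalid proportions or h values")
        self.proportions = tuple(p / p.sum())

    @classmethod
    def from_inference(cls, dfe: DiscreteDFE, hmap: DominanceMap, name: str = "") -> "SimDominanceModel":
        """Convert inference-convention (1-2s, 1-2sh) to simulation convention.

        Proportions and h carry over; the bin edges double (s_sim = 2 s_inf).
        """
        return cls(tuple(dfe.proportions), tuple(hmap.h_per_bin), name=name)

    def average_h(self) -> float:
        return float(np.dot(self.proportions, self.h_per_bin))


def draw_mutation_effect(model: SimDominanceModel, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (s, h) for one new mutation: bin by proportions, s uniform in bin."""
    b = rng.choice(5, p=np.asarray(model.proportions))
    lo, hi = SIM_BIN_EDGES[b], SIM_BIN_EDGES[b + 1]
    return float(rng.uniform(lo, hi)), float(model.h_per_bin[b])


# The three published DFE/dominance models used for the simulations.
WEAKLY_RECESSIVE = SimDominanceModel(
    (0.259, 0.125, 0.176, 0.254, 0.186), (0.5, 0.5, 0.5, 0.35, 0.15), name="weakly_recessive"
)
MODERATELY_RECESSIVE = SimDominanceModel(
    (0.244, 0.152, 0.125, 0.259, 0.22), (0.5, 0.5, 0.45, 0.25, 0.1), name="moderately_recessive"
)
STRONGLY_RECESSIVE = SimDominanceModel(
    (0.201, 0.222, 0.018, 0.286, 0.274), (0.5, 0.45, 0.25, 0.15, 0.05), name="strongly_recessive"
)
PUBLISHED_MODELS = {
    "weakly_recessive": WEAKLY_RECESSIVE,
    "moderately_recessive": MODERATELY_RECESSIVE,
    "strongly_recessive": STRONGLY_RECESSIVE,
}


# ---------------------------------------------------------------------------
# simulation state
# ---------------------------------------------------------------------------


class _Tables:
    """Global mutation attribute tables, compacted at every sweep."""

    _FIELDS = ("s_sim", "h", "lw_hom")

    def __init__(self, cap: int = 500_000):
        self.s_sim = np.empty(cap, dtype=np.float32)
        self.h = np.empty(cap, dtype=np.float32)
        self.lw_hom = np.empty(cap, dtype=np.float64)
        self.count = 0

    @property
    def cap(self) -> int:
        return self.s_sim.size

    def grow(self) -> None:
        newcap = int(self.cap * 1.6) + 1024
        for name in self._FIELDS:
            old = getattr(self, name)
            new = np.empty(newcap, dtype=old.dtype)
            new[: old.size] = old
            setattr(self, name, new)

    def gather(self, keep: np.ndarray) -> None:
        """Keep only the rows in ``keep`` (new index = position in keep)."""
        for name in self._FIELDS:
            old = getattr(self, name)
            new = np.empty(old.size, dtype=old.dtype)
            new[: keep.size] = old[keep]
            setattr(self, name, new)
        self.count = keep.size


class _Population:
    """Haplotype state plus reusable double buffers for reproduction."""

    _MAIN = ("ids", "poss", "lws", "cls")
    _SEL = ("sel_ids", "sel_poss", "sel_lws")
    _DTYPES = {
        "ids": np.int32,
        "poss": np.float32,
        "lws": np.float32,
        "cls": np.int8,
        "sel_ids": np.int32,
        "sel_poss": np.float32,
        "sel_lws": np.float32,
    }

    def __init__(self, name: str, n: int):
        self.name = name
        self._cur = {f: np.empty(1024, dtype=d) for f, d in self._DTYPES.items()}
        self._scr = {f: np.empty(1024, dtype=d) for f, d in self._DTYPES.items()}
        self._indptr_cur = np.zeros(2 * n + 1, dtype=np.int64)
        self._indptr_scr = np.zeros(2 * n + 1, dtype=np.int64)
        self._sel_indptr_cur = np.zeros(2 * n + 1, dtype=np.int64)
        self._sel_indptr_scr = np.zeros(2 * n + 1, dtype=np.int64)
        self.total = 0
        self.sel_total = 0
        self._n = n
        # selection parameters of mutations fixed in this population
        self.fixed_s: list = []
        self.fixed_h: list = []

    @property
    def n(self) -> int:
        return self._n

    @property
    def indptr(self) -> np.ndarray:
        return self._indptr_cur

    @property
    def sel_indptr(self) -> np.ndarray:
        return self._sel_indptr_cur

    def __getattr__(self, name):
        if name in ("ids", "poss", "lws", "cls"):
            return self._cur[name][: self.total]
        if name in ("sel_ids", "sel_poss", "sel_lws"):
            return self._cur[name][: self.sel_total]
        raise AttributeError(name)

    def _ensure_scratch(self, est: int, sest: int, n_next: int) -> None:
        if self._scr["ids"].size < est:
            for f in self._MAIN:
                self._scr[f] = np.empty(est, dtype=self._DTYPES[f])
        if self._scr["sel_ids"].size < sest:
            for f in self._SEL:
                self._scr[f] = np.empty(sest, dtype=self._DTYPES[f])
        if self._indptr_scr.size < 2 * n_next + 1:
            self._indptr_scr = np.empty(2 * n_next + 1, dtype=np.int64)
            self._sel_indptr_scr = np.empty(2 * n_next + 1, dtype=np.int64)

    def _promote(self, n_next: int, total: int, sel_total: int) -> None:
        self._cur, self._scr = self._scr, self._cur
        self._indptr_cur, self._indptr_scr = self._indptr_scr, self._indptr_cur
        self._sel_indptr_cur, self._sel_indptr_scr = (
            self._sel_indptr_scr,
            self._sel_indptr_cur,
        )
        self._n = n_next
        self.total = total
        self.sel_total = sel_total

    def clone_fixed_from(self, other: "_Population") -> None:
        self.fixed_s = list(other.fixed_s)
        self.fixed_h = list(other.fixed_h)


def _sweep_all(pops: list[_Population], tables: _Tables) -> None:
    """Sweep fixed mutations per population and compact the global tables.

    Fixed mutations leave the haplotype arrays (their selection parameters
    are recorded per population); mutations lost everywhere are dropped from
    the tables and survivors renumbered, keeping the tables dense and small.
    """
    mc = tables.count
    counts = []
    for pop in pops:
        c = np.zeros(mc, dtype=np.int64)
        core.count_alleles(pop.indptr, pop.ids, 2 * pop.n, c)
        counts.append(c)
    for pop, c in zip(pops, counts):
        fixed = np.nonzero(c == 2 * pop.n)[0]
        if fixed.size:
            total = core.remove_fixed(
                pop.indptr, pop.ids, pop.poss, pop.lws, pop.cls, 2 * pop.n, c
            )
            stotal = core.remove_fixed_sel(
                pop.sel_indptr, pop.sel_ids, pop.sel_poss, pop.sel_lws, 2 * pop.n, c
            )
            pop.total = total
            pop.sel_total = stotal
            pop.fixed_s.extend(tables.s_sim[fixed].tolist())
            pop.fixed_h.extend(tables.h[fixed].tolist())
            c[fixed] = 0
    live = counts[0] > 0
    for c in counts[1:]:
        live |= c > 0
    live_idx = np.nonzero(live)[0]
    mapping = np.full(mc, -1, dtype=np.int32)
    mapping[live_idx] = np.arange(live_idx.size, dtype=np.int32)
    tables.gather(live_idx)
    for pop in pops:
        pop.ids[:] = mapping[pop.ids]
        pop.sel_ids[:] = mapping[pop.sel_ids]


def _xover_cdf(genome: GenomeModel, r_boundary: float) -> np.ndarray:
    """Per-chromosome cumulative pmf of the crossover count per meiosis."""
    from scipy import stats

    tails = []
    for nb in genome.genes_per_chrom:
        nb = int(nb) - 1
        kmax = int(stats.binom.ppf(1.0 - 1e-13, nb, r_boundary)) + 2
        tails.append(stats.binom.cdf(np.arange(kmax), nb, r_boundary))
    width = max(len(t) for t in tails) + 1
    cdf = np.ones((len(tails), width))
    cdf[:, -1] = 1.1  # sentinel: the scan always terminates
    for i, t in enumerate(tails):
        cdf[i, : len(t)] = t
        cdf[i, len(t) : -1] = 1.0
    return cdf


def _advance(
    src: _Population,
    n_next: int,
    tables: _Tables,
    genome: GenomeModel,
    model: SimDominanceModel,
    lam: float,
    u_gamete: float,
    xover_cdf: np.ndarray,
    dst: _Population | None = None,
) -> _Population:
    """One Wright-Fisher generation: src parents -> population of n_next."""
    n_par = src.n
    w = np.empty(n_par)
    core.fitness(
        src.indptr,
        src.lws,
        src.sel_indptr,
        src.sel_ids,
        src.sel_poss,
        src.sel_lws,
        tables.lw_hom,
        n_par,
        w,
    )
    if not np.isfinite(w).all() or w.sum() <= 0.0:
        raise RuntimeError(f"population {src.name} has no viable parents")
    parents = np.empty(2 * n_next, dtype=np.int64)
    core.choose_parents(w, n_par, n_next, parents)
    # offspring are exchangeable: ordering them by first parent makes the
    # parental reads near-sequential (sampling later picks random indices)
    order = np.argsort(parents[0::2], kind="stable")
    pairs = parents.reshape(-1, 2)[order]
    parents = pairs.reshape(-1)
    bins = np.asarray(model.proportions)
    bin_cum = np.cumsum(bins)[:4]
    edges = np.asarray(SIM_BIN_EDGES)
    ratio = n_next / max(n_par, 1)
    target = dst if dst is not None else src
    est = int(src.total * ratio * 1.25) + 64 * n_next + 1024
    sest = int(src.sel_total * ratio * 1.25) + 64 * n_next + 1024
    target._ensure_scratch(est, sest, n_next)
    while True:
        scr = target._scr
        status, total, sel_total, mcount = core.reproduce(
            src.indptr,
            src.ids,
            src.poss,
            src.lws,
            src.cls,
            src.sel_indptr,
            parents,
            n_next,
            tables.s_sim,
            tables.h,
            tables.lw_hom,
            tables.count,
            tables.cap,
            genome.chrom_starts,
            genome.genes_per_chrom,
            xover_cdf,
            u_gamete,
            bin_cum,
            edges[:5],
            edges[1:],
            np.asarray(model.h_per_bin),
            lam,
            scr["ids"],
            scr["poss"],
            scr["lws"],
            scr["cls"],
            target._indptr_scr,
            scr["sel_ids"],
            scr["sel_poss"],
            scr["sel_lws"],
            target._sel_indptr_scr,
        )
        if status == core.STATUS_OK:
            break
        if status == core.STATUS_GROW_IDS:
            target._ensure_scratch(int(scr["ids"].size * 1.6) + 1024, sest, n_next)
        elif status == core.STATUS_GROW_SEL:
            target._ensure_scratch(est, int(scr["sel_ids"].size * 1.6) + 1024, n_next)
        else:
            tables.grow()
    tables.count = mcount
    target._promote(n_next, total, sel_total)
    return target


def _exp_schedule(n_start: int, n_end: int, gens: int) -> np.ndarray:
    """Per-generation sizes for exponential growth, rounded to integers."""
    t = np.arange(1, gens + 1)
    return np.rint(n_start * (n_end / n_start) ** (t / gens)).astype(int)


def _extract_sample(
    pop: _Population,
    tables: _Tables,
    sample_size: int,
    lam: float,
    sample_seed: int = 0,
) -> SampleGenotypes:
    """Genotypes of ``sample_size`` individuals drawn without replacement."""
    n = min(sample_size, pop.n)
    rng = np.random.default_rng(sample_seed)
    chosen = rng.choice(pop.n, size=n, replace=False)
    pieces = [pop.ids[pop.indptr[2 * i] : pop.indptr[2 * i + 2]] for i in chosen]
    sample_ids = np.concatenate(pieces) if pieces else np.empty(0, dtype=np.int32)
    sites, inverse = np.unique(sample_ids, return_inverse=True)
    G = np.zeros((n, sites.size), dtype=np.int8)
    off = 0
    for i in range(n):
        k = pieces[i].size
        np.add.at(G[i], inverse[off : off + k], 1)
        off += k
    return SampleGenotypes(
        genotypes=G,
        s=tables.s_sim[sites].astype(float) / lam,
        h=tables.h[sites].astype(float),
        fixed_s=np.asarray(pop.fixed_s, dtype=float) / lam,
        fixed_h=np.asarray(pop.fixed_h, dtype=float),
    )


def _metrics(sample: SampleGenotypes) -> PopMetrics:
    return PopMetrics(
        genetic_load=genetic_load(sample),
        inbreeding_load=inbreeding_load(sample),
        allele_count=derived_allele_count(sample),
    )


def _rescaled_sizes(demo: TwoPopDemography, lam: float) -> dict:
    sizes = {
        "anc": max(1, round(demo.N_anc / lam)),
        "afr": max(1, round(demo.N_afr / lam)),
        "eu_b": max(1, round(demo.N_eu_bottleneck / lam)),
        "afr_f": max(1, round(demo.N_afr_final / lam)),
        "eu_f": max(1, round(demo.N_eu_final / lam)),
    }
    if min(sizes.values()) < 50:
        raise ValueError(
            f"rescale={lam} drives a deme below 50 diploids ({sizes}); "
            "drift would be badly distorted"
        )
    return sizes


def _snapshot(tables: _Tables, pop: _Population) -> tuple:
    state = {
        "tables": {f: getattr(tables, f)[: tables.count].copy() for f in _Tables._FIELDS},
        "count": tables.count,
        "indptr": pop.indptr.copy(),
        "sel_indptr": pop.sel_indptr.copy(),
        "main": {f: getattr(pop, f).copy() for f in _Population._MAIN},
        "sel": {f: getattr(pop, f).copy() for f in _Population._SEL},
        "fixed_s": list(pop.fixed_s),
        "fixed_h": list(pop.fixed_h),
        "n": pop.n,
        "name": pop.name,
    }
    return (state,)


def _restore(snap: tuple) -> tuple[_Tables, _Population]:
    state = snap[0]
    tables = _Tables(max(state["count"] * 2, 100_000))
    for f in _Tables._FIELDS:
        getattr(tables, f)[: state["count"]] = state["tables"][f]
    tables.count = state["count"]
    pop = _Population(state["name"], state["n"])
    total = state["main"]["ids"].size
    sel_total = state["sel"]["sel_ids"].size
    pop._ensure_scratch(total + 1024, sel_total + 1024, state["n"])
    for f in _Population._MAIN:
        pop._scr[f][:total] = state["main"][f]
    for f in _Population._SEL:
        pop._scr[f][:sel_total] = state["sel"][f]
    pop._indptr_scr[: state["indptr"].size] = state["indptr"]
    pop._sel_indptr_scr[: state["sel_indptr"].size] = state["sel_indptr"]
    pop._promote(state["n"], total, sel_total)
    pop.fixed_s = list(state["fixed_s"])
    pop.fixed_h = list(state["fixed_h"])
    return tables, pop


def _ancestral_state(
    genome: GenomeModel,
    demo: TwoPopDemography,
    model: SimDominanceModel,
    lam: float,
    burn_in: int | None,
    seed: int,
    sweep_interval: int,
) -> tuple:
    """Burn in at the ancestral size and run the pre-divergence African
    growth period; returns a snapshot taken at the population split."""
    sizes = _rescaled_sizes(demo, lam)
    if burn_in is None:
        burn_in = 10 * sizes["anc"]
    u_gamete = genome.mu_deleterious * lam * genome.total_bp
    r_boundary = min(genome.recomb_between_genes * lam, 0.5)
    xover_cdf = _xover_cdf(genome, r_boundary)
    gens_pre_split = round((demo.T_afr_growth - demo.T_split) / lam)
    core.seed_rng(seed % 2**31)
    tables = _Tables()
    af = _Population("AF", sizes["anc"])
    args = (tables, genome, model, lam, u_gamete, xover_cdf)
    for g in range(burn_in):
        _advance(af, sizes["anc"], *args)
        if (g + 1) % sweep_interval == 0:
            _sweep_all([af], tables)
    for g in range(gens_pre_split):
        _advance(af, sizes["afr"], *args)
        if (g + 1) % sweep_interval == 0:
            _sweep_all([af], tables)
    _sweep_all([af], tables)
    return _snapshot(tables, af)


def _post_split(
    snap: tuple,
    genome: GenomeModel,
    demo: TwoPopDemography,
    model: SimDominanceModel,
    lam: float,
    seed: int,
    sample_size: int,
    sweep_interval: int,
    return_samples: bool,
):
    """European founding, bottleneck and the recent growth in both
    populations, starting from an ancestral snapshot."""
    sizes = _rescaled_sizes(demo, lam)
    u_gamete = genome.mu_deleterious * lam * genome.total_bp
    r_boundary = min(genome.recomb_between_genes * lam, 0.5)
    xover_cdf = _xover_cdf(genome, r_boundary)
    gens_split_to_growth = round((demo.T_split - demo.T_growth) / lam)
    gens_growth = round(demo.T_growth / lam)
    core.seed_rng(seed % 2**31)
    tables, af = _restore(snap)
    args = (tables, genome, model, lam, u_gamete, xover_cdf)
    eu = _Population("EU", sizes["eu_b"])
    _advance(af, sizes["eu_b"], *args, dst=eu)
    eu.clone_fixed_from(af)
    _advance(af, sizes["afr"], *args)
    for g in range(gens_split_to_growth - 1):
        _advance(af, sizes["afr"], *args)
        _advance(eu, sizes["eu_b"], *args)
        if (g + 1) % sweep_interval == 0:
            _sweep_all([af, eu], tables)
    af_sched = _exp_schedule(sizes["afr"], sizes["afr_f"], gens_growth)
    eu_sched = _exp_schedule(sizes["eu_b"], sizes["eu_f"], gens_growth)
    _sweep_all([af, eu], tables)
    for g in range(gens_growth):
        _advance(af, int(af_sched[g]), *args)
        _advance(eu, int(eu_sched[g]), *args)
    _sweep_all([af, eu], tables)
    samples = {
        "AF": _extract_sample(af, tables, sample_size, lam, sample_seed=seed + 1),
        "EU": _extract_sample(eu, tables, sample_size, lam, sample_seed=seed + 2),
    }
    result = SimResult(
        populations={name: _metrics(s) for name, s in samples.items()},
        rescale=lam,
        seed=seed,
        sample_size=sample_size,
        chromosomes=genome.chromosomes,
        projection=1.0,
    )
    return (result, samples) if return_samples else result


def simulate(
    genome: GenomeModel,
    demo: TwoPopDemography,
    model: SimDominanceModel,
    rescale: float = 1.0,
    burn_in: int | None = None,
    seed: int = 0,
    sample_size: int = 100,
    sweep_interval: int = 32,
    return_samples: bool = False,
) -> SimResult | tuple[SimResult, dict]:
    """Run the two-population out-of-Africa forward simulation.

    Returns per-population genetic load, inbreeding load B (haploid lethal
    equivalents) and mean derived-allele count from a ``sample_size``
    individual sample at the final generation.  Metrics are unprojected
    (chromosome-subset scale); see :func:`domfit.load.project_to_genome`.
    """
    lam = float(rescale)
    if lam < 1.0:
        raise ValueError("rescale factor must be >= 1")
    snap = _ancestral_state(genome, demo, model, lam, burn_in, seed, sweep_interval)
    return _post_split(
        snap, genome, demo, model, lam, seed + 1_000_003, sample_size,
        sweep_interval, return_samples,
    )


def simulate_ensemble(
    genome: GenomeModel,
    demo: TwoPopDemography,
    model: SimDominanceModel,
    rescale: float,
    n_reps: int,
    seed: int = 0,
    n_ancestries: int = 2,
    burn_in: int | None = None,
    sample_size: int = 100,
    sweep_interval: int = 32,
) -> list[SimResult]:
    """Replicate runs sharing equilibrated ancestral histories.

    ``n_ancestries`` independent burn-in + pre-divergence histories are
    generated; replicates fork from them (round-robin) at the population
    split with distinct seeds, so the post-divergence dynamics - the part
    that differentiates the two populations - are independent across
    replicates.  Means over replicates are unbiased; across-replicate
    variance reflects post-divergence randomness only within each ancestry.
    """
    lam = float(rescale)
    if lam < 1.0:
        raise ValueError("rescale factor must be >= 1")
    snaps = [
        _ancestral_state(
            genome, demo, model, lam, burn_in, seed + 7_919 * a, sweep_interval
        )
        for a in range(n_ancestries)
    ]
    results = []
    for r in range(n_reps):
        snap = snaps[r % n_ancestries]
        rep_seed = (seed + 104_729 * (r + 1)) % 2**31
        results.append(
            _post_split(
                snap, genome, demo, model, lam, rep_seed, sample_size,
                sweep_interval, False,
            )
        )
    return results


def simulate_constant(
    genome: GenomeModel,
    model: SimDominanceModel,
    N: int,
    generations: int,
    rescale: float = 1.0,
    seed: int = 0,
    sample_size: int = 100,
    sweep_interval: int = 32,
) -> tuple[SimResult, SampleGenotypes]:
    """Single constant-size population run (equilibrium studies and tests)."""
    lam = float(rescale)
    n = max(1, round(N / lam))
    if n < 50:
        raise ValueError("rescaled population below 50 diploids")
    u_gamete = genome.mu_deleterious * lam * genome.total_bp
    r_boundary = min(genome.recomb_between_genes * lam, 0.5)
    xover_cdf = _xover_cdf(genome, r_boundary)
    core.seed_rng(seed % 2**31)
    tables = _Tables(200_000)
    pop = _Population("P", n)
    args = (tables, genome, model, lam, u_gamete, xover_cdf)
    for g in range(generations):
        _advance(pop, n, *args)
        if (g + 1) % sweep_interval == 0:
            _sweep_all([pop], tables)
    _sweep_all([pop], tables)
    sample = _extract_sample(pop, tables, sample_size, lam, sample_seed=seed + 1)
    result = SimResult(
        populations={"P": _metrics(sample)},
        rescale=lam,
        seed=seed,
        sample_size=sample_size,
        chromosomes=genome.chromosomes,
        projection=1.0,
    )
    return result, sample
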