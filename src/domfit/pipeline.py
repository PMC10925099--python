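"""Full-analysis orchestration: demography -> caches -> DFE/dominance fits
-> filters -> model averaging -> simulations -> report.

Every stage is seeded from the global seed, logged with its runtime, and
written as a TSV table in the output directory, so a run is reproducible
bit-for-bit from its config.  Expected-SFS caches are stored on disk keyed
by (h, demography, n) and reused when the key matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .demography import EpochModel
from .dfe import (
    H_CHOICES,
    H_SCAN,
    HSModel,
    average_h,
    enumerate_hs_models,
    monotonic_filter,
)
from .expected import ExpectedSFSCache, build_grid_cache
from .inference import (
    LL_THRESHOLD,
    average_hs_models,
    fit_demography,
    plausibility_filter,
    profile_h_scan,
    sweep_hs_models,
)
from .load import project_to_genome, results_frame
from .sfs import read_sfs

logger = logging.getLogger("domfit.pipeline")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    syn_sfs: str
    nonsyn_sfs: str
    outdir: str = "domfit_out"
    mu: float = 1.5e-8
    L_S: float = 3.33e7
    ratio_NS_S: float = 2.31
    seed: int = 1
    ll_threshold: float = LL_THRESHOLD
    gamma_starts: int = 25
    hs_starts: int = 5
    demog_starts: int = 5
    h_scan: tuple = H_SCAN
    h_choices: tuple = H_CHOICES
    n_s: int = 1000
    demog_template: dict | None = None
    demog_free: tuple | None = None
    run_hs_sweep: bool = True
    simulate: dict | None = None

    def __post_init__(self) -> None:
        if self.ll_threshold <= 0:
            raise ValueError("the LL plausibility threshold must be positive")
        for h in tuple(self.h_scan) + tuple(self.h_choices):
            if not 0.0 <= h <= 1.0:
                raise ValueError("h values must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("h_scan", "h_choices", "demog_free"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _cache_key(h: float, demo: EpochModel, n: int, n_s: int) -> str:
    payload = json.dumps(
        {"h": h, "demo": demo.key(), "N_anc": demo.N_anc, "n": n, "n_s": n_s},
        sort_keys=True,
        default=float,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _get_cache(
    h: float, demo: EpochModel, n: int, n_s: int, cache_dir: Path
) -> ExpectedSFSCache:
    key = _cache_key(h, demo, n, n_s)
    path = cache_dir / f"cache_h{h}_{key}.npz"
    if path.exists():
        logger.info("reusing expected-SFS cache %s", path.name)
        return ExpectedSFSCache.load(path)
    t0 = time.time()
    cache = build_grid_cache(h, demo, n, N_anc=demo.N_anc, n_s=n_s)
    cache.save(path)
    logger.info("built cache h=%s in %.1fs", h, time.time() - t0)
    return cache


def _models_table(models: list[HSModel]) -> pd.DataFrame:
    rows = []
    for m in models:
        row = {}
        for i, p in enumerate(m.dfe.proportions):
            row[f"p{i + 1}"] = p
        for i, h in enumerate(m.hmap.h_per_bin):
            row[f"h{i + 1}"] = h
        row["ll"] = m.ll
        row["aic"] = m.aic
        row["avg_h"] = average_h(m.dfe, m.hmap)
        row["monotonic"] = m.hmap.is_monotonic_decay()
        rows.append(row)
    return pd.DataFrame(rows)


def _average_row(label: str, avg) -> dict:
    row = {"model_set": label, "n_models": avg.n_models}
    for i, p in enumerate(avg.dfe_proportions):
        row[f"p{i + 1}"] = p
    for i, h in enumerate(avg.h_per_bin):
        row[f"h{i + 1}"] = h
    row["avg_h"] = avg.overall_h
    return row


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle as DataFrames.

    Stages: demographic fit on the synonymous SFS; expected-SFS caches for
    every h in use; gamma and discrete profile-h scans; the per-bin h-s model
    sweep; LL-plausibility and monotonic-decay filters; Akaike-weight model
    averages for the three model sets; optional forward simulations.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache_dir = outdir / "caches"
    cache_dir.mkdir(exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO, format="%(asctime)s %(name)s %(message)s")

    syn = read_sfs(config.syn_sfs)
    nonsyn = read_sfs(config.nonsyn_sfs)
    if syn.n != nonsyn.n:
        raise ValueError("synonymous and nonsynonymous SFS have different n")
    bundle: dict = {}

    # stage 1: demography from the synonymous SFS, theta profiled out
    t0 = time.time()
    kwargs = {}
    if config.demog_free is not None:
        kwargs["free"] = config.demog_free
    demog_fit, pg, demo = fit_demography(
        syn,
        mu=config.mu,
        L_S=config.L_S,
        template=config.demog_template,
        n_starts=config.demog_starts,
        seed=config.seed,
        ratio_NS_S=config.ratio_NS_S,
        **kwargs,
    )
    logger.info(
        "demography: LL=%.2f theta_S=%.1f N_anc=%.0f (%.1fs)",
        demog_fit.ll, pg.theta_S, pg.N_anc, time.time() - t0,
    )
    demog_df = pd.DataFrame([{**demog_fit.params, "ll": demog_fit.ll,
                              "N_anc": pg.N_anc, "theta_NS": pg.theta_NS}])
    demog_df.to_csv(outdir / "demography.tsv", sep="\t", index=False)
    bundle["demography"] = demog_df

    # stage 2: expected-SFS caches for every dominance value in use
    h_needed = sorted(set(config.h_scan) | set(config.h_choices) | {0.5})
    caches = {
        h: _get_cache(h, demo, syn.n, config.n_s, cache_dir) for h in h_needed
    }

    # stage 3: profile-h scans for the gamma and discrete families
    t0 = time.time()
    gamma_scan = profile_h_scan(
        nonsyn, caches, "gamma", tuple(config.h_scan), pg.theta_NS,
        n_starts=config.gamma_starts, seed=config.seed + 1,
    )
    gamma_scan.to_csv(outdir / "gamma_scan.tsv", sep="\t", index=False)
    discrete_scan = profile_h_scan(
        nonsyn, caches, "discrete", tuple(config.h_scan), pg.theta_NS,
        n_starts=config.hs_starts, seed=config.seed + 2,
    )
    discrete_scan.to_csv(outdir / "discrete_scan.tsv", sep="\t", index=False)
    logger.info("profile-h scans done (%.1fs)", time.time() - t0)
    bundle["gamma_scan"] = gamma_scan
    bundle["discrete_scan"] = discrete_scan

    # stage 4: per-bin h-s sweep, filters and model averaging
    if config.run_hs_sweep:
        t0 = time.time()
        hmaps = enumerate_hs_models(tuple(config.h_choices))
        models = sweep_hs_models(
            nonsyn, caches, hmaps, pg.theta_NS,
            n_starts=config.hs_starts, seed=config.seed + 3,
        )
        models_df = _models_table(models)
        models_df.to_csv(outdir / "hs_models.tsv", sep="\t", index=False)
        high_ll = plausibility_filter(models, config.ll_threshold)
        monotonic = monotonic_filter(high_ll)
        averages = pd.DataFrame(
            [
                _average_row("all", average_hs_models(models)),
                _average_row("high_ll", average_hs_models(high_ll)),
                _average_row("monotonic", average_hs_models(monotonic)),
            ]
        )
        averages.to_csv(outdir / "model_averages.tsv", sep="\t", index=False)
        logger.info(
            "h-s sweep: %d models, %d high-LL, %d monotonic (%.1fs)",
            len(models), len(high_ll), len(monotonic), time.time() - t0,
        )
        bundle["hs_models"] = models_df
        bundle["model_averages"] = averages

    # stage 5: optional forward simulations of the retained dominance models
    if config.simulate and config.simulate.get("enabled", False):
        from .forward_sim import GenomeModel, PUBLISHED_MODELS, TwoPopDemography, simulate_ensemble

        sim_cfg = config.simulate
        genome = GenomeModel(chromosomes=int(sim_cfg.get("chromosomes", 2)))
        demo2 = TwoPopDemography()
        all_results = []
        for name in sim_cfg.get("models", list(PUBLISHED_MODELS)):
            t0 = time.time()
            results = simulate_ensemble(
                genome,
                demo2,
                PUBLISHED_MODELS[name],
                rescale=float(sim_cfg.get("rescale", 10)),
                n_reps=int(sim_cfg.get("reps", 20)),
                seed=config.seed + 10,
                n_ancestries=int(sim_cfg.get("n_ancestries", 2)),
            )
            factor = 22 // genome.chromosomes
            frame = results_frame([project_to_genome(r, factor) for r in results])
            frame.insert(0, "model", name)
            all_results.append(frame)
            logger.info("simulated %s (%.1fs)", name, time.time() - t0)
        sims = pd.concat(all_results, ignore_index=True)
        sims.to_csv(outdir / "simulations.tsv", sep="\t", index=False)
        bundle["simulations"] = sims

    _write_report(bundle, outdir, config, time.time() - t_start)
    return bundle


def _write_report(bundle: dict, outdir: Path, config: RunConfig, elapsed: float) -> None:
    lines = [
        "# domfit analysis report",
        "",
        f"seed: {config.seed}; runtime: {elapsed:.0f}s",
        "",
        "## Demography (synonymous SFS)",
        bundle["demography"].to_markdown(index=False),
        "",
        "## Profile-h scans",
        "### Gamma DFE",
        bundle["gamma_scan"].to_markdown(index=False),
        "### Discrete DFE",
        bundle["discrete_scan"].to_markdown(index=False),
    ]
    if "model_averages" in bundle:
        lines += [
            "",
            "## Model-averaged DFE and dominance",
            bundle["model_averages"].to_markdown(index=False),
        ]
    if "simulations" in bundle:
        summary = (
            bundle["simulations"]
            .groupby(["model", "population"])[["load", "inbreeding_load", "allele_count"]]
            .mean()
            .reset_index()
        )
        lines += ["", "## Simulated load (projected to 22 autosomes)",
                  summary.to_markdown(index=False)]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
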