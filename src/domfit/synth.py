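"""Synthetic observed SFS pairs with the statistical structure the PRF assumes.

Emulates the study's observable: a folded synonymous and nonsynonymous SFS
from n = 864 chromosomes (432 diploids), generated by Poisson-sampling every
unmasked entry of the expected spectrum under a chosen demography, DFE,
dominance map and theta_S (theta_NS = 2.31 * theta_S).  Because the PRF
treats sites as independent, this sampling is exact: every inference stage
can be tested end-to-end with no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .demography import EpochModel
from .dfe import DiscreteDFE, DominanceMap, GammaDFE, mixture_expected_sfs
from .expected import SelectionParams, build_grid_cache, expected_sfs
from .sfs import SFS

__all__ = ["SyntheticSpec", "poisson_sample_sfs", "make_dataset"]


@dataclass
class SyntheticSpec:
    """Generating parameters for one synthetic dataset."""

    demography: EpochModel
    dfe: GammaDFE | DiscreteDFE
    hmap: DominanceMap
    theta_S: float = 20_000.0
    ratio_NS_S: float = 2.31
    n: int = 864
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_S <= 0:
            raise ValueError("theta_S must be positive")
        if self.n % 2 != 0:
            raise ValueError("n must be even so the spectrum can be folded")

    def truth_record(self) -> dict:
        rec = {
            "theta_S": float(self.theta_S),
            "theta_NS": float(self.ratio_NS_S * self.theta_S),
            "ratio_NS_S": float(self.ratio_NS_S),
            "n": int(self.n),
            "seed": int(self.seed),
            "N_anc": self.demography.N_anc,
            "demography": [
                {
                    "nu_start": e.nu_start,
                    "nu_end": e.nu_end,
                    "duration": e.duration,
                    "mode": e.mode,
                }
                for e in self.demography.epochs
            ],
            "h_per_bin": list(self.hmap.h_per_bin),
        }
        if isinstance(self.dfe, GammaDFE):
            rec["dfe"] = {"family": "gamma", "shape": self.dfe.shape, "scale": self.dfe.scale}
        else:
            rec["dfe"] = {"family": "discrete", "proportions": list(self.dfe.proportions)}
        return rec

    def save_truth(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.truth_record(), fh)

    @classmethod
    def from_truth(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            rec = yaml.safe_load(fh)
        from .demography import Epoch

        demo = EpochModel(
            epochs=[
                Epoch(
                    nu_start=d["nu_start"],
                    duration=d["duration"],
                    mode=d["mode"],
                    nu_end=d["nu_end"],
                )
                for d in rec["demography"]
            ],
            N_anc=rec.get("N_anc"),
        )
        if rec["dfe"]["family"] == "gamma":
            dfe = GammaDFE(rec["dfe"]["shape"], rec["dfe"]["scale"])
        else:
            dfe = DiscreteDFE(tuple(rec["dfe"]["proportions"]))
        return cls(
            demography=demo,
            dfe=dfe,
            hmap=DominanceMap(tuple(rec["h_per_bin"])),
            theta_S=rec["theta_S"],
            ratio_NS_S=rec["ratio_NS_S"],
            n=rec["n"],
            seed=rec["seed"],
        )


def poisson_sample_sfs(expected: SFS, seed: int) -> SFS:
    """Draw each unmasked entry independently from Poisson(m_i)."""
    if not np.all(np.isfinite(expected.counts[expected.unmasked])):
        raise ValueError("expected spectrum has non-finite unmasked entries")
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(expected.counts)
    sel = expected.unmasked
    counts[sel] = rng.poisson(expected.counts[sel]).astype(float)
    return SFS(counts, expected.n, expected.folded, expected.mask.copy())


def make_dataset(
    spec: SyntheticSpec, caches: dict | None = None
) -> tuple[SFS, SFS, dict]:
    """Generate (synonymous SFS, nonsynonymous SFS, truth record).

    The synonymous spectrum is Poisson-sampled from the neutral expectation
    at theta_S under the demography; the nonsynonymous one from the
    DFE/dominance mixture at theta_NS = ratio * theta_S.  Both are folded.
    ``caches`` (h -> ExpectedSFSCache at the generating demography) may be
    supplied to avoid rebuilding the selection grid.
    """
    demo = spec.demography
    N_anc = demo.N_anc
    if N_anc is None:
        raise ValueError("the generating demography must carry N_anc")
    syn_expected = expected_sfs(
        SelectionParams(0.0, 0.5, N_anc), demo, spec.n, theta=spec.theta_S, folded=True
    )
    if caches is None:
        caches = {}
    for h in set(spec.hmap.h_per_bin):
        if h not in caches:
            caches[h] = build_grid_cache(h, demo, spec.n, N_anc=N_anc)
    theta_NS = spec.ratio_NS_S * spec.theta_S
    nonsyn_expected = mixture_expected_sfs(
        spec.dfe, spec.hmap, caches, theta_NS, folded=True
    )
    syn = poisson_sample_sfs(syn_expected, seed=spec.seed)
    nonsyn = poisson_sample_sfs(nonsyn_expected, seed=spec.seed + 1)
    return syn, nonsyn, spec.truth_record()
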