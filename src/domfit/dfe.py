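"""DFE families, dominance maps, h-s model enumeration and mixture spectra.

Two families describe the distribution of fitness effects (DFE) of new
deleterious mutations over the selection coefficient s (inference convention,
s in [0, 0.5]):

* a gamma distribution with shape alpha and scale beta (in unscaled s units);
* a discrete mixture of uniform distributions over five bins of |s|:
  neutral (0, 1e-5], nearly neutral (1e-5, 1e-4], weakly deleterious
  (1e-4, 1e-3], moderately deleterious (1e-3, 1e-2] and strongly deleterious
  (1e-2, 0.5].

A dominance map attaches one h per bin (or one global h).  Enumerating all
per-bin h combinations from the eight candidate values, with the neutral bin
pinned to additivity (h = 0.5), yields the 8^4 = 4096 h-s models swept by the
inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expected import S_MIN, ExpectedSFSCache
from .sfs import SFS, fold

__all__ = [
    "BIN_EDGES",
    "BIN_NAMES",
    "H_CHOICES",
    "GammaDFE",
    "DiscreteDFE",
    "DominanceMap",
    "HSModel",
    "enumerate_hs_models",
    "mixture_expected_sfs",
    "average_h",
    "monotonic_filter",
]

#: inference-convention bin edges over |s|
BIN_EDGES = (0.0, 1e-5, 1e-4, 1e-3, 1e-2, 0.5)
BIN_NAMES = ("neutral", "nearly_neutral", "weak", "moderate", "strong")
#: candidate per-bin dominance coefficients in the h-s sweep
H_CHOICES = (0.0, 0.05, 0.10, 0.15, 0.25, 0.35, 0.45, 0.50)
#: h values of the single-h profile scan
H_SCAN = (0.0, 0.05, 0.10, 0.15, 0.25, 0.35, 0.45, 0.50, 0.75, 1.0)


@dataclass(frozen=True)
class GammaDFE:
    """Gamma-distributed DFE; ``scale`` is in unscaled s units."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be positive")

    def mean_s(self) -> float:
        """E[s] of the untruncated gamma distribution."""
        return self.shape * self.scale

    def bin_masses(self, edges: tuple = BIN_EDGES) -> np.ndarray:
        """Probability mass in each discrete bin (for display/comparison)."""
        cdf = stats.gamma.cdf(np.asarray(edges), self.shape, scale=self.scale)
        out = np.diff(cdf)
        out[-1] += 1.0 - cdf[-1]  # tail above the last edge
        return out


@dataclass(frozen=True)
class DiscreteDFE:
    """Five-bin discrete DFE; proportions sum to 1 (4 free parameters)."""

    proportions: tuple

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (5,):
            raise ValueError("discrete DFE needs exactly 5 proportions")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("proportions must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError(f"proportions must sum to 1, got {p.sum()}")
        object.__setattr__(self, "proportions", tuple(float(x) for x in p))

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.proportions)


@dataclass(frozen=True)
class DominanceMap:
    """Dominance coefficient per DFE bin (five values, neutral bin first)."""

    h_per_bin: tuple

    def __post_init__(self) -> None:
        h = tuple(float(x) for x in self.h_per_bin)
        if len(h) != 5:
            raise ValueError("dominance map needs exactly 5 h values")
        if any(not 0.0 <= x <= 1.0 for x in h):
            raise ValueError("h values must lie in [0, 1]")
        object.__setattr__(self, "h_per_bin", h)

    @classmethod
    def global_h(cls, h: float) -> "DominanceMap":
        return cls((h,) * 5)

    @property
    def h_values(self) -> set:
        return set(self.h_per_bin)

    def is_monotonic_decay(self) -> bool:
        """Non-strict decay of h from the neutral to the strong bin."""
        h = self.h_per_bin
        return all(h[i] >= h[i + 1] for i in range(4))


@dataclass
class HSModel:
    """A fitted discrete-DFE model with per-bin dominance."""

    dfe: DiscreteDFE
    hmap: DominanceMap
    ll: float = np.nan
    aic: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.ll) and np.isfinite(self.aic):
            expect = 2 * 4 - 2 * self.ll  # k = 4 free DFE proportions
            if abs(self.aic - expect) > 1e-6:
                raise ValueError("AIC inconsistent with k=4 and the stored LL")


def enumerate_hs_models(h_choices: tuple = H_CHOICES) -> list[DominanceMap]:
    """All per-bin dominance maps with the neutral bin fixed additive.

    Returns ``len(h_choices)**4`` maps in deterministic lexicographic order
    (8^4 = 4096 for the standard candidate set).
    """
    maps = [
        DominanceMap((0.5,) + combo)
        for combo in itertools.product(h_choices, repeat=4)
    ]
    return maps


def _grid_cell_edges(s_grid: np.ndarray) -> np.ndarray:
    """Cell edges around the log-spaced s grid (log-midpoints, clamped)."""
    mid = np.sqrt(s_grid[:-1] * s_grid[1:])
    return np.concatenate([[s_grid[0]], mid, [s_grid[-1]]])


def _uniform_bin_weights(s_grid: np.ndarray, lo: float, hi: float) -> tuple[np.ndarray, float]:
    """Grid-cell weights for unit mass uniform on [lo, hi] (linear in s).

    Mass below the grid (and below S_MIN) is returned separately as the
    neutral fraction; mass above S_MAX contributes nothing (such mutations do
    not segregate).
    """
    edges = _grid_cell_edges(s_grid)
    left = np.maximum(edges[:-1], lo)
    right = np.minimum(edges[1:], hi)
    w = np.clip(right - left, 0.0, None) / (hi - lo)
    neutral_frac = max(0.0, (min(hi, s_grid[0]) - lo)) / (hi - lo)
    return w, neutral_frac


def _gamma_weights(s_grid: np.ndarray, dfe: GammaDFE) -> tuple[np.ndarray, float]:
    """Grid-cell gamma masses; sub-S_MIN mass is neutral, >S_MAX mass drops."""
    edges = _grid_cell_edges(s_grid)
    cdf = stats.gamma.cdf(edges, dfe.shape, scale=dfe.scale)
    w = np.diff(cdf)
    neutral_frac = float(cdf[0])
    return w, neutral_frac


def mixture_expected_sfs(
    dfe: GammaDFE | DiscreteDFE,
    hmap: DominanceMap,
    caches: dict,
    theta_NS: float,
    folded: bool = False,
) -> SFS:
    """Expected nonsynonymous SFS for a DFE/dominance mixture.

    ``caches`` maps h -> :class:`ExpectedSFSCache` (all at the working
    demography and sample size).  The expectation is linear in the DFE mass
    and in theta_NS: each grid cell contributes its DFE mass times the
    unit-theta spectrum at that s under the bin's h.  Mass below the grid is
    effectively neutral; mass above s = 0.25 contributes no variants.
    """

    def cache_for(h: float) -> ExpectedSFSCache:
        try:
            return caches[h]
        except KeyError:
            raise KeyError(f"no expected-SFS cache for h={h}") from None

    if isinstance(dfe, GammaDFE):
        h = hmap.h_per_bin[0]
        if len(set(hmap.h_per_bin)) != 1:
            raise ValueError("gamma DFE uses a single global h")
        cache = cache_for(h)
        w, neutral_frac = _gamma_weights(cache.s_grid, dfe)
        counts = theta_NS * (w @ cache.spectra + neutral_frac * cache.neutral)
        n = cache.n
    else:
        counts = None
        n = None
        for b, (p_b, h_b) in enumerate(zip(dfe.proportions, hmap.h_per_bin)):
            if p_b == 0.0:
                continue
            lo, hi = BIN_EDGES[b], BIN_EDGES[b + 1]
            cache = cache_for(h_b)
            n = cache.n
            if hi <= S_MIN:
                contrib = p_b * cache.neutral
            else:
                w, neutral_frac = _uniform_bin_weights(cache.s_grid, lo, hi)
                contrib = p_b * (w @ cache.spectra + neutral_frac * cache.neutral)
            counts = contrib if counts is None else counts + contrib
        counts = theta_NS * counts
    out = SFS(counts, n, folded=False)
    return fold(out) if folded else out


def average_h(dfe: DiscreteDFE, hmap: DominanceMap) -> float:
    """Proportion-weighted mean dominance over new mutations: sum p_i h_i."""
    return float(np.dot(dfe.p, np.asarray(hmap.h_per_bin)))


def monotonic_filter(models: list[HSModel]) -> list[HSModel]:
    """Keep models whose h decays (non-strictly) from neutral to strong bin."""
    return [m for m in models if m.hmap.is_monotonic_decay()]
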