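"""Poisson random field inference: demography, DFE and dominance fitting.

Under the Poisson random field model each unmasked SFS entry x_i is an
independent Poisson count with mean m_i given by the expected spectrum, so
the log-likelihood is sum_i [x_i ln m_i - m_i - ln x_i!].  The population
mutation rate theta enters every expected entry multiplicatively and its MLE
has the closed form theta_hat = sum x_i / sum m_i (unit-theta model), which
is used to profile theta out of the demographic fit.  The synonymous SFS
fixes the demography and theta_S (hence N_anc = theta_S / (4 mu L_S) and
theta_NS = 2.31 * theta_S); the nonsynonymous SFS then identifies the DFE
and dominance parameters with theta_NS held fixed.

Model comparison uses AIC = 2k - 2 ln L (k = 2 for the gamma DFE, 4 for the
discrete DFE) and parameter estimates are model-averaged with Akaike weights
w_i proportional to exp(-dAIC_i / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .demography import Epoch, EpochModel
from .dfe import (
    BIN_EDGES,
    DiscreteDFE,
    DominanceMap,
    GammaDFE,
    HSModel,
    _gamma_weights,
    _uniform_bin_weights,
)
from .expected import S_MIN, expected_sfs
from .sfs import SFS

__all__ = [
    "PopGenParams",
    "FitResult",
    "ModelAverage",
    "poisson_ll",
    "optimal_theta",
    "aic",
    "fit_demography",
    "fit_dfe",
    "profile_h_scan",
    "sweep_hs_models",
    "plausibility_filter",
    "akaike_weights",
    "model_average",
    "average_hs_models",
]

#: default chi-square(1df, 95%) / 2 log-likelihood plausibility threshold
LL_THRESHOLD = 1.92


@dataclass
class PopGenParams:
    """Population-genetic scale parameters tied together by theta_S = 4 N mu L."""

    mu: float
    L_S: float
    theta_S: float
    ratio_NS_S: float = 2.31

    @property
    def N_anc(self) -> float:
        return self.theta_S / (4.0 * self.mu * self.L_S)

    @property
    def theta_NS(self) -> float:
        return self.ratio_NS_S * self.theta_S


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    params: dict
    ll: float
    k: int
    n_starts: int
    converged: bool
    seed: int | None = None
    start_lls: list = field(default_factory=list)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.ll


@dataclass
class ModelAverage:
    """Akaike-weighted averages over a set of fitted h-s models."""

    dfe_proportions: np.ndarray
    h_per_bin: np.ndarray
    overall_h: float
    weights: np.ndarray
    n_models: int


# ---------------------------------------------------------------------------
# likelihood primitives
# ---------------------------------------------------------------------------


def _check_compatible(data: SFS, model: SFS) -> None:
    if data.n != model.n or data.folded != model.folded:
        raise ValueError("data and model spectra differ in n or folded state")
    if not np.array_equal(data.mask, model.mask):
        raise ValueError("data and model spectra have different masks")


def poisson_ll(data: SFS, model: SFS) -> float:
    """Poisson random field log-likelihood over unmasked entries."""
    _check_compatible(data, model)
    sel = data.unmasked
    x = data.counts[sel]
    m = model.counts[sel]
    if np.any((m == 0) & (x > 0)):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x > 0, x * np.log(m), 0.0) - m - gammaln(x + 1.0)
    return float(terms.sum())


def _poisson_ll_vec(x: np.ndarray, m: np.ndarray, logfact: np.ndarray) -> float:
    if np.any((m <= 0) & (x > 0)):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.where(m > 0, np.log(m), 0.0)
    return float(np.sum(x * lm - m) - logfact.sum())


def optimal_theta(data: SFS, unit_model: SFS) -> float:
    """Closed-form Poisson MLE of the multiplicative scale theta.

    theta_hat = sum x_i / sum m_i over unmasked entries; this value maximizes
    poisson_ll(data, theta * unit_model) exactly.
    """
    _check_compatible(data, unit_model)
    sel = data.unmasked
    denom = unit_model.counts[sel].sum()
    if denom <= 0:
        raise ValueError("unit model is zero on all unmasked entries")
    return float(data.counts[sel].sum() / denom)


def aic(fit: FitResult | float, k: int | None = None) -> float:
    """AIC = 2k - 2 ln L."""
    if isinstance(fit, FitResult):
        return 2.0 * (k if k is not None else fit.k) - 2.0 * fit.ll
    if k is None:
        raise ValueError("k is required when passing a bare log-likelihood")
    return 2.0 * k - 2.0 * float(fit)


# ---------------------------------------------------------------------------
# demographic fit (synonymous SFS)
# ---------------------------------------------------------------------------

_DEMOG_BOUNDS = {"nu": (1e-3, 1e3), "tau": (1e-4, 1.0)}


def _build_three_epoch(nuB, tauB, nuR, tauR, nuG, tauG) -> EpochModel:
    return EpochModel(
        epochs=[
            Epoch(nu_start=nuB, duration=tauB),
            Epoch(nu_start=nuR, duration=tauR),
            Epoch(nu_start=nuR, nu_end=nuG, duration=tauG, mode="exponential"),
        ]
    )


_PARAM_NAMES = ("nuB", "tauB", "nuR", "tauR", "nuG", "tauG")


def fit_demography(
    syn_sfs: SFS,
    mu: float,
    L_S: float,
    template: dict | None = None,
    free: tuple = _PARAM_NAMES,
    n_starts: int = 5,
    seed: int = 0,
    ratio_NS_S: float = 2.31,
    grid: np.ndarray | None = None,
    maxiter: int = 60,
    start_spread: float = 0.7,
) -> tuple[FitResult, PopGenParams, EpochModel]:
    """Fit a three-epoch history (bottleneck, recovery, exponential growth).

    Sizes/durations in ``free`` are optimized (log scale, bounded, multi-start
    quasi-Newton); the rest stay at the template values.  theta is profiled
    out with its closed-form MLE at every objective evaluation, and the
    ancestral size follows from theta_S = 4 N_anc mu L_S.
    """
    if not syn_sfs.folded:
        raise ValueError("demographic fitting expects a folded synonymous SFS")
    defaults = {"nuB": 0.2, "tauB": 0.05, "nuR": 1.0, "tauR": 0.05, "nuG": 10.0, "tauG": 0.01}
    if template:
        defaults.update(template)
    free = tuple(free)
    rng = np.random.default_rng(seed)
    n = syn_sfs.n
    neutral = None

    def expected_for(params: dict) -> SFS:
        demo = _build_three_epoch(*(params[k] for k in _PARAM_NAMES))
        return expected_sfs(
            SelectionNeutral, demo, n, theta=1.0, folded=True, grid=grid
        )

    # neutral selection params: s=0 so N_anc is irrelevant to the expectation
    from .expected import SelectionParams

    SelectionNeutral = SelectionParams(0.0, 0.5, 1.0)

    def objective(x: np.ndarray) -> float:
        params = dict(defaults)
        for name, xi in zip(free, x):
            params[name] = np.exp(xi)
        try:
            unit = expected_for(params)
            th = optimal_theta(syn_sfs, unit)
            ll = poisson_ll(syn_sfs, th * unit)
        except (RuntimeError, ValueError):
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    bounds = [
        tuple(np.log(_DEMOG_BOUNDS["nu" if name.startswith("nu") else "tau"]))
        for name in free
    ]
    x0 = np.log([defaults[name] for name in free])
    best = None
    start_lls = []
    for i in range(n_starts):
        xi = x0 if i == 0 else x0 + rng.normal(0.0, start_spread, size=x0.size)
        xi = np.clip(xi, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective, xi, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
        )
        start_lls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"demographic fit failed to converge in {n_starts} starts; "
            f"best objective {None if best is None else best.fun}"
        )
    params = dict(defaults)
    for name, xi in zip(free, best.x):
        params[name] = float(np.exp(xi))
    demo = _build_three_epoch(*(params[k] for k in _PARAM_NAMES))
    unit = expected_for(params)
    theta_hat = optimal_theta(syn_sfs, unit)
    ll = poisson_ll(syn_sfs, theta_hat * unit)
    pg = PopGenParams(mu=mu, L_S=L_S, theta_S=theta_hat, ratio_NS_S=ratio_NS_S)
    demo.N_anc = pg.N_anc
    fit = FitResult(
        params={**params, "theta_S": theta_hat},
        ll=ll,
        k=len(free) + 1,
        n_starts=n_starts,
        converged=bool(best.success),
        seed=seed,
        start_lls=start_lls,
    )
    return fit, pg, demo


# ---------------------------------------------------------------------------
# DFE fits (nonsynonymous SFS, demography and theta_NS fixed)
# ---------------------------------------------------------------------------


from functools import lru_cache


@lru_cache(maxsize=8)
def _fold_matrix(n: int) -> np.ndarray:
    """Linear map from an unfolded length-(n+1) spectrum to folded counts."""
    half = n // 2
    F = np.zeros((n + 1, n + 1))
    for i in range(1, half + 1):
        F[i, i] = 1.0
        if n - i != i:
            F[i, n - i] = 1.0
    return F


def _prepare_discrete(caches: dict, hmap: DominanceMap, data: SFS) -> np.ndarray:
    """Per-bin unit-theta folded model vectors on the unmasked entries."""
    sel = data.unmasked
    F = _fold_matrix(data.n)
    cols = []
    for b in range(5):
        h_b = hmap.h_per_bin[b]
        if h_b not in caches:
            raise KeyError(f"no expected-SFS cache for h={h_b}")
        cache = caches[h_b]
        lo, hi = BIN_EDGES[b], BIN_EDGES[b + 1]
        if hi <= S_MIN:
            unfolded = cache.neutral
        else:
            w, neutral_frac = _uniform_bin_weights(cache.s_grid, lo, hi)
            unfolded = w @ cache.spectra + neutral_frac * cache.neutral
        cols.append((F @ unfolded)[sel])
    return np.column_stack(cols)


def _softmax5(z: np.ndarray) -> np.ndarray:
    """Map 4 unconstrained logits to the 5-simplex (last logit pinned at 0)."""
    full = np.concatenate([z, [0.0]])
    e = np.exp(full - full.max())
    return e / e.sum()


def fit_dfe(
    nonsyn_sfs: SFS,
    caches: dict,
    family: str,
    hmap: DominanceMap,
    theta_NS: float,
    n_starts: int = 5,
    seed: int = 0,
    maxiter: int = 200,
) -> FitResult:
    """Maximum-likelihood DFE fit with demography and theta_NS held fixed.

    ``family`` is "gamma" (shape, scale; k = 2) or "discrete" (4 free
    proportions through an unconstrained simplex transform, the fifth by
    complement; k = 4).  The best of ``n_starts`` seeded random restarts is
    returned.
    """
    if not nonsyn_sfs.folded:
        raise ValueError("DFE fitting expects a folded nonsynonymous SFS")
    rng = np.random.default_rng(seed)
    sel = nonsyn_sfs.unmasked
    x = nonsyn_sfs.counts[sel]
    logfact = gammaln(x + 1.0)

    if family == "discrete":
        B = _prepare_discrete(caches, hmap, nonsyn_sfs)  # (entries, 5)

        def objective(z: np.ndarray) -> float:
            p = _softmax5(z)
            m = theta_NS * (B @ p)
            ll = _poisson_ll_vec(x, m, logfact)
            return -ll if np.isfinite(ll) else 1e12

        best = None
        start_lls = []
        for i in range(n_starts):
            z0 = np.zeros(4) if i == 0 else rng.normal(0.0, 1.5, size=4)
            res = minimize(objective, z0, method="L-BFGS-B", options={"maxiter": maxiter})
            start_lls.append(-res.fun)
            if best is None or res.fun < best.fun:
                best = res
        p = _softmax5(best.x)
        params = {"p": tuple(float(v) for v in p)}
        k = 4
    elif family == "gamma":
        hset = set(hmap.h_per_bin)
        if len(hset) != 1:
            raise ValueError("gamma DFE uses a single global h")
        h = hmap.h_per_bin[0]
        if h not in caches:
            raise KeyError(f"no expected-SFS cache for h={h}")
        cache = caches[h]
        F = _fold_matrix(nonsyn_sfs.n)
        spectra_f = (F @ cache.spectra.T)[sel].T  # (n_s, entries)
        neutral_f = (F @ cache.neutral)[sel]
        bounds = [(np.log(1e-3), np.log(50.0)), (np.log(1e-7), np.log(10.0))]

        def objective(zx: np.ndarray) -> float:
            dfe = GammaDFE(shape=float(np.exp(zx[0])), scale=float(np.exp(zx[1])))
            w, neutral_frac = _gamma_weights(cache.s_grid, dfe)
            m = theta_NS * (w @ spectra_f + neutral_frac * neutral_f)
            ll = _poisson_ll_vec(x, m, logfact)
            return -ll if np.isfinite(ll) else 1e12

        x0 = np.log([0.2, 0.01])
        best = None
        start_lls = []
        for i in range(n_starts):
            zi = x0 if i == 0 else x0 + rng.normal(0.0, 1.0, size=2)
            zi = np.clip(zi, [b[0] for b in bounds], [b[1] for b in bounds])
            res = minimize(
                objective, zi, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
            )
            start_lls.append(-res.fun)
            if best is None or res.fun < best.fun:
                best = res
        params = {
            "shape": float(np.exp(best.x[0])),
            "scale": float(np.exp(best.x[1])),
        }
        k = 2
    else:
        raise ValueError("family must be 'gamma' or 'discrete'")

    ll = -best.fun
    return FitResult(
        params=params,
        ll=float(ll),
        k=k,
        n_starts=n_starts,
        converged=bool(best.success) and np.isfinite(ll),
        seed=seed,
        start_lls=start_lls,
    )


def profile_h_scan(
    nonsyn_sfs: SFS,
    caches: dict,
    family: str,
    h_values: tuple,
    theta_NS: float,
    n_starts: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the DFE at each single global h; one row per h with a dLL column."""
    rows = []
    for h in h_values:
        fit = fit_dfe(
            nonsyn_sfs,
            caches,
            family,
            DominanceMap.global_h(h),
            theta_NS,
            n_starts=n_starts,
            seed=seed,
        )
        rows.append({"h": h, "ll": fit.ll, "aic": fit.aic, **fit.params})
    df = pd.DataFrame(rows)
    df["delta_ll"] = df["ll"].max() - df["ll"]
    return df


def sweep_hs_models(
    nonsyn_sfs: SFS,
    caches: dict,
    hmaps: list[DominanceMap],
    theta_NS: float,
    n_starts: int = 5,
    seed: int = 0,
) -> list[HSModel]:
    """Fit the discrete DFE under every dominance map in ``hmaps``.

    Each model gets its own seed derived from the global seed and the model
    index, so the sweep is reproducible under any execution order.
    """
    models = []
    for idx, hmap in enumerate(hmaps):
        fit = fit_dfe(
            nonsyn_sfs,
            caches,
            "discrete",
            hmap,
            theta_NS,
            n_starts=n_starts,
            seed=(seed * 100003 + idx) % (2**31),
        )
        models.append(
            HSModel(dfe=DiscreteDFE(fit.params["p"]), hmap=hmap, ll=fit.ll, aic=fit.aic)
        )
    return models


# ---------------------------------------------------------------------------
# model filtering and averaging
# ---------------------------------------------------------------------------


def plausibility_filter(models: list, delta_ll: float = LL_THRESHOLD) -> list:
    """Retain models with LL within ``delta_ll`` units of the best model."""
    if not models:
        raise ValueError("no models to filter")
    lls = np.array([m.ll for m in models])
    cutoff = lls.max() - delta_ll
    return [m for m, ll in zip(models, lls) if ll >= cutoff]


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    """Normalized exp(-dAIC/2) weights; dAIC relative to the minimum AIC."""
    aics = np.asarray(aics, dtype=float)
    d = aics - aics.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def model_average(models: list, extract) -> np.ndarray | float:
    """Akaike-weight average of ``extract(model)`` over the model set."""
    if not models:
        raise ValueError("no models to average")
    w = akaike_weights([m.aic for m in models])
    vals = np.asarray([np.asarray(extract(m), dtype=float) for m in models])
    out = np.tensordot(w, vals, axes=1)
    return float(out) if np.ndim(out) == 0 else out


def average_hs_models(models: list[HSModel]) -> ModelAverage:
    """Model-average DFE proportions, per-bin h and the overall mean h."""
    w = akaike_weights([m.aic for m in models])
    props = model_average(models, lambda m: m.dfe.p)
    props = props / props.sum()
    h_bins = model_average(models, lambda m: np.asarray(m.hmap.h_per_bin))
    from .dfe import average_h

    overall = model_average(models, lambda m: average_h(m.dfe, m.hmap))
    return ModelAverage(
        dfe_proportions=props,
        h_per_bin=h_bins,
        overall_h=float(overall),
        weights=w,
        n_models=len(models),
    )
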