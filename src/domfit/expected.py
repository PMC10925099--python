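"""Expected site frequency spectra under selection with arbitrary dominance.

The engine computes, for a scaled selection coefficient gamma = 2*N_anc*s and
dominance coefficient h, the density f(q; gamma, h) of derived-allele
frequency at mutation-drift-selection balance, propagates it through a
piecewise demographic history with a one-dimensional forward diffusion, and
binomially samples it into an expected SFS,

    E[x_i] = theta * F(n, i; gamma, h),
    F(n, i) = int_0^1 C(n,i) q^i (1-q)^(n-i) f(q) dq.

Selection is stored in the inference convention: deleterious s is positive,
the mutant homozygote has fitness 1-2s and the heterozygote 1-2sh, with
s = 0.5 lethal.  Inside the diffusion the drift coefficient for a deleterious
mutation is negative, so the scaled coefficient is negated internally; the
orientation (deleterious parameters push mass toward low frequency) is
asserted by the test suite.

A dense Wright-Fisher transition-matrix oracle (exact binomial resampling
around the deterministic post-selection frequency) validates the diffusion at
small population sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.integrate import quad
from scipy.special import gammaln

from .demography import EpochModel
from .sfs import SFS, fold

__all__ = [
    "SelectionParams",
    "FrequencyDensity",
    "ExpectedSFSCache",
    "make_grid",
    "stationary_density",
    "equilibrium_density",
    "propagate_density",
    "sample_expected_sfs",
    "expected_sfs",
    "wf_matrix_oracle",
    "build_grid_cache",
]

#: maximum selection coefficient the diffusion is evaluated for; mutations
#: with s > S_MAX are treated as not segregating.
S_MAX = 0.25
S_MIN = 1e-5

DEFAULT_GRID_POINTS = 2200
_X_MIN = 1e-8


@dataclass(frozen=True)
class SelectionParams:
    """Selection/dominance parameters in the inference convention.

    ``s`` is the positive deleterious selection coefficient (homozygote
    fitness 1-2s), ``h`` the dominance coefficient, and ``N_anc`` the
    ancestral diploid size fixing ``gamma = 2*N_anc*s``.
    """

    s: float
    h: float
    N_anc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 0.5:
            raise ValueError("s must lie in [0, 0.5]")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        if self.N_anc <= 0:
            raise ValueError("N_anc must be positive")

    @property
    def gamma(self) -> float:
        """Population-scaled selection coefficient 2*N_anc*s (positive)."""
        return 2.0 * self.N_anc * self.s


@dataclass
class FrequencyDensity:
    """Mutation-flux-scaled density of allele frequency on an interior grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.grid[0] <= 0.0 or self.grid[-1] >= 1.0:
            raise ValueError("grid must lie strictly inside (0, 1)")

    def copy(self) -> "FrequencyDensity":
        return FrequencyDensity(self.grid.copy(), self.values.copy())


def make_grid(n_points: int = DEFAULT_GRID_POINTS, x_min: float = _X_MIN) -> np.ndarray:
    """Interior frequency grid crowded geometrically toward both boundaries."""
    half = n_points // 2
    left = np.geomspace(x_min, 0.5, half)
    right = 1.0 - np.geomspace(x_min, 0.5, half)[::-1]
    grid = np.unique(np.concatenate([left, right]))
    return grid


def _exponent(eps: np.ndarray, gamma_eff: float, h: float) -> np.ndarray:
    """A(eps) = 4*gamma_eff*h*eps + 2*gamma_eff*(1-2h)*eps^2 (signed gamma)."""
    return 4.0 * gamma_eff * h * eps + 2.0 * gamma_eff * (1.0 - 2.0 * h) * eps * eps


def stationary_density(q: float, sel: SelectionParams) -> float:
    """Quasi-stationary allele-frequency density at a single frequency.

    Evaluates f(q; gamma, h) by adaptive quadrature (relative tolerance below
    1e-10).  The neutral case returns exactly 1/q.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly inside (0, 1)")
    if sel.s == 0.0:
        return 1.0 / q
    gamma_eff = -sel.gamma  # deleterious s>0 -> negative drift coefficient
    h = sel.h
    a1 = float(_exponent(np.array(1.0), gamma_eff, h))
    # shifted integrand exp(A(1) - A(eps)) <= 1 for deleterious parameters

    def integrand(eps: float) -> float:
        return float(np.exp(a1 - _exponent(np.array(eps), gamma_eff, h)))

    t_q, _ = quad(integrand, q, 1.0, epsabs=0.0, epsrel=1e-12, limit=200)
    t_0, _ = quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=1e-12, limit=200)
    aq = float(_exponent(np.array(q), gamma_eff, h))
    return float(np.exp(aq) * (t_q / t_0) / (q * (1.0 - q)))


_GL5_X, _GL5_W = np.polynomial.legendre.leggauss(5)


def _suffix_integral(grid: np.ndarray, gamma_eff: float, h: float) -> tuple[np.ndarray, float]:
    """T(x_k) = int_{x_k}^1 exp(A(1)-A(eps)) deps for every grid node, and T(0)."""
    edges = np.concatenate([[0.0], grid, [1.0]])
    lo, hi = edges[:-1], edges[1:]
    mid = 0.5 * (lo + hi)
    halfw = 0.5 * (hi - lo)
    nodes = mid[:, None] + halfw[:, None] * _GL5_X[None, :]
    a1 = float(_exponent(np.array(1.0), gamma_eff, h))
    vals = np.exp(a1 - _exponent(nodes, gamma_eff, h))
    cell = (vals * _GL5_W[None, :]).sum(axis=1) * halfw
    suffix = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])
    # suffix[k] = integral from edges[k] to 1; grid node k is edges[k+1]
    return suffix[1:-1], float(suffix[0])


def equilibrium_density(sel: SelectionParams, grid: np.ndarray) -> FrequencyDensity:
    """Stationary density on a grid, in unit-theta (mutation-flux) scaling.

    For the neutral case the values are exactly 1/q.  At h = 0.5 the result
    reduces to the classical genic-selection flux density.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] <= 0.0 or grid[-1] >= 1.0:
        raise ValueError("grid must exclude 0 and 1")
    if sel.s > S_MAX:
        raise ValueError(
            f"s={sel.s} exceeds the numerically supported range (s <= {S_MAX})"
        )
    if sel.s == 0.0:
        return FrequencyDensity(grid, 1.0 / grid)
    gamma_eff = -sel.gamma
    t_grid, t_zero = _suffix_integral(grid, gamma_eff, sel.h)
    a = _exponent(grid, gamma_eff, sel.h)
    vals = np.exp(a) * (t_grid / t_zero) / (grid * (1.0 - grid))
    return FrequencyDensity(grid, vals)


# ---------------------------------------------------------------------------
# forward diffusion (implicit finite volume, Scharfetter-Gummel fluxes)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _bernoulli_fn(z):
    """z / (exp(z) - 1), stable near zero."""
    if abs(z) < 1e-5:
        return 1.0 - 0.5 * z + z * z / 12.0
    if z > 700.0:
        return 0.0
    return z / np.expm1(z)


@njit(cache=True)
def _face_coeffs(x, gamma_eff, h, nu, alpha, beta):
    """Exponentially fitted face coefficients: J_f = alpha*phi_left - beta*phi_right.

    The flux J = M*phi - d(D*phi)/dq is discretized Scharfetter-Gummel style
    in the variable psi = D*phi (D = q(1-q)/(2 nu)), which makes the neutral
    stationary profile phi = 1/q an exact fixed point of the discrete
    operator: psi is then linear in q and M/D vanishes.  D = 0 at the
    absorbing endpoints gives the Dirichlet condition automatically.
    """
    K = x.size
    for f in range(K + 1):
        xl = 0.0 if f == 0 else x[f - 1]
        xr = 1.0 if f == K else x[f]
        dx = xr - xl
        xm = 0.5 * (xl + xr)
        # p = (M/D) * dx with M/D = 4 nu gamma_eff (h + (1-2h) q)
        p = 4.0 * nu * gamma_eff * (h + (1.0 - 2.0 * h) * xm) * dx
        Dl = xl * (1.0 - xl) / (2.0 * nu)
        Dr = xr * (1.0 - xr) / (2.0 * nu)
        alpha[f] = Dl / dx * _bernoulli_fn(-p)
        beta[f] = Dr / dx * _bernoulli_fn(p)


@njit(cache=True)
def _implicit_steps(phi, x, w, alpha, beta, dt, nsteps, src0):
    """nsteps of implicit Euler with fixed face coefficients and injection."""
    K = x.size
    lo = np.empty(K)
    di = np.empty(K)
    up = np.empty(K)
    for k in range(K):
        lo[k] = -dt * alpha[k] / w[k]
        di[k] = 1.0 + dt * (beta[k] + alpha[k + 1]) / w[k]
        up[k] = -dt * beta[k + 1] / w[k]
    cp = np.empty(K)
    dp = np.empty(K)
    for _ in range(nsteps):
        phi[0] += dt * src0
        # Thomas solve (I - dt L) phi_new = phi
        cp[0] = up[0] / di[0]
        dp[0] = phi[0] / di[0]
        for k in range(1, K):
            m = di[k] - lo[k] * cp[k - 1]
            cp[k] = up[k] / m
            dp[k] = (phi[k] - lo[k] * dp[k - 1]) / m
        phi[K - 1] = dp[K - 1]
        for k in range(K - 2, -1, -1):
            phi[k] = dp[k] - cp[k] * phi[k + 1]
    return phi


@njit(cache=True)
def _propagate_kernel(phi, x, gamma_eff, h, epochs, dt_max, theta):
    K = x.size
    w = np.empty(K)
    for k in range(K):
        xl = 0.0 if k == 0 else x[k - 1]
        xr = 1.0 if k == K - 1 else x[k + 1]
        w[k] = 0.5 * (xr - xl)
    src0 = theta * 0.5 / (x[0] * w[0])
    alpha = np.empty(K + 1)
    beta = np.empty(K + 1)
    for e in range(epochs.shape[0]):
        nu0 = epochs[e, 0]
        nu1 = epochs[e, 1]
        dur = epochs[e, 2]
        expo = epochs[e, 3] > 0.5
        if dur <= 0.0:
            continue
        nsteps = int(np.ceil(dur / dt_max))
        dt = dur / nsteps
        if not expo and nu0 == nu1:
            _face_coeffs(x, gamma_eff, h, nu0, alpha, beta)
            _implicit_steps(phi, x, w, alpha, beta, dt, nsteps, src0)
        else:
            lognu = np.log(nu1 / nu0)
            for step in range(nsteps):
                tmid = (step + 0.5) * dt
                nu = nu0 * np.exp(lognu * tmid / dur) if expo else nu0
                _face_coeffs(x, gamma_eff, h, nu, alpha, beta)
                _implicit_steps(phi, x, w, alpha, beta, dt, 1, src0)
    return phi


def propagate_density(
    phi: FrequencyDensity,
    demo: EpochModel,
    sel: SelectionParams,
    dt: float = 1e-3,
    theta: float = 1.0,
) -> FrequencyDensity:
    """Integrate the 1D forward diffusion through all epochs of ``demo``.

    ``phi`` should be the equilibrium density at the ancestral size; the
    returned density is the transient distribution after the size changes,
    with drift and selection-with-dominance terms and mutational influx at the
    low-frequency boundary.  Time and drift are rescaled per epoch by the
    relative size ``nu``.
    """
    epochs = demo.as_array()
    out = phi.values.copy()
    if epochs.shape[0] == 0:
        return FrequencyDensity(phi.grid, out)
    gamma_eff = -sel.gamma
    out = _propagate_kernel(out, phi.grid, gamma_eff, sel.h, epochs, dt, theta)
    if not np.all(np.isfinite(out)):
        raise RuntimeError(
            f"diffusion integration diverged (grid {phi.grid.size}, dt {dt})"
        )
    return FrequencyDensity(phi.grid, out)


# ---------------------------------------------------------------------------
# binomial sampling quadrature
# ---------------------------------------------------------------------------

_GL3_X, _GL3_W = np.polynomial.legendre.leggauss(3)
_KERNEL_CACHE: dict = {}


def _quad_nodes(grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Composite 3-point Gauss-Legendre nodes/weights over [0,1] on the grid cells."""
    edges = np.concatenate([[0.0], grid, [1.0]])
    lo, hi = edges[:-1], edges[1:]
    mid = 0.5 * (lo + hi)
    halfw = 0.5 * (hi - lo)
    nodes = (mid[:, None] + halfw[:, None] * _GL3_X[None, :]).ravel()
    weights = (halfw[:, None] * _GL3_W[None, :]).ravel()
    return nodes, weights


def _kernel_matrix(n: int, grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matrix K[i-1, node] = C(n,i) q^(i-1) (1-q)^(n-i-1) * w_node, i=1..n-1."""
    key = (n, grid.size, float(grid[0]), float(grid[-1]))
    hit = _KERNEL_CACHE.get(key)
    if hit is not None:
        return hit
    nodes, weights = _quad_nodes(grid)
    i = np.arange(1, n, dtype=float)[:, None]
    logc = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    logq = np.log(nodes)[None, :]
    log1mq = np.log1p(-nodes)[None, :]
    logk = logc + (i - 1.0) * logq + (n - i - 1.0) * log1mq
    mat = np.exp(logk) * weights[None, :]
    _KERNEL_CACHE[key] = (mat, nodes)
    return mat, nodes


def _g_at_nodes(phi: FrequencyDensity, nodes: np.ndarray) -> np.ndarray:
    """Interpolate g(q) = phi(q) q (1-q) to the quadrature nodes.

    g is linearly extrapolated to the boundaries (it is finite there: the
    density carries the 1/q and 1/(1-q) endpoint asymptotics analytically).
    """
    x = phi.grid
    g = phi.values * x * (1.0 - x)
    g0 = g[0] - (g[1] - g[0]) / (x[1] - x[0]) * x[0]
    g1 = g[-1] + (g[-1] - g[-2]) / (x[-1] - x[-2]) * (1.0 - x[-1])
    xs = np.concatenate([[0.0], x, [1.0]])
    gs = np.concatenate([[max(g0, 0.0)], g, [max(g1, 0.0)]])
    return np.interp(nodes, xs, gs)


def _atomize_sample(
    g: np.ndarray,
    nodes: np.ndarray,
    weights: np.ndarray,
    N: int,
    n: int,
    theta: float,
) -> np.ndarray:
    """Bin a continuum density into the 2N+1 frequency atoms, then sample.

    The continuum carries mass below half a copy (q < 1/(4N)) that a finite
    population of 2N chromosomes cannot hold; binning the density into the
    atoms j/(2N) before binomial sampling is the consistent way to compare
    the diffusion with a finite-N Wright-Fisher chain.
    """
    f = np.where((nodes > 0) & (nodes < 1), g / (nodes * (1.0 - nodes)), 0.0)
    edges = (np.arange(2 * N) + 0.5) / (2 * N)
    cell = np.searchsorted(edges, nodes)
    m = np.bincount(cell, weights=weights * f, minlength=2 * N + 1)
    samp = _binom_pmf_matrix(n, np.arange(1, 2 * N) / (2 * N))
    counts = theta * (m[1 : 2 * N] @ samp)
    counts[0] = counts[n] = 0.0
    return counts


def sample_expected_sfs(
    phi: FrequencyDensity,
    n: int,
    theta: float = 1.0,
    folded: bool = False,
    pop_size: int | None = None,
) -> SFS:
    """Binomially sample a frequency density into an expected SFS.

    Entry i (1 <= i <= n-1) equals theta * F(n, i); under neutrality entry i
    is theta / i.  When ``pop_size`` (diploid N) is given the density is
    first binned onto the finite population's 2N+1 frequency atoms (see
    :func:`_atomize_sample`), which is how the engine is compared against the
    Wright-Fisher matrix oracle.
    """
    if n < 2:
        raise ValueError("sample size n must be at least 2")
    mat, nodes = _kernel_matrix(n, phi.grid)
    g = _g_at_nodes(phi, nodes)
    counts = np.zeros(n + 1)
    if pop_size is not None:
        _, weights = _quad_nodes(phi.grid)
        counts[:] = _atomize_sample(g, nodes, weights, pop_size, n, theta)
    else:
        counts[1:n] = theta * (mat @ g)
    out = SFS(counts, n, folded=False)
    return fold(out) if folded else out


def _sample_from_g(g: np.ndarray, n: int, grid: np.ndarray, theta: float) -> SFS:
    mat, _ = _kernel_matrix(n, grid)
    counts = np.zeros(n + 1)
    counts[1:n] = theta * (mat @ g)
    return SFS(counts, n, folded=False)


def _analytic_g_at_nodes(sel: SelectionParams, nodes: np.ndarray) -> np.ndarray:
    """g(q) = f(q) q (1-q) for the analytic equilibrium density at the nodes."""
    if sel.s == 0.0:
        return 1.0 - nodes
    gamma_eff = -sel.gamma
    h = sel.h
    # suffix integrals at the quadrature nodes themselves (5-pt GL per gap)
    order = np.argsort(nodes)
    xs = nodes[order]
    edges = np.concatenate([xs, [1.0]])
    lo, hi = edges[:-1], edges[1:]
    mid = 0.5 * (lo + hi)
    halfw = 0.5 * (hi - lo)
    sub = mid[:, None] + halfw[:, None] * _GL5_X[None, :]
    a1 = float(_exponent(np.array(1.0), gamma_eff, h))
    cell = (np.exp(a1 - _exponent(sub, gamma_eff, h)) * _GL5_W[None, :]).sum(
        axis=1
    ) * halfw
    suffix = np.concatenate([np.cumsum(cell[::-1])[::-1], [0.0]])[:-1]
    head, _ = quad(
        lambda e: float(np.exp(a1 - _exponent(np.array(e), gamma_eff, h))),
        0.0,
        float(xs[0]),
        epsabs=0.0,
        epsrel=1e-12,
    )
    t0 = float(suffix[0] + head)
    g_sorted = np.exp(_exponent(xs, gamma_eff, h)) * (suffix / t0)
    g = np.empty_like(g_sorted)
    g[order] = g_sorted
    return g


def expected_sfs(
    sel: SelectionParams,
    demo: EpochModel | None,
    n: int,
    theta: float = 1.0,
    folded: bool = False,
    grid: np.ndarray | None = None,
    dt: float = 1e-3,
    pop_size: int | None = None,
) -> SFS:
    """Expected SFS under (s, h) and a demographic history.

    Constant-size histories use the analytic equilibrium density directly
    (exact up to quadrature); histories with size changes run the diffusion.
    ``pop_size`` applies the finite-population frequency floor (see
    :func:`sample_expected_sfs`).
    """
    if grid is None:
        grid = make_grid()
    if demo is None or demo.is_equilibrium():
        _, nodes = _kernel_matrix(n, grid)
        g = _analytic_g_at_nodes(sel, nodes)
        if pop_size is not None:
            _, weights = _quad_nodes(grid)
            counts = np.zeros(n + 1)
            counts[:] = _atomize_sample(g, nodes, weights, pop_size, n, theta)
            out = SFS(counts, n, folded=False)
            return fold(out) if folded else out
        out = _sample_from_g(g, n, grid, theta)
    else:
        phi = equilibrium_density(sel, grid)
        phi = propagate_density(phi, demo, sel, dt=dt)
        out = sample_expected_sfs(phi, n, theta, pop_size=pop_size)
    return fold(out) if folded else out


# ---------------------------------------------------------------------------
# Wright-Fisher transition-matrix oracle
# ---------------------------------------------------------------------------


def _binom_pmf_matrix(trials: int, probs: np.ndarray) -> np.ndarray:
    """Rows: probability vectors Binom(trials, p) over counts 0..trials."""
    k = np.arange(trials + 1, dtype=float)[None, :]
    p = np.clip(probs, 1e-300, 1.0 - 1e-16)[:, None]
    logpmf = (
        gammaln(trials + 1)
        - gammaln(k + 1)
        - gammaln(trials - k + 1)
        + k * np.log(p)
        + (trials - k) * np.log1p(-p)
    )
    return np.exp(logpmf)


def _post_selection_freq(
    q: np.ndarray, s: float, h: float, linearized: bool = True
) -> np.ndarray:
    """Deterministic mutant frequency after selection (inference convention).

    The first-order update q' = q - 2 s q (1-q) (h + (1-2h) q) is the change
    implied by the fitness convention to leading order in s and is the drift
    the diffusion integrates; ``linearized=False`` uses the exact
    mean-fitness-normalized update instead.
    """
    if linearized:
        return q - 2.0 * s * q * (1.0 - q) * (h + (1.0 - 2.0 * h) * q)
    waa = 1.0 - 2.0 * s
    wha = 1.0 - 2.0 * s * h
    num = q * q * waa + q * (1.0 - q) * wha
    den = q * q * waa + 2.0 * q * (1.0 - q) * wha + (1.0 - q) ** 2
    return num / den


def _wf_step_matrix(N_from: int, N_to: int, s: float, h: float) -> np.ndarray:
    """Transition pmf from counts 0..2*N_from to counts 0..2*N_to."""
    q = np.arange(2 * N_from + 1, dtype=float) / (2 * N_from)
    qp = _post_selection_freq(q, s, h)
    return _binom_pmf_matrix(2 * N_to, qp)


def wf_matrix_oracle(
    N: int,
    sel: SelectionParams,
    demo: EpochModel | None,
    n: int,
    theta: float = 1.0,
    folded: bool = False,
) -> SFS:
    """Expected SFS from the exact Wright-Fisher transition matrix.

    Iterates binomial resampling around the deterministic post-selection
    frequency with constant mutational influx (theta/2 new mutations per
    generation, entering as single copies), starting from the stationary
    solution at the ancestral size ``N`` and stepping through the epoch
    schedule generation by generation.  Feasible for 2N <= 1000.
    """
    if 2 * N > 1000:
        raise ValueError("matrix oracle limited to 2N <= 1000")
    influx_rate = theta / 2.0

    def stationary(Npop: int) -> np.ndarray:
        T = _wf_step_matrix(Npop, Npop, sel.s, sel.h)
        interior = T[1:-1, 1:-1]
        b = np.zeros(2 * Npop - 1)
        b[0] = influx_rate
        v = np.linalg.solve(np.eye(2 * Npop - 1) - interior.T, b)
        return v

    v = stationary(N)
    Ncur = N
    if demo is not None:
        for e in demo.epochs:
            gens = int(round(e.duration * 2 * N))
            for g in range(gens):
                tau = (g + 0.5) * e.duration / max(gens, 1)
                Nnext = int(round(e.nu_at(tau) * N))
                Nnext = max(Nnext, 2)
                T = _wf_step_matrix(Ncur, Nnext, sel.s, sel.h)
                v_full = np.concatenate([[0.0], v, [0.0]])
                v = (v_full @ T)[1:-1]
                # new mutations arise at rate 2*N*mu per generation, i.e. in
                # proportion to the current population size
                v[0] += influx_rate * Nnext / N
                Ncur = Nnext
    q = np.arange(1, 2 * Ncur) / (2 * Ncur)
    sample = _binom_pmf_matrix(n, q)
    counts = np.zeros(n + 1)
    counts[:] = v @ sample
    counts[0] = counts[n] = 0.0
    out = SFS(counts, n, folded=False)
    return fold(out) if folded else out


# ---------------------------------------------------------------------------
# cache of expected spectra over the selection grid
# ---------------------------------------------------------------------------


@dataclass
class ExpectedSFSCache:
    """Unit-theta expected spectra on a log-spaced grid of s, for one h.

    ``spectra[j]`` is the unfolded expected SFS (length n+1) at ``s_grid[j]``;
    ``neutral`` is the s = 0 spectrum.  Deterministic given (h, demography, n).
    """

    h: float
    n: int
    N_anc: float
    s_grid: np.ndarray
    spectra: np.ndarray
    neutral: np.ndarray
    demo_key: tuple = ()

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            Path(path),
            h=self.h,
            n=self.n,
            N_anc=self.N_anc,
            s_grid=self.s_grid,
            spectra=self.spectra,
            neutral=self.neutral,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ExpectedSFSCache":
        d = np.load(Path(path))
        return cls(
            h=float(d["h"]),
            n=int(d["n"]),
            N_anc=float(d["N_anc"]),
            s_grid=d["s_grid"],
            spectra=d["spectra"],
            neutral=d["neutral"],
        )


def build_grid_cache(
    h: float,
    demo: EpochModel | None,
    n: int,
    N_anc: float | None = None,
    n_s: int = 1000,
    s_min: float = S_MIN,
    s_max: float = S_MAX,
    grid: np.ndarray | None = None,
    dt: float = 1e-3,
) -> ExpectedSFSCache:
    """Precompute unit-theta expected spectra on a log-spaced s grid.

    The grid spans exactly [s_min, s_max] with ``n_s`` log-spaced points;
    gamma = 2*N_anc*s.  The neutral spectrum is stored alongside.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError("h must lie in [0, 1]")
    if N_anc is None:
        N_anc = demo.N_anc if demo is not None and demo.N_anc else None
    if N_anc is None:
        raise ValueError("N_anc must be supplied (directly or via the demography)")
    if grid is None:
        grid = make_grid()
    s_grid = np.geomspace(s_min, s_max, n_s)
    mat, nodes = _kernel_matrix(n, grid)
    use_pde = demo is not None and not demo.is_equilibrium()
    G = np.empty((nodes.size, n_s))
    for j, s in enumerate(s_grid):
        sel = SelectionParams(s=float(s), h=h, N_anc=N_anc)
        if use_pde:
            phi = equilibrium_density(sel, grid)
            phi = propagate_density(phi, demo, sel, dt=dt)
            G[:, j] = _g_at_nodes(phi, nodes)
        else:
            G[:, j] = _analytic_g_at_nodes(sel, nodes)
    body = mat @ G  # (n-1, n_s)
    spectra = np.zeros((n_s, n + 1))
    spectra[:, 1:n] = body.T
    neutral_sel = SelectionParams(s=0.0, h=h, N_anc=N_anc)
    if use_pde:
        phi = equilibrium_density(neutral_sel, grid)
        phi = propagate_density(phi, demo, neutral_sel, dt=dt)
        gN = _g_at_nodes(phi, nodes)
    else:
        gN = _analytic_g_at_nodes(neutral_sel, nodes)
    neutral = np.zeros(n + 1)
    neutral[1:n] = mat @ gN
    return ExpectedSFSCache(
        h=h,
        n=n,
        N_anc=float(N_anc),
        s_grid=s_grid,
        spectra=spectra,
        neutral=neutral,
        demo_key=demo.key() if demo is not None else (),
    )
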