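"""Diffusion engine: stationary density, demographic transients, sampling,
and agreement with the exact Wright-Fisher transition-matrix oracle."""

import mpmath
import numpy as np
import pytest

from domfit.demography import Epoch, EpochModel
from domfit.expected import (
    SelectionParams,
    build_grid_cache,
    equilibrium_density,
    expected_sfs,
    make_grid,
    propagate_density,
    sample_expected_sfs,
    stationary_density,
    wf_matrix_oracle,
)
from domfit.expected import FrequencyDensity


def neutral(N=100.0):
    return SelectionParams(0.0, 0.5, N)


class TestStationaryDensity:
    def test_neutral_is_one_over_q(self):
        assert stationary_density(0.5, neutral()) == pytest.approx(2.0)
        assert stationary_density(0.25, neutral()) == pytest.approx(4.0)

    def test_matches_independent_high_precision_quadrature(self):
        # independent oracle: the selection-with-dominance density evaluated
        # with mpmath quadrature; deleterious parameters carry a negative
        # drift coefficient
        q, gamma, h = 0.1, 5.0, 0.2
        g = -gamma

        def A(e):
            return 4 * g * h * e + 2 * g * (1 - 2 * h) * e * e

        with mpmath.workdps(30):
            num = mpmath.quad(lambda e: mpmath.e ** (-A(e)), [q, 1])
            den = mpmath.quad(lambda e: mpmath.e ** (-A(e)), [0, 1])
            expected = float(mpmath.e ** (A(q)) / (q * (1 - q)) * num / den)
        sel = SelectionParams(s=gamma / (2 * 500.0), h=h, N_anc=500.0)
        assert stationary_density(q, sel) == pytest.approx(expected, rel=1e-8)

    def test_domain_error_at_boundaries(self):
        with pytest.raises(ValueError):
            stationary_density(0.0, neutral())
        with pytest.raises(ValueError):
            stationary_density(1.0, neutral())

    def test_deleterious_shifts_mass_to_low_frequency(self, grid):
        # orientation check: with positive (deleterious) s the mean sample
        # frequency must fall below the neutral value
        sel = SelectionParams(0.02, 0.3, 500.0)
        sfs_sel = expected_sfs(sel, None, 40)
        sfs_neu = expected_sfs(neutral(500.0), None, 40)
        i = np.arange(41)

        def mean_freq(s):
            return (i * s.counts).sum() / (40 * s.counts.sum())

        assert mean_freq(sfs_sel) < mean_freq(sfs_neu)


class TestEquilibriumDensity:
    def test_neutral_values_are_inverse_q(self, grid):
        fd = equilibrium_density(neutral(), grid)
        assert np.allclose(fd.values, 1.0 / grid, rtol=1e-12)

    def test_h_half_reduces_to_genic_closed_form(self, grid):
        # at h = 0.5 the density must equal the classical genic-selection
        # flux density; deleterious orientation puts -gamma in the exponent
        N, gamma = 1000.0, 2.0
        fd = equilibrium_density(SelectionParams(gamma / (2 * N), 0.5, N), grid)
        closed = (1 - np.exp(2 * gamma * (1 - grid))) / (
            grid * (1 - grid) * (1 - np.exp(2 * gamma))
        )
        assert np.allclose(fd.values, closed, rtol=1e-8)

    def test_deleterious_mass_below_neutral(self, grid):
        sel = SelectionParams(0.01, 0.3, 500.0)
        f_sel = equilibrium_density(sel, grid)
        f_neu = equilibrium_density(neutral(500.0), grid)
        mass = lambda fd: np.trapezoid(fd.grid * fd.values, fd.grid)
        assert mass(f_sel) < mass(f_neu)

    def test_rejects_s_beyond_supported_range(self, grid):
        with pytest.raises(ValueError, match="range"):
            equilibrium_density(SelectionParams(0.3, 0.5, 100.0), grid)


class TestPropagation:
    def test_neutral_constant_size_is_stationary(self, grid):
        phi = equilibrium_density(neutral(), grid)
        phi2 = propagate_density(phi, EpochModel([Epoch(1.0, 0.2)]), neutral())
        assert np.allclose(phi2.values, phi.values, rtol=1e-6)

    def test_long_run_converges_to_new_size_equilibrium(self, grid):
        # after a long time at relative size nu, the density equals the
        # equilibrium of the operator with gamma and 1/nu diffusion, which is
        # nu times the analytic density at nu*gamma
        N, gamma, h, nu = 100.0, 3.0, 0.4, 2.0
        sel = SelectionParams(gamma / (2 * N), h, N)
        phi = propagate_density(
            equilibrium_density(sel, grid), EpochModel([Epoch(nu, 8.0)]), sel
        )
        sel_scaled = SelectionParams(nu * gamma / (2 * N), h, N)
        target = equilibrium_density(sel_scaled, grid).values * nu
        s1 = sample_expected_sfs(phi, 20)
        s2 = sample_expected_sfs(FrequencyDensity(grid, target), 20)
        assert np.allclose(s1.counts[1:20], s2.counts[1:20], rtol=5e-3)


class TestSampling:
    def test_neutral_sfs_is_theta_over_i(self):
        sfs = expected_sfs(neutral(), None, 4, theta=6.0)
        assert sfs.counts[1:4] == pytest.approx([6.0, 3.0, 2.0], rel=1e-9)
        sfs10 = expected_sfs(neutral(), None, 10, theta=10.0)
        assert sfs10.counts[1] == pytest.approx(10.0, rel=1e-6)
        assert sfs10.counts[5] == pytest.approx(2.0, rel=1e-6)

    def test_neutral_through_pde_path_matches_theta_over_i(self, grid):
        phi = equilibrium_density(neutral(), grid)
        phi = propagate_density(phi, EpochModel([Epoch(1.0, 0.05)]), neutral())
        sfs = sample_expected_sfs(phi, 20, theta=1.0)
        assert np.allclose(sfs.counts[1:20] * np.arange(1, 20), 1.0, rtol=1e-6)


class TestWrightFisherOracle:
    def test_neutral_constant_size_proportional_to_inverse_i(self):
        # n << 2N so that single-copy discreteness is negligible
        orc = wf_matrix_oracle(500, neutral(500.0), None, 10)
        assert np.allclose(orc.counts[1:10] * np.arange(1, 10), 1.0, rtol=0.01)

    def test_lethal_selection_concentrates_singletons(self):
        sel = SelectionParams(0.5, 0.5, 100.0)
        orc = wf_matrix_oracle(100, sel, None, 20)
        assert orc.counts[3:20].max() < 0.01 * orc.counts[1]

    def test_equilibrium_agreement_with_diffusion(self):
        # moderate-gamma agreement at 2N in {200, 400}; the density is binned
        # onto the finite population's frequency atoms before sampling
        for N, gamma, h in ((100, 2, 0.3), (200, 10, 0.5)):
            sel = SelectionParams(gamma / (2 * N), h, N)
            orc = wf_matrix_oracle(N, sel, None, 20)
            dif = expected_sfs(sel, None, 20, pop_size=N)
            assert np.allclose(dif.counts[1:20], orc.counts[1:20], rtol=0.02)

    def test_bottleneck_agreement_with_diffusion(self, grid):
        demo = EpochModel([Epoch(0.3, 0.1), Epoch(1.5, 0.05)])
        for N in (100, 200):
            sel = SelectionParams(5.0 / (2 * N), 0.3, N)
            orc = wf_matrix_oracle(N, sel, demo, 20)
            phi = propagate_density(equilibrium_density(sel, grid), demo, sel)
            dif = sample_expected_sfs(phi, 20, pop_size=int(1.5 * N))
            assert np.allclose(dif.counts[1:20], orc.counts[1:20], rtol=0.02)

    def test_growth_agreement_with_diffusion(self, grid):
        demo = EpochModel([Epoch(1.0, nu_end=5.0, duration=0.05, mode="exponential")])
        sel = SelectionParams(8.0 / 400.0, 0.5, 200.0)
        orc = wf_matrix_oracle(200, sel, demo, 20)
        phi = propagate_density(equilibrium_density(sel, grid), demo, sel)
        dif = sample_expected_sfs(phi, 20, pop_size=1000)
        assert np.allclose(dif.counts[1:20], orc.counts[1:20], rtol=0.02)

    def test_oracle_rejects_large_populations(self):
        with pytest.raises(ValueError):
            wf_matrix_oracle(600, neutral(), None, 10)


class TestGridCache:
    def test_grid_spans_prescribed_selection_range(self, demo10k):
        cache = build_grid_cache(0.5, demo10k, 20, N_anc=10_000.0, n_s=1000)
        assert cache.s_grid.size == 1000
        assert cache.s_grid[0] == pytest.approx(1e-5)
        assert cache.s_grid[-1] == pytest.approx(0.25)

    def test_spectra_decrease_with_s_for_partially_dominant_h(self):
        cache = build_grid_cache(0.3, None, 20, N_anc=2_000.0, n_s=60)
        # beyond a weak-selection threshold every frequency class shrinks
        # monotonically as s grows
        body = cache.spectra[20:, 1:20]
        assert np.all(np.diff(body, axis=0) <= 1e-12)

    def test_weak_selection_limit_is_neutral(self):
        # gamma -> 0: at N_anc = 100 the smallest grid s gives gamma = 2e-3
        cache = build_grid_cache(0.5, None, 20, N_anc=100.0, n_s=10)
        assert np.allclose(cache.spectra[0][1:20], cache.neutral[1:20], rtol=5e-3)

    def test_cache_round_trips_through_disk(self, tmp_path):
        cache = build_grid_cache(0.5, None, 10, N_anc=100.0, n_s=5)
        cache.save(tmp_path / "c.npz")
        back = type(cache).load(tmp_path / "c.npz")
        assert np.array_equal(back.spectra, cache.spectra)
        assert back.h == cache.h and back.n == cache.n


def test_transient_neutral_sfs_matches_msprime():
    """Coalescent cross-check of the demographic transient (neutral)."""
    msprime = pytest.importorskip("msprime")
    N = 2_000
    demo = EpochModel([Epoch(0.25, 0.05), Epoch(2.0, 0.02)])
    # matching msprime demography (times in generations, backwards)
    t2 = 0.02 * 2 * N
    t1 = (0.05 + 0.02) * 2 * N
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=2.0 * N)
    dem.add_population_parameters_change(time=t2, initial_size=0.25 * N)
    dem.add_population_parameters_change(time=t1, initial_size=N)
    n = 10
    reps = 2000
    ts_iter = msprime.sim_ancestry(
        samples=5, demography=dem, sequence_length=1, random_seed=7,
        num_replicates=reps, ploidy=2,
    )
    per_rep = np.empty((reps, n + 1))
    for r, ts in enumerate(ts_iter):
        per_rep[r] = ts.allele_frequency_spectrum(
            mode="branch", polarised=True, span_normalise=False
        )
    afs = per_rep.mean(axis=0)
    se = per_rep.std(axis=0) / np.sqrt(reps)
    sel = SelectionParams(0.0, 0.5, N)
    phi = propagate_density(equilibrium_density(sel, make_grid()), demo, sel)
    # branch-mode AFS measures E[branch length] in generations; a mutation
    # rate of 1 per generation then gives expected counts theta/i = 4N/i at
    # constant size, so the diffusion spectrum is compared at theta = 4N
    dif = sample_expected_sfs(phi, n, theta=4 * N)
    z = (dif.counts[1:n] - afs[1:n]) / se[1:n]
    assert np.max(np.abs(z)) < 4.0
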