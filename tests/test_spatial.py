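"""Phase-by-phase behavior of the spatial model, against exact oracles."""

import numpy as np
import pytest

from phagegrid import (EMPTY, INFECTED, SimParams, UNINFECTED, build_kernel,
                       diffusion_phase, infection_phase, lysis_phase,
                       new_grid, reproduction_phase, run_spatial, step)
from phagegrid.experiments import make_fixture
from phagegrid.spatial import first_success_probs


def bare_world(width=5, height=5, seed=0, **kw):
    params = SimParams(width=width, height=height, init_cell_frac=0.0,
                       init_phage_frac=0.0, eps_fraction_E=0.0,
                       n_steps=10, avg_window=5, seed=seed, **kw)
    return params, new_grid(params)


class TestLysis:
    def test_burst_exactly_lifespan_steps_after_infection(self):
        params, grid = bare_world(burst_b=7, infected_lifespan=3,
                                  cell_repro_prob=0.0, diffuse_fraction=0.0)
        grid.occupant[2, 2] = INFECTED
        grid.infected_age[2, 2] = 0  # just infected
        for i in range(2):
            assert lysis_phase(grid, params) == 0
        assert lysis_phase(grid, params) == 1
        assert grid.occupant[2, 2] == EMPTY
        assert grid.phage[2, 2] == 7

    def test_cell_one_step_from_death_bursts_next_phase(self):
        params, grid = bare_world(burst_b=4, infected_lifespan=20)
        grid.occupant[1, 1] = INFECTED
        grid.infected_age[1, 1] = 19
        assert lysis_phase(grid, params) == 1
        assert grid.phage[1, 1] == 4

    def test_no_infected_cells_is_a_no_op(self):
        params, grid = bare_world()
        grid.occupant[0, 0] = UNINFECTED
        before = grid.occupant.copy()
        assert lysis_phase(grid, params) == 0
        assert np.array_equal(grid.occupant, before)

    def test_debris_persists_two_phases_then_expires(self):
        params, grid = bare_world(burst_b=6, infected_lifespan=1,
                                  debris_enabled=True, debris_lifespan=2)
        grid.occupant[2, 2] = INFECTED
        lysis_phase(grid, params)
        assert grid.phage[2, 2] == 6
        assert grid.debris[2, 2] == 2
        lysis_phase(grid, params)
        assert grid.debris[2, 2] == 1
        lysis_phase(grid, params)
        assert grid.debris[2, 2] == 0


class TestReproduction:
    def test_fully_surrounded_cell_never_reproduces(self):
        params, grid = bare_world(width=3, height=3, cell_repro_prob=1.0)
        grid.occupant[:] = UNINFECTED  # torus: every neighbor occupied
        assert reproduction_phase(grid, params) == 0

    def test_zero_probability_changes_nothing(self):
        params, grid = bare_world(cell_repro_prob=0.0)
        grid.occupant[2, 2] = UNINFECTED
        before = grid.occupant.copy()
        reproduction_phase(grid, params)
        assert np.array_equal(grid.occupant, before)

    def test_daughters_prefer_orthogonal_patches_uniformly(self):
        """Single parent on an empty grid: each orthogonal neighbor ~1/4."""
        counts = {}
        n_trials = 10_000
        for seed in range(n_trials):
            params, grid = bare_world(seed=seed, cell_repro_prob=1.0)
            grid.occupant[2, 2] = UNINFECTED
            assert reproduction_phase(grid, params) == 1
            spots = set(zip(*np.nonzero(grid.occupant == UNINFECTED))) - {(2, 2)}
            (spot,) = spots
            counts[spot] = counts.get(spot, 0) + 1
        assert set(counts) == {(1, 2), (3, 2), (2, 1), (2, 3)}
        sd = np.sqrt(n_trials * 0.25 * 0.75)
        for c in counts.values():
            assert abs(c - n_trials / 4) < 4 * sd

    def test_diagonal_fallback_when_orthogonals_blocked(self):
        params, grid = bare_world(cell_repro_prob=1.0)
        grid.occupant[2, 2] = UNINFECTED
        for r, c in ((1, 2), (3, 2), (2, 1), (2, 3)):
            grid.occupant[r, c] = INFECTED
        reproduction_phase(grid, params)
        daughters = set(zip(*np.nonzero(grid.occupant == UNINFECTED))) - {(2, 2)}
        assert daughters <= {(1, 1), (1, 3), (3, 1), (3, 3)}
        assert len(daughters) == 1

    def test_two_daughters_never_share_a_patch(self):
        for seed in range(50):
            params, grid = bare_world(width=4, height=4, seed=seed,
                                      cell_repro_prob=1.0)
            grid.occupant[0, 0] = grid.occupant[0, 2] = UNINFECTED
            n_before = 2
            births = reproduction_phase(grid, params)
            assert (grid.occupant == UNINFECTED).sum() == n_before + births


class TestInfection:
    def test_first_success_distribution_sums_to_one(self):
        for ks in [(0.25, 0.0, 0.0, 0.35), (0.5, 0.5, 0.5, 0.5),
                   (0.0, 0.0, 0.0, 0.0), (1.0, 0.2, 0.0, 0.9)]:
            p = first_success_probs(ks)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)
            # escape probability is order-independent
            assert p[-1] == pytest.approx(np.prod([1 - k for k in ks if k > 0]))

    def test_eps_only_patch_matches_binomial_oracle(self):
        """Phage facing only EPS adsorb like Binomial(n, k_E)."""
        k_E, n = 0.35, 10_000
        losses = []
        for seed in range(100):
            params, grid = bare_world(width=1, height=1, seed=seed, k_E=k_E,
                                      diffuse_fraction=0.0)
            grid.eps[0, 0] = True
            grid.phage[0, 0] = n
            t = infection_phase(grid, params)
            losses.append(t["loss_E"])
            assert t["loss_E"] + grid.phage[0, 0] == n
        sd = np.sqrt(n * k_E * (1 - k_E))  # ~47.7
        assert abs(np.mean(losses) - n * k_E) < 3 * sd / np.sqrt(100)

    def test_empty_patch_loses_nothing(self):
        params, grid = bare_world()
        grid.phage[2, 2] = 500
        t = infection_phase(grid, params)
        assert t == dict(loss_C=0, loss_I=0, loss_D=0, loss_E=0,
                         infections_eps=0)
        assert grid.phage[2, 2] == 500

    def test_certain_adsorption_infects_exactly_once(self):
        """k_C=1, k_I=0: the first phage infects, the rest stay free."""
        params, grid = bare_world(k_C=1.0, k_I=0.0)
        grid.occupant[2, 2] = UNINFECTED
        grid.phage[2, 2] = 5
        t = infection_phase(grid, params)
        assert t["loss_C"] == 1
        assert grid.occupant[2, 2] == INFECTED
        assert grid.phage[2, 2] == 4

    def test_newly_infected_cell_is_visible_to_later_phage(self):
        """With k_I=1 every phage after the infecting one superinfects."""
        params, grid = bare_world(k_C=1.0, k_I=1.0)
        grid.occupant[2, 2] = UNINFECTED
        grid.phage[2, 2] = 8
        t = infection_phase(grid, params)
        assert t["loss_C"] == 1
        assert t["loss_I"] == 7
        assert grid.phage[2, 2] == 0

    def test_infection_on_eps_patch_is_tallied(self):
        params, grid = bare_world(k_C=1.0)
        grid.occupant[1, 1] = UNINFECTED
        grid.eps[1, 1] = True
        grid.phage[1, 1] = 1
        t = infection_phase(grid, params)
        assert t["infections_eps"] == 1


class TestDiffusion:
    def test_point_source_spreads_by_kernel_weights(self):
        kernel = build_kernel(1.0)
        n = 1000
        stays, orth = [], []
        for seed in range(200):
            params, grid = bare_world(seed=seed)
            grid.phage[2, 2] = n
            diffusion_phase(grid, kernel)
            assert grid.total_phage() >= 0
            stays.append(grid.phage[2, 2])
            orth.append(grid.phage[1, 2])
        assert np.mean(stays) == pytest.approx(n * kernel.w_center, rel=0.05)
        assert np.mean(orth) == pytest.approx(n * kernel.w_orth, rel=0.05)

    def test_uniform_field_is_conserved_in_expectation(self):
        kernel = build_kernel(0.8)
        totals = []
        c = 7
        for seed in range(300):
            params, grid = bare_world(seed=seed)
            grid.phage[:] = c
            diffusion_phase(grid, kernel)
            totals.append(grid.total_phage())
        n_patches = 25
        # each patch's load is exactly c (integer): rounding is a no-op
        assert all(t == c * n_patches for t in totals)

    def test_stochastic_rounding_is_unbiased(self):
        """Mean total over repetitions stays within 3 sd of the true total."""
        kernel = build_kernel(1.3)
        base = np.random.default_rng(99).integers(0, 50, size=(5, 5))
        # exact variance of the rounded total from the deterministic loads
        src = base.astype(float)
        load = np.zeros_like(src)
        w = kernel.as_array()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                load += w[dr + 1, dc + 1] * np.roll(src, (dr, dc), axis=(0, 1))
        frac = load - np.floor(load)
        var_total = float(np.sum(frac * (1 - frac)))
        reps = 1000
        totals = []
        for seed in range(reps):
            params, grid = bare_world(seed=seed)
            grid.phage[:] = base
            diffusion_phase(grid, kernel)
            totals.append(grid.total_phage())
        true_total = int(base.sum())
        assert load.sum() == pytest.approx(true_total, abs=1e-9)
        sd_mean = np.sqrt(var_total / reps)
        assert abs(np.mean(totals) - true_total) < 3 * sd_mean + 1e-9


class TestStepAndRun:
    def test_no_phage_only_reproduction_changes_state(self):
        params, grid = bare_world(cell_repro_prob=0.5, diffuse_fraction=0.3)
        grid.occupant[2, 2] = UNINFECTED
        s = step(grid, params)
        assert s.P == 0 and s.bursts == 0 and s.loss_C == 0
        assert s.I == 0

    def test_kc_zero_cells_never_infected(self):
        params, grid = bare_world(k_C=0.0, k_E=0.35, diffuse_fraction=0.0)
        grid.occupant[2, 2] = UNINFECTED
        grid.eps[2, 2] = True
        grid.phage[2, 2] = 100
        for _ in range(5):
            s = step(grid, params)
            assert s.I == 0 and s.loss_C == 0
        assert s.loss_E >= 0 and grid.phage[2, 2] < 100

    def test_hand_traced_infection_and_lysis_on_one_patch(self):
        """Forced cycle: infect at step 1, lyse exactly lifespan later."""
        params, grid = make_fixture("one_patch")  # k_C=1, b=5, lifespan 20
        s1 = step(grid, params)
        assert s1.loss_C == 1 and s1.P == 0
        assert grid.occupant[0, 0] == INFECTED
        stats = [step(grid, params) for _ in range(params.infected_lifespan)]
        assert all(s.bursts == 0 for s in stats[:-1])
        assert stats[-1].bursts == 1
        assert stats[-1].step == 1 + params.infected_lifespan
        assert grid.phage[0, 0] == params.burst_b

    def test_identical_seed_gives_bit_identical_summary(self, small_params):
        a = run_spatial(small_params)
        b = run_spatial(small_params)
        assert a == b

    def test_single_burst_with_eps_loss_cannot_sustain_phage(self):
        params = SimParams(width=15, height=15, burst_b=1, eps_fraction_E=0.3,
                           k_C=0.25, k_E=0.35, cell_repro_prob=0.1,
                           diffuse_fraction=0.3, n_steps=2000, avg_window=100,
                           seed=4)
        s = run_spatial(params)
        assert s.extinct  # phage die out: b=1 cannot offset EPS losses

    def test_no_phage_death_routes_eliminates_cells(self):
        params = SimParams(width=15, height=15, burst_b=10,
                           eps_fraction_E=0.0, k_C=0.25, k_E=0.0, k_I=0.0,
                           k_D=0.0, cell_repro_prob=0.1, diffuse_fraction=0.3,
                           n_steps=3000, avg_window=100, seed=4)
        s = run_spatial(params)
        assert s.extinct
        # cells, not phage, are the casualties
        assert s.mean_C == 0 or s.n_steps_run < params.n_steps

    def test_infected_count_is_cumulatively_exact(self, small_params):
        _, series = run_spatial(small_params, return_series=True)
        running = (series["loss_C"].cumsum() - series["bursts"].cumsum())
        assert np.array_equal(running.to_numpy(),
                              series["n_infected"].to_numpy())

    def test_phage_bookkeeping_closes_without_diffusion(self):
        """P changes only by +b per burst and -1 per adsorption."""
        params = SimParams(width=10, height=10, burst_b=6, eps_fraction_E=0.3,
                           k_C=0.25, k_E=0.35, cell_repro_prob=0.1,
                           diffuse_fraction=0.0, n_steps=100, avg_window=50,
                           seed=2)
        _, series = run_spatial(params, return_series=True)
        p = series["P"].to_numpy()
        p_prev = np.concatenate([[params.burst_b * 30], p[:-1]])
        expected = (p_prev + params.burst_b * series["bursts"].to_numpy()
                    - series[["loss_C", "loss_I", "loss_D", "loss_E"]]
                    .sum(axis=1).to_numpy())
        assert np.array_equal(p, expected)
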