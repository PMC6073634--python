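"""The GARD rate law, SSA stepping, growth-fission reproduction and the
finite-supply equilibrium run."""

import numpy as np
import pytest
from scipy import stats

import gardsim as g


def uniform_beta(n, value=0.0):
    return g.BetaMatrix(np.full((n, n), float(value)), norm_scale=1.0)


class TestPropensities:
    def test_basal_rates_without_catalysis(self):
        p = g.GardParameters(beta=uniform_beta(4), n_max=10, k_f=1.0, k_b=1.0, rho=1.0)
        fwd, bwd = g.propensities(g.Assembly([1, 1, 0, 0]), p)
        assert np.allclose(fwd, 2.0)          # k rho N with C = 1
        assert np.allclose(bwd, [1.0, 1.0, 0.0, 0.0])

    def test_hand_substitution_into_rate_law(self):
        beta = g.BetaMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), norm_scale=1.0)
        p = g.GardParameters(beta=beta, n_max=10, k_f=1.0, k_b=1.0, rho=1.0)
        fwd, _ = g.propensities(g.Assembly([1, 1]), p)
        # forward_1 = 1 * 1 * 2 * (1 + (0*1 + 1*1)/2) = 3
        assert np.isclose(fwd[0], 3.0)

    def test_catalysis_preserves_equilibrium_constant(self, small_params):
        # forward/backward ratio is independent of beta for any occupied type
        a = g.Assembly(np.full(20, 2))
        fwd, bwd = g.propensities(a, small_params)
        fwd0, bwd0 = g.propensities(a, small_params.with_(beta=uniform_beta(20)))
        assert np.allclose(fwd / bwd, fwd0 / bwd0)

    def test_empty_assembly_rejected(self, small_params):
        with pytest.raises(g.GardError):
            g.propensities(g.Assembly(np.zeros(20, int)), small_params)

    def test_zero_count_type_cannot_leave(self, small_params):
        _, bwd = g.propensities(g.Assembly([5] + [0] * 19), small_params)
        assert np.all(bwd[1:] == 0)


class TestStepSSA:
    def test_molecule_count_changes_by_one(self, small_params, rng):
        a = g.Assembly(np.full(20, 1))
        for _ in range(50):
            b, dt = g.step_ssa(a, small_params, rng)
            assert abs(b.size - a.size) == 1 and dt > 0
            a = b

    def test_selection_follows_propensity_ratio(self, rng):
        # single type, forward 3 vs backward 1: entry chosen 75% +/- 3 sigma
        p = g.GardParameters(beta=uniform_beta(1), n_max=10, k_f=3.0, k_b=1.0, rho=1.0)
        a = g.Assembly([1])
        entries = sum(g.step_ssa(a, p, rng)[0].size == 2 for _ in range(10_000))
        assert abs(entries / 10_000 - 0.75) < 3 * np.sqrt(0.75 * 0.25 / 10_000)

    def test_same_seed_same_event_sequence(self, small_params):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            a = g.Assembly(np.full(20, 1))
            seq = []
            for _ in range(100):
                a, dt = g.step_ssa(a, small_params, rng)
                seq.append((a.counts.tobytes(), dt))
            runs.append(seq)
        assert runs[0] == runs[1]

    def test_stalled_system_raises(self):
        # construct an (invalid in normal use) zero-rate system by bypassing
        # parameter validation: every propensity vanishes
        p = g.GardParameters(beta=uniform_beta(2), n_max=10, k_f=1.0, k_b=0.0, rho=1.0)
        object.__setattr__(p, "rho", np.zeros(2))
        with pytest.raises(g.StalledGrowthError):
            g.step_ssa(g.Assembly([1, 0]), p, np.random.default_rng(0))


class TestGrowAndSplit:
    def test_growth_reaches_n_max_exactly(self, small_params, rng):
        grown, elapsed = g.grow_to_size(g.Assembly(np.full(20, 1)), small_params, rng)
        assert grown.size == small_params.n_max and elapsed > 0

    def test_already_at_n_max_is_a_no_op(self, small_params):
        a = g.Assembly([small_params.n_max] + [0] * 19)
        state = np.random.default_rng(1)
        grown, elapsed = g.grow_to_size(a, small_params, state)
        assert grown.size == small_params.n_max and elapsed == 0.0
        # no randomness consumed
        assert state.random() == np.random.default_rng(1).random()

    def test_catalysis_accelerates_growth(self):
        # paired runs, same seeds: strong uniform catalysis grows strictly
        # faster on average than no catalysis
        times = {}
        for name, value in [("none", 0.0), ("strong", 50.0)]:
            p = g.GardParameters(beta=uniform_beta(10, value), n_max=20,
                                 k_f=1.0, k_b=1.0, rho=1.0)
            total = 0.0
            for cycle in range(100):
                rng = np.random.default_rng(500 + cycle)
                total += g.grow_to_size(g.Assembly(np.full(10, 1)), p, rng)[1]
            times[name] = total / 100
        assert times["strong"] < times["none"]

    def test_split_conserves_counts_and_halves(self, rng):
        counts = rng.integers(0, 10, 30)
        counts[0] += (counts.sum() % 2)  # make even
        parent = g.Assembly(counts)
        a, b = g.split(parent, rng)
        assert np.array_equal(a.counts + b.counts, parent.counts)
        assert a.size == b.size == parent.size // 2

    def test_split_follows_hypergeometric_law(self, rng):
        parent = g.Assembly([2, 2])
        draws = np.array([g.split(parent, rng)[0].counts[0] for _ in range(10_000)])
        expected = stats.hypergeom(4, 2, 2).pmf([0, 1, 2]) * 10_000
        observed = np.bincount(draws, minlength=3)
        assert stats.chisquare(observed, expected).pvalue > 0.001

    def test_odd_count_rejected(self, rng):
        with pytest.raises(g.GardError):
            g.split(g.Assembly([3]), rng)


class TestMutateComposition:
    def test_identity_and_inverse(self):
        a = g.Assembly([2, 0, 5])
        assert np.array_equal(g.mutate_composition(a, 1, 0).counts, a.counts)
        back = g.mutate_composition(g.mutate_composition(a, 0, 1), 0, -1)
        assert np.array_equal(back.counts, a.counts)

    def test_grows_a_zero_type(self):
        a = g.mutate_composition(g.Assembly([1, 0]), 1, 3)
        assert a.counts[1] == 3 and a.size == 4

    def test_negative_result_rejected(self):
        with pytest.raises(g.GardError):
            g.mutate_composition(g.Assembly([1, 0]), 1, -1)


class TestRunTrace:
    def test_length_times_and_sizes(self, short_trace, small_params):
        assert len(short_trace) == 40
        assert np.all(short_trace.compositions.sum(axis=1) == small_params.n_max)
        assert np.all(np.diff(short_trace.times) > 0)

    def test_same_seed_identical_trace(self, small_params, short_trace):
        again = g.run_trace(small_params, 40, seed=11)
        assert np.array_equal(again.compositions, short_trace.compositions)
        assert np.array_equal(again.times, short_trace.times)

    def test_different_seed_differs(self, small_params, short_trace):
        other = g.run_trace(small_params, 40, seed=12)
        assert not np.array_equal(other.compositions, short_trace.compositions)


@pytest.fixture(scope="module")
def series():
    p = g.GardParameters(beta=g.sample_beta(50, seed=5), n_max=100,
                         supply_mode="finite", supply_budget=2000,
                         fission_mode=False)
    return g.run_to_equilibrium(p, seed=6, max_events=200_000, sample_every=500)


class TestRunToEquilibrium:
    def test_supply_absorbed_to_a_plateau(self, series):
        sizes = series.sizes()
        assert sizes[-1] > 10 * sizes[0]
        late = sizes[-len(sizes) // 5:]
        assert late.std() < 0.05 * late.mean()     # flat plateau
        # external reservoir essentially exhausted
        assert series.external[-1].sum() < 0.1 * 2000

    def test_equal_constants_give_equal_fractions(self, series):
        # time-averaged plateau molar fractions equal within multinomial noise
        fractions = series.molar_fractions()[-20:].mean(axis=0)
        n_types = fractions.size
        n_final = series.sizes()[-1]
        sigma = np.sqrt((1 / n_types) * (1 - 1 / n_types) / n_final)
        assert np.max(np.abs(fractions - 1 / n_types)) < 3 * sigma

    def test_transient_is_composome_like(self, series):
        # before resources run out, kinetics (not thermodynamics) sets the
        # composition: some molar fractions transiently run far above the
        # equal-share plateau value
        mf = series.molar_fractions()
        transient_peak = mf[1:8].max()
        plateau = mf[-5:].max(axis=1).mean()
        assert transient_peak > 2.5 * plateau

    def test_stationary_fractions_match_detailed_balance_oracle(self):
        # uniform catalysis, unequal K_i: solve the self-consistent balance
        #   n_i = K_i rho0_i (E0_i - n_i + n0_i)/E0_i * N,  N = sum n
        # by fixed-point iteration (independent of the SSA path)
        kf = np.array([2.0, 1.0, 1.0, 0.5, 0.25] * 2)
        p = g.GardParameters(beta=uniform_beta(10, 5.0), n_max=100,
                             k_f=kf, k_b=1.0, rho=1.0,
                             supply_mode="finite", supply_budget=3000,
                             fission_mode=False)
        series = g.run_to_equilibrium(p, seed=13, max_events=250_000, sample_every=500)
        from scipy.optimize import brentq

        e0 = 300.0
        n0 = series.compositions[0].astype(float)

        def n_of(total):
            # per-type balance at fixed N has the closed form
            # n_i = a_i N (e0 + n0_i) / (e0 + a_i N), a_i = K_i rho_i
            return kf * total * (e0 + n0) / (e0 + kf * total)

        total = brentq(lambda t: n_of(t).sum() - t, 1.0, 10 * e0 * 10)
        predicted = n_of(total) / total
        observed = series.molar_fractions()[-20:].mean(axis=0)
        assert np.max(np.abs(observed - predicted)) < 0.02

    def test_mode_validation(self, small_params):
        with pytest.raises(g.GardError):
            g.run_to_equilibrium(small_params, seed=0)


class TestKeqSweep:
    def test_scale_one_reproduces_unscaled_statistics(self, small_params):
        table = g.keq_sweep(small_params, [1.0], 30, seed=11)
        trace = g.run_trace(small_params, 30, seed=11)
        eps = g.detect_composomes(trace)
        covered = sum(e.end - e.start + 1 for e in eps) / 30
        assert table["persistence"].iloc[0] == pytest.approx(covered)

    def test_persistence_bounded(self, small_params):
        table = g.keq_sweep(small_params, [1.0, 0.5, 0.2], 20, seed=3)
        assert table["persistence"].between(0, 1).all()

    def test_empty_grid_rejected(self, small_params):
        with pytest.raises(g.GardError):
            g.keq_sweep(small_params, [], 10, seed=0)


class TestOdeCrossCheck:
    def test_mean_field_growth_direction(self):
        # uniform catalysis (equal C_i): the mean-field equations reduce to a
        # linear system whose growing solution aligns with the k_f_i rho_i
        # vector -- exponential growth at kf-proportional molar fractions
        from scipy.integrate import solve_ivp

        kf = np.array([4.0, 2.0, 1.0, 0.5, 0.5])
        p = g.GardParameters(beta=uniform_beta(5), n_max=10, k_f=kf, k_b=1.0, rho=1.0)
        sol = solve_ivp(g.ode_rhs, (0, 1.5), np.full(5, 2.0), args=(p,), rtol=1e-10)
        n_end = sol.y[:, -1]
        assert n_end.sum() > 10.0
        assert np.allclose(n_end / n_end.sum(), kf / kf.sum(), atol=1e-3)


class TestMorowitzBoundary:
    """Transmissible compositional information requires N_MAX <= N_G."""

    def test_morowitz_information_direction(self):
        """The transmissible-information reading of the Morowitz boundary:
        parent-to-progeny similarity *in excess of the random-assembly baseline*
        is higher at (N_G=100, N_MAX=100) than at (N_G=10, N_MAX=100)."""
        rng = np.random.default_rng(0)
        wins = 0
        for m in range(10):
            excesses = []
            for n_types in (100, 10):
                params = g.GardParameters(beta=g.sample_beta(n_types, seed=500 + m),
                                          n_max=100)
                trace = g.run_trace(params, 200, seed=900 + m)
                unit = trace.compositions / np.linalg.norm(
                    trace.compositions, axis=1, keepdims=True)
                consecutive = float(np.sum(unit[:-1] * unit[1:], axis=1).mean())
                # baseline: similarity between temporally distant compositions
                # of the same run (no inheritance at 50-generation lag)
                baseline = float(np.mean([
                    np.dot(unit[i], unit[i + 50]) for i in range(0, 150, 5)
                ]))
                excesses.append((consecutive - baseline) / (1 - baseline + 1e-12))
            wins += excesses[0] > excesses[1]
        assert wins >= 7
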