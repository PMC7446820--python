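import itertools

import numpy as np
import pytest

from crneutral import (
    CommunityParams,
    ConsumptionMatrix,
    SimState,
    Schedule,
    apply_event,
    build_specialist_matrix,
    calibrate_community,
    draw_next_event,
    event_rates,
    link_extinctions,
    run_simulation,
)


@pytest.fixture
def tiny():
    """1 consumer, 1 resource with hand-checkable rates."""
    C = ConsumptionMatrix(np.array([[2.0]]))
    params = CommunityParams(S=1, K=1, eps=1.0, n=2, r=3, rho=np.array([4.0]), eta=np.array([0.5]))
    state = SimState(N=np.array([2]), R=np.array([3]))
    return C, params, state


class TestEventRates:
    def test_hand_evaluated(self, tiny):
        C, params, state = tiny
        rates = event_rates(state, params, C)
        assert rates.inflow[0] == 4.0
        assert rates.death[0] == 1.0
        assert rates.consumption_birth[0, 0] == 12.0
        assert rates.consumption_no_birth[0, 0] == 0.0
        assert rates.total == 17.0

    def test_total_invariant_to_eps(self, tiny):
        C, params, state = tiny
        half = CommunityParams(S=1, K=1, eps=0.5, n=2, r=3, rho=params.rho, eta=params.eta)
        rates = event_rates(state, half, C)
        assert rates.consumption_birth[0, 0] == 6.0
        assert rates.consumption_no_birth[0, 0] == 6.0
        assert rates.total == 17.0

    def test_empty_resource_kills_consumption(self, tiny):
        C, params, _ = tiny
        rates = event_rates(SimState(N=np.array([2]), R=np.array([0])), params, C)
        assert rates.consumption_total == 0.0


class TestDrawNextEvent:
    def test_only_inflow_possible(self, tiny):
        C, params, _ = tiny
        rates = event_rates(SimState(N=np.array([1]), R=np.array([0])), params, C)
        # suppress death by zeroing it via a custom RateSet
        rates = rates._replace(death=np.zeros(1))
        rng = np.random.default_rng(0)
        for _ in range(20):
            event, _ = draw_next_event(rates, rng)
            assert event[0] == "inflow"

    def test_event_frequencies_match_probabilities(self, tiny):
        C, params, state = tiny
        rates = event_rates(state, params, C)
        rng = np.random.default_rng(42)
        draws = 100_000
        counts = {"inflow": 0, "death": 0, "birth": 0, "consume": 0}
        wait_sum = 0.0
        for _ in range(draws):
            event, dt = draw_next_event(rates, rng)
            counts[event[0]] += 1
            wait_sum += dt
        # exact probabilities 4/17, 1/17, 12/17; 3 sigma multinomial tolerance
        for key, p in [("inflow", 4 / 17), ("death", 1 / 17), ("birth", 12 / 17)]:
            tol = 3 * np.sqrt(p * (1 - p) / draws)
            assert counts[key] / draws == pytest.approx(p, abs=tol)
        # waiting time mean 1/17 within 3 sigma (exponential sd = mean)
        assert wait_sum / draws == pytest.approx(1 / 17, abs=3 / (17 * np.sqrt(draws)))


class TestApplyEvent:
    def test_death_decrements(self):
        s = SimState(N=np.array([5]), R=np.array([0]))
        apply_event(s, ("death", 0))
        assert s.N[0] == 4

    def test_speciation_floor_logs_extinction(self):
        s = SimState(N=np.array([1]), R=np.array([2]), t=3.5)
        log = []
        apply_event(s, ("death", 0), log)
        assert s.N[0] == 1
        assert log == [(0, 3.5)]

    def test_birth_consumption_bookkeeping(self):
        s = SimState(N=np.array([2]), R=np.array([3]))
        apply_event(s, ("birth", 0, 0))
        assert s.R[0] == 2 and s.N[0] == 3

    def test_consumption_from_empty_resource_raises(self):
        s = SimState(N=np.array([2]), R=np.array([0]))
        with pytest.raises(RuntimeError):
            apply_event(s, ("consume", 0, 0))


class TestRunSimulation:
    def test_determinism(self):
        C = build_specialist_matrix(5, 2.0, 1.0)
        params = calibrate_community(C, n=10, r=10)
        sched = Schedule(burn_in=5, runtime=50, cadence=5)
        a = run_simulation(C, params, sched, seed=123)
        b = run_simulation(C, params, sched, seed=123)
        assert np.array_equal(a.N, b.N)
        assert np.array_equal(a.R, b.R)
        assert a.extinctions.equals(b.extinctions)

    def test_speciation_floor_never_violated(self):
        C = build_specialist_matrix(6, 1.0, 1.0)
        params = calibrate_community(C, n=4, r=4)
        traj = run_simulation(C, params, Schedule(burn_in=10, runtime=300, cadence=1), seed=7)
        assert traj.N.min() >= 1
        assert len(traj.extinctions) > 0

    def test_birth_count_equals_consumption_at_full_efficiency(self):
        C = build_specialist_matrix(4, 1.0, 1.0)
        params = calibrate_community(C, n=20, r=20, eps=1.0)
        traj = run_simulation(C, params, Schedule(burn_in=0, runtime=50, cadence=10, record_events=True), seed=5)
        assert traj.n_births == traj.n_consumptions
        assert traj.event_counts.sum() == traj.n_consumptions

    def test_time_averaged_mean_self_consistent(self):
        """Mean abundance of a shorter run within 10% of a 10x longer run."""
        C = build_specialist_matrix(10, 1.0, 1.0)
        params = calibrate_community(C, n=40, r=40)
        short = run_simulation(C, params, Schedule(burn_in=200, runtime=400, cadence=10), seed=21)
        long = run_simulation(C, params, Schedule(burn_in=200, runtime=4000, cadence=10), seed=22)
        assert short.N.mean() == pytest.approx(long.N.mean(), rel=0.10)

    def test_resource_marginals_near_poisson(self):
        """Stationary resource dispersion index (var/mean) close to 1."""
        C = build_specialist_matrix(10, 1.0, 1.0)
        params = calibrate_community(C, n=40, r=40)
        traj = run_simulation(C, params, Schedule(burn_in=100, runtime=2000, cadence=2), seed=3)
        disp = traj.R.var(axis=0) / traj.R.mean(axis=0)
        assert np.all(disp > 0.8) and np.all(disp < 1.2)

    def test_neutral_species_exchangeable(self):
        C = build_specialist_matrix(8, 1.0, 1.0)
        params = calibrate_community(C, n=30, r=30)
        traj = run_simulation(C, params, Schedule(burn_in=300, runtime=4000, cadence=5), seed=9)
        means = traj.N.mean(axis=0)
        # all species share the same stationary mean up to sampling error
        assert means.std() / means.mean() < 0.5
        assert means.min() > 0.3 * means.mean()


class TestExactness:
    def test_stationary_distribution_matches_brute_force(self):
        """Empirical 1x1 stationary law vs the truncated chain's linear solve."""
        C = ConsumptionMatrix(np.array([[1.0]]))
        params = calibrate_community(C, n=2, r=1, eps=1.0)  # rho=2, eta=1
        n_cap, r_cap = 25, 15

        # generator over states (N, R) with N >= 1, R >= 0, reflecting caps
        states = list(itertools.product(range(1, n_cap + 1), range(0, r_cap + 1)))
        index = {s: i for i, s in enumerate(states)}
        Q = np.zeros((len(states), len(states)))
        for (N, R), i in index.items():
            flows = []
            if R < r_cap:
                flows.append(((N, R + 1), params.rho[0]))
            if N > 1:
                flows.append(((N - 1, R), params.eta[0] * N))
            if R > 0 and N < n_cap:
                flows.append(((N + 1, R - 1), R * C.entries[0, 0] * N))
            for s2, rate in flows:
                j = index[s2]
                Q[i, j] += rate
                Q[i, i] -= rate
        A = np.vstack([Q.T, np.ones(len(states))])
        b = np.zeros(len(states) + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)

        traj = run_simulation(
            C, params, Schedule(burn_in=50, runtime=30000, cadence=0.5), seed=77
        )
        # stationary marginal of N
        pi_N = np.zeros(n_cap + 1)
        for (N, R), i in index.items():
            pi_N[N] += pi[i]
        emp_N = np.bincount(traj.N[:, 0], minlength=n_cap + 1)[: n_cap + 1]
        emp_N = emp_N / emp_N.sum()
        assert np.abs(emp_N - pi_N).max() < 0.02
        pi_R = np.zeros(r_cap + 1)
        for (N, R), i in index.items():
            pi_R[R] += pi[i]
        emp_R = np.bincount(traj.R[:, 0], minlength=r_cap + 1)[: r_cap + 1]
        emp_R = emp_R / emp_R.sum()
        assert np.abs(emp_R - pi_R).max() < 0.02

    def test_reference_engine_agrees_with_kernel(self):
        """Slow transparent loop and compiled kernel sample the same law."""
        from crneutral import run_reference

        C = ConsumptionMatrix(np.array([[1.0]]))
        params = calibrate_community(C, n=2, r=1, eps=1.0)
        _, _, samples = run_reference(C, params, t_end=2000.0, seed=5, sample_every=1.0)
        traj = run_simulation(C, params, Schedule(burn_in=0, runtime=2000, cadence=1), seed=6)
        assert abs(samples[:, 0].mean() - traj.N.mean()) < 0.15
        assert abs(samples[:, 1].mean() - traj.R.mean()) < 0.15


def test_link_extinctions_pairs_observations_forward():
    C = build_specialist_matrix(5, 1.0, 1.0)
    params = calibrate_community(C, n=5, r=5)
    traj = run_simulation(C, params, Schedule(burn_in=20, runtime=500, cadence=5), seed=13)
    linked = link_extinctions(traj)
    assert not linked.empty
    assert (linked["wait_generations"] >= 0).all()
    assert (linked["observed_abundance"] >= 1).all()
    # every linked abundance appears in the snapshots of that species
    row = linked.iloc[0]
    assert row["observed_abundance"] in traj.N[:, int(row["species"])]
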