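import numpy as np
import pytest

from microhet.capacity import (StateDecomposition, StateMatrix, build_target,
                               capacity_score, harvest_states, legendre_poly,
                               memory_capacity, optimal_resolution,
                               total_capacity)
from microhet.engine import StimulusProgram, choose_input_targets, simulate


def delay_line_states(u, k_max):
    return np.stack([np.concatenate([np.zeros(k), u[:len(u) - k]])
                     for k in range(k_max + 1)])


def linear_reservoir(u, n_units=8, seed=0):
    taus = np.linspace(0.5, 0.95, n_units)
    X = np.empty((n_units, len(u)))
    x = np.zeros(n_units)
    for n in range(len(u)):
        x = taus * x + (1 - taus) * (2 * u[n] - 1)
        X[:, n] = x
    return X


class TestLegendre:
    def test_degree_zero_constant(self):
        s = np.linspace(-1, 1, 11)
        assert np.allclose(legendre_poly(0, s, normalized=False), 1.0)

    def test_degree_one_and_value_at_one(self):
        assert legendre_poly(1, 0.3, normalized=True) == pytest.approx(
            np.sqrt(3) * 0.3)
        for d in range(6):
            assert legendre_poly(d, 1.0, normalized=False) == pytest.approx(1.0)

    def test_degree_two_closed_form(self):
        assert legendre_poly(2, 0.5, normalized=False) == pytest.approx(-0.125)

    def test_negative_degree_rejected(self):
        with pytest.raises(ValueError):
            legendre_poly(-1, 0.0)

    def test_orthonormality_monte_carlo(self):
        # Gram matrix of random product bases on iid uniform input
        rng = np.random.default_rng(0)
        T = 100_000
        u = rng.uniform(0, 1, T)
        bases = []
        while len(bases) < 20:
            ks = rng.choice(10, size=rng.integers(1, 4), replace=False)
            b = {int(k): int(rng.integers(1, 4)) for k in ks}
            if b not in bases:
                bases.append(b)
        k_max = 9
        Z = []
        for b in bases:
            z, k0 = build_target(u, b)
            Z.append(z[k_max - k0:] if k0 < k_max else z)
        Z = np.stack(Z)
        G = (Z @ Z.T) / Z.shape[1]
        tol = 3.0 / np.sqrt(T)
        assert np.all(np.abs(G - np.eye(len(bases))) < tol + 0.01)


class TestBuildTarget:
    def test_linear_term_is_scaled_input(self):
        u = np.linspace(0, 1, 50)
        z, off = build_target(u, {0: 1})
        assert off == 0
        assert np.allclose(z, np.sqrt(3) * (2 * u - 1))

    def test_delayed_term_is_delayed_input(self):
        rng = np.random.default_rng(1)
        u = rng.uniform(0, 1, 100)
        z, off = build_target(u, {3: 1})
        assert off == 3
        assert np.allclose(z, np.sqrt(3) * (2 * u[:-3] - 1))

    def test_empty_and_invalid_bases(self):
        u = np.zeros(10)
        with pytest.raises(ValueError):
            build_target(u, {})
        with pytest.raises(ValueError):
            build_target(u, {0: 0})
        with pytest.raises(ValueError):
            build_target(u, {20: 1})


class TestCapacityScore:
    def test_perfect_reconstruction_of_own_row(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2000))
        assert capacity_score(X, X[7]) == pytest.approx(1.0, abs=1e-9)

    def test_noise_bias_matches_n_over_t(self):
        rng = np.random.default_rng(3)
        n_state, T = 50, 5000
        X = rng.normal(size=(n_state, T))
        cs = [capacity_score(X, rng.normal(size=T)) for _ in range(40)]
        assert np.mean(cs) == pytest.approx(n_state / T, rel=0.2)

    def test_zero_target_rejected(self):
        with pytest.raises(ValueError):
            capacity_score(np.random.default_rng(0).normal(size=(3, 100)),
                           np.zeros(100))

    def test_matches_brute_force_regression_oracle(self):
        # independent oracle: explicit least squares with intercept
        rng = np.random.default_rng(4)
        T = 4000
        u = rng.uniform(0, 1, T)
        X = np.tanh(linear_reservoir(u, 5, seed=0) + 0.1)
        for basis in ({0: 1}, {2: 1}, {1: 2}, {0: 1, 3: 1}):
            z, k0 = build_target(u, basis)
            Xa = X[:, k0:] if k0 else X
            c = capacity_score(Xa, z)
            A = np.vstack([Xa, np.ones(Xa.shape[1])]).T
            beta, *_ = np.linalg.lstsq(A, z, rcond=None)
            resid = z - A @ beta
            zc = z - z.mean()
            brute = 1.0 - (resid @ resid) / (zc @ zc)
            assert c == pytest.approx(brute, abs=1e-8)


class TestMemoryCapacity:
    def test_delay_line_curve(self):
        rng = np.random.default_rng(5)
        u = rng.uniform(0, 1, 5000)
        X = delay_line_states(u, 10)
        curve, C_M = memory_capacity(X, u, k_max=40)
        assert np.allclose(curve[:11], 1.0, atol=1e-6)
        assert np.all(curve[11:] == 0.0)  # sub-threshold tail zeroed
        assert C_M == pytest.approx(11.0, abs=1e-4)

    def test_curve_bounded_by_one(self):
        rng = np.random.default_rng(6)
        u = rng.uniform(0, 1, 3000)
        X = linear_reservoir(u)
        curve, _ = memory_capacity(X, u, k_max=30)
        assert np.all(curve <= 1.0 + 1e-12)

    def test_k_max_precondition(self):
        with pytest.raises(ValueError):
            memory_capacity(np.zeros((3, 100)), np.zeros(100), k_max=100)


class TestTotalCapacity:
    def test_linear_system_has_no_quadratic_capacity(self):
        rng = np.random.default_rng(7)
        u = rng.uniform(0, 1, 6000)
        X = linear_reservoir(u)
        res = total_capacity(X, u, d_max=2, k_max=20, budget=3000)
        assert res.per_degree[1] > 3.0
        # degree-2 capacity is pure finite-sample leakage, far below linear
        assert res.per_degree[2] < 0.05 * res.per_degree[1]

    def test_bounded_by_state_count_and_sums(self):
        rng = np.random.default_rng(8)
        u = rng.uniform(0, 1, 4000)
        X = np.tanh(linear_reservoir(u, 6) * 1.5)
        res = total_capacity(X, u, d_max=3, k_max=15, budget=2000)
        assert res.C_T <= X.shape[0] + 1e-9
        assert res.C_T == pytest.approx(sum(res.per_degree.values()))
        assert all(v >= 0 for v in res.per_degree.values())
        assert all(0.0 <= e["capacity"] <= 1.0 for e in res.entries)

    def test_budget_truncation_recorded(self):
        rng = np.random.default_rng(9)
        u = rng.uniform(0, 1, 2000)
        X = linear_reservoir(u)
        res = total_capacity(X, u, d_max=4, k_max=50, budget=50)
        assert res.meta["truncated"]


class TestHarvestAndResolution:
    def test_state_matrix_shape_contract(self, fixture_circuit):
        sm = harvest_states(fixture_circuit, T=50, dt_input=5.0, rho_u=300.0,
                            nu_in=5.0, washout=10, seed=0)
        assert sm.X.shape == (200, 50)
        assert len(sm.u) == 50
        assert np.all(np.isfinite(sm.X))

    def test_input_dependence(self, fixture_circuit):
        a = harvest_states(fixture_circuit, T=30, dt_input=5.0, rho_u=300.0,
                           nu_in=5.0, washout=5, seed=1)
        b = harvest_states(fixture_circuit, T=30, dt_input=5.0, rho_u=300.0,
                           nu_in=5.0, washout=5, seed=2)
        assert not np.allclose(a.X, b.X)

    def test_optimal_resolution_on_perfect_readout(self):
        # a system whose state IS the input reaches the criterion at the
        # grid minimum
        class _FakeCircuit:
            pass

        rng = np.random.default_rng(0)

        def fake_harvest(dtu, seed):
            u = rng.uniform(0, 1, 400)
            return StateMatrix(X=u[None, :] + 0.0, u=u, dt_input=dtu,
                               washout=0)

        import microhet.capacity as cap
        orig = cap.harvest_states
        cap.harvest_states = (lambda circuit, T, dt_input, rho_u, nu_in,
                              washout, seed, resolution, target_idx=None:
                              fake_harvest(dt_input, seed))
        try:
            dt_star, curve = cap.optimal_resolution(_FakeCircuit(),
                                                    [1.0, 2.0, 4.0], T=400,
                                                    rho_u=1.0, nu_in=0.0)
        finally:
            cap.harvest_states = orig
        assert dt_star == 1.0
        assert np.all(curve["capacity"] >= 0.99)
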