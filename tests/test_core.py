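"""Core factorization: constraint/objective oracles, block updates, fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from btnd import (
    ActivationProfiles,
    BTNDConfig,
    EdgeIndex,
    FCSeries,
    FusedLassoParams,
    MultiSeizureDataset,
    SubgraphSet,
    adapt_fused_params,
    compute_zeta,
    constraint_value,
    fit,
    fit_single,
    objective,
    update_activations,
    update_subgraphs,
)
from btnd._tv import tv_prox


def constraint_oracle(v, gamma, eta):
    """Term-by-term independent evaluation of the activation budget."""
    total = 0.0
    for t in range(len(v)):
        total += gamma * abs(v[t]) + v[t] * v[t]
    for t in range(len(v) - 1):
        total += eta * abs(v[t + 1] - v[t])
    return total


def objective_oracle(F, V_list, X_list, zeta, lam):
    """Naive double-loop evaluation of the penalized data fit."""
    S = len(X_list)
    total = 0.0
    for s in range(S):
        recon = np.zeros_like(X_list[s])
        for l in range(F.shape[0]):
            for t in range(X_list[s].shape[1]):
                recon[l, t] = sum(
                    F[l, k] * V_list[s][t, k] for k in range(F.shape[1])
                )
        total += zeta[s] * np.sum((X_list[s] - recon) ** 2)
    for l in range(F.shape[0]):
        for k in range(F.shape[1]):
            total += lam / S * abs(F[l, k])
    return total


def _dataset(X_list, n_channels):
    ei = EdgeIndex.from_n_channels(n_channels)
    return MultiSeizureDataset(
        seizures=[
            FCSeries(values=x, edge_index=ei, window_length_s=4.0,
                     window_step_s=1.0, seizure_id=str(s))
            for s, x in enumerate(X_list)
        ]
    )


class TestConstraintValue:
    def test_zero_vector(self):
        assert constraint_value(np.zeros(5), FusedLassoParams(0.3, 0.4)) == 0.0

    def test_hand_computed_example(self):
        v = np.array([0.0, 0.5, 0.0])
        params = FusedLassoParams(gamma=0.1, eta=0.2)
        # 0.1*0.5 + 0.2*(0.5 + 0.5) + 0.25
        assert constraint_value(v, params) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_independent_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 2, size=6)
        gamma, eta = rng.uniform(0, 1, size=2)
        got = constraint_value(v, FusedLassoParams(gamma, eta))
        assert got == pytest.approx(constraint_oracle(v, gamma, eta), rel=1e-12)


class TestObjective:
    def test_zero_factors_leave_data_energy(self, planted_small):
        X, _ = planted_small
        F = SubgraphSet(np.zeros((X.L, 2)), X.edge_index)
        V = [ActivationProfiles(np.zeros((fc.T, 2))) for fc in X.seizures]
        cfg = BTNDConfig(K=2, lam=0.0, zeta=[1.0] * X.S,
                         per_seizure_fused=[FusedLassoParams()] * X.S)
        expected = sum(np.sum(fc.values**2) for fc in X.seizures)
        assert objective(F, V, X, cfg) == pytest.approx(expected)

    def test_true_factors_reach_zero_when_noiseless(self, planted_small):
        X, truth = planted_small
        F = SubgraphSet(truth.true_subgraphs, X.edge_index)
        V = [ActivationProfiles(v) for v in truth.true_activations]
        cfg = BTNDConfig(K=truth.K, lam=0.0)
        assert objective(F, V, X, cfg) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        L, K, Ts = 6, 2, (4, 5)
        F = rng.uniform(size=(L, K))
        V_list = [rng.uniform(size=(T, K)) for T in Ts]
        X_list = [rng.uniform(size=(L, T)) for T in Ts]
        zeta = rng.uniform(0.5, 2.0, size=2).tolist()
        lam = rng.uniform(0, 1)
        X = _dataset(X_list, 4)
        cfg = BTNDConfig(K=K, lam=lam, zeta=zeta,
                         per_seizure_fused=[FusedLassoParams()] * 2)
        got = objective(
            SubgraphSet(F, X.edge_index),
            [ActivationProfiles(v) for v in V_list],
            X, cfg,
        )
        want = objective_oracle(F, V_list, X_list, zeta, lam)
        assert got == pytest.approx(want, rel=1e-10)

    def test_shape_mismatch_rejected(self, planted_small):
        X, _ = planted_small
        F = SubgraphSet(np.zeros((X.L, 2)), X.edge_index)
        V = [ActivationProfiles(np.zeros((fc.T + 1, 2))) for fc in X.seizures]
        with pytest.raises(ValueError, match="mismatch"):
            objective(F, V, X, BTNDConfig(K=2))


class TestTVProx:
    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10**6), lam=st.floats(0.01, 2.0))
    def test_kkt_certificate(self, seed, lam):
        # x solves the TV-denoising problem iff the running residual sum
        # u_t = cumsum(x - y) stays inside [-lam, lam] and ends at 0
        rng = np.random.default_rng(seed)
        y = rng.normal(size=rng.integers(2, 40))
        x = tv_prox(y, lam)
        u = np.cumsum(x - y)
        assert abs(u[-1]) < 1e-8
        assert np.all(np.abs(u[:-1]) <= lam + 1e-8)
        jumps = np.diff(x)
        active = np.abs(jumps) > 1e-10
        # where x jumps, the dual is at its bound with the jump's sign
        assert np.allclose(u[:-1][active], lam * np.sign(jumps[active]))


class TestUpdateSubgraphs:
    def test_true_factors_are_a_fixed_point(self, planted_small):
        X, truth = planted_small
        F = SubgraphSet(truth.true_subgraphs, X.edge_index)
        V = [ActivationProfiles(v) for v in truth.true_activations]
        cfg = BTNDConfig(K=truth.K, lam=0.0)
        out = update_subgraphs(F, V, X, cfg)
        assert np.allclose(out.weights, truth.true_subgraphs, atol=1e-10)

    def test_large_lambda_empties_subgraphs(self, planted_small):
        X, truth = planted_small
        rng = np.random.default_rng(0)
        V = [ActivationProfiles(rng.uniform(size=(fc.T, 2)))
             for fc in X.seizures]
        zeta = compute_zeta(X)
        # instance-specific gradient bound
        B = sum(z * fc.values @ v.values for z, fc, v in
                zip(zeta, X.seizures, V))
        lam = 2 * X.S * float(B.max()) * 1.0001
        cfg = BTNDConfig(K=2, lam=lam)
        F = SubgraphSet(rng.uniform(size=(X.L, 2)), X.edge_index)
        out = update_subgraphs(F, V, X, cfg)
        assert np.all(out.weights == 0)

    def test_never_increases_objective(self, planted_small, small_config):
        X, _ = planted_small
        rng = np.random.default_rng(3)
        cfg = small_config.resolved(X)
        F = SubgraphSet(rng.uniform(size=(X.L, 2)), X.edge_index)
        V = [ActivationProfiles(rng.uniform(size=(fc.T, 2)) * 0.1)
             for fc in X.seizures]
        before = objective(F, V, X, cfg)
        after = objective(update_subgraphs(F, V, X, cfg), V, X, cfg)
        assert after <= before + 1e-10

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_per_row_convex_oracle(self, seed):
        # K=1, S=1: each row solves a scalar non-negative lasso
        rng = np.random.default_rng(seed)
        L, T = 6, 5
        Xm = rng.uniform(size=(L, T))
        v = rng.uniform(size=(T, 1))
        v /= max(np.linalg.norm(v), 1.0)
        X = _dataset([Xm], 4)
        zeta = [1.7]
        lam = rng.uniform(0, 2)
        cfg = BTNDConfig(K=1, lam=lam, zeta=zeta,
                         per_seizure_fused=[FusedLassoParams()])
        F0 = SubgraphSet(rng.uniform(size=(L, 1)), X.edge_index)
        got = update_subgraphs(F0, [ActivationProfiles(v)], X, cfg).weights
        A = zeta[0] * float(v[:, 0] @ v[:, 0])
        for l in range(L):
            b = zeta[0] * float(Xm[l] @ v[:, 0])

            def row_obj(f, b=b):
                return A * f * f - 2 * b * f + lam * abs(f)

            res = minimize_scalar(row_obj, bounds=(0, 100), method="bounded",
                                  options={"xatol": 1e-10})
            assert got[l, 0] == pytest.approx(max(res.x, 0.0), abs=1e-4)


def activation_grid_oracle(b, a, params, step=0.005):
    """Exhaustive search of the T=3 constrained column subproblem."""
    grid = np.arange(0.0, 1.0 + step, step)
    best, best_val = np.zeros(3), np.inf
    for v1 in grid:
        v2, v3 = np.meshgrid(grid, grid, indexing="ij")
        c = (params.gamma * (v1 + v2 + v3)
             + params.eta * (np.abs(v2 - v1) + np.abs(v3 - v2))
             + v1 * v1 + v2 * v2 + v3 * v3)
        obj = a * (v1 * v1 + v2 * v2 + v3 * v3) - 2 * (
            b[0] * v1 + b[1] * v2 + b[2] * v3
        )
        obj = np.where(c <= 1.0, obj, np.inf)
        idx = np.unravel_index(np.argmin(obj), obj.shape)
        if obj[idx] < best_val:
            best_val = obj[idx]
            best = np.array([v1, v2[idx], v3[idx]])
    return best


class TestUpdateActivations:
    def test_zero_data_gives_zero_activations(self):
        ei = EdgeIndex.from_n_channels(4)
        X_s = FCSeries(values=np.zeros((6, 5)), edge_index=ei,
                       window_length_s=4.0, window_step_s=1.0)
        F = SubgraphSet(np.random.default_rng(0).uniform(size=(6, 2)), ei)
        V0 = ActivationProfiles(np.random.default_rng(1).uniform(size=(5, 2)) * 0.3)
        out = update_activations(V0, F, X_s, FusedLassoParams(0.1, 0.2))
        assert np.all(out.values == 0)

    def test_rank_one_noiseless_recovers_unit_norm_direction(self):
        rng = np.random.default_rng(2)
        ei = EdgeIndex.from_n_channels(4)
        f = rng.uniform(0.5, 1.0, size=(6, 1))
        v = rng.uniform(0.2, 1.0, size=(8, 1))
        X_s = FCSeries(values=np.clip(f @ v.T, 0, 1), edge_index=ei,
                       window_length_s=4.0, window_step_s=1.0)
        out = update_activations(
            ActivationProfiles(np.full((8, 1), 0.1)),
            SubgraphSet(f, ei), X_s, FusedLassoParams(0.0, 0.0),
        )
        got = out.values[:, 0]
        # gamma=eta=0 reduces the budget to the unit ball ||v||^2 <= 1
        assert np.linalg.norm(got) <= 1.0 + 1e-6
        cos = got @ v[:, 0] / (np.linalg.norm(got) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_zero_subgraph_column_is_flagged(self):
        ei = EdgeIndex.from_n_channels(4)
        F = SubgraphSet(np.hstack([np.zeros((6, 1)),
                                   np.ones((6, 1))]), ei)
        X_s = FCSeries(values=np.full((6, 5), 0.5), edge_index=ei,
                       window_length_s=4.0, window_step_s=1.0)
        out = update_activations(
            ActivationProfiles(np.full((5, 2), 0.2)), F, X_s,
            FusedLassoParams(0.1, 0.2),
        )
        assert out.zeroed_components == [0]
        assert np.all(out.values[:, 0] == 0)

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(seed=st.integers(0, 10**6))
    def test_matches_grid_oracle_on_t3_toys(self, seed):
        rng = np.random.default_rng(seed)
        ei = EdgeIndex.from_n_channels(4)
        params = FusedLassoParams(gamma=0.3, eta=0.2)
        f = rng.uniform(0.3, 1.0, size=(6, 1))
        X_s = FCSeries(values=rng.uniform(size=(6, 3)), edge_index=ei,
                       window_length_s=4.0, window_step_s=1.0)
        out = update_activations(
            ActivationProfiles(np.zeros((3, 1))),
            SubgraphSet(f, ei), X_s, params,
        )
        a = float(f[:, 0] @ f[:, 0])
        b = X_s.values.T @ f[:, 0]
        want = activation_grid_oracle(b, a, params)
        assert np.all(np.abs(out.values[:, 0] - want) <= 0.02)


class TestZetaAndDurationAdaptation:
    def test_zeta_inverse_energy(self, planted_small):
        X, _ = planted_small
        zeta = compute_zeta(X)
        for z, fc in zip(zeta, X.seizures):
            assert z == pytest.approx(1.0 / np.sum(fc.values**2))

    def test_single_seizure_known_energy(self):
        ei = EdgeIndex.from_n_channels(3)
        fc = FCSeries(values=np.full((3, 4), np.sqrt(1 / 3.0)), edge_index=ei,
                      window_length_s=4.0, window_step_s=1.0)
        # ||X||_F^2 = 3*4*(1/3) = 4 -> zeta = 0.25
        X = MultiSeizureDataset(seizures=[fc])
        assert compute_zeta(X) == [pytest.approx(0.25)]

    def test_equal_energy_gives_equal_zeta(self):
        ei = EdgeIndex.from_n_channels(3)
        vals = np.random.default_rng(0).uniform(size=(3, 5))
        fcs = [FCSeries(values=vals.copy(), edge_index=ei,
                        window_length_s=4.0, window_step_s=1.0,
                        seizure_id=str(s)) for s in range(2)]
        zeta = compute_zeta(MultiSeizureDataset(seizures=fcs))
        assert zeta[0] == pytest.approx(zeta[1])

    def test_tiling_halves_zeta(self):
        ei = EdgeIndex.from_n_channels(3)
        vals = np.random.default_rng(1).uniform(size=(3, 5))
        single = FCSeries(values=vals, edge_index=ei,
                          window_length_s=4.0, window_step_s=1.0, seizure_id="a")
        tiled = FCSeries(values=np.tile(vals, (1, 2)), edge_index=ei,
                         window_length_s=4.0, window_step_s=1.0, seizure_id="b")
        zeta = compute_zeta(MultiSeizureDataset(seizures=[single, tiled]))
        assert zeta[1] == pytest.approx(zeta[0] / 2)

    def test_zero_energy_rejected(self):
        ei = EdgeIndex.from_n_channels(3)
        fc = FCSeries(values=np.zeros((3, 4)), edge_index=ei,
                      window_length_s=4.0, window_step_s=1.0)
        with pytest.raises(ValueError, match="zero energy"):
            compute_zeta(MultiSeizureDataset(seizures=[fc]))

    def test_equal_durations_unchanged(self):
        base = FusedLassoParams(gamma=0.3, eta=0.2)
        out = adapt_fused_params(base, [50, 50, 50])
        assert all(p == base for p in out)

    def test_median_scaling_rule(self):
        base = FusedLassoParams(gamma=0.2, eta=0.2)
        out = adapt_fused_params(base, [50, 200])
        t_ref = 125.0
        assert out[0].gamma == pytest.approx(0.2 * np.sqrt(t_ref / 50))
        assert out[1].gamma == pytest.approx(0.2 * np.sqrt(t_ref / 200))
        assert out[0].eta == pytest.approx(0.2 * np.sqrt(t_ref / 50))


class TestFit:
    def test_noiseless_planted_reaches_zero_objective(self, planted_small):
        X, truth = planted_small
        cfg = BTNDConfig(K=truth.K, lam=0.0,
                         base_fused=FusedLassoParams(0.0, 0.0),
                         n_restarts=5, seed=0)
        dec = fit(X, cfg)
        scale = sum(z * np.sum(fc.values**2)
                    for z, fc in zip(dec.config.zeta, X.seizures))
        assert dec.final_objective <= 1e-6 * scale

    def test_max_iter_one_gives_trace_length_two(self, planted_small,
                                                 small_config):
        X, _ = planted_small
        from dataclasses import replace
        dec = fit_single(X, replace(small_config, max_iter=1), restart_seed=0)
        assert len(dec.objective_trace) == 2

    def test_same_seed_is_bit_identical(self, planted_small, small_config):
        X, _ = planted_small
        a = fit(X, small_config)
        b = fit(X, small_config)
        assert np.array_equal(a.subgraphs.weights, b.subgraphs.weights)
        assert all(
            np.array_equal(x.values, y.values)
            for x, y in zip(a.activations, b.activations)
        )
        assert a.objective_trace == b.objective_trace

    def test_single_restart_equals_fit_single(self, planted_small,
                                              small_config):
        X, _ = planted_small
        from dataclasses import replace
        cfg = replace(small_config, n_restarts=1)
        whole = fit(X, cfg)
        seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0]) % 2**31
        alone = fit_single(X, cfg, seed)
        assert np.array_equal(whole.subgraphs.weights, alone.subgraphs.weights)

    def test_default_restart_count_is_twenty(self):
        assert BTNDConfig(K=3).n_restarts == 20

    def test_selected_restart_attains_minimum(self, planted_small,
                                              small_config):
        X, _ = planted_small
        dec = fit(X, small_config)
        assert dec.selected_restart == int(np.argmin(dec.restart_objectives))
        assert dec.final_objective == min(dec.restart_objectives)

    def test_monotone_trace_and_feasible_columns(self, planted_small,
                                                 small_config):
        X, _ = planted_small
        dec = fit(X, small_config)
        tr = np.asarray(dec.objective_trace)
        assert np.all(tr[1:] <= tr[:-1] * (1 + 1e-8))
        for act, params in zip(dec.activations,
                               dec.config.per_seizure_fused):
            for k in range(act.K):
                assert constraint_value(act.values[:, k], params) <= 1 + 1e-6

    def test_edge_permutation_equivariance(self, planted_small, small_config):
        X, _ = planted_small
        rng = np.random.default_rng(11)
        perm = rng.permutation(X.L)
        Xp = _dataset([fc.values[perm] for fc in X.seizures],
                      X.edge_index.n_channels)
        a = fit(X, small_config)
        b = fit(Xp, small_config)
        assert np.allclose(b.subgraphs.weights, a.subgraphs.weights[perm],
                           atol=1e-6)

    def test_sparsity_monotone_in_lambda(self, planted_small):
        X, _ = planted_small
        from dataclasses import replace
        counts = []
        for lam in [0.0, 0.002, 0.01, 0.05, 0.2]:
            cfg = BTNDConfig(K=2, lam=lam,
                             base_fused=FusedLassoParams(gamma=lam, eta=0.2),
                             n_restarts=2, seed=0)
            dec = fit(X, cfg)
            counts.append(int(np.count_nonzero(dec.subgraphs.weights)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_k_above_edge_count_rejected(self, planted_small, small_config):
        X, _ = planted_small
        from dataclasses import replace
        with pytest.raises(ValueError, match="exceeds"):
            fit_single(X, replace(small_config, K=X.L + 1), 0)
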