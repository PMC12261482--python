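import numpy as np
import pytest
from scipy.optimize import minimize

from causalscca import (HyperParams, LDBlockPartition, PenaltyWeights, fit,
                        full_objective, init_state, project_Q, solve_U_block,
                        update_Q, update_U, update_V, update_smoothed_weights)
from causalscca.solver import _unpack


def _zero_penalty_hp(**kw):
    pen = PenaltyWeights(lambda_u1=0, lambda_u2=0, lambda_u3=0, lambda_v=0,
                         lambda_Q=0)
    return HyperParams(penalty=pen, **kw)


def simplex_projection_oracle(v, total):
    """Quadratic program solved by a generic constrained optimizer."""
    n = len(v)
    res = minimize(lambda x: 0.5 * np.sum((x - v) ** 2), np.full(n, total / n),
                   jac=lambda x: x - v,
                   constraints=[{"type": "eq", "fun": lambda x: x.sum() - total}],
                   bounds=[(0, None)] * n, method="SLSQP",
                   options={"ftol": 1e-14, "maxiter": 500})
    return res.x


class TestProjectQ:
    @pytest.mark.parametrize("raw, total, expected", [
        ([2, 0, 1], 3, [2, 0, 1]),            # already feasible
        ([4, 4, 4], 3, [1, 1, 1]),            # symmetric shrink
        ([-1, 2, 2], 3, [0, 1.5, 1.5]),       # negative entry clipped
    ])
    def test_hand_examples(self, raw, total, expected):
        np.testing.assert_allclose(project_Q(np.array(raw, float), total),
                                   expected)

    def test_matches_quadratic_program_oracle(self, rng):
        for _ in range(10):
            v = rng.normal(scale=3, size=7)
            got = project_Q(v, 7.0)
            want = simplex_projection_oracle(v, 7.0)
            np.testing.assert_allclose(got, want, atol=1e-6)
            assert got.sum() == pytest.approx(7.0)
            assert np.all(got >= 0)

    def test_allow_negative_mean_shift(self):
        out = project_Q(np.array([-3.0, 1.0]), 2.0, allow_negative=True)
        np.testing.assert_allclose(out, [-1.0, 3.0])
        assert out.sum() == pytest.approx(2.0)


class TestSolveUBlock:
    def test_orthonormal_columns_reduce_to_projection(self, rng):
        Xk = np.linalg.qr(rng.normal(size=(6, 3)))[0]
        yv = rng.normal(size=6)
        sm = (np.zeros(3), np.zeros(3), np.zeros(3))
        hp = _zero_penalty_hp(gamma_ridge=1.0)
        u = solve_U_block(Xk, np.ones(6), Xk.T @ yv, sm, hp)
        np.testing.assert_allclose(u, Xk.T @ yv, atol=1e-10)

    def test_diagonal_system_hand_solve(self):
        Xk = np.array([[1.0, 0.0], [0.0, 2.0]])
        yv = np.ones(2)
        hp = _zero_penalty_hp(gamma_ridge=1.0)
        u = solve_U_block(Xk, np.ones(2), Xk.T @ yv,
                          (np.zeros(2), np.zeros(2), np.zeros(2)), hp)
        np.testing.assert_allclose(u, [1.0, 0.5])

    def test_blockwise_equals_dense_when_cross_block_gram_zero(self, rng):
        # construct X whose two column groups are exactly orthogonal
        A = rng.normal(size=(10, 5))
        B = rng.normal(size=(10, 5))
        B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]
        X = np.hstack([A, B])
        Q = np.ones(10)
        yv = rng.normal(size=10)
        rhs = X.T @ yv
        U0 = rng.normal(size=(10, 1))
        sm = update_smoothed_weights(U0, 1e-8)
        hp = HyperParams(penalty=PenaltyWeights(lambda_u1=0.1, lambda_u2=0.1,
                                                lambda_u3=0.1))
        dense = solve_U_block(X, Q, rhs, (sm.D1, sm.D2, sm.D3[:, 0]), hp)
        u1 = solve_U_block(A, Q, rhs[:5], (sm.D1[:5], sm.D2[:5], sm.D3[:5, 0]), hp)
        u2 = solve_U_block(B, Q, rhs[5:], (sm.D1[5:], sm.D2[5:], sm.D3[5:, 0]), hp)
        np.testing.assert_allclose(np.concatenate([u1, u2]), dense, atol=1e-8)


class TestUpdates:
    def test_init_state_contracts(self, tiny_data, default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        st1 = init_state(data, tiny_data["partition"], default_hp, seed=3)
        st2 = init_state(data, tiny_data["partition"], default_hp, seed=3)
        X = tiny_data["geno"].values
        assert st1.Q.sum() == pytest.approx(len(st1.Q))
        for f in range(st1.U.shape[1]):
            assert np.linalg.norm(X @ st1.U[:, f]) == pytest.approx(1.0)
        np.testing.assert_array_equal(st1.U, st2.U)   # bit-identical per seed

    def test_update_u_single_block_matches_unpartitioned(self, tiny_data,
                                                         default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        p = tiny_data["geno"].p
        one_block = LDBlockPartition([np.arange(p)], 0.2)
        st = init_state(data, one_block, default_hp, seed=0)
        out = update_U(st, data, one_block, default_hp)
        assert np.all(np.isfinite(out.U))

    def test_update_u_never_increases_objective(self, tiny_data, default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        part = tiny_data["partition"]
        X, Ys, z = _unpack(data)
        st = init_state(data, part, default_hp, seed=1)
        for _ in range(4):
            before, _ = full_objective(st.U, st.V, st.Q, X, Ys, z, part,
                                       default_hp)
            st = update_U(st, data, part, default_hp)
            after, _ = full_objective(st.U, st.V, st.Q, X, Ys, z, part,
                                      default_hp)
            assert after <= before + 1e-10

    def test_repeated_update_u_reaches_fixed_point(self, tiny_data, default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        part = tiny_data["partition"]
        st = init_state(data, part, default_hp, seed=0)
        prev = st.U.copy()
        deltas = []
        for _ in range(25):
            st = update_U(st, data, part, default_hp)
            deltas.append(np.max(np.abs(st.U - prev)))
            prev = st.U.copy()
        assert deltas[-1] < 1e-6

    def test_update_q_keeps_feasibility_and_descends(self, tiny_data, default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        part = tiny_data["partition"]
        X, Ys, z = _unpack(data)
        st = init_state(data, part, default_hp, seed=0)
        st = update_U(st, data, part, default_hp)
        before, _ = full_objective(st.U, st.V, st.Q, X, Ys, z, part, default_hp)
        out = update_Q(st, data, part, default_hp)
        after, _ = full_objective(out.U, out.V, out.Q, X, Ys, z, part, default_hp)
        assert after <= before + 1e-10
        assert out.Q.sum() == pytest.approx(len(out.Q), abs=1e-8)
        assert np.all(out.Q >= 0)

    def test_large_ridge_pulls_q_to_uniform(self, tiny_data):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        part = tiny_data["partition"]
        hp = HyperParams(eta=0.0, penalty=PenaltyWeights(lambda_Q=1e6))
        st = init_state(data, part, hp, seed=0)
        st.Q = project_Q(st.Q + np.linspace(-0.5, 0.5, len(st.Q)))
        for _ in range(80):
            st = update_Q(st, data, part, hp)
        np.testing.assert_allclose(st.Q, 1.0, atol=1e-2)

    def test_update_v_proportional_to_back_projection(self, tiny_data):
        """With no sparsity and no diagnosis loss, a first gradient step from
        a small v moves toward Y' diag(Q) X u."""
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        part = tiny_data["partition"]
        hp = _zero_penalty_hp(psi_kind="off", eta=0.0)
        st = init_state(data, part, hp, seed=0)
        X, Ys, _ = _unpack(data)
        direction = Ys[0].T @ (st.Q * (X @ st.U[:, 0]))
        tiny = 1e-9 * direction / np.linalg.norm(direction)
        st.V[0] = tiny / np.linalg.norm(Ys[0] @ tiny)
        out = update_V(st, data, hp)
        cos = (out.V[0] @ direction) / (np.linalg.norm(out.V[0])
                                        * np.linalg.norm(direction))
        assert cos > 0.99

    def test_heavy_l1_zeroes_weak_phenotype_coordinates(self, tiny_data):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        part = tiny_data["partition"]
        hp = HyperParams(eta=0.0, psi_kind="off",
                         penalty=PenaltyWeights(lambda_v=5.0))
        st = init_state(data, part, hp, seed=0)
        out = update_V(st, data, hp)
        assert min(np.mean(v == 0) for v in out.V) > 0.3


class TestFit:
    def test_trace_monotone_and_constraints_hold(self, tiny_data, default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        res = fit(data, tiny_data["partition"], default_hp, seed=0)
        assert np.all(np.diff(res.objective_trace) <= 1e-10)
        X = tiny_data["geno"].values
        for f in range(res.U.shape[1]):
            assert np.linalg.norm(X @ res.U[:, f]) == pytest.approx(1.0, abs=1e-6)
            assert np.linalg.norm(
                tiny_data["pheno"].views[f] @ res.V[f]) == pytest.approx(1.0, abs=1e-6)

    def test_same_seed_bit_identical(self, tiny_data, default_hp):
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        r1 = fit(data, tiny_data["partition"], default_hp, seed=5)
        r2 = fit(data, tiny_data["partition"], default_hp, seed=5)
        np.testing.assert_array_equal(r1.U, r2.U)
        np.testing.assert_array_equal(r1.Q, r2.Q)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_module_switch_off_reduces_to_plain_sparse_cca(self, tiny_data):
        """eta = 0 with a huge Q ridge and no diagnosis loss keeps Q uniform."""
        data = (tiny_data["geno"], tiny_data["pheno"], tiny_data["labels"])
        hp = HyperParams(eta=0.0, psi_kind="off",
                         penalty=PenaltyWeights(lambda_Q=1e6))
        res = fit(data, tiny_data["partition"], hp, seed=0)
        np.testing.assert_allclose(res.Q, 1.0, atol=1e-3)

    def test_blockwise_equals_dense_on_block_orthogonal_data(self, rng):
        """When cross-block sample correlations are exactly zero the K-block
        fit and the single-block fit coincide."""
        n, ppb = 40, 3
        # orthogonalize two column groups against each other
        A = rng.normal(size=(n, ppb))
        B = rng.normal(size=(n, ppb))
        B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]
        A -= A.mean(0)
        B -= B.mean(0)
        B -= A @ np.linalg.lstsq(A, B, rcond=None)[0]
        X = np.hstack([A, B])
        Y = [rng.normal(size=(n, 4))]
        z = (rng.uniform(size=n) > 0.5).astype(float)
        hp = HyperParams(eta=0.0, penalty=PenaltyWeights(lambda_Q=1e3))
        blocks = LDBlockPartition([np.arange(3), np.arange(3, 6)], 0.2)
        dense = LDBlockPartition([np.arange(6)], 0.2)
        r_blocks = fit((X, Y, z), blocks, hp, seed=0)
        r_dense = fit((X, Y, z), dense, hp, seed=0)
        np.testing.assert_allclose(r_blocks.U, r_dense.U, atol=1e-8)
        np.testing.assert_allclose(r_blocks.V[0], r_dense.V[0], atol=1e-8)
        np.testing.assert_allclose(r_blocks.Q, r_dense.Q, atol=1e-8)
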