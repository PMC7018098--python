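import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

from ibsurprise.ib import (
    IBSolution,
    build_joint,
    effective_capacity_ib,
    effective_capacity_noc,
    ib_info_curve,
    ib_surprise,
    ib_update_cycle,
    mutual_information,
    solve_ib,
    surprise_table,
)
from ibsurprise.sequence import InvalidParameterError, generate_sequence, oddball_count

from conftest import make_sequence


def beta_integral_oracle(N, n):
    """Numeric Beta integral for p(y=1, x=n) under a uniform prior on the rate."""
    val, _ = quad(lambda th: comb(N, n) * th ** (n + 1) * (1 - th) ** (N - n), 0, 1)
    return val


class TestJointDistribution:
    @pytest.mark.parametrize("N", [1, 4, 11, 23])
    def test_closed_form_matches_numeric_integral(self, N):
        j = build_joint(N)
        for n in range(N + 1):
            assert j.p_xy[n, 1] == pytest.approx(beta_integral_oracle(N, n), abs=1e-12)
        assert j.p_xy.sum() == pytest.approx(1.0, abs=1e-12)

    def test_worked_entry(self):
        assert build_joint(4).p_xy[2, 1] == pytest.approx(3 / 30)

    @pytest.mark.parametrize("N", [1, 4, 11])
    def test_uniform_count_marginal_and_symmetric_tone_marginal(self, N):
        j = build_joint(N)
        assert np.allclose(j.p_x, 1 / (N + 1), atol=1e-14)
        assert j.p_y[1] == pytest.approx(0.5, abs=1e-14)

    def test_rejects_invalid_window(self):
        with pytest.raises(InvalidParameterError):
            build_joint(0)


class TestMutualInformation:
    def test_independent_table_zero(self):
        p = np.outer([0.3, 0.7], [0.6, 0.4])
        assert mutual_information(p) == pytest.approx(0.0, abs=1e-12)

    def test_identity_table_one_bit(self):
        assert mutual_information(np.eye(2) / 2) == pytest.approx(1.0)

    def test_uniform_prior_joint_against_extended_precision_sum(self):
        j = build_joint(4)
        p = j.p_xy.astype(np.longdouble)
        pa = p.sum(axis=1, keepdims=True)
        pb = p.sum(axis=0, keepdims=True)
        ref = float(np.sum(p * np.log2(p / (pa * pb))))
        assert mutual_information(j.p_xy) == pytest.approx(ref, abs=1e-12)

    def test_rejects_unnormalized_table(self):
        with pytest.raises(InvalidParameterError):
            mutual_information(np.full((2, 2), 0.3))


class TestSolveIB:
    def test_zero_beta_collapses_to_marginal(self, ib_cache):
        sol = ib_cache.solution(4, 0.0)
        assert sol.I_xm == pytest.approx(0.0, abs=1e-9)
        occupied = sol.p_m > 1e-12
        assert np.allclose(sol.decoder[occupied], 0.5, atol=1e-9)

    @pytest.mark.parametrize("N", [4, 11])
    def test_high_beta_reaches_lossless_capacity(self, N, ib_cache):
        sol = ib_cache.solution(N, 1e4)
        assert abs(sol.I_xm - np.log2(N + 1)) < 0.01

    def test_fixed_point_is_stationary_under_one_cycle(self, ib_cache):
        for N, beta in [(4, 1e4), (11, 10.0), (11, 48.33)]:
            sol = ib_cache.solution(N, beta)
            assert sol.converged
            new = ib_update_cycle(sol, ib_cache.joint(N))
            assert np.max(np.abs(new - sol.encoder)) < ib_cache.tol

    def test_encoder_rows_are_distributions(self, ib_cache):
        sol = ib_cache.solution(11, 48.33)
        assert np.allclose(sol.encoder.sum(axis=1), 1.0, atol=1e-10)
        assert (sol.encoder >= 0).all()

    def test_information_inequalities(self, ib_cache):
        j = build_joint(11)
        ixy = mutual_information(j.p_xy)
        for beta in (5.0, 48.33, 1e4):
            sol = ib_cache.solution(11, beta)
            assert -1e-9 <= sol.I_xm <= np.log2(12) + 1e-9
            assert sol.I_my <= sol.I_xm + 1e-9  # data processing
            assert sol.I_my <= ixy + 1e-9

    def test_capacity_conservation(self, ib_cache):
        # I(X;M) + H(X|M) = H(X) = log2(N+1)
        sol = ib_cache.solution(11, 20.0)
        j = build_joint(11)
        p_xm = j.p_x[:, None] * sol.encoder
        p_m = p_xm.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cond = p_xm * np.log2(p_m[None, :] / p_xm)
        h_x_given_m = np.nansum(np.where(p_xm > 0, cond, 0.0))
        assert sol.I_xm + h_x_given_m == pytest.approx(np.log2(12), abs=1e-9)

    def test_negative_beta_rejected(self):
        with pytest.raises(InvalidParameterError):
            solve_ib(build_joint(4), -1.0)

    def test_info_curve_monotone_in_beta(self):
        sols = ib_info_curve(build_joint(7), np.geomspace(0.5, 80, 12), seed=1)
        ixm = np.array([s.I_xm for s in sols])
        imy = np.array([s.I_my for s in sols])
        assert np.all(np.diff(ixm) >= -1e-6)
        assert np.all(np.diff(imy) >= -1e-6)


class TestSurprise:
    def test_zero_beta_surprise_is_one_bit(self, ib_cache):
        seq = generate_sequence([0.3], 60, seed=1)
        surp = ib_surprise(ib_cache.solution(4, 0.0), seq)
        assert np.allclose(surp.masked(), 1.0, atol=1e-9)

    def test_high_beta_matches_laplace_rule(self, ib_cache):
        # at beta -> inf the decoder reproduces p(y|n) = Laplace succession rule
        N = 4
        sol = ib_cache.solution(N, 1e4)
        table = surprise_table(sol)
        n = np.arange(N + 1)
        expected_odd = -np.log2((n + 1) / (N + 2))
        expected_std = -np.log2((N - n + 1) / (N + 2))
        assert np.allclose(table[:, 1], expected_odd, atol=1e-3)
        assert np.allclose(table[:, 0], expected_std, atol=1e-3)
        assert table[0, 1] == pytest.approx(-np.log2(1 / 6), abs=1e-3)

    def test_surprise_monotone_in_count_at_high_beta(self, ib_cache):
        table = surprise_table(ib_cache.solution(11, 1e4))
        assert np.all(np.diff(table[:, 1]) <= 1e-12)  # oddball: less surprising after more oddballs
        assert np.all(np.diff(table[:, 0]) >= -1e-12)  # standard: more surprising after more oddballs

    def test_surprise_nonnegative_and_aligned(self, ib_cache):
        seq = generate_sequence([0.2, 0.4], 100, seed=2)
        sol = ib_cache.solution(6, 10.0)
        surp = ib_surprise(sol, seq)
        counts = oddball_count(seq, 6)
        assert np.array_equal(surp.valid, counts.valid)
        assert np.all(surp.masked() >= 0)

    def test_high_beta_surprise_converges_to_exact_predictive_surprise(self, ib_cache):
        # beta -> inf, m_card = N+1: surprise -> -log2 p(y|x) of the joint
        j = build_joint(11)
        table = surprise_table(ib_cache.solution(11, 1e4))
        exact = -np.log2(j.p_y_given_x)
        assert np.max(np.abs(table - exact)) < 1e-3

    def test_mismatched_counts_rejected(self, ib_cache):
        seq = generate_sequence([0.3], 50, seed=0)
        counts = oddball_count(seq, 5)
        with pytest.raises(InvalidParameterError):
            ib_surprise(ib_cache.solution(4, 10.0), seq, counts=counts)


class TestCapacity:
    def test_noc_capacity_examples(self):
        assert effective_capacity_noc(1) == pytest.approx(1.0)
        assert effective_capacity_noc(4) == pytest.approx(np.log2(5))
        assert effective_capacity_noc(11) == pytest.approx(np.log2(12))

    def test_ib_capacity_is_bounded_by_count_entropy(self, ib_cache):
        for beta in (0.0, 10.0, 1e4):
            sol = ib_cache.solution(11, beta)
            assert effective_capacity_ib(sol) <= np.log2(12) + 1e-9


class TestSolutionSerialization:
    def test_json_roundtrip_preserves_surprise(self, tmp_path, ib_cache):
        sol = ib_cache.solution(5, 30.0)
        path = sol.to_json(tmp_path / "sol.json")
        back = IBSolution.from_json(path)
        assert back.N == sol.N and back.beta == sol.beta
        assert np.allclose(back.encoder, sol.encoder)
        assert np.allclose(surprise_table(back), surprise_table(sol))
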