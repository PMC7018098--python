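import numpy as np
import pytest
import statsmodels.api as sm

from ibsurprise.fitting import (
    DegenerateDesignError,
    IBCache,
    InfeasibleGridError,
    SubjectData,
    _permute_within_blocks,
    asymptotic_weights,
    bin_surprise,
    grid_search,
    multi_subject_summary,
    noc_value_probabilities,
    permutation_test,
    weighted_linear_fit,
)
from ibsurprise.ib import build_joint, effective_capacity_noc
from ibsurprise.sequence import generate_sequence, noc_predictor
from ibsurprise.synth import SubjectSpec, generate_auc_subject


class TestBinSurprise:
    def test_floor_to_left_edge(self):
        assert bin_surprise(np.array([2.58496]))[0] == pytest.approx(2.5849)

    def test_zero_stays_zero(self):
        assert bin_surprise(np.array([0.0]))[0] == 0.0

    def test_values_within_one_bin_coincide(self):
        a, b = bin_surprise(np.array([1.23452, 1.23458]))
        assert a == b


class TestAsymptoticWeights:
    def test_noc_worked_example(self):
        # N=4, n=0: p = p(y=0,x=0) + p(y=1,x=4) = (5+5)/30, weight 3
        j = build_joint(4)
        seq = generate_sequence([0.3], 50, seed=0)
        w = asymptotic_weights(noc_predictor(seq, 4), j)
        assert w[0.0] == pytest.approx(3.0)

    @pytest.mark.parametrize("N", [4, 6, 10])
    def test_midpoint_symmetry_closed_form(self, N):
        # for even N at n = N/2: p(n) = 2(N-n+1)/((N+1)(N+2))
        p = noc_value_probabilities(build_joint(N))
        n = N // 2
        assert p[n] == pytest.approx(2 * (N - n + 1) / ((N + 1) * (N + 2)))

    def test_noc_probabilities_match_enumeration_oracle(self):
        # brute force: sum joint cells contributing to each predictor value
        for N in (3, 5, 8):
            j = build_joint(N)
            ref = np.zeros(N + 1)
            for n in range(N + 1):
                for y in (0, 1):
                    value = N - n if y == 1 else n
                    ref[value] += j.p_xy[n, y]
            assert np.allclose(noc_value_probabilities(j), ref, atol=1e-15)

    def test_weights_independent_of_sequence(self):
        j = build_joint(5)
        a = asymptotic_weights(noc_predictor(generate_sequence([0.1], 60, 1), 5), j)
        b = asymptotic_weights(noc_predictor(generate_sequence([0.5], 60, 2), 5), j)
        assert a == b

    def test_ib_zero_beta_single_level_weight_one(self, ib_cache):
        from ibsurprise.ib import ib_surprise

        seq = generate_sequence([0.3], 60, seed=1)
        sol = ib_cache.solution(4, 0.0)
        w = asymptotic_weights(ib_surprise(sol, seq), build_joint(4), sol)
        assert len(w) == 1  # one binned surprise level near 1 bit, weight 1
        (level, weight), = w.items()
        assert level == pytest.approx(1.0, abs=1e-4)
        assert weight == pytest.approx(1.0)

    def test_ib_weights_sum_of_joint_cells(self, ib_cache):
        from ibsurprise.fitting import _ib_tables

        j = build_joint(6)
        sol = ib_cache.solution(6, 20.0)
        sb, w = _ib_tables(j, sol)
        # reciprocal weights per level must total 1 over distinct levels
        levels = {}
        for n in range(7):
            for y in (0, 1):
                levels.setdefault(sb[n, y], 0.0)
                levels[sb[n, y]] += j.p_xy[n, y]
        for n in range(7):
            for y in (0, 1):
                assert w[n, y] == pytest.approx(1.0 / levels[sb[n, y]])


class TestWeightedLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        w = np.linspace(0.5, 2.0, 10)
        slope, intercept, r2 = weighted_linear_fit(x, 2 * x + 1, w)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_pure_noise_has_near_zero_r2(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        _, _, r2 = weighted_linear_fit(x, y, np.ones(5000))
        assert r2 < 0.01

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_statsmodels_wls(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        w = rng.uniform(0.1, 5.0, size=n)
        slope, intercept, r2 = weighted_linear_fit(x, y, w)
        res = sm.WLS(y, sm.add_constant(x), weights=w).fit()
        assert slope == pytest.approx(res.params[1], rel=1e-9)
        assert intercept == pytest.approx(res.params[0], rel=1e-9)
        assert r2 == pytest.approx(res.rsquared, abs=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateDesignError):
            weighted_linear_fit(np.ones(5), np.arange(5.0), np.ones(5))


class TestGridSearch:
    def test_noiseless_noc_subject_recovered_exactly(self, ib_cache):
        spec = SubjectSpec(true_model="noc", true_N=8, slope=0.09, intercept=0.2,
                           noise_sd=0.0, seed=4)
        subj = generate_auc_subject(spec, ib_cache)
        fit, r2_map = grid_search(subj.auc, subj.seq, "noc", np.arange(2, 15),
                                  cache=ib_cache)
        assert fit.N == 8
        assert fit.weighted_r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.09, abs=1e-12)
        assert fit.capacity_bits == pytest.approx(effective_capacity_noc(8))

    def test_noiseless_ib_subject_recovered(self, ib_cache):
        beta_grid = np.array([5.0, 20.0, 48.33, 100.0])
        spec = SubjectSpec(true_model="ib", true_N=11, true_beta=48.33,
                           slope=0.93, noise_sd=0.0, seed=4)
        subj = generate_auc_subject(spec, ib_cache)
        fit, _ = grid_search(subj.auc, subj.seq, "ib", np.arange(8, 15), beta_grid,
                             cache=ib_cache)
        assert fit.N == 11
        assert fit.beta == pytest.approx(48.33)
        assert fit.weighted_r2 > 0.9999  # 1e-4 binning only
        assert fit.slope == pytest.approx(0.93, rel=1e-3)

    def test_r2_map_bookkeeping(self, ib_cache):
        spec = SubjectSpec(true_model="noc", true_N=5, noise_sd=0.3, seed=1)
        subj = generate_auc_subject(spec, ib_cache)
        N_grid = np.arange(2, 12)
        fit, r2_map = grid_search(subj.auc, subj.seq, "noc", N_grid, cache=ib_cache)
        assert len(r2_map) == len(N_grid)
        assert np.nanmax(r2_map["weighted_r2"]) == pytest.approx(fit.weighted_r2)

    def test_distance_baseline_fits_oddballs_only(self, ib_cache):
        spec = SubjectSpec(true_model="noc", true_N=5, noise_sd=0.2, seed=2)
        subj = generate_auc_subject(spec, ib_cache)
        fit, _ = grid_search(subj.auc, subj.seq, "distance")
        assert fit.model_kind == "distance"
        assert fit.n_points == int((subj.seq.tones == 1).sum()
                                   - len(list(subj.seq.block_slices())))
        assert fit.capacity_bits is None

    def test_empty_grid_rejected(self, ib_cache):
        spec = SubjectSpec(true_model="noc", true_N=5, noise_sd=0.2, seed=2)
        subj = generate_auc_subject(spec, ib_cache)
        with pytest.raises(InfeasibleGridError):
            grid_search(subj.auc, subj.seq, "noc", np.array([]), cache=ib_cache)


class TestPermutationTest:
    def test_within_block_shuffle_preserves_block_counts(self):
        seq = generate_sequence([0.2, 0.5], 40, seed=0)
        perms = _permute_within_blocks(seq, 50, np.random.default_rng(1))
        for _, sl in seq.block_slices():
            assert np.all(perms[:, sl].sum(axis=1) == seq.tones[sl].sum())

    def test_pure_signal_reaches_minimal_p(self, ib_cache):
        spec = SubjectSpec(true_model="noc", true_N=5, slope=0.09, noise_sd=0.0, seed=3)
        subj = generate_auc_subject(spec, ib_cache)
        p, null, fit = permutation_test(subj.auc, subj.seq, "noc", np.arange(2, 10),
                                        n_perm=99, seed=5, cache=ib_cache)
        assert p == pytest.approx(1 / 100)
        assert fit.p_value == p
        assert null.size == 99 and np.nanmax(null) < fit.weighted_r2

    def test_caching_is_semantically_invisible(self):
        spec = SubjectSpec(true_model="ib", true_N=4, true_beta=20.0, slope=1.0,
                           noise_sd=0.5, seed=6, block_probs=(0.2, 0.4),
                           trials_per_block=80)
        subj = generate_auc_subject(spec)
        args = (subj.auc, subj.seq, "ib", np.arange(2, 7), np.array([5.0, 20.0]))
        warm = IBCache()
        warm.populate(np.arange(2, 7), [5.0, 20.0])
        p1, null1, _ = permutation_test(*args, n_perm=50, seed=9, cache=warm)
        p2, null2, _ = permutation_test(*args, n_perm=50, seed=9, cache=None)
        assert p1 == p2
        assert np.array_equal(null1, null2, equal_nan=True)


class TestMultiSubjectSummary:
    def _subject(self, seed, ib_cache):
        spec = SubjectSpec(true_model="noc", true_N=5, slope=0.09, intercept=0.05,
                           noise_sd=0.0, seed=seed)
        subj = generate_auc_subject(spec, ib_cache)
        noc_fit, _ = grid_search(subj.auc, subj.seq, "noc", np.arange(3, 8),
                                 cache=ib_cache)
        ib_fit, _ = grid_search(subj.auc, subj.seq, "ib", np.arange(3, 8),
                                np.array([5.0, 48.33]), cache=ib_cache)
        norm = subj.auc / (subj.auc[subj.seq.tones == 1].mean()
                           - subj.auc[subj.seq.tones == 0].mean())
        return SubjectData(seq=subj.seq, auc_norm=norm, noc_fit=noc_fit, ib_fit=ib_fit)

    def test_duplicated_subject_preserves_fit(self, ib_cache):
        s = self._subject(0, ib_cache)
        pooled = multi_subject_summary([s, s], cache=ib_cache)
        solo_x = pooled.points_noc.query("subject == 'subject0'")
        _, _, r2 = (lambda d: weighted_linear_fit(
            d["x"].to_numpy(), d["mean_auc_norm"].to_numpy(),
            np.ones(len(d))))(solo_x)
        assert pooled.fit_noc["r2"] == pytest.approx(r2, abs=1e-9)

    def test_capacity_table_respects_entropy_bound(self, ib_cache):
        subs = [self._subject(s, ib_cache) for s in (0, 1)]
        pooled = multi_subject_summary(subs, cache=ib_cache)
        tab = pooled.capacity_table
        assert np.allclose(tab["noc_capacity_bits"],
                           np.log2(tab["noc_N"].to_numpy() + 1))
        same_n = tab["noc_N"] == tab["ib_N"]
        assert np.all(tab.loc[same_n, "ib_capacity_bits"]
                      <= tab.loc[same_n, "noc_capacity_bits"] + 1e-9)

    def test_pooled_fit_matches_normal_equations_oracle(self, ib_cache):
        subs = [self._subject(s, ib_cache) for s in (0, 1)]
        pooled = multi_subject_summary(subs, cache=ib_cache)
        x = pooled.points_ib["x"].to_numpy()
        y = pooled.points_ib["mean_auc_norm"].to_numpy()
        # explicit normal equations
        A = np.vstack([np.ones_like(x), x]).T
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        assert pooled.fit_ib["intercept"] == pytest.approx(coef[0], abs=1e-9)
        assert pooled.fit_ib["slope"] == pytest.approx(coef[1], abs=1e-9)

    def test_single_subject_warns(self, ib_cache):
        with pytest.warns(UserWarning):
            multi_subject_summary([self._subject(0, ib_cache)], cache=ib_cache)
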