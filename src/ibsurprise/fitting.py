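"""Fitting surprise predictors to single-trial P300 features.

The response model is linear: on each valid trial the AUC feature is
``intercept + slope * predictor + noise``.  Because high-surprise
trials are rare by construction, ordinary least squares would be
dominated by the common low-surprise trials; the fit therefore uses
inverse-probability weighting, with the probability of each predictor
value taken from the model's asymptotic joint table (never from
empirical frequencies).  Goodness of fit is the weighted R-squared

    R2_w = 1 - sum w (y - yhat)^2 / sum w (y - ybar_w)^2,

with ``ybar_w`` the weight-weighted mean.  Model parameters (window
length ``N``; for the IB model also the trade-off ``beta``) are chosen
by exhaustive grid search on ``R2_w``; significance is assessed with a
within-block permutation test whose statistic is the maximum weighted
R-squared over the whole grid, which absorbs the multiple comparisons
of the search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ib as ib_mod
from .ib import (
    IBSolution,
    JointDistribution,
    build_joint,
    effective_capacity_ib,
    effective_capacity_noc,
    solve_ib,
    surprise_table,
)
from .sequence import (
    InvalidParameterError,
    OddballSequence,
    PredictorSeries,
    noc_predictor,
    oddball_count,
)

__all__ = [
    "SURPRISE_BIN_WIDTH",
    "FitResult",
    "DegenerateDesignError",
    "InfeasibleGridError",
    "bin_surprise",
    "noc_value_probabilities",
    "asymptotic_weights",
    "weighted_linear_fit",
    "IBCache",
    "grid_search",
    "permutation_test",
    "SubjectData",
    "PooledSummary",
    "multi_subject_summary",
    "default_n_grid",
    "default_beta_grid",
]

SURPRISE_BIN_WIDTH = 1e-4


class DegenerateDesignError(ValueError):
    """All predictor values identical; the linear fit is undefined."""


class InfeasibleGridError(ValueError):
    """No grid point yields enough valid trials to fit."""


def default_n_grid() -> np.ndarray:
    """Window lengths 2..50 (effects of up to 50 past elements are considered)."""
    return np.arange(2, 51)


def default_beta_grid(num: int = 30) -> np.ndarray:
    """Geometric trade-off grid on [0.5, 100]."""
    return np.geomspace(0.5, 100.0, num)


def bin_surprise(values: np.ndarray, width: float = SURPRISE_BIN_WIDTH) -> np.ndarray:
    """Map each surprise value to the left edge of its bin on a fixed grid anchored at 0.

    Binning removes insignificant floating-point differences between
    surprise values before they are used as regression levels.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise InvalidParameterError("surprise values must be finite")
    return np.floor(values / width) * width


def noc_value_probabilities(joint: JointDistribution) -> np.ndarray:
    """Asymptotic probability of each opposite-tone-count value n.

    ``p(n) = p(y=0, x=n) + p(y=1, x=N-n)``: a predictor value n arises
    either from a standard tone after n oddballs or from an oddball
    after N-n oddballs.
    """
    N = joint.N
    return joint.p_xy[:, 0] + joint.p_xy[::-1, 1]


def _noc_weight_table(joint: JointDistribution) -> np.ndarray:
    return 1.0 / noc_value_probabilities(joint)


def _ib_tables(joint: JointDistribution, solution: IBSolution):
    """Binned surprise table S[n, y] and matching inverse-probability weights.

    The probability of a binned surprise level is the sum of joint
    probabilities p(x, y) over all cells whose binned surprise equals it.
    """
    sb = bin_surprise(surprise_table(solution))
    levels, inverse = np.unique(sb, return_inverse=True)
    p_level = np.zeros(levels.size)
    np.add.at(p_level, inverse.ravel(), joint.p_xy.ravel())
    w = (1.0 / p_level)[inverse].reshape(sb.shape)
    return sb, w


def asymptotic_weights(
    predictor: PredictorSeries,
    joint: JointDistribution,
    solution: IBSolution | None = None,
) -> dict[float, float]:
    """Inverse-probability weight per distinct predictor value.

    Weights are computed from the model's asymptotic tables only and
    therefore depend on ``(kind, N, beta)`` but never on the observed
    sequence.
    """
    if predictor.N != joint.N:
        raise InvalidParameterError("joint table does not match the predictor's N")
    if predictor.kind == "noc":
        w = _noc_weight_table(joint)
        return {float(n): float(w[n]) for n in range(joint.N + 1)}
    if predictor.kind == "ib_surprise":
        if solution is None:
            raise InvalidParameterError("ib weights require the IB solution")
        sb, w = _ib_tables(joint, solution)
        return {float(s): float(wv) for s, wv in zip(sb.ravel(), w.ravel())}
    raise InvalidParameterError(f"no asymptotic weights for kind {predictor.kind!r}")


def _fit_rows(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least squares with intercept, row-wise.

    ``x``/``w`` are (rows, points); ``y`` broadcasts.  Returns
    (slope, intercept, r2) arrays of length rows; degenerate rows
    (constant x or zero total variance) give NaN.
    """
    sw = w.sum(axis=-1)
    swx = (w * x).sum(axis=-1)
    swy = (w * y).sum(axis=-1)
    swxx = (w * x * x).sum(axis=-1)
    swxy = (w * x * y).sum(axis=-1)
    swyy = (w * y * y).sum(axis=-1)
    den = sw * swxx - swx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (sw * swxy - swx * swy) / den
        intercept = (swy - slope * swx) / sw
        sse = (
            swyy
            - 2 * (slope * swxy + intercept * swy)
            + slope**2 * swxx
            + 2 * slope * intercept * swx
            + intercept**2 * sw
        )
        sst = swyy - swy**2 / sw
        r2 = 1.0 - sse / sst
    bad = ~(np.abs(den) > 1e-12 * np.maximum(sw * swxx, 1e-300)) | ~(sst > 0)
    slope = np.where(bad, np.nan, slope)
    intercept = np.where(bad, np.nan, intercept)
    r2 = np.where(bad, np.nan, np.clip(r2, 0.0, 1.0))
    return slope, intercept, r2


def weighted_linear_fit(x, y, w) -> tuple[float, float, float]:
    """Weighted linear regression with intercept; returns (slope, intercept, R2_w)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if x.size < 3:
        raise InvalidParameterError("need at least 3 points")
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all predictor values identical")
    slope, intercept, r2 = _fit_rows(x[None, :], y[None, :], w[None, :])
    return float(slope[0]), float(intercept[0]), float(r2[0])


@dataclass
class FitResult:
    """Outcome of a weighted-regression grid search for one subject and model."""

    model_kind: str
    N: int | None
    beta: float | None
    slope: float
    intercept: float
    weighted_r2: float
    p_value: float | None
    n_points: int
    capacity_bits: float | None

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "N": self.N,
            "beta": self.beta,
            "slope": self.slope,
            "intercept": self.intercept,
            "weighted_r2": self.weighted_r2,
            "p_value": self.p_value,
            "n_points": self.n_points,
            "capacity_bits": self.capacity_bits,
        }


class IBCache:
    """Cache of IB solutions and derived fitting tables, keyed by (N, beta).

    Solutions depend only on the model parameters, never on data, so a
    single cache can back grid searches over many subjects and all
    permutations.  The miss path is exactly ``solve_ib`` with this
    cache's solver settings, which keeps caching semantically invisible.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 30000, n_restarts: int = 0, seed: int = 0):
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts
        self.seed = seed
        self._joints: dict[int, JointDistribution] = {}
        self._solutions: dict[tuple[int, float], IBSolution] = {}
        self._tables: dict[tuple[int, float], tuple[np.ndarray, np.ndarray]] = {}
        self.hits = 0
        self.misses = 0

    def joint(self, N: int) -> JointDistribution:
        if N not in self._joints:
            self._joints[N] = build_joint(N)
        return self._joints[N]

    def solution(self, N: int, beta: float) -> IBSolution:
        key = (int(N), float(beta))
        if key not in self._solutions:
            self.misses += 1
            self._solutions[key] = solve_ib(
                self.joint(N),
                beta,
                tol=self.tol,
                max_iter=self.max_iter,
                n_restarts=self.n_restarts,
                seed=self.seed,
            )
        else:
            self.hits += 1
        return self._solutions[key]

    def tables(self, N: int, beta: float) -> tuple[np.ndarray, np.ndarray]:
        """Binned surprise table and weight table for one (N, beta)."""
        key = (int(N), float(beta))
        if key not in self._tables:
            self._tables[key] = _ib_tables(self.joint(N), self.solution(N, beta))
        return self._tables[key]

    def populate(self, N_grid, beta_grid) -> None:
        for N in N_grid:
            for beta in beta_grid:
                self.solution(int(N), float(beta))

    @property
    def n_unconverged(self) -> int:
        return sum(not s.converged for s in self._solutions.values())


def _batch_counts(tones: np.ndarray, seq: OddballSequence, N: int, window_scope: str):
    """Sliding-window oddball counts for a batch of tone rows sharing one block layout.

    Returns (counts (rows, T) int, valid (T,) bool); valid depends only
    on positions, not tone values.
    """
    tones = np.atleast_2d(tones).astype(np.int64)
    T = seq.n_trials
    counts = np.zeros(tones.shape, dtype=np.int64)
    valid = np.zeros(T, dtype=bool)
    scopes = (
        seq.block_slices() if window_scope == "block" else [(0, slice(0, T))]
    )
    for _, sl in scopes:
        L = sl.stop - sl.start
        if L <= N:
            continue
        block = tones[:, sl]
        csum = np.concatenate(
            [np.zeros((tones.shape[0], 1), dtype=np.int64), np.cumsum(block, axis=1)],
            axis=1,
        )
        counts[:, sl.start + N : sl.stop] = csum[:, N:L] - csum[:, : L - N]
        valid[sl.start + N : sl.stop] = True
    return counts, valid


def _grid_r2_rows(
    tones: np.ndarray,
    seq: OddballSequence,
    auc: np.ndarray,
    model_kind: str,
    N_grid,
    beta_grid,
    cache: IBCache,
    window_scope: str,
):
    """Weighted R2 per grid point for a batch of tone rows; yields
    (N, beta, slope, intercept, r2, n_points) with vector entries per row."""
    tones = np.atleast_2d(tones)
    for N in N_grid:
        N = int(N)
        counts, valid = _batch_counts(tones, seq, N, window_scope)
        if valid.sum() < 3:
            continue
        y = auc[valid][None, :]
        n = counts[:, valid]
        ytone = tones[:, valid]
        if model_kind == "noc":
            wtab = _noc_weight_table(cache.joint(N))
            x = np.where(ytone == 1, N - n, n).astype(float)
            w = wtab[np.where(ytone == 1, N - n, n)]
            slope, intercept, r2 = _fit_rows(x, y, w)
            yield N, None, slope, intercept, r2, int(valid.sum())
        elif model_kind == "ib":
            for beta in beta_grid:
                # Below the first IB phase transition the optimal encoder
                # carries no information about the count; any residual
                # spread in its surprise values is solver noise, not a
                # predictor.  Such grid points are excluded from the fit.
                if cache.solution(N, float(beta)).I_xm < 1e-6:
                    nanv = np.full(tones.shape[0], np.nan)
                    yield N, float(beta), nanv, nanv, nanv, int(valid.sum())
                    continue
                sb, wtab = cache.tables(N, float(beta))
                x = sb[n, ytone]
                w = wtab[n, ytone]
                slope, intercept, r2 = _fit_rows(x, y, w)
                yield N, float(beta), slope, intercept, r2, int(valid.sum())
        else:
            raise InvalidParameterError(f"unknown model kind {model_kind!r}")


def grid_search(
    auc: np.ndarray,
    seq: OddballSequence,
    model_kind: str,
    N_grid=None,
    beta_grid=None,
    cache: IBCache | None = None,
    window_scope: str = "block",
) -> tuple[FitResult, pd.DataFrame]:
    """Exhaustive weighted-R2 search over model parameters.

    Returns the best fit (ties broken toward smaller N, then smaller
    beta, by scanning the grid in ascending order with a strict
    improvement rule) together with the full R2 map, one row per grid
    point.  The ``distance`` model has no parameters: it is a single
    unweighted fit of AUC against the distance-from-last-oddball
    baseline on oddball trials.
    """
    auc = np.asarray(auc, dtype=float)
    if auc.size != seq.n_trials:
        raise InvalidParameterError("auc must align with the sequence")

    if model_kind == "distance":
        from .sequence import distance_from_last_oddball

        pred = distance_from_last_oddball(seq)
        x = pred.masked()
        y = auc[pred.valid]
        slope, intercept, r2 = weighted_linear_fit(x, y, np.ones_like(x))
        fit = FitResult(
            model_kind="distance",
            N=None,
            beta=None,
            slope=slope,
            intercept=intercept,
            weighted_r2=r2,
            p_value=None,
            n_points=int(pred.n_valid),
            capacity_bits=None,
        )
        return fit, pd.DataFrame(
            [{"N": np.nan, "beta": np.nan, "weighted_r2": r2}]
        )

    if N_grid is None:
        N_grid = default_n_grid()
    if model_kind == "ib" and beta_grid is None:
        beta_grid = default_beta_grid()
    if model_kind == "noc":
        beta_grid = [None]
    if cache is None:
        cache = IBCache()
    if len(np.atleast_1d(N_grid)) == 0 or len(np.atleast_1d(beta_grid)) == 0:
        raise InfeasibleGridError("empty parameter grid")

    rows = []
    best = None
    for N, beta, slope, intercept, r2, npts in _grid_r2_rows(
        seq.tones, seq, auc, model_kind, N_grid, beta_grid if model_kind == "ib" else [], cache, window_scope
    ):
        r2v = float(r2[0])
        rows.append({"N": N, "beta": beta, "weighted_r2": r2v})
        if np.isnan(r2v):
            continue
        if best is None or r2v > best["weighted_r2"]:
            best = {
                "N": N,
                "beta": beta,
                "slope": float(slope[0]),
                "intercept": float(intercept[0]),
                "weighted_r2": r2v,
                "n_points": npts,
            }
    if best is None:
        raise InfeasibleGridError("no grid point yields a well-posed fit")

    if model_kind == "noc":
        capacity = effective_capacity_noc(best["N"])
    else:
        capacity = effective_capacity_ib(cache.solution(best["N"], best["beta"]))
    fit = FitResult(
        model_kind=model_kind,
        N=best["N"],
        beta=best["beta"],
        slope=best["slope"],
        intercept=best["intercept"],
        weighted_r2=best["weighted_r2"],
        p_value=None,
        n_points=best["n_points"],
        capacity_bits=capacity,
    )
    return fit, pd.DataFrame(rows)


def _permute_within_blocks(
    seq: OddballSequence, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """n_perm tone rows, each with every block's trials independently shuffled."""
    out = np.tile(seq.tones, (n_perm, 1))
    for _, sl in seq.block_slices():
        keys = rng.random((n_perm, sl.stop - sl.start))
        order = np.argsort(keys, axis=1)
        out[:, sl] = np.take_along_axis(out[:, sl], order, axis=1)
    return out


def permutation_test(
    auc: np.ndarray,
    seq: OddballSequence,
    model_kind: str,
    N_grid=None,
    beta_grid=None,
    n_perm: int = 1000,
    seed: int = 0,
    cache: IBCache | None = None,
    window_scope: str = "block",
) -> tuple[float, np.ndarray, FitResult]:
    """Within-block max-statistic permutation test of the grid-search fit.

    For each permutation the tone order is shuffled independently within
    each block (AUC values stay attached to trial positions), the full
    grid search is re-run on the permuted predictor, and the maximum
    weighted R2 over the grid is recorded.  The add-one p-value
    ``(1 + #{null >= observed}) / (1 + n_perm)`` is never exactly zero.
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    if N_grid is None:
        N_grid = default_n_grid()
    if model_kind == "ib" and beta_grid is None:
        beta_grid = default_beta_grid()
    if cache is None:
        cache = IBCache()
    auc = np.asarray(auc, dtype=float)

    observed, _ = grid_search(
        auc, seq, model_kind, N_grid, beta_grid, cache=cache, window_scope=window_scope
    )
    rng = np.random.default_rng(seed)
    perms = _permute_within_blocks(seq, n_perm, rng)
    null = np.full(n_perm, -np.inf)
    for _, _, _, _, r2, _ in _grid_r2_rows(
        perms, seq, auc, model_kind, N_grid, beta_grid if model_kind == "ib" else [], cache, window_scope
    ):
        null = np.fmax(null, r2)
    null[~np.isfinite(null)] = np.nan
    p = float((1 + np.nansum(null >= observed.weighted_r2)) / (1 + n_perm))
    observed.p_value = p
    return p, null, observed


@dataclass
class SubjectData:
    """Per-subject inputs for the pooled multi-subject comparison."""

    seq: OddballSequence
    auc_norm: np.ndarray
    noc_fit: FitResult
    ib_fit: FitResult
    label: str | None = None


@dataclass
class PooledSummary:
    """Pooled mean responses and fits across subjects, plus capacities.

    ``fit_noc``/``fit_ib`` are ordinary-least-squares summaries over the
    pooled per-value subject means: slope, intercept, r2, f_stat,
    p_value, n_points.
    """

    points_noc: pd.DataFrame
    fit_noc: dict
    points_ib: pd.DataFrame
    fit_ib: dict
    capacity_table: pd.DataFrame


def _subject_means(x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"x": x, "mean_auc_norm": y})
    out = df.groupby("x", as_index=False).agg(
        mean_auc_norm=("mean_auc_norm", "mean"), n_trials=("mean_auc_norm", "size")
    )
    return out


def multi_subject_summary(
    subjects: list[SubjectData],
    cache: IBCache | None = None,
    window_scope: str = "block",
) -> PooledSummary:
    """Pool per-subject mean responses and fit a single line across subjects.

    For the count model the per-subject predictor is normalised to the
    running probability ``n/N`` (each subject has their own fitted N);
    the IB surprise is already on a common bits scale.  The pooled fit
    is a single unweighted regression through all subjects' per-value
    means.  The capacity table compares ``log2(N+1)`` (count model)
    with ``I(X;M)`` (IB model) per subject.
    """
    if len(subjects) < 2:
        warnings.warn("fewer than 2 subjects; pooled outputs reduce to the single subject")
    if cache is None:
        cache = IBCache()
    pts_noc, pts_ib, cap_rows = [], [], []
    for i, s in enumerate(subjects):
        label = s.label if s.label is not None else f"subject{i}"
        pred = noc_predictor(s.seq, s.noc_fit.N, window_scope)
        rp = pred.masked() / s.noc_fit.N
        m = _subject_means(rp, s.auc_norm[pred.valid])
        m.insert(0, "subject", label)
        pts_noc.append(m)

        sol = cache.solution(s.ib_fit.N, s.ib_fit.beta)
        surp = ib_mod.ib_surprise(sol, s.seq, window_scope=window_scope)
        sb = bin_surprise(surp.masked())
        m = _subject_means(sb, s.auc_norm[surp.valid])
        m.insert(0, "subject", label)
        pts_ib.append(m)

        cap_rows.append(
            {
                "subject": label,
                "noc_N": s.noc_fit.N,
                "noc_capacity_bits": s.noc_fit.capacity_bits,
                "ib_N": s.ib_fit.N,
                "ib_beta": s.ib_fit.beta,
                "ib_capacity_bits": s.ib_fit.capacity_bits,
            }
        )

    points_noc = pd.concat(pts_noc, ignore_index=True)
    points_ib = pd.concat(pts_ib, ignore_index=True)

    def pooled_fit(points: pd.DataFrame) -> dict:
        # single unweighted point-level regression across all subjects
        import statsmodels.api as sm

        x = points["x"].to_numpy()
        y = points["mean_auc_norm"].to_numpy()
        res = sm.OLS(y, sm.add_constant(x)).fit()
        return {
            "slope": float(res.params[1]),
            "intercept": float(res.params[0]),
            "r2": float(res.rsquared),
            "f_stat": float(res.fvalue),
            "p_value": float(res.f_pvalue),
            "n_points": int(x.size),
        }

    return PooledSummary(
        points_noc=points_noc,
        fit_noc=pooled_fit(points_noc),
        points_ib=points_ib,
        fit_ib=pooled_fit(points_ib),
        capacity_table=pd.DataFrame(cap_rows),
    )
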