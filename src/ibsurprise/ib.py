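"""Information Bottleneck model of a capacity-limited oddball observer.

The observer summarises the last ``N`` tones by the oddball count
``x`` (the minimal sufficient statistic for the block's Bernoulli
parameter) and predicts the next tone ``y``.  Under a uniform prior on
the oddball probability the joint distribution of count and next tone
has the closed form

    p(y=1, x=n) = (n+1) / ((N+1)(N+2)),

with a uniform marginal p(x=n) = 1/(N+1).  A memory-limited observer
does not keep ``x`` exactly but a stochastic compressed representation
``m`` found by minimising the Information Bottleneck Lagrangian

    L[p(m|x)] = I(X;M) - beta * I(M;Y),

where ``beta`` trades representation accuracy against compression
(low beta = strong compression).  The optimum satisfies the
self-consistent equations

    p(m|x) = p(m)/C(x, beta) * exp(-beta * KL[p(y|x) || p(y|m)])
    p(m)   = sum_x p(x) p(m|x)
    p(y|m) = sum_x p(y|x) p(x|m)

iterated to a fixed point.  The KL divergence inside the exponent is
taken in nats (so ``beta`` follows the natural-log convention); all
reported informations and surprises are in bits.

The per-trial subjective surprise of an observer holding solution
``(encoder, decoder)`` is

    S(y | x=n) = - sum_m p(m|n) log2 p(y|m)   [bits],

averaging the decoder's surprisal over the possible memory states.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence import InvalidParameterError, OddballSequence, PredictorSeries, oddball_count

__all__ = [
    "JointDistribution",
    "IBSolution",
    "build_joint",
    "mutual_information",
    "solve_ib",
    "ib_info_curve",
    "ib_update_cycle",
    "surprise_table",
    "ib_surprise",
    "effective_capacity_ib",
    "effective_capacity_noc",
]

_LOG_FLOOR = 1e-300  # floor for logging only; probabilities are never renormalized


@dataclass(frozen=True)
class JointDistribution:
    """Joint probability of past oddball count x in {0..N} and next tone y in {0,1}."""

    N: int
    p_xy: np.ndarray  # shape (N+1, 2); p_xy[n, y]

    @property
    def p_x(self) -> np.ndarray:
        return self.p_xy.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.p_xy.sum(axis=0)

    @property
    def p_y_given_x(self) -> np.ndarray:
        return self.p_xy / self.p_x[:, None]


def build_joint(N: int) -> JointDistribution:
    """Closed-form Beta-Bernoulli joint under a uniform prior on the oddball rate.

    ``p(y=1, x=n) = (n+1)/((N+1)(N+2))`` and
    ``p(y=0, x=n) = (N-n+1)/((N+1)(N+2))``; the count marginal is uniform.
    """
    if int(N) != N or N < 1:
        raise InvalidParameterError("N must be an integer >= 1")
    N = int(N)
    n = np.arange(N + 1)
    denom = (N + 1) * (N + 2)
    p_xy = np.column_stack([(N - n + 1) / denom, (n + 1) / denom])
    return JointDistribution(N=N, p_xy=p_xy)


def mutual_information(p_table: np.ndarray, tol: float = 1e-8) -> float:
    """Mutual information (bits) of a two-dimensional joint probability table."""
    p = np.asarray(p_table, dtype=float)
    if p.ndim != 2:
        raise InvalidParameterError("joint table must be two-dimensional")
    if np.any(p < -1e-12):
        raise InvalidParameterError("joint table has negative entries")
    if abs(p.sum() - 1.0) > tol:
        raise InvalidParameterError("joint table must sum to 1")
    pa = p.sum(axis=1, keepdims=True)
    pb = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.ones_like(p)
    np.divide(p, pa * pb, out=ratio, where=mask)
    return float(np.sum(p[mask] * np.log2(ratio[mask])))


@dataclass
class IBSolution:
    """A converged fixed point of the IB self-consistent equations.

    ``encoder`` rows are p(m|x); ``decoder`` rows are p(y|m);
    informations are in bits; ``objective`` is I(X;M) - beta * I(M;Y).
    """

    N: int
    beta: float
    encoder: np.ndarray  # (N+1, M)
    p_m: np.ndarray  # (M,)
    decoder: np.ndarray  # (M, 2)
    I_xm: float
    I_my: float
    n_iter: int
    converged: bool
    objective: float

    @property
    def m_card(self) -> int:
        return int(self.encoder.shape[1])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "N": self.N,
                    "beta": self.beta,
                    "m_card": self.m_card,
                    "encoder": self.encoder.tolist(),
                    "p_m": self.p_m.tolist(),
                    "decoder": self.decoder.tolist(),
                    "I_xm": self.I_xm,
                    "I_my": self.I_my,
                    "n_iter": self.n_iter,
                    "converged": self.converged,
                    "objective": self.objective,
                },
                indent=2,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "IBSolution":
        d = json.loads(Path(path).read_text())
        d.pop("m_card", None)
        for key in ("encoder", "p_m", "decoder"):
            d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def _decoder_from_encoder(enc, p_x, p_y_given_x, p_y):
    """p(m) and p(y|m) induced by an encoder; dead clusters decode to p(y)."""
    p_m = enc.T @ p_x
    joint_my = (enc * p_x[:, None]).T @ p_y_given_x  # (M, 2) = p(m, y)
    dec = np.where(p_m[:, None] > 0, joint_my / np.maximum(p_m, _LOG_FLOOR)[:, None], p_y)
    return p_m, dec


def _encoder_update(p_m, dec, p_y_given_x, beta, neg_h=None):
    """One encoder update: p(m|x) proportional to p(m) exp(-beta KL[p(y|x)||p(y|m)])."""
    log_dec = np.log(np.maximum(dec, _LOG_FLOOR))
    # KL in nats, decoder as second argument
    if neg_h is None:
        neg_h = np.sum(p_y_given_x * np.log(p_y_given_x), axis=1)  # (X,)
    kl = neg_h[:, None] - p_y_given_x @ log_dec.T  # (X, M)
    with np.errstate(divide="ignore"):
        log_pm = np.where(p_m > 0, np.log(np.maximum(p_m, _LOG_FLOOR)), -np.inf)
    log_enc = log_pm[None, :] - beta * kl
    # in-line log-sum-exp normalization per row
    log_enc -= log_enc.max(axis=1, keepdims=True)
    enc = np.exp(log_enc)
    return enc / enc.sum(axis=1, keepdims=True)


def _iterate(enc, joint: JointDistribution, beta, tol, max_iter):
    """Run the self-consistent updates to a fixed point.

    Plain successive substitution is accelerated with SQUAREM-style
    extrapolation (two base steps, one extrapolated step, one
    stabilizing base step); convergence is always declared on the
    max-abs change of a *plain* update falling below ``tol``, so an
    accepted fixed point satisfies the unaccelerated criterion.
    Extrapolation falls back to the plain step whenever it would leave
    the probability simplex.
    """
    p_x = joint.p_x
    p_y_given_x = joint.p_y_given_x
    p_y = joint.p_y
    neg_h = np.sum(p_y_given_x * np.log(p_y_given_x), axis=1)

    def step(e):
        p_m, dec = _decoder_from_encoder(e, p_x, p_y_given_x, p_y)
        return _encoder_update(p_m, dec, p_y_given_x, beta, neg_h)

    it = 0
    while it < max_iter:
        e1 = step(enc)
        it += 1
        if np.max(np.abs(e1 - enc)) < tol:
            return e1, it, True
        e2 = step(e1)
        it += 1
        if np.max(np.abs(e2 - e1)) < tol:
            return e2, it, True
        r = e1 - enc
        v = (e2 - e1) - r
        nv = np.linalg.norm(v)
        if nv == 0:
            enc = e2
            continue
        alpha = max(-np.linalg.norm(r) / nv, -512.0)
        acc = enc - 2.0 * alpha * r + alpha * alpha * v
        if (acc < 0).any() or not np.isfinite(acc).all():
            enc = e2
            continue
        acc /= acc.sum(axis=1, keepdims=True)
        enc = step(acc)
        it += 1
    return enc, it, False


def _finish(enc, joint: JointDistribution, beta, n_iter, converged) -> IBSolution:
    p_m, dec = _decoder_from_encoder(enc, joint.p_x, joint.p_y_given_x, joint.p_y)
    I_xm = mutual_information(joint.p_x[:, None] * enc)
    I_my = mutual_information(p_m[:, None] * dec)
    return IBSolution(
        N=joint.N,
        beta=float(beta),
        encoder=enc,
        p_m=p_m,
        decoder=dec,
        I_xm=I_xm,
        I_my=I_my,
        n_iter=n_iter,
        converged=converged,
        objective=I_xm - beta * I_my,
    )


def _init_encoder(X: int, M: int, rng: np.random.Generator, eps: float = 0.05):
    """Slightly perturbed (soft) identity encoder."""
    enc = np.full((X, M), eps / M)
    enc[np.arange(X), np.arange(X) % M] += 1.0 - eps
    enc *= 1.0 + 0.01 * rng.random((X, M))
    return enc / enc.sum(axis=1, keepdims=True)


def solve_ib(
    joint: JointDistribution,
    beta: float,
    m_card: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 30000,
    n_restarts: int = 2,
    seed: int = 0,
    init_encoder: np.ndarray | None = None,
) -> IBSolution:
    """Solve the IB fixed-point equations at one ``(N, beta)``.

    The default start is a slightly perturbed identity encoder iterated
    directly at the target beta: at low beta the iteration contracts to
    the fully compressed solution, at high beta the identity is already
    near the optimum, and the perturbation breaks the symmetry of the
    collapsed (all-rows-equal) saddle that is a fixed point at every
    beta.  ``n_restarts`` additional seeded random starts guard against
    poor local optima; the candidate with the smallest objective wins.
    """
    if beta < 0:
        raise InvalidParameterError("beta must be >= 0")
    if m_card is None:
        m_card = joint.N + 1
    if m_card < 1:
        raise InvalidParameterError("m_card must be >= 1")
    X = joint.N + 1
    rng = np.random.default_rng(seed)

    candidates: list[IBSolution] = []
    if init_encoder is not None:
        starts = [np.asarray(init_encoder, dtype=float)]
    else:
        starts = [_init_encoder(X, m_card, rng)]
        starts += [_init_encoder(X, m_card, rng, eps=0.3) for _ in range(n_restarts)]
    for enc0 in starts:
        enc, it, conv = _iterate(enc0, joint, beta, tol, max_iter)
        candidates.append(_finish(enc, joint, beta, it, conv))

    best = min(candidates, key=lambda s: s.objective)
    if not best.converged:
        warnings.warn(
            f"IB solver did not converge at N={joint.N}, beta={beta} "
            f"within {max_iter} iterations",
            stacklevel=2,
        )
    return best


def ib_info_curve(
    joint: JointDistribution,
    betas,
    m_card: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 30000,
    seed: int = 0,
) -> list[IBSolution]:
    """Deterministic annealing: solve along an ascending beta ladder.

    Each rung is warm-started from the previous solution with a small
    multiplicative jitter re-injected so the encoder can break the
    symmetry of the collapsed saddle once beta crosses a critical
    value.  Returns one solution per requested beta, ascending;
    successive solutions move outward on the information plane (both
    I(X;M) and I(M;Y) non-decreasing in beta).
    """
    betas = np.sort(np.asarray(betas, dtype=float))
    if m_card is None:
        m_card = joint.N + 1
    rng = np.random.default_rng(seed)
    enc = _init_encoder(joint.N + 1, m_card, rng)
    out = []
    for b in betas:
        enc = enc * (1.0 + 1e-3 * rng.random(enc.shape))
        enc = enc / enc.sum(axis=1, keepdims=True)
        enc, it, conv = _iterate(enc, joint, b, tol, max_iter)
        out.append(_finish(enc, joint, b, it, conv))
    return out


def ib_update_cycle(solution: IBSolution, joint: JointDistribution) -> np.ndarray:
    """Apply one full update cycle to a solution's encoder and return the new encoder."""
    p_m, dec = _decoder_from_encoder(
        solution.encoder, joint.p_x, joint.p_y_given_x, joint.p_y
    )
    return _encoder_update(p_m, dec, joint.p_y_given_x, solution.beta)


def surprise_table(solution: IBSolution) -> np.ndarray:
    """Subjective surprise S[n, y] = -sum_m p(m|n) log2 p(y|m), in bits.

    A decoder probability of exactly zero for an observed tone yields
    +inf surprise with a warning; this cannot occur at finite beta with
    the uniform-prior joint.
    """
    enc = solution.encoder
    dec = solution.decoder
    with np.errstate(divide="ignore"):
        log2_dec = np.where(dec > 0, np.log2(np.maximum(dec, _LOG_FLOOR)), -np.inf)
    contrib = np.where(enc[:, :, None] > 0, enc[:, :, None] * log2_dec[None, :, :], 0.0)
    table = -contrib.sum(axis=1)  # (N+1, 2)
    if np.isinf(table).any():
        warnings.warn("decoder assigns zero probability to an observed tone", stacklevel=2)
    return table


def ib_surprise(
    solution: IBSolution,
    seq: OddballSequence,
    counts: PredictorSeries | None = None,
    window_scope: str = "block",
) -> PredictorSeries:
    """Per-trial IB surprise (bits) of the observed tone given the past count."""
    if counts is None:
        counts = oddball_count(seq, solution.N, window_scope)
    elif counts.N != solution.N:
        raise InvalidParameterError("counts were computed with a different window length")
    table = surprise_table(solution)
    values = np.zeros(seq.n_trials)
    n = counts.values.astype(int)
    values[counts.valid] = table[n[counts.valid], seq.tones[counts.valid]]
    return PredictorSeries(
        kind="ib_surprise",
        values=values,
        valid=counts.valid.copy(),
        N=solution.N,
        beta=solution.beta,
    )


def effective_capacity_ib(solution: IBSolution) -> float:
    """Effective memory capacity of an IB observer: I(X;M) in bits."""
    return float(solution.I_xm)


def effective_capacity_noc(N: int) -> float:
    """Memory needed to code the count exactly: log2(N+1) bits."""
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    return float(np.log2(N + 1))
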