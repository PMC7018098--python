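"""Block-structured oddball stimulus sequences and count-based predictors.

An oddball session is a concatenation of blocks; within each block the
stimulus on every trial is an independent Bernoulli draw (1 = oddball /
high tone, 0 = standard / low tone) with a block-specific oddball
probability.  The predictors defined here summarise the recent past of
the sequence through the oddball count in a sliding window of ``N``
trials: the raw count, the opposite-tone count (the naive-oddball-count
predictor), the running probability ``n/N``, and a
distance-from-last-oddball baseline.

Trials whose window would reach outside the block (or, for the distance
predictor, oddballs with no predecessor in the block) are carried with
``valid = False`` rather than dropped, so predictor series stay
index-aligned with per-trial ERP features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "InvalidParameterError",
    "OddballSequence",
    "PredictorSeries",
    "generate_sequence",
    "oddball_count",
    "noc_predictor",
    "running_probability",
    "distance_from_last_oddball",
]


class InvalidParameterError(ValueError):
    """A parameter violates its documented precondition."""


@dataclass
class OddballSequence:
    """A binary tone sequence organised in blocks.

    Parameters
    ----------
    tones
        Per-trial tone, 1 = oddball (high tone), 0 = standard (low tone).
    block_id
        Per-trial block index; non-decreasing and contiguous from 0.
    block_probs
        Oddball probability of each block, one entry per distinct block.
    seed
        Seed used to draw the sequence, if it was generated.
    """

    tones: np.ndarray
    block_id: np.ndarray
    block_probs: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.tones = np.asarray(self.tones, dtype=np.int8)
        self.block_id = np.asarray(self.block_id, dtype=np.int64)
        self.block_probs = np.atleast_1d(np.asarray(self.block_probs, dtype=float))
        if self.tones.ndim != 1:
            raise InvalidParameterError("tones must be one-dimensional")
        if self.block_id.shape != self.tones.shape:
            raise InvalidParameterError("block_id must align with tones")
        if not np.isin(self.tones, (0, 1)).all():
            raise InvalidParameterError("tones must be 0 or 1")
        if self.tones.size == 0:
            raise InvalidParameterError("sequence must contain at least one trial")
        if (np.diff(self.block_id) < 0).any():
            raise InvalidParameterError("block_id must be non-decreasing")
        uniq = np.unique(self.block_id)
        if not np.array_equal(uniq, np.arange(uniq.size)):
            raise InvalidParameterError("block ids must be contiguous from 0 (no empty blocks)")
        if self.block_probs.size != uniq.size:
            raise InvalidParameterError("block_probs must have one entry per block")

    @property
    def n_trials(self) -> int:
        return int(self.tones.size)

    @property
    def n_blocks(self) -> int:
        return int(self.block_probs.size)

    def block_slices(self):
        """Yield ``(block, slice)`` pairs covering the session in order."""
        bounds = np.flatnonzero(np.diff(self.block_id)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [self.n_trials]])
        for b, (lo, hi) in enumerate(zip(starts, stops)):
            yield b, slice(int(lo), int(hi))

    # -- serialization ---------------------------------------------------

    def to_files(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.tsv`` (trial_index, tone) and ``<prefix>.json`` sidecar."""
        prefix = Path(prefix)
        table = prefix.with_suffix(".tsv")
        sidecar = prefix.with_suffix(".json")
        pd.DataFrame(
            {"trial_index": np.arange(self.n_trials), "tone": self.tones}
        ).to_csv(table, sep="\t", index=False)
        block_sizes = [int(sl.stop - sl.start) for _, sl in self.block_slices()]
        sidecar.write_text(
            json.dumps(
                {
                    "block_sizes": block_sizes,
                    "block_probs": self.block_probs.tolist(),
                    "seed": self.seed,
                },
                indent=2,
                sort_keys=True,
            )
        )
        return table, sidecar

    @classmethod
    def from_files(cls, prefix: str | Path) -> "OddballSequence":
        prefix = Path(prefix)
        table = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
        meta = json.loads(prefix.with_suffix(".json").read_text())
        block_id = np.repeat(np.arange(len(meta["block_sizes"])), meta["block_sizes"])
        return cls(
            tones=table["tone"].to_numpy(),
            block_id=block_id,
            block_probs=np.asarray(meta["block_probs"]),
            seed=meta.get("seed"),
        )

    @classmethod
    def from_tone_line(cls, line: str, prob: float = 0.5) -> "OddballSequence":
        """Parse a plain ``0``/``1`` character string as a single-block sequence."""
        tones = np.array([int(c) for c in line.strip() if not c.isspace()], dtype=np.int8)
        return cls(tones=tones, block_id=np.zeros(tones.size, dtype=int), block_probs=[prob])


@dataclass
class PredictorSeries:
    """Per-trial values of a surprise/count predictor with a validity mask.

    ``kind`` is one of ``noc`` (counts / opposite-tone counts),
    ``running_prob`` (fraction in [0, 1]), ``ib_surprise`` (bits) or
    ``distance`` (trials since the last oddball).
    """

    kind: str
    values: np.ndarray
    valid: np.ndarray
    N: int | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise InvalidParameterError("values and valid must align")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def masked(self) -> np.ndarray:
        """Values on valid trials only."""
        return self.values[self.valid]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_index": np.arange(self.values.size),
                "valid": self.valid,
                "value": self.values,
            }
        )


def generate_sequence(
    block_probs, trials_per_block: int, seed: int | None = None
) -> OddballSequence:
    """Draw a block-structured Bernoulli oddball sequence.

    Each trial's tone is drawn independently with its block's oddball
    probability; identical seeds give identical sequences.
    """
    block_probs = np.atleast_1d(np.asarray(block_probs, dtype=float))
    if np.any((block_probs <= 0) | (block_probs >= 1)):
        raise InvalidParameterError("block probabilities must lie strictly inside (0, 1)")
    if trials_per_block < 1:
        raise InvalidParameterError("trials_per_block must be >= 1")
    rng = np.random.default_rng(seed)
    tones = (rng.random((block_probs.size, trials_per_block)) < block_probs[:, None]).astype(
        np.int8
    )
    block_id = np.repeat(np.arange(block_probs.size), trials_per_block)
    return OddballSequence(
        tones=tones.ravel(), block_id=block_id, block_probs=block_probs, seed=seed
    )


def _window_scopes(seq: OddballSequence, window_scope: str):
    if window_scope == "block":
        yield from seq.block_slices()
    elif window_scope == "session":
        yield 0, slice(0, seq.n_trials)
    else:
        raise InvalidParameterError(f"unknown window_scope {window_scope!r}")


def oddball_count(
    seq: OddballSequence, N: int, window_scope: str = "block"
) -> PredictorSeries:
    """Number of oddballs among the ``N`` trials immediately preceding each trial.

    The window never crosses a block boundary (with the default
    ``window_scope='block'``); the first ``N`` trials of each block are
    flagged invalid.  If no trial has a full window a warning is emitted
    and the whole series is invalid.
    """
    if N < 1:
        raise InvalidParameterError("N must be >= 1")
    T = seq.n_trials
    values = np.zeros(T)
    valid = np.zeros(T, dtype=bool)
    for _, sl in _window_scopes(seq, window_scope):
        t = seq.tones[sl].astype(np.int64)
        if t.size <= N:
            continue
        csum = np.concatenate([[0], np.cumsum(t)])
        counts = csum[N : t.size] - csum[: t.size - N]
        idx = np.arange(sl.start + N, sl.stop)
        values[idx] = counts
        valid[idx] = True
    if not valid.any():
        warnings.warn(
            f"window length N={N} leaves no trial with a full window", stacklevel=2
        )
    return PredictorSeries(kind="noc", values=values, valid=valid, N=N)


def noc_predictor(
    seq: OddballSequence, N: int, window_scope: str = "block"
) -> PredictorSeries:
    """Opposite-tone count: ``N - n`` on oddball trials, ``n`` on standard trials."""
    counts = oddball_count(seq, N, window_scope)
    values = np.where(seq.tones == 1, N - counts.values, counts.values)
    values[~counts.valid] = 0.0
    return PredictorSeries(kind="noc", values=values, valid=counts.valid, N=N)


def running_probability(
    seq: OddballSequence, N: int, window_scope: str = "block"
) -> PredictorSeries:
    """Opposite-tone running probability ``p = n/N``."""
    pred = noc_predictor(seq, N, window_scope)
    return PredictorSeries(
        kind="running_prob", values=pred.values / N, valid=pred.valid, N=N
    )


def distance_from_last_oddball(seq: OddballSequence) -> PredictorSeries:
    """Trials elapsed since the previous oddball, on oddball trials only.

    Standard trials and the first oddball of each block carry no value
    (``valid = False``).
    """
    T = seq.n_trials
    values = np.full(T, np.nan)
    valid = np.zeros(T, dtype=bool)
    for _, sl in seq.block_slices():
        pos = np.flatnonzero(seq.tones[sl] == 1)
        if pos.size > 1:
            idx = sl.start + pos[1:]
            values[idx] = np.diff(pos)
            valid[idx] = True
    return PredictorSeries(kind="distance", values=values, valid=valid)
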