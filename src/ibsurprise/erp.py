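"""Single-trial P300 area-under-the-curve extraction and surprise-related averaging.

The P300 feature is defined on the mean oddball-minus-standard
difference trace: the peak latency ``t_peak`` is the argmax of the
difference trace between 300 and 500 ms after stimulus onset, and the
integration bounds ``t1 < t_peak < t2`` are the zero crossings of the
trace nearest the peak (located with sub-sample linear interpolation).
The per-trial feature is then the signed trapezoidal integral of each
trial's waveform between ``t1`` and ``t2`` (uV*s).  Per-trial values
are normalised by the AUC of the difference trace itself, which makes
the feature dimensionless and comparable across subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sequence import InvalidParameterError, PredictorSeries

__all__ = [
    "NoPeakError",
    "EpochSet",
    "AUCFeatures",
    "difference_trace",
    "find_auc_window",
    "auc_per_trial",
    "extract_auc",
    "sra",
    "SRAGroup",
    "choose_channel",
]


class NoPeakError(RuntimeError):
    """The difference trace has no positive peak in the search window."""


@dataclass
class EpochSet:
    """Stimulus-locked EEG epochs for one channel.

    ``data`` is trials x samples in uV; ``times`` are sample times in
    seconds relative to stimulus onset on a uniform grid at ``srate``.
    """

    data: np.ndarray
    times: np.ndarray
    srate: float
    tone: np.ndarray
    block_id: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tone = np.asarray(self.tone, dtype=np.int8)
        self.block_id = np.asarray(self.block_id, dtype=np.int64)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be trials x samples")
        if self.times.size != self.data.shape[1]:
            raise InvalidParameterError("times must match the sample axis")
        step = np.diff(self.times)
        if np.any(step <= 0) or not np.allclose(step, 1.0 / self.srate, rtol=1e-6):
            raise InvalidParameterError("times must increase uniformly at 1/srate")
        if self.times[0] > 0 or self.times[-1] < 0.5:
            raise InvalidParameterError("epochs must cover at least [0, 0.5] s")
        if self.tone.size != self.data.shape[0] or self.block_id.size != self.data.shape[0]:
            raise InvalidParameterError("per-trial labels must match the trial axis")

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    def baseline_corrected(self, window: tuple[float, float] = (-0.2, 0.0)) -> "EpochSet":
        """Subtract each trial's mean over the pre-stimulus baseline window."""
        mask = (self.times >= window[0]) & (self.times <= window[1])
        if not mask.any():
            raise InvalidParameterError("baseline window contains no samples")
        base = self.data[:, mask].mean(axis=1, keepdims=True)
        return EpochSet(
            data=self.data - base,
            times=self.times,
            srate=self.srate,
            tone=self.tone,
            block_id=self.block_id,
        )

    # -- serialization ---------------------------------------------------

    def to_files(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.tsv`` (dense trials x samples) and a JSON sidecar."""
        prefix = Path(prefix)
        table = prefix.with_suffix(".tsv")
        sidecar = prefix.with_suffix(".json")
        np.savetxt(table, self.data, delimiter="\t")
        sidecar.write_text(
            json.dumps(
                {
                    "times": self.times.tolist(),
                    "srate": self.srate,
                    "tone": self.tone.tolist(),
                    "block_id": self.block_id.tolist(),
                },
                sort_keys=True,
            )
        )
        return table, sidecar

    @classmethod
    def from_files(cls, prefix: str | Path) -> "EpochSet":
        prefix = Path(prefix)
        data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            data=data,
            times=np.asarray(meta["times"]),
            srate=meta["srate"],
            tone=np.asarray(meta["tone"]),
            block_id=np.asarray(meta["block_id"]),
        )


@dataclass
class AUCFeatures:
    """Per-trial P300 AUC feature with its extraction window.

    ``auc`` is in uV*s; ``auc_norm = auc / norm_constant`` where
    ``norm_constant`` is the AUC of the mean difference trace (so the
    difference trace itself has normalised AUC 1).
    """

    t_peak: float
    t1: float
    t2: float
    auc: np.ndarray
    auc_norm: np.ndarray
    norm_constant: float

    def to_frame(self, tone=None, block_id=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial_index": np.arange(self.auc.size),
                "auc": self.auc,
                "auc_norm": self.auc_norm,
            }
        )
        if tone is not None:
            df.insert(1, "tone", np.asarray(tone))
        if block_id is not None:
            df.insert(2, "block", np.asarray(block_id))
        return df


def difference_trace(epochs: EpochSet) -> np.ndarray:
    """Mean oddball epoch minus mean standard epoch, per sample (uV)."""
    odd = epochs.tone == 1
    if not odd.any() or odd.all():
        raise InvalidParameterError("need at least one oddball and one standard trial")
    return epochs.data[odd].mean(axis=0) - epochs.data[~odd].mean(axis=0)


def _cross_left(diff, times, start):
    """Nearest zero crossing at or before sample ``start`` (sub-sample)."""
    nonpos = np.flatnonzero(diff[: start + 1] <= 0)
    if nonpos.size == 0:
        warnings.warn("no zero crossing before the peak; clipping to epoch edge")
        return float(times[0])
    i = int(nonpos[-1])  # nearest to the peak resolves flat zero runs
    if diff[i] == 0:
        return float(times[i])
    frac = -diff[i] / (diff[i + 1] - diff[i])
    return float(times[i] + frac * (times[i + 1] - times[i]))


def _cross_right(diff, times, start):
    """Nearest zero crossing after sample ``start`` (sub-sample)."""
    rel = np.flatnonzero(diff[start:] <= 0)
    if rel.size == 0:
        warnings.warn("no zero crossing after the peak; clipping to epoch edge")
        return float(times[-1])
    j = start + int(rel[0])
    if diff[j] == 0:
        return float(times[j])
    frac = -diff[j - 1] / (diff[j] - diff[j - 1])
    return float(times[j - 1] + frac * (times[j] - times[j - 1]))


def find_auc_window(
    diff: np.ndarray,
    times: np.ndarray,
    search_lo: float = 0.3,
    search_hi: float = 0.5,
) -> tuple[float, float, float]:
    """Locate the P300 peak and its surrounding zero-crossing bounds.

    ``t_peak`` is the argmax of ``diff`` within ``[search_lo, search_hi]``;
    ``t1``/``t2`` are the zero crossings nearest the peak on either side,
    located by linear interpolation between samples of opposite sign.
    Raises :class:`NoPeakError` if the maximum in the window is not
    positive (the subject-exclusion path).
    """
    diff = np.asarray(diff, dtype=float)
    times = np.asarray(times, dtype=float)
    in_win = np.flatnonzero((times >= search_lo) & (times <= search_hi))
    if in_win.size == 0:
        raise InvalidParameterError("search window contains no samples")
    peak = int(in_win[np.argmax(diff[in_win])])
    if diff[peak] <= 0:
        raise NoPeakError("no positive peak in the search window")
    t1 = _cross_left(diff, times, peak)
    t2 = _cross_right(diff, times, peak)
    return float(times[peak]), t1, t2


def _integrate(data: np.ndarray, times: np.ndarray, t1: float, t2: float) -> np.ndarray:
    """Signed trapezoidal integral of each row between t1 and t2.

    Sub-sample bounds are included via linearly interpolated endpoint
    values on the native grid.
    """
    data = np.atleast_2d(data)
    j1 = int(np.searchsorted(times, t1, side="right"))
    j2 = int(np.searchsorted(times, t2, side="left"))

    def endpoint(t):
        k = int(np.searchsorted(times, t, side="right")) - 1
        k = min(max(k, 0), times.size - 2)
        frac = (t - times[k]) / (times[k + 1] - times[k])
        return data[:, k] + frac * (data[:, k + 1] - data[:, k])

    grid = np.concatenate([[t1], times[j1:j2], [t2]])
    vals = np.column_stack([endpoint(t1), data[:, j1:j2], endpoint(t2)])
    return np.trapezoid(vals, grid, axis=1)


def auc_per_trial(
    epochs: EpochSet, t1: float, t2: float, t_peak: float | None = None
) -> AUCFeatures:
    """Per-trial signed AUC between ``t1`` and ``t2``, normalised by the
    AUC of the mean difference trace over the same window."""
    if not (epochs.times[0] <= t1 < t2 <= epochs.times[-1]):
        raise InvalidParameterError("integration bounds outside the epoch span")
    auc = _integrate(epochs.data, epochs.times, t1, t2)
    diff = difference_trace(epochs)
    norm = float(_integrate(diff, epochs.times, t1, t2)[0])
    return AUCFeatures(
        t_peak=float(t_peak) if t_peak is not None else float("nan"),
        t1=float(t1),
        t2=float(t2),
        auc=auc,
        auc_norm=auc / norm,
        norm_constant=norm,
    )


def extract_auc(
    epochs: EpochSet,
    search_lo: float = 0.3,
    search_hi: float = 0.5,
    baseline: tuple[float, float] | None = (-0.2, 0.0),
) -> AUCFeatures:
    """Full feature path: baseline correction, peak window search, per-trial AUC."""
    if baseline is not None and epochs.times[0] < 0:
        epochs = epochs.baseline_corrected(baseline)
    diff = difference_trace(epochs)
    t_peak, t1, t2 = find_auc_window(diff, epochs.times, search_lo, search_hi)
    return auc_per_trial(epochs, t1, t2, t_peak=t_peak)


@dataclass
class SRAGroup:
    """One surprise-related average: all trials sharing a predictor value."""

    value: float
    mean_waveform: np.ndarray
    count: int


def sra(
    epochs: EpochSet, predictor: PredictorSeries, decimals: int | None = None
) -> list[SRAGroup]:
    """Surprise-related analysis: mean waveform per distinct predictor value.

    Only valid trials enter; ``decimals`` optionally rounds the
    predictor before grouping (coarser surprise bins).
    """
    if predictor.values.size != epochs.n_trials:
        raise InvalidParameterError("predictor must align with epochs")
    vals = predictor.values.copy()
    if decimals is not None:
        vals = np.round(vals, decimals)
    mask = predictor.valid
    if not mask.any():
        warnings.warn("no valid trials for SRA")
        return []
    groups = []
    for v in np.unique(vals[mask]):
        sel = mask & (vals == v)
        groups.append(
            SRAGroup(
                value=float(v),
                mean_waveform=epochs.data[sel].mean(axis=0),
                count=int(sel.sum()),
            )
        )
    return groups


def choose_channel(
    channels: dict[str, EpochSet], search_lo: float = 0.3, search_hi: float = 0.5
) -> str:
    """Pick the channel whose difference trace peaks highest in the search window."""
    def peak(ep: EpochSet) -> float:
        diff = difference_trace(ep)
        win = (ep.times >= search_lo) & (ep.times <= search_hi)
        return float(diff[win].max())

    return max(channels, key=lambda name: peak(channels[name]))
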