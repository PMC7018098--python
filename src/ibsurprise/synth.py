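"""Synthetic subjects with known ground truth.

The generator emulates the study conditions of the auditory oddball
protocol: 5 blocks of 240 trials with oddball probabilities 0.1-0.5,
per-trial P300 AUC values that are linear in a chosen model's surprise
predictor plus Gaussian noise, and (optionally) epoched waveforms in
which each trial's AUC is rendered as a Gaussian-shaped positive
deflection near 400 ms on a 256 Hz grid.

Randomness is split into independent seeded streams (sequence draw,
AUC noise, waveform noise) spawned from one subject seed, so changing
one source leaves the others bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .erp import EpochSet
from .fitting import IBCache, asymptotic_weights
from .ib import build_joint, ib_surprise, solve_ib
from .sequence import (
    InvalidParameterError,
    OddballSequence,
    PredictorSeries,
    generate_sequence,
    noc_predictor,
)

__all__ = [
    "WaveformSpec",
    "SubjectSpec",
    "SyntheticSubject",
    "true_predictor",
    "generate_auc_subject",
    "generate_waveform_subject",
    "calibrate_noise_sd",
]


@dataclass(frozen=True)
class WaveformSpec:
    """How to render per-trial AUC targets as epoched waveforms."""

    srate: float = 256.0
    tmin: float = -0.2
    tmax: float = 0.9
    bump_center: float = 0.4  # inside [0.3, 0.5] so the peak search finds it
    bump_width: float = 0.03  # Gaussian sd, s
    noise_sd_wave: float = 0.0  # white noise per sample, uV

    def __post_init__(self):
        if not (0.3 <= self.bump_center <= 0.5):
            raise InvalidParameterError("bump_center must lie in [0.3, 0.5] s")
        if self.bump_center - 4 * self.bump_width < self.tmin or (
            self.bump_center + 4 * self.bump_width > self.tmax
        ):
            raise InvalidParameterError("bump extends beyond the epoch span")


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth description of one synthetic subject.

    Defaults mirror the study conditions: an IB observer with N = 11,
    beta = 48.33 and slope 0.93 uV*s/bit on a 5 x 240-trial session
    with block oddball probabilities 0.1-0.5.
    """

    true_model: str = "ib"  # "noc" or "ib"
    true_N: int = 11
    true_beta: float = 48.33
    slope: float = 0.93  # uV*s per predictor unit (per bit for ib)
    intercept: float = 0.0  # uV*s
    noise_sd: float = 0.4  # uV*s, sd of additive Gaussian AUC noise
    block_probs: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    trials_per_block: int = 240
    seed: int = 0
    waveform: WaveformSpec | None = None

    def __post_init__(self):
        if self.true_model not in ("noc", "ib"):
            raise InvalidParameterError("true_model must be 'noc' or 'ib'")
        if self.true_N < 1:
            raise InvalidParameterError("true_N must be >= 1")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        if not np.isfinite(self.slope):
            raise InvalidParameterError("slope must be finite")


@dataclass
class SyntheticSubject:
    """A generated subject: sequence, per-trial AUC and the true predictor."""

    spec: SubjectSpec
    seq: OddballSequence
    auc: np.ndarray
    predictor: PredictorSeries


def _child_seeds(seed: int) -> tuple[int, int, int]:
    """(sequence, auc-noise, waveform-noise) seeds spawned from one subject seed."""
    ss = np.random.SeedSequence(seed)
    seq_ss, auc_ss, wave_ss = ss.spawn(3)
    return (
        int(seq_ss.generate_state(1)[0] % (2**31)),
        int(auc_ss.generate_state(1)[0] % (2**31)),
        int(wave_ss.generate_state(1)[0] % (2**31)),
    )


def true_predictor(
    spec: SubjectSpec, seq: OddballSequence, cache: IBCache | None = None
) -> PredictorSeries:
    """The generative predictor series of a spec on a given sequence."""
    if spec.true_model == "noc":
        return noc_predictor(seq, spec.true_N)
    if cache is not None:
        sol = cache.solution(spec.true_N, spec.true_beta)
    else:
        sol = solve_ib(build_joint(spec.true_N), spec.true_beta)
    return ib_surprise(sol, seq)


def generate_auc_subject(
    spec: SubjectSpec, cache: IBCache | None = None
) -> SyntheticSubject:
    """Sequence plus per-trial AUC linear in the true model's predictor.

    ``AUC_t = intercept + slope * predictor_t + eps_t`` with i.i.d.
    Gaussian noise on valid trials; invalid trials (incomplete window)
    carry intercept-plus-noise only and are flagged by the predictor's
    validity mask.
    """
    seq_seed, auc_seed, _ = _child_seeds(spec.seed)
    seq = generate_sequence(spec.block_probs, spec.trials_per_block, seed=seq_seed)
    pred = true_predictor(spec, seq, cache)
    rng = np.random.default_rng(auc_seed)
    noise = rng.normal(0.0, spec.noise_sd, size=seq.n_trials)
    auc = spec.intercept + noise
    auc[pred.valid] += spec.slope * pred.values[pred.valid]
    return SyntheticSubject(spec=spec, seq=seq, auc=auc, predictor=pred)


def generate_waveform_subject(
    spec: SubjectSpec, cache: IBCache | None = None
) -> tuple[EpochSet, SyntheticSubject]:
    """Render a subject's per-trial AUC targets as epoched waveforms.

    Each epoch is a Gaussian bump whose time-integral equals that
    trial's target AUC (the bump is parameterised by its integral, so
    the target is exact by construction), plus optional white noise.
    """
    if spec.waveform is None:
        raise InvalidParameterError("spec has no waveform sub-spec")
    wf = spec.waveform
    subj = generate_auc_subject(spec, cache)
    _, _, wave_seed = _child_seeds(spec.seed)
    rng = np.random.default_rng(wave_seed)

    n_samp = int(round((wf.tmax - wf.tmin) * wf.srate)) + 1
    times = wf.tmin + np.arange(n_samp) / wf.srate
    shape = np.exp(-0.5 * ((times - wf.bump_center) / wf.bump_width) ** 2)
    shape = shape / (wf.bump_width * np.sqrt(2 * np.pi))  # unit integral
    data = subj.auc[:, None] * shape[None, :]
    if wf.noise_sd_wave > 0:
        data = data + rng.normal(0.0, wf.noise_sd_wave, size=data.shape)
    epochs = EpochSet(
        data=data,
        times=times,
        srate=wf.srate,
        tone=subj.seq.tones,
        block_id=subj.seq.block_id,
    )
    return epochs, subj


def calibrate_noise_sd(
    spec: SubjectSpec, target_r2: float, cache: IBCache | None = None
) -> float:
    """Noise level that puts the expected single-trial weighted R2 at a target.

    Under the linear response model the expected weighted R2 is
    ``slope^2 V_w / (slope^2 V_w + sigma^2)`` with ``V_w`` the
    inverse-probability-weighted variance of the true predictor on this
    subject's sequence; inverting gives
    ``sigma = |slope| * sqrt(V_w (1/R2 - 1))``.
    """
    if not (0 < target_r2 < 1):
        raise InvalidParameterError("target_r2 must lie in (0, 1)")
    seq_seed, _, _ = _child_seeds(spec.seed)
    seq = generate_sequence(spec.block_probs, spec.trials_per_block, seed=seq_seed)
    pred = true_predictor(spec, seq, cache)
    joint = build_joint(spec.true_N)
    if spec.true_model == "noc":
        wmap = asymptotic_weights(pred, joint)
        x = pred.masked()
    else:
        if cache is not None:
            sol = cache.solution(spec.true_N, spec.true_beta)
        else:
            sol = solve_ib(joint, spec.true_beta)
        from .fitting import bin_surprise

        wmap = asymptotic_weights(pred, joint, sol)
        x = bin_surprise(pred.masked())
    w = np.array([wmap[float(v)] for v in x])
    xbar = np.average(x, weights=w)
    v_w = np.average((x - xbar) ** 2, weights=w)
    return float(abs(spec.slope) * np.sqrt(v_w * (1.0 / target_r2 - 1.0)))
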