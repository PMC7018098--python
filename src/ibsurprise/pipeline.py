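"""End-to-end orchestration: data (synthetic or supplied) -> features -> fits -> capacity.

``run_subject`` takes one :class:`RunConfig`, generates or loads the
subject's data, extracts the P300 AUC feature when waveforms are
involved, grid-searches both surprise models (plus the
distance-from-last-oddball baseline), optionally runs the permutation
test, and writes result tables and a deterministic JSON manifest.
``run_cohort`` maps over subjects and pools them with
:func:`ibsurprise.fitting.multi_subject_summary`.

All randomness derives from one master seed via named substreams, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .erp import EpochSet, NoPeakError, extract_auc, sra
from .fitting import (
    FitResult,
    IBCache,
    SubjectData,
    default_beta_grid,
    default_n_grid,
    grid_search,
    multi_subject_summary,
    permutation_test,
)
from .ib import ib_surprise
from .sequence import InvalidParameterError, OddballSequence
from .synth import SubjectSpec, generate_auc_subject, generate_waveform_subject

__all__ = ["RunConfig", "SubjectResult", "CohortResult", "run_subject", "run_cohort"]


@dataclass
class RunConfig:
    """One subject run: input, grids, significance settings and toggles."""

    spec: SubjectSpec | None = None  # synthetic input
    epochs: EpochSet | None = None  # or user-supplied epochs...
    seq: OddballSequence | None = None  # ...with their stimulus sequence
    auc: np.ndarray | None = None  # or a precomputed feature series
    N_grid: np.ndarray | None = None
    beta_grid: np.ndarray | None = None
    n_perm: int = 0  # 0 = skip significance testing
    seed: int = 0
    out_dir: str | Path | None = None
    window_scope: str = "block"
    baseline: tuple[float, float] | None = (-0.2, 0.0)
    label: str = "subject0"

    def resolved_grids(self):
        N_grid = self.N_grid if self.N_grid is not None else default_n_grid()
        beta_grid = self.beta_grid if self.beta_grid is not None else default_beta_grid()
        return np.asarray(N_grid), np.asarray(beta_grid, dtype=float)

    def digest(self) -> str:
        """Stable hash of the run configuration (for the manifest)."""
        N_grid, beta_grid = self.resolved_grids()
        payload = {
            "spec": None if self.spec is None else _spec_dict(self.spec),
            "N_grid": N_grid.tolist(),
            "beta_grid": beta_grid.tolist(),
            "n_perm": self.n_perm,
            "seed": self.seed,
            "window_scope": self.window_scope,
            "baseline": self.baseline,
            "label": self.label,
            "has_epochs": self.epochs is not None,
            "has_auc": self.auc is not None,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spec_dict(spec: SubjectSpec) -> dict:
    d = asdict(spec)
    d["block_probs"] = list(d["block_probs"])
    return d


@dataclass
class SubjectResult:
    """Everything computed for one subject."""

    label: str
    excluded: bool
    reason: str | None
    seq: OddballSequence | None
    auc: np.ndarray | None
    auc_norm: np.ndarray | None
    noc_fit: FitResult | None
    ib_fit: FitResult | None
    distance_fit: FitResult | None
    r2_map_noc: pd.DataFrame | None
    r2_map_ib: pd.DataFrame | None
    sra_groups: list | None
    manifest: dict


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    summary: object | None  # PooledSummary when >= 1 subject survived


def _normalize_auc(auc: np.ndarray, seq: OddballSequence) -> tuple[np.ndarray, float]:
    """Per-subject normalisation by the oddball-minus-standard mean AUC.

    For feature-table input there is no difference trace; its AUC equals
    the mean per-trial AUC of oddballs minus that of standards, which is
    used as the normalisation constant.
    """
    odd = seq.tones == 1
    norm = float(auc[odd].mean() - auc[~odd].mean())
    if norm == 0:
        raise NoPeakError("zero oddball-minus-standard contrast; cannot normalize")
    return auc / norm, norm


def run_subject(config: RunConfig, cache: IBCache | None = None) -> SubjectResult:
    """Run the full single-subject analysis described by ``config``.

    An extraction failure (no positive P300 peak) marks the subject as
    excluded in the manifest instead of raising, mirroring the
    subject-exclusion rule; other inputs are analysed normally.
    """
    if cache is None:
        cache = IBCache()
    N_grid, beta_grid = config.resolved_grids()
    manifest: dict = {
        "label": config.label,
        "config_digest": config.digest(),
        "package_version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "grid_size": {"N": int(len(N_grid)), "beta": int(len(beta_grid))},
    }

    seq = config.seq
    auc = config.auc
    epochs = config.epochs
    sra_groups = None
    norm_const = None

    try:
        if config.spec is not None:
            if config.spec.waveform is not None:
                epochs, subj = generate_waveform_subject(config.spec, cache)
                seq = subj.seq
            else:
                subj = generate_auc_subject(config.spec, cache)
                seq, auc = subj.seq, subj.auc
        if seq is None:
            raise InvalidParameterError("config provides no stimulus sequence")
        if epochs is not None:
            feats = extract_auc(epochs, baseline=config.baseline)
            auc = feats.auc
            norm_const = feats.norm_constant
            auc_norm = feats.auc_norm
        elif auc is not None:
            auc = np.asarray(auc, dtype=float)
            auc_norm, norm_const = _normalize_auc(auc, seq)
        else:
            raise InvalidParameterError("config provides neither epochs nor AUC values")
    except NoPeakError as err:
        manifest["excluded"] = True
        manifest["reason"] = str(err)
        return SubjectResult(
            label=config.label,
            excluded=True,
            reason=str(err),
            seq=seq,
            auc=None,
            auc_norm=None,
            noc_fit=None,
            ib_fit=None,
            distance_fit=None,
            r2_map_noc=None,
            r2_map_ib=None,
            sra_groups=None,
            manifest=manifest,
        )

    noc_fit, r2_map_noc = grid_search(
        auc, seq, "noc", N_grid, cache=cache, window_scope=config.window_scope
    )
    ib_fit, r2_map_ib = grid_search(
        auc, seq, "ib", N_grid, beta_grid, cache=cache, window_scope=config.window_scope
    )
    try:
        distance_fit, _ = grid_search(auc, seq, "distance")
    except (InvalidParameterError, ValueError):
        distance_fit = None

    null_noc = null_ib = None
    if config.n_perm > 0:
        _, null_noc, noc_fit = permutation_test(
            auc, seq, "noc", N_grid, n_perm=config.n_perm,
            seed=config.seed, cache=cache, window_scope=config.window_scope,
        )
        _, null_ib, ib_fit = permutation_test(
            auc, seq, "ib", N_grid, beta_grid, n_perm=config.n_perm,
            seed=config.seed + 1, cache=cache, window_scope=config.window_scope,
        )

    if epochs is not None:
        sol = cache.solution(ib_fit.N, ib_fit.beta)
        surp = ib_surprise(sol, seq, window_scope=config.window_scope)
        sra_groups = sra(epochs, surp, decimals=2)

    manifest.update(
        {
            "excluded": False,
            "n_trials": int(seq.n_trials),
            "norm_constant": norm_const,
            "cache": {"hits": cache.hits, "misses": cache.misses,
                      "unconverged": cache.n_unconverged},
            "fits": {
                "noc": noc_fit.to_dict(),
                "ib": ib_fit.to_dict(),
                "distance": None if distance_fit is None else distance_fit.to_dict(),
            },
        }
    )

    result = SubjectResult(
        label=config.label,
        excluded=False,
        reason=None,
        seq=seq,
        auc=auc,
        auc_norm=auc_norm,
        noc_fit=noc_fit,
        ib_fit=ib_fit,
        distance_fit=distance_fit,
        r2_map_noc=r2_map_noc,
        r2_map_ib=r2_map_ib,
        sra_groups=sra_groups,
        manifest=manifest,
    )
    if config.out_dir is not None:
        _export(result, config, null_noc, null_ib)
    return result


def _export(result: SubjectResult, config: RunConfig, null_noc, null_ib) -> None:
    out = Path(config.out_dir) / result.label
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    if result.excluded:
        return
    result.seq.to_files(out / "sequence")
    pd.DataFrame(
        {
            "trial_index": np.arange(result.seq.n_trials),
            "tone": result.seq.tones,
            "block": result.seq.block_id,
            "auc": result.auc,
            "auc_norm": result.auc_norm,
        }
    ).to_csv(out / "features.tsv", sep="\t", index=False)
    fits = pd.DataFrame(
        [f.to_dict() for f in (result.noc_fit, result.ib_fit, result.distance_fit) if f]
    )
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    result.r2_map_noc.to_csv(out / "r2_map_noc.tsv", sep="\t", index=False)
    result.r2_map_ib.to_csv(out / "r2_map_ib.tsv", sep="\t", index=False)
    for name, null in (("null_noc.tsv", null_noc), ("null_ib.tsv", null_ib)):
        if null is not None:
            pd.DataFrame({"max_weighted_r2": null}).to_csv(out / name, sep="\t", index=False)


def run_cohort(configs: list[RunConfig], cache: IBCache | None = None) -> CohortResult:
    """Run every subject, then pool the survivors.

    Degenerate cohorts never crash: if every subject is excluded the
    summary is ``None`` and each manifest names its failure mode.
    """
    if cache is None:
        cache = IBCache()
    results = [run_subject(c, cache) for c in configs]
    kept = [r for r in results if not r.excluded]
    if not kept:
        warnings.warn("all subjects excluded; no pooled summary")
        return CohortResult(subjects=results, summary=None)
    subjects = [
        SubjectData(
            seq=r.seq, auc_norm=r.auc_norm, noc_fit=r.noc_fit, ib_fit=r.ib_fit,
            label=r.label,
        )
        for r in kept
    ]
    summary = multi_subject_summary(subjects, cache=cache)
    return CohortResult(subjects=results, summary=summary)
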