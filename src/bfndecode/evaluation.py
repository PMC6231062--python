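"""Scoring of decoded trajectories and the cross-validation protocol.

Decoded series are smoothed with a zero-phase 4th-order Butterworth low-pass
(1 Hz) before scoring; per-axis Pearson correlations are averaged into a
subject-level score.  ``cross_validate`` runs seeded repeated k-fold
validation over trials with arbitrary fit/predict callables, and the
reference-range ROC binarizes both series by their central 95% interval and
scores the agreement by AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from bfndecode._utils import as_1d_float
from bfndecode.decoder import DecodedTrajectory

AXES = ("x", "y", "z")


@dataclass
class AxisScores:
    R_x: float
    R_y: float
    R_z: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.R_x, self.R_y, self.R_z)


@dataclass
class SubjectScore:
    R: float
    axis_scores: AxisScores | None = None
    provenance: dict = field(default_factory=dict)


@dataclass
class FoldPlan:
    runs: int = 10
    folds: int = 10
    seed: int = 0

    def assignments(self, n_trials: int) -> list[list[np.ndarray]]:
        """Per-run fold memberships (lists of trial-index arrays), seeded."""
        if self.folds > n_trials:
            raise ValueError(f"{self.folds} folds but only {n_trials} trials")
        rng = np.random.default_rng(self.seed)
        plans = []
        for _ in range(self.runs):
            perm = rng.permutation(n_trials)
            plans.append([np.sort(fold) for fold in np.array_split(perm, self.folds)])
        return plans


@dataclass
class ROCResult:
    auc: float
    lower: float
    upper: float


def smooth_decoded(
    decoded: DecodedTrajectory, rate: float, order: int = 4, cutoff_hz: float = 1.0
) -> DecodedTrajectory:
    """Zero-phase Butterworth low-pass smoothing of each decoded axis.

    NaN head samples (missing lag history) are preserved; series too short
    for the filter are returned unchanged with a warning.
    """
    if rate <= 2 * cutoff_hz:
        raise ValueError(f"rate {rate} Hz too low for a {cutoff_hz} Hz cutoff")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    out = []
    for arr in (decoded.x, decoded.y, decoded.z):
        arr = np.asarray(arr, dtype=float)
        finite = np.isfinite(arr)
        seg = arr[finite]
        if len(seg) < 3 * (order + 1):
            warnings.warn("series too short to smooth; returned unfiltered")
            out.append(arr.copy())
            continue
        sm = arr.copy()
        sm[finite] = signal.sosfiltfilt(sos, seg)
        out.append(sm)
    return DecodedTrajectory(times=decoded.times, x=out[0], y=out[1], z=out[2])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if len(a) < 3:
        raise ValueError("need at least 3 paired finite samples")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in one series; correlation undefined")
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def axis_pcc(measured, decoded) -> AxisScores:
    """Per-axis Pearson correlation between measured and decoded series.

    Accepts (3, T) arrays or trajectory-like objects with x/y/z; pairs with
    missing decoded samples (NaN lag-history head) are dropped.
    """
    m = measured.xyz if hasattr(measured, "xyz") else np.asarray(measured, dtype=float)
    d = decoded.xyz if hasattr(decoded, "xyz") else np.asarray(decoded, dtype=float)
    if m.shape != d.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {d.shape}")
    return AxisScores(*(_pearson(m[i], d[i]) for i in range(3)))


def subject_score(axis_scores: AxisScores | tuple) -> SubjectScore:
    """Mean of the three axis correlations."""
    vals = axis_scores.as_tuple() if isinstance(axis_scores, AxisScores) else tuple(axis_scores)
    arr = np.asarray(vals, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected exactly three axis scores")
    if not np.all(np.isfinite(arr)):
        return SubjectScore(R=np.nan, axis_scores=None)
    scores = axis_scores if isinstance(axis_scores, AxisScores) else AxisScores(*vals)
    return SubjectScore(R=float(arr.mean()), axis_scores=scores)


def aggregate_scores(subject_scores) -> float:
    """Arithmetic mean of subject-level R values."""
    vals = [s.R if isinstance(s, SubjectScore) else float(s) for s in subject_scores]
    if not vals:
        raise ValueError("no scores to aggregate")
    return float(np.mean(vals))


def cross_validate(
    trials: list,
    fit_fn,
    predict_fn,
    foldplan: FoldPlan | None = None,
    rate: float = 100.0,
    smooth: bool = True,
) -> dict:
    """Seeded repeated k-fold cross-validation over trials.

    Per run the trials are permuted and split into folds; each fold is
    decoded by a model fitted on the others and scored axis-wise against the
    measured trajectory (after smoothing).  Returns per-(run, fold) scores
    plus their mean and SD.  Pooling several subjects' trials into one list
    realizes the pooled-dataset protocol.
    """
    plan = foldplan or FoldPlan()
    assignments = plan.assignments(len(trials))
    fold_scores: list[SubjectScore] = []
    for run, folds in enumerate(assignments):
        for fold_id, test_idx in enumerate(folds):
            if len(test_idx) == 0:
                continue
            train = [t for i, t in enumerate(trials) if i not in set(test_idx.tolist())]
            model = fit_fn(train)
            axis_vals = []
            for i in test_idx:
                decoded = predict_fn(model, trials[i])
                if smooth:
                    decoded = smooth_decoded(decoded, rate=rate)
                axis_vals.append(axis_pcc(trials[i].trajectory, decoded).as_tuple())
            mean_axes = AxisScores(*np.mean(axis_vals, axis=0))
            ss = subject_score(mean_axes)
            ss.provenance = {"run": run, "fold": fold_id, "trials": test_idx.tolist()}
            fold_scores.append(ss)
    rs = np.array([s.R for s in fold_scores])
    return {
        "fold_scores": fold_scores,
        "mean_R": float(np.nanmean(rs)),
        "sd_R": float(np.nanstd(rs, ddof=1)) if len(rs) > 1 else 0.0,
    }


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the tie-adjusted rank-sum probability (Mann-Whitney)."""
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_reference_range(measured, decoded, coverage: float = 0.95) -> ROCResult:
    """Reference-range agreement AUC between measured and decoded series.

    Points of the measured series outside its central ``coverage`` interval
    are labelled abnormal (1); the decoded series is binarized by its own
    central interval and used as the score.  AUC is the probability that an
    abnormal measured point carries the higher decoded flag.
    """
    m = as_1d_float(measured, "measured")
    d = as_1d_float(decoded, "decoded")
    if m.shape != d.shape:
        raise ValueError("measured and decoded must have equal lengths")
    mask = np.isfinite(m) & np.isfinite(d)
    m, d = m[mask], d[mask]
    if m.std() == 0 or d.std() == 0:
        raise ValueError("degenerate (constant) series")
    tail = (1 - coverage) / 2 * 100
    lo_m, hi_m = np.percentile(m, [tail, 100 - tail])
    lo_d, hi_d = np.percentile(d, [tail, 100 - tail])
    labels = ((m < lo_m) | (m > hi_m)).astype(int)
    flags = ((d < lo_d) | (d > hi_d)).astype(int)
    auc = _rank_auc(labels, flags)
    return ROCResult(auc=auc, lower=float(lo_m), upper=float(hi_m))
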