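"""Two-level linear trajectory decoding from lagged EEG.

Level 1 regresses each hand coordinate on lagged EEG from the characteristic
electrodes.  Level 2 lets per-epoch network covariates (clustering
coefficient and average path length of the band networks, over a short epoch
history) modulate both the intercept and every lag slope.  Substituting
level 2 into level 1 yields a single composite linear model whose predictors
are the lagged EEG samples, the across-band covariate means, and all
EEG x covariate interaction terms; it is fitted per axis by ridge least
squares with the penalty chosen on an inner held-out split.  The
multiple-linear-regression baseline is the same design without any level-2
block.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from bfndecode.io import SyncedTrial

#: Characteristic electrodes selected by the network analysis.
CHARACTERISTIC_ELECTRODES = ("F4", "F8", "C3", "CZ", "C4", "CP4", "T3", "T4")

#: Characteristic bands selected by the network analysis.
CHARACTERISTIC_BANDS = ("delta", "theta", "gamma1")

AXES = ("x", "y", "z")

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-3, 3, 7))


@dataclass(frozen=True)
class Level1Spec:
    """Lagged-EEG regression structure: which electrodes, how many lags."""

    electrodes: tuple[str, ...] = CHARACTERISTIC_ELECTRODES
    n_lags: int = 10  # lags 0..n_lags at the analysis rate
    analysis_rate: float = 100.0

    def __post_init__(self) -> None:
        if self.n_lags < 0:
            raise ValueError("n_lags must be >= 0")
        if not self.electrodes:
            raise ValueError("electrode list must be non-empty")


@dataclass(frozen=True)
class Level2Spec:
    """Network-covariate structure: bands and epoch-history depth."""

    bands: tuple[str, ...] = CHARACTERISTIC_BANDS
    n_history: int = 3  # epochs 0..n_history before the current one

    def __post_init__(self) -> None:
        if self.n_history < 0:
            raise ValueError("n_history must be >= 0")


def design_width(n_electrodes: int, l1: int, n_bands: int, l2: int) -> int:
    """Composite predictor count: intercept + covariate means + lags + interactions."""
    lag_cols = n_electrodes * (l1 + 1)
    return 1 + 2 * (l2 + 1) + lag_cols + lag_cols * 2 * n_bands * (l2 + 1)


@dataclass
class _Blocks:
    """Raw (pre-standardization) design blocks for one trial."""

    slag: np.ndarray  # (T, N*(L1+1))
    cov_int: np.ndarray | None  # (T, 2*(L2+1)) across-band means, or None for MLR
    cov_band: np.ndarray | None  # (T, 2*|bands|*(L2+1)), or None for MLR
    y: np.ndarray  # (T, 3)
    times: np.ndarray
    valid: np.ndarray  # bool (T,)


def _epoch_indices(trial: SyncedTrial) -> np.ndarray:
    if not trial.epochs or trial.unit_s is None:
        raise ValueError("trial has no epochs; run epoch() first")
    t0 = trial.epochs[0][0]
    idx = np.floor((trial.trajectory.times - t0) / trial.unit_s + 1e-9).astype(int)
    idx[(idx < 0) | (idx >= len(trial.epochs))] = -1
    return idx


def _trial_blocks(
    trial: SyncedTrial, l1spec: Level1Spec, l2spec: Level2Spec | None
) -> _Blocks:
    if trial.eeg_analysis is None:
        raise ValueError("trial has no analysis-rate EEG; run synchronize() first")
    labels = trial.eeg.channel_labels
    try:
        rows = [labels.index(e) for e in l1spec.electrodes]
    except ValueError as err:
        raise ValueError(f"electrode missing from trial: {err}") from None
    S = trial.eeg_analysis[rows]
    T = min(S.shape[1], len(trial.trajectory.times))
    S = S[:, :T]
    y = trial.trajectory.xyz.T[:T]
    times = trial.trajectory.times[:T]

    L1 = l1spec.n_lags
    N = len(rows)
    slag = np.zeros((T, N * (L1 + 1)))
    for n in range(N):
        for s in range(L1 + 1):
            slag[s:, n * (L1 + 1) + s] = S[n, : T - s]
    valid = np.arange(T) >= L1
    if trial.epochs:  # both decoders train on the epoched region only
        valid &= _epoch_indices(trial)[:T] >= 0

    cov_int = cov_band = None
    if l2spec is not None:
        e_idx = _epoch_indices(trial)[:T]
        L2 = l2spec.n_history
        valid &= e_idx >= L2
        if trial.features is None:
            raise ValueError("trial has no network features; run compute_trial_features()")
        n_ep = len(trial.epochs)
        nb = len(l2spec.bands)
        C = np.zeros((n_ep, nb))
        P = np.zeros((n_ep, nb))
        for ep in range(n_ep):
            feats = trial.features.get(ep, {})
            for bi, b in enumerate(l2spec.bands):
                if b not in feats:
                    raise ValueError(f"missing network features for (epoch {ep}, band {b})")
                C[ep, bi] = feats[b].Cluster
                P[ep, bi] = feats[b].VPLength
        e_hist = np.clip(e_idx, 0, None)
        cov_int = np.zeros((T, 2 * (L2 + 1)))
        cov_band = np.zeros((T, 2 * nb * (L2 + 1)))
        for k in range(L2 + 1):
            ep_k = np.clip(e_hist - k, 0, n_ep - 1)
            cov_int[:, 2 * k] = C[ep_k].mean(axis=1)
            cov_int[:, 2 * k + 1] = P[ep_k].mean(axis=1)
            for bi in range(nb):
                base = 2 * (bi * (L2 + 1) + k)
                cov_band[:, base] = C[ep_k, bi]
                cov_band[:, base + 1] = P[ep_k, bi]

    if not valid.any():
        warnings.warn("trial too short for the requested lag/epoch history; empty design")
    return _Blocks(slag=slag, cov_int=cov_int, cov_band=cov_band, y=y, times=times, valid=valid)


def _robust_std(arr: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Column SD with numerically-constant columns snapped to exactly 0."""
    if len(arr) == 0:
        return np.zeros(arr.shape[1])
    std = arr.std(axis=0)
    tol = 1e-10 * (np.abs(mean) + 1.0)
    return np.where(std > tol, std, 0.0)


def _assemble(blocks: list[_Blocks], l2: bool, stats: dict | None = None):
    """Stack trials into a standardized design matrix (and fit stats).

    Band covariates are standardized before forming interactions, so a
    covariate that is constant over the training rows produces identically
    zero interaction columns instead of duplicating the lag block; every
    final column is then standardized itself (zero-variance columns are
    zeroed).  ``stats`` from a fit are reused verbatim at prediction time.
    """
    slag = np.vstack([b.slag[b.valid] for b in blocks])
    y = np.vstack([b.y[b.valid] for b in blocks])
    if l2:
        cov_int = np.vstack([b.cov_int[b.valid] for b in blocks])
        cov_band = np.vstack([b.cov_band[b.valid] for b in blocks])
        if stats is None:
            cb_mean = (
                cov_band.mean(axis=0) if len(cov_band) else np.zeros(cov_band.shape[1])
            )
            cb_std = _robust_std(cov_band, cb_mean)
        else:
            cb_mean, cb_std = stats["cov_band_mean"], stats["cov_band_std"]
        scale = np.where(cb_std > 0, cb_std, 1.0)
        cov_band_z = np.where(cb_std > 0, (cov_band - cb_mean) / scale, 0.0)
        inter = (slag[:, :, None] * cov_band_z[:, None, :]).reshape(
            len(slag), slag.shape[1] * cov_band_z.shape[1]
        )
        raw = np.hstack([cov_int, slag, inter])
    else:
        cb_mean = cb_std = None
        raw = slag

    if stats is None:
        col_mean = raw.mean(axis=0) if len(raw) else np.zeros(raw.shape[1])
        col_std = _robust_std(raw, col_mean)
        stats = {
            "cov_band_mean": cb_mean,
            "cov_band_std": cb_std,
            "col_mean": col_mean,
            "col_std": col_std,
        }
    col_mean, col_std = stats["col_mean"], stats["col_std"]
    scale = np.where(col_std > 0, col_std, 1.0)
    Z = np.where(col_std > 0, (raw - col_mean) / scale, 0.0)
    X = np.hstack([np.ones((len(Z), 1)), Z])
    return X, y, stats


def ridge_solve(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Ridge least squares; the first (intercept) column is unpenalized."""
    p = X.shape[1]
    pen = np.full(p, float(lam))
    pen[0] = 0.0
    xtx = X.T @ X + np.diag(pen)
    try:
        return np.linalg.solve(xtx, X.T @ Y)
    except np.linalg.LinAlgError:
        if lam == 0:
            raise np.linalg.LinAlgError(
                "design is rank deficient with lambda=0; request lambda > 0"
            ) from None
        raise


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class _LinearDecoder:
    """Fitted composite decoder (shared by the HLM and MLR variants)."""

    l1spec: Level1Spec
    l2spec: Level2Spec | None
    betas: np.ndarray  # (p+1, 3) in standardized-column space
    stats: dict
    lam: float
    residual_var: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_columns(self) -> int:
        return self.betas.shape[0]

    def raw_coefficients(self, axis: int) -> tuple[float, np.ndarray]:
        """(intercept, slopes) on the pre-standardization feature scale."""
        beta = self.betas[:, axis]
        std = self.stats["col_std"]
        mean = self.stats["col_mean"]
        scale = np.where(std > 0, std, 1.0)
        slopes = np.where(std > 0, beta[1:] / scale, 0.0)
        intercept = beta[0] - float((slopes * mean).sum())
        return intercept, slopes

    def to_json(self) -> str:
        payload = {
            "version": 1,
            "kind": "hlm" if self.l2spec is not None else "mlr",
            "l1": {
                "electrodes": list(self.l1spec.electrodes),
                "n_lags": self.l1spec.n_lags,
                "analysis_rate": self.l1spec.analysis_rate,
            },
            "l2": None
            if self.l2spec is None
            else {"bands": list(self.l2spec.bands), "n_history": self.l2spec.n_history},
            "lambda": self.lam,
            "betas": self.betas.tolist(),
            "residual_var": self.residual_var.tolist(),
            "stats": {
                k: (None if v is None else np.asarray(v).tolist())
                for k, v in self.stats.items()
            },
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "_LinearDecoder":
        d = json.loads(text)
        l1 = Level1Spec(tuple(d["l1"]["electrodes"]), d["l1"]["n_lags"], d["l1"]["analysis_rate"])
        l2 = None
        if d["l2"] is not None:
            l2 = Level2Spec(tuple(d["l2"]["bands"]), d["l2"]["n_history"])
        stats = {
            k: (None if v is None else np.asarray(v, dtype=float))
            for k, v in d["stats"].items()
        }
        klass = HLMModel if l2 is not None else MLRModel
        return klass(
            l1spec=l1,
            l2spec=l2,
            betas=np.asarray(d["betas"], dtype=float),
            stats=stats,
            lam=d["lambda"],
            residual_var=np.asarray(d["residual_var"], dtype=float),
        )


class HLMModel(_LinearDecoder):
    """Hierarchical (network-modulated) composite decoder."""


class MLRModel(_LinearDecoder):
    """Plain lagged multiple-linear-regression decoder."""


@dataclass
class DecodedTrajectory:
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    @property
    def xyz(self) -> np.ndarray:
        return np.vstack([self.x, self.y, self.z])


def build_design(
    trial: SyncedTrial, l1spec: Level1Spec, l2spec: Level2Spec | None
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized composite design and targets for one trial (self-statistics).

    Mainly a convenience for inspection and tests; fitting standardizes over
    the full training split instead.
    """
    blocks = _trial_blocks(trial, l1spec, l2spec)
    X, y, _ = _assemble([blocks], l2=l2spec is not None)
    return X, y


def _fit(
    trials: list[SyncedTrial],
    l1spec: Level1Spec,
    l2spec: Level2Spec | None,
    lam_grid=DEFAULT_LAMBDA_GRID,
    lam: float | None = None,
) -> _LinearDecoder:
    if not trials:
        raise ValueError("no training trials")
    blocks = [_trial_blocks(t, l1spec, l2spec) for t in trials]
    n_rows = sum(int(b.valid.sum()) for b in blocks)
    if n_rows == 0:
        raise ValueError("no usable time points across training trials")
    use_l2 = l2spec is not None

    if lam is None:
        lam = _select_lambda(blocks, use_l2, lam_grid)

    X, y, stats = _assemble(blocks, l2=use_l2)
    betas = ridge_solve(X, y, lam)
    resid = y - X @ betas
    model_cls = HLMModel if use_l2 else MLRModel
    return model_cls(
        l1spec=l1spec,
        l2spec=l2spec,
        betas=betas,
        stats=stats,
        lam=float(lam),
        residual_var=resid.var(axis=0),
    )


def _select_lambda(blocks: list[_Blocks], use_l2: bool, lam_grid) -> float:
    """Pick the penalty by held-out correlation on the last 20% of rows."""
    X, y, stats = _assemble(blocks, l2=use_l2)
    n = len(X)
    cut = max(int(np.floor(0.8 * n)), 1)
    if cut >= n:  # too few rows for a split: fall back to mid-grid
        return float(sorted(lam_grid)[len(lam_grid) // 2])
    Xtr, ytr, Xva, yva = X[:cut], y[:cut], X[cut:], y[cut:]
    best_lam, best_score = None, -np.inf
    for lam in lam_grid:
        try:
            b = ridge_solve(Xtr, ytr, lam)
        except np.linalg.LinAlgError:
            continue
        pred = Xva @ b
        score = np.mean([_corr(pred[:, i], yva[:, i]) for i in range(3)])
        if score > best_score:
            best_lam, best_score = float(lam), score
    if best_lam is None:
        raise np.linalg.LinAlgError("no penalty in the grid produced a solvable system")
    return best_lam


def fit_hlm(
    trials: list[SyncedTrial],
    l1spec: Level1Spec | None = None,
    l2spec: Level2Spec | None = None,
    lam_grid=DEFAULT_LAMBDA_GRID,
    lam: float | None = None,
) -> HLMModel:
    """Fit the hierarchical decoder on a list of epoched, featured trials."""
    model = _fit(trials, l1spec or Level1Spec(), l2spec or Level2Spec(), lam_grid, lam)
    assert isinstance(model, HLMModel)
    return model


def fit_mlr(
    trials: list[SyncedTrial],
    l1spec: Level1Spec | None = None,
    lam_grid=DEFAULT_LAMBDA_GRID,
    lam: float | None = None,
) -> MLRModel:
    """Fit the lagged multiple-linear-regression baseline."""
    model = _fit(trials, l1spec or Level1Spec(), None, lam_grid, lam)
    assert isinstance(model, MLRModel)
    return model


def predict(model: _LinearDecoder, trial: SyncedTrial) -> DecodedTrajectory:
    """Decode a trial; points lacking lag/epoch history are NaN."""
    blocks = _trial_blocks(trial, model.l1spec, model.l2spec)
    T = len(blocks.times)
    out = np.full((T, 3), np.nan)
    if blocks.valid.any():
        sub = _Blocks(
            slag=blocks.slag,
            cov_int=blocks.cov_int,
            cov_band=blocks.cov_band,
            y=blocks.y,
            times=blocks.times,
            valid=blocks.valid,
        )
        X, _, _ = _assemble([sub], l2=model.l2spec is not None, stats=model.stats)
        expected = model.n_columns
        if X.shape[1] != expected:
            raise ValueError(
                f"design width {X.shape[1]} does not match model ({expected}); "
                "trial structure differs from training"
            )
        out[blocks.valid] = X @ model.betas
    return DecodedTrajectory(times=blocks.times, x=out[:, 0], y=out[:, 1], z=out[:, 2])
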