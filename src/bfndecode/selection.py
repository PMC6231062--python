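"""Cross-mode summarization of network features and band/electrode selection.

Node-degree vectors from every (epoch, band) are grouped by motion mode;
per-(band, electrode) Kruskal-Wallis tests across the three mode groups give
a p-value table, from which characteristic bands (enough significant
electrodes) and characteristic electrodes (significant in every retained
band) are selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from bfndecode._utils import sample_sd

logger = logging.getLogger(__name__)

MOTION_MODES = ("BF", "LR", "UD")

#: Marker for (band, electrode) cells whose degrees are identically zero in
#: every mode; the rank test is undefined there and the cell must never be
#: confused with a small p-value.
DEGENERATE = "degenerate"


@dataclass
class DegreeSample:
    """Per-epoch node-degree vector for one (mode, band)."""

    epoch: int
    mode: str
    band: str
    degrees: np.ndarray
    electrodes: list[str]

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=float)
        if len(self.degrees) != len(self.electrodes):
            raise ValueError("degree vector length must match electrode count")


@dataclass
class ModeSpreadTable:
    """Per-(band, electrode) SD across per-mode mean degrees + band means."""

    per_electrode: pd.DataFrame  # index electrodes, columns bands
    band_means: pd.Series  # column means over electrodes


@dataclass
class KWTable:
    """Kruskal-Wallis p-values per (band, electrode); NaN marks degenerate cells."""

    pvalues: pd.DataFrame  # index electrodes, columns bands; NaN = degenerate

    @property
    def bands(self) -> list[str]:
        return list(self.pvalues.columns)

    @property
    def electrodes(self) -> list[str]:
        return list(self.pvalues.index)

    def significant_count(self, band: str, alpha: float = 0.05) -> int:
        """Electrodes with p < alpha in ``band``, excluding degenerate cells."""
        col = self.pvalues[band]
        return int(((col < alpha) & col.notna()).sum())

    def degenerate_count(self, electrode: str) -> int:
        return int(self.pvalues.loc[electrode].isna().sum())


@dataclass
class FeatureSelection:
    selected_bands: list[str]
    selected_electrodes: list[str]
    exclusion_log: list[dict] = field(default_factory=list)


def per_mode_metric_means(features_by_epoch) -> dict[str, pd.DataFrame]:
    """Mean of VDegree / VPLength / Cluster per (band, mode) over epochs.

    ``features_by_epoch`` is an iterable of dicts with keys
    ``mode, band, VDegree, VPLength, Cluster``.  Returns one band x mode
    DataFrame per metric.  Raises if any mode is absent for some band.
    """
    df = pd.DataFrame(list(features_by_epoch))
    required = {"mode", "band", "VDegree", "VPLength", "Cluster"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature records missing fields: {sorted(missing)}")
    out = {}
    for metric in ("VDegree", "VPLength", "Cluster"):
        table = df.pivot_table(index="band", columns="mode", values=metric, aggfunc="mean")
        absent = [m for m in MOTION_MODES if m not in table.columns or table[m].isna().any()]
        if absent:
            raise ValueError(f"missing motion mode(s) {absent} for metric {metric}")
        out[metric] = table[list(MOTION_MODES)]
    return out


def mode_spread(values) -> float:
    """Sample SD (n-1) of the three per-mode summary values."""
    arr = np.asarray(values, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected exactly 3 per-mode values, got shape {arr.shape}")
    return sample_sd(arr)


def degree_spread_table(samples: list[DegreeSample]) -> ModeSpreadTable:
    """Per-(band, electrode) spread of mode-mean degrees.

    For each (band, electrode) the degrees are averaged over epochs within
    each mode, and the sample SD is taken across the three mode means; the
    per-band column mean over electrodes summarizes each band's sensitivity
    to the motion mode.
    """
    if not samples:
        raise ValueError("no degree samples")
    rows = []
    for s in samples:
        for el, d in zip(s.electrodes, s.degrees):
            rows.append({"band": s.band, "mode": s.mode, "electrode": el, "degree": d})
    df = pd.DataFrame(rows)
    got_modes = set(df["mode"].unique())
    if not set(MOTION_MODES) <= got_modes:
        raise ValueError(f"samples must span modes {MOTION_MODES}, got {sorted(got_modes)}")

    bands = list(dict.fromkeys(s.band for s in samples))
    electrodes = list(dict.fromkeys(el for s in samples for el in s.electrodes))
    table = pd.DataFrame(index=electrodes, columns=bands, dtype=float)
    mode_means = df.groupby(["band", "electrode", "mode"])["degree"].mean()
    for b in bands:
        for el in electrodes:
            try:
                vals = [mode_means.loc[(b, el, m)] for m in MOTION_MODES]
            except KeyError:
                logger.info("electrode %s absent from some mode in band %s; excluded", el, b)
                continue
            table.loc[el, b] = mode_spread(vals)
    return ModeSpreadTable(per_electrode=table, band_means=table.mean(axis=0))


def kruskal_wallis_statistic(*groups) -> float:
    """Tie-corrected Kruskal-Wallis H statistic (helper, also used by tests)."""
    return float(stats.kruskal(*groups).statistic)


def kruskal_wallis_table(samples: list[DegreeSample]) -> KWTable:
    """Kruskal-Wallis p per (band, electrode) across the three mode groups.

    Cells where the degree is zero for every epoch of every mode carry the
    degenerate marker (NaN) instead of a p-value.  Cells where all degrees
    are identical but nonzero are likewise undefined and marked.
    """
    if not samples:
        raise ValueError("no degree samples")
    bands = list(dict.fromkeys(s.band for s in samples))
    electrodes = list(dict.fromkeys(el for s in samples for el in s.electrodes))
    table = pd.DataFrame(index=electrodes, columns=bands, dtype=float)

    for b in bands:
        subset = [s for s in samples if s.band == b]
        for ei, el in enumerate(electrodes):
            groups = []
            for m in MOTION_MODES:
                vals = [
                    s.degrees[s.electrodes.index(el)]
                    for s in subset
                    if s.mode == m and el in s.electrodes
                ]
                if len(vals) >= 2:
                    groups.append(np.asarray(vals))
            if len(groups) < 2:
                raise ValueError(f"fewer than 2 non-empty mode groups for ({b}, {el})")
            allvals = np.concatenate(groups)
            if np.all(allvals == 0):
                table.loc[el, b] = np.nan  # always-zero degree: test undefined
                continue
            try:
                table.loc[el, b] = stats.kruskal(*groups).pvalue
            except ValueError:  # all values identical -> no ranking information
                table.loc[el, b] = np.nan
    return KWTable(pvalues=table)


def select_features(
    kwtable: KWTable,
    alpha: float = 0.05,
    min_electrode_fraction: float = 0.5,
    manual_exclusions: tuple[str, ...] = ("FP1", "FP2"),
    spread: ModeSpreadTable | None = None,
    bonferroni: bool = False,
    bands: tuple[str, ...] | None = None,
) -> FeatureSelection:
    """Select characteristic bands and electrodes from the p-value table.

    A band is retained when at least ``min_electrode_fraction`` of the
    electrodes are significant in it; degenerate cells never count toward
    band retention.  An electrode is retained when it is significant in
    every retained band.  A degenerate cell cannot be judged from the test
    alone: if a mode-spread table is supplied, the cell passes when the
    electrode's cross-mode degree spread in that band exceeds the band's
    average spread (an electrode whose degree separates the modes more than
    typical is discriminative even where the rank test degenerates); without
    a spread table degenerate cells fail.  ``manual_exclusions`` are applied
    last (ocular contamination of the frontopolar sites).  Passing ``bands``
    fixes the retained-band set instead of deriving it from the counts;
    electrode selection is then monotone in ``alpha``.
    """
    pv = kwtable.pvalues
    eff_alpha = alpha / pv.size if bonferroni else alpha
    n_el = len(kwtable.electrodes)

    if bands is not None:
        selected_bands = [b for b in kwtable.bands if b in bands]
    else:
        selected_bands = [
            b for b in kwtable.bands
            if kwtable.significant_count(b, eff_alpha) >= min_electrode_fraction * n_el
        ]
    exclusions: list[dict] = []
    if not selected_bands:
        warnings.warn("no band reaches the significant-electrode fraction; empty selection")
        return FeatureSelection([], [], exclusions)

    selected = []
    for el in kwtable.electrodes:
        ok = True
        for b in selected_bands:
            p = pv.loc[el, b]
            if np.isnan(p):
                if spread is not None and b in spread.per_electrode.columns:
                    if spread.per_electrode.loc[el, b] > spread.band_means[b]:
                        continue
                ok = False
                exclusions.append(
                    {"electrode": el, "reason": f"degenerate, non-discriminative in {b}"}
                )
                break
            if not p < eff_alpha:
                ok = False
                break
        if ok:
            selected.append(el)

    for el in manual_exclusions:
        if el in selected:
            selected.remove(el)
            exclusions.append({"electrode": el, "reason": "ocular contamination"})
    return FeatureSelection(selected_bands, selected, exclusions)
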