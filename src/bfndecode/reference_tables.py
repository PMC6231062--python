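"""Published reference values bundled for validation.

These are the printed summary tables from the source experiments: per-mode
network-metric means, the node-degree spread table, the Kruskal-Wallis
p-value table, and the per-subject decoding correlations for the two spiral
trajectories under both decoder variants.  They serve as worked-example
inputs for the summary-statistics routines; cells printed as exactly 0 or 1
in the p-value table are always-zero-degree markers, not probabilities, and
are loaded as degenerate (NaN).  One garbled printed cell (O1 / gamma2) is
stored as missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bfndecode.selection import KWTable, ModeSpreadTable

BAND_ORDER = ("delta", "theta", "alpha1", "alpha2", "beta1", "beta2", "gamma1", "gamma2")
MODE_ORDER = ("BF", "LR", "UD")

#: Per-mode average node degree (rows: band; columns: BF, LR, UD; printed SD last).
MODE_DEGREE = {
    "delta":  (4.24, 4.27, 4.31, 0.035),
    "theta":  (4.41, 4.27, 4.46, 0.098),
    "alpha1": (4.32, 4.35, 4.48, 0.085),
    "alpha2": (4.31, 4.37, 4.45, 0.070),
    "beta1":  (4.30, 4.29, 4.39, 0.055),
    "beta2":  (4.32, 4.26, 4.30, 0.031),
    "gamma1": (4.34, 4.24, 4.38, 0.072),
    "gamma2": (4.29, 4.33, 4.43, 0.072),
}

#: Per-mode average path length.
MODE_PATH_LENGTH = {
    "delta":  (2.08, 2.04, 2.13, 0.045),
    "theta":  (2.18, 2.09, 2.37, 0.143),
    "alpha1": (2.08, 2.23, 2.32, 0.121),
    "alpha2": (2.02, 2.15, 2.35, 0.166),
    "beta1":  (1.89, 2.07, 2.16, 0.137),
    "beta2":  (1.85, 1.94, 2.07, 0.111),
    "gamma1": (1.83, 2.03, 2.10, 0.140),
    "gamma2": (1.88, 1.95, 2.14, 0.135),
}

#: Per-mode clustering coefficient.
MODE_CLUSTERING = {
    "delta":  (0.49, 0.51, 0.51, 0.012),
    "theta":  (0.51, 0.51, 0.52, 0.006),
    "alpha1": (0.51, 0.50, 0.51, 0.006),
    "alpha2": (0.50, 0.49, 0.49, 0.006),
    "beta1":  (0.49, 0.50, 0.49, 0.006),
    "beta2":  (0.51, 0.49, 0.50, 0.010),
    "gamma1": (0.51, 0.49, 0.50, 0.010),
    "gamma2": (0.51, 0.50, 0.50, 0.006),
}

#: Cross-mode SD of per-electrode mean node degree, 25 electrodes x 8 bands.
DEGREE_SPREAD = {
    "FP1": (0.68, 0.75, 0.73, 0.72, 0.76, 0.74, 0.74, 0.90),
    "FP2": (0.86, 1.16, 1.13, 1.03, 1.07, 0.68, 0.57, 0.62),
    "F3":  (0.10, 0.29, 0.28, 0.31, 0.20, 0.28, 0.28, 0.13),
    "FZ":  (0.43, 0.50, 0.24, 0.52, 0.27, 0.32, 0.54, 0.38),
    "F4":  (0.71, 0.70, 0.96, 0.95, 1.12, 0.94, 0.36, 0.40),
    "F8":  (0.88, 1.09, 0.67, 0.47, 0.38, 0.34, 0.40, 0.37),
    "FT7": (0.63, 0.46, 0.44, 0.45, 0.30, 0.20, 0.29, 0.22),
    "FC3": (0.16, 0.32, 0.21, 0.26, 0.27, 0.40, 0.17, 0.20),
    "C3":  (0.89, 0.63, 0.62, 0.37, 0.27, 0.59, 0.55, 0.66),
    "CZ":  (0.91, 0.89, 0.81, 0.85, 0.67, 0.68, 0.61, 0.64),
    "C4":  (0.75, 0.71, 0.52, 0.32, 0.50, 0.26, 0.15, 0.20),
    "CP3": (0.71, 0.56, 0.36, 0.17, 0.20, 0.28, 0.63, 0.81),
    "CPZ": (0.72, 0.60, 0.41, 0.39, 0.16, 0.49, 0.98, 1.14),
    "CP4": (0.58, 0.51, 0.03, 0.22, 0.50, 0.71, 0.62, 0.82),
    "P3":  (0.38, 0.41, 0.19, 0.13, 0.32, 0.57, 0.56, 0.11),
    "PZ":  (0.53, 0.16, 0.17, 0.10, 0.31, 0.18, 0.28, 0.55),
    "P4":  (0.21, 0.26, 0.27, 0.24, 0.40, 0.28, 0.31, 0.52),
    "T3":  (0.95, 0.83, 0.52, 0.60, 0.43, 0.24, 0.14, 0.09),
    "T5":  (1.24, 0.88, 0.53, 0.71, 0.47, 0.13, 0.06, 0.07),
    "T4":  (1.40, 1.60, 1.22, 0.72, 0.34, 0.26, 0.22, 0.28),
    "TP8": (0.78, 1.00, 0.63, 0.64, 0.23, 0.08, 0.060, 0.0),
    "T6":  (0.53, 0.36, 0.07, 0.15, 0.03, 0.02, 0.02, 0.04),
    "O1":  (0.75, 0.44, 0.32, 0.41, 0.09, 0.21, 0.22, 0.18),
    "OZ":  (0.61, 0.53, 0.60, 0.61, 0.45, 0.50, 0.37, 0.32),
    "O2":  (0.05, 0.12, 0.53, 0.42, 0.26, 0.32, 0.19, 0.13),
}

#: Kruskal-Wallis p-values, 25 electrodes x 8 bands.  0.0 and 1.0 are
#: always-zero-degree markers; NaN marks the one garbled printed cell.
KW_PVALUES = {
    "FP1": (0.03, 0.007, 0.006, 0.013, 0.003, 0.003, 0.006, 0.001),
    "FP2": (0.001, 0.0, 0.0, 0.0, 0.0, 0.002, 0.006, 0.003),
    "F3":  (0.856, 0.029, 0.379, 0.254, 0.76, 0.531, 0.376, 0.769),
    "FZ":  (0.218, 0.099, 0.738, 0.195, 0.809, 0.316, 0.025, 0.285),
    "F4":  (0.032, 0.003, 0.0, 0.0, 0.0, 0.0, 0.032, 0.013),
    "F8":  (0.001, 0.0, 0.0, 0.011, 0.024, 0.035, 0.009, 0.008),
    "FT7": (0.002, 0.09, 0.267, 0.112, 0.141, 0.001, 0.0, 0.002),
    "FC3": (0.843, 0.149, 0.633, 0.33, 0.282, 0.168, 0.661, 0.34),
    "C3":  (0.009, 0.024, 0.025, 0.213, 0.594, 0.006, 0.023, 0.072),
    "CZ":  (0.006, 0.014, 0.051, 0.006, 0.055, 0.05, 0.033, 0.016),
    "C4":  (0.029, 0.008, 0.018, 0.307, 0.016, 0.147, 0.048, 0.756),
    "CP3": (0.057, 0.017, 0.269, 0.714, 0.613, 0.158, 0.001, 0.0),
    "CPZ": (0.054, 0.005, 0.215, 0.529, 0.918, 0.079, 0.002, 0.0),
    "CP4": (0.003, 0.009, 0.893, 0.83, 0.422, 0.014, 0.007, 0.006),
    "P3":  (0.17, 0.034, 0.23, 0.656, 0.606, 0.319, 0.5, 0.568),
    "PZ":  (0.058, 0.739, 0.674, 0.675, 0.437, 0.801, 0.568, 0.053),
    "P4":  (0.714, 0.326, 0.268, 0.237, 0.009, 0.013, 0.071, 0.0),
    "T3":  (0.001, 0.015, 0.008, 0.0, 0.0, 0.005, 0.016, 0.152),
    "T5":  (0.0, 0.0, 0.009, 0.004, 0.003, 0.102, 0.604, 0.23),
    "T4":  (0.007, 0.024, 0.0, 0.0, 0.0, 0.005, 0.005, 0.005),
    "TP8": (0.0, 0.0, 0.0, 0.0, 0.001, 0.064, 0.165, 1.0),
    "T6":  (0.003, 0.033, 0.217, 0.238, 0.348, 0.368, 0.368, 0.132),
    "O1":  (0.023, 0.008, 0.002, 0.001, 0.1891, 0.0, 0.0, np.nan),
    "OZ":  (0.005, 0.003, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "O2":  (0.834, 0.805, 0.0, 0.0, 0.009, 0.0, 0.067, 0.248),
}

#: Per-subject decoding correlations: {table: axis -> 5 subject values}.
#: mlr/hlm = baseline vs hierarchical decoder; 1/2 = spiral trajectory.
DECODING_PCC = {
    "mlr_spiral1": {
        "Rx": (0.7348, 0.3481, 0.4722, 0.4199, 0.4647),
        "Ry": (0.5781, 0.4872, 0.6118, 0.4772, 0.6108),
        "Rz": (0.6061, 0.4369, 0.3728, 0.5788, 0.4886),
        "R":  (0.6397, 0.4241, 0.4856, 0.4920, 0.5213),
    },
    "hlm_spiral1": {
        "Rx": (0.5908, 0.5895, 0.5186, 0.8233, 0.7821),
        "Ry": (0.8625, 0.8224, 0.8244, 0.9955, 0.7568),
        "Rz": (0.6171, 0.6735, 0.5041, 0.8712, 0.6392),
        "R":  (0.6710, 0.6332, 0.5927, 0.8606, 0.7118),
    },
    "mlr_spiral2": {
        "Rx": (0.8826, 0.4059, 0.7592, 0.5715, 0.6792),
        "Ry": (0.3004, 0.4440, 0.4844, 0.3205, 0.2503),
        "Rz": (0.5058, 0.5296, 0.6203, 0.6598, 0.4822),
        "R":  (0.5629, 0.4598, 0.6213, 0.5172, 0.4706),
    },
    "hlm_spiral2": {
        "Rx": (0.5213, 0.6084, 0.9062, 0.4426, 0.7966),
        "Ry": (0.7017, 0.6085, 0.7979, 0.3297, 0.4740),
        "Rz": (0.6887, 0.8823, 0.9123, 0.8826, 0.7545),
        "R":  (0.6372, 0.6997, 0.8721, 0.5516, 0.6750),
    },
}


def mode_metric_table(metric: str) -> pd.DataFrame:
    """Band x (BF, LR, UD, SD_printed) table for one network metric."""
    source = {
        "VDegree": MODE_DEGREE,
        "VPLength": MODE_PATH_LENGTH,
        "Cluster": MODE_CLUSTERING,
    }[metric]
    return pd.DataFrame.from_dict(
        source, orient="index", columns=list(MODE_ORDER) + ["SD_printed"]
    )


def spread_table() -> ModeSpreadTable:
    """The degree-spread table wrapped for use by the selection rules."""
    df = pd.DataFrame.from_dict(DEGREE_SPREAD, orient="index", columns=list(BAND_ORDER))
    return ModeSpreadTable(per_electrode=df, band_means=df.mean(axis=0))


def kw_table() -> KWTable:
    """The p-value table with 0/1 marker cells mapped to degenerate (NaN)."""
    df = pd.DataFrame.from_dict(KW_PVALUES, orient="index", columns=list(BAND_ORDER))
    marker = (df == 0.0) | (df == 1.0)
    return KWTable(pvalues=df.mask(marker))


def decoding_table(which: str) -> pd.DataFrame:
    """Per-subject axis correlations for one (decoder, trajectory) table."""
    subjects = [f"S{i}" for i in range(1, 6)]
    return pd.DataFrame.from_dict(
        DECODING_PCC[which], orient="index", columns=subjects
    )
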