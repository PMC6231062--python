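"""Band-wise functional-network construction from EEG epochs.

For each 2-s epoch the EEG is decomposed with a complex Morlet continuous
wavelet transform into eight canonical frequency bands; per band, the
magnitude envelope (averaged over in-band scales) of every electrode is rank
correlated with every other, the Spearman matrix is thresholded by a network
cost, and the resulting weighted graph is summarized by degree, average path
length, clustering and mean link weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from scipy.sparse.csgraph import shortest_path

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    lo: float
    hi: float

    @property
    def center(self) -> float:
        """Geometric band centre, used for scale placement and gain reference."""
        return float(np.sqrt(self.lo * self.hi))


#: The eight canonical analysis bands.
BANDS: tuple[FrequencyBand, ...] = (
    FrequencyBand("delta", 1, 3),
    FrequencyBand("theta", 4, 7),
    FrequencyBand("alpha1", 8, 9),
    FrequencyBand("alpha2", 10, 12),
    FrequencyBand("beta1", 13, 17),
    FrequencyBand("beta2", 18, 30),
    FrequencyBand("gamma1", 31, 40),
    FrequencyBand("gamma2", 41, 50),
)

BAND_BY_NAME = {b.name: b for b in BANDS}


@dataclass
class WaveletConfig:
    n_cycles: float = 6.0
    n_scales: int = 4


@dataclass
class BandCoefficientMatrix:
    band: FrequencyBand
    envelope: np.ndarray  # (electrodes, time), nonnegative amplitude
    labels: list[str] = field(default_factory=list)


@dataclass
class CorrelationMatrix:
    p: np.ndarray  # symmetric, zero diagonal, entries in [-1, 1]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        n = self.p.shape[0]
        if self.p.shape != (n, n):
            raise ValueError("correlation matrix must be square")


@dataclass
class BFNetwork:
    """Thresholded weighted graph for one (epoch, band)."""

    a: np.ndarray  # symmetric nonnegative weights, zero diagonal
    cost: float  # target network cost used as the subtraction threshold
    labels: list[str] = field(default_factory=list)
    band: str = ""
    epoch: int = -1

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_links(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.a[iu]))

    @property
    def realized_cost(self) -> float:
        n = self.n_nodes
        return self.n_links / (n * (n - 1) / 2)

    @property
    def binary(self) -> np.ndarray:
        return (self.a > 0).astype(int)


@dataclass
class NetworkFeatures:
    DVector: np.ndarray  # per-node binary degree
    VDegree: float  # mean degree
    VPLength: float  # average shortest-path length over reachable pairs
    Cluster: float  # mean local clustering
    Pbar: float  # mean weight over existing links
    n_unreachable_pairs: int = 0


def morlet_cwt(x: np.ndarray, rate: float, freqs, n_cycles: float = 6.0) -> np.ndarray:
    """Complex Morlet transform of ``x`` (..., time) at centre frequencies.

    Each wavelet is a Gaussian-windowed complex exponential whose temporal
    SD is ``n_cycles / (2*pi*f)``; the window is L1-normalized and doubled so
    a unit-amplitude sinusoid at the centre frequency yields |coef| ~= 1.
    Returns an array of shape ``freqs x ... x time``.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty((len(freqs),) + x.shape, dtype=complex)
    for i, f in enumerate(freqs):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(5 * sigma_t * rate))
        t = np.arange(-half, half + 1) / rate
        win = np.exp(-(t**2) / (2 * sigma_t**2))
        psi = 2.0 * win / win.sum() * np.exp(2j * np.pi * f * t)
        # reflect-pad so segment edges do not look like steps to the wavelet
        pad = min(half, x.shape[-1] - 1)
        spec = [(0, 0)] * (x.ndim - 1) + [(pad, pad)]
        xp = np.pad(x, spec, mode="reflect")
        shaped = psi.reshape((1,) * (x.ndim - 1) + (-1,))
        conv = signal.fftconvolve(xp, shaped, mode="same", axes=-1)
        out[i] = conv[..., pad : pad + x.shape[-1]]
    return out


def _mean_scale_gain(band: FrequencyBand, freqs: np.ndarray, n_cycles: float) -> float:
    # Mean Gaussian frequency response of the scale bank, evaluated at the
    # band centre; used to put averaged envelopes on an amplitude scale.
    sigma_f = freqs / n_cycles
    gains = np.exp(-((band.center - freqs) ** 2) / (2 * sigma_f**2))
    return float(gains.mean())


def band_envelope(
    epoch_eeg: np.ndarray,
    rate: float,
    band: FrequencyBand | str,
    wavelet_cfg: WaveletConfig | None = None,
    labels: list[str] | None = None,
) -> BandCoefficientMatrix:
    """Per-electrode amplitude envelope of one band.

    The magnitude of the complex Morlet coefficients is averaged over
    ``n_scales`` log-spaced centre frequencies inside the band and rescaled
    by the bank's mean gain at the band centre so that a unit sinusoid near
    the centre produces an envelope near 1.
    """
    if isinstance(band, str):
        band = BAND_BY_NAME[band]
    cfg = wavelet_cfg or WaveletConfig()
    if band.hi >= rate / 2:
        raise ValueError(
            f"band {band.name} ({band.lo}-{band.hi} Hz) exceeds Nyquist at rate {rate} Hz"
        )
    epoch_eeg = np.atleast_2d(np.asarray(epoch_eeg, dtype=float))
    freqs = np.geomspace(band.lo, band.hi, cfg.n_scales)
    coefs = morlet_cwt(epoch_eeg, rate, freqs, cfg.n_cycles)
    env = np.abs(coefs).mean(axis=0) / _mean_scale_gain(band, freqs, cfg.n_cycles)
    return BandCoefficientMatrix(band=band, envelope=env, labels=list(labels or []))


def correlation_matrix(coeffs: BandCoefficientMatrix | np.ndarray,
                       labels: list[str] | None = None) -> CorrelationMatrix:
    """Spearman rank-correlation matrix of envelope rows, zero diagonal.

    Rows with zero variance have undefined rank correlation; their entries
    are set to 0 and the event is logged.
    """
    if isinstance(coeffs, BandCoefficientMatrix):
        env, labels = coeffs.envelope, labels or coeffs.labels
    else:
        env = np.atleast_2d(np.asarray(coeffs, dtype=float))
    n, t = env.shape
    if n < 2:
        raise ValueError("need at least two electrodes")
    if t < 4:
        raise ValueError("need at least 4 time points")

    constant = env.std(axis=1) == 0
    ranks = stats.rankdata(env, axis=1)  # average ranks = tie-corrected Spearman
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    if constant.any():
        logger.info("constant envelope rows %s: correlations set to 0", np.where(constant)[0])
        rho[constant, :] = 0.0
        rho[:, constant] = 0.0
    rho = np.nan_to_num(rho, nan=0.0)
    rho = (rho + rho.T) / 2
    np.fill_diagonal(rho, 0.0)
    return CorrelationMatrix(p=rho, labels=list(labels or []))


def build_bfn(corr: CorrelationMatrix, target_cost: float = 0.18,
              band: str = "", epoch: int = -1) -> BFNetwork:
    """Threshold a correlation matrix into a weighted network.

    Weights are ``max(p_ij - cost, 0)``: the target cost acts as the
    subtraction threshold, so only correlations strictly above it survive as
    links.  Negative correlations never link.
    """
    if not 0 <= target_cost < 1:
        raise ValueError("target_cost must be in [0, 1)")
    a = corr.p - target_cost
    a[a < 0] = 0.0
    np.fill_diagonal(a, 0.0)
    net = BFNetwork(a=a, cost=target_cost, labels=list(corr.labels), band=band, epoch=epoch)
    if net.n_links == 0:
        warnings.warn(
            f"all correlations <= target cost {target_cost}; network is empty", stacklevel=2
        )
    return net


def network_features(bfn: BFNetwork) -> NetworkFeatures:
    """Degree vector, mean degree, average path length, clustering, mean weight.

    Path length and clustering use the binarized graph.  Unreachable node
    pairs are excluded from the path-length average (their count is
    recorded); nodes with fewer than two neighbours contribute 0 clustering.
    """
    n = bfn.n_nodes
    if n < 2:
        raise ValueError("need at least two nodes")
    b = bfn.binary
    degrees = b.sum(axis=1)
    vdegree = float(degrees.mean())

    k = bfn.n_links
    iu = np.triu_indices(n, k=1)
    pbar = float(bfn.a[iu].sum() / k) if k else 0.0

    dist = shortest_path(b, method="D", unweighted=True, directed=False)
    upper = dist[iu]
    reachable = np.isfinite(upper)
    n_unreach = int(np.count_nonzero(~reachable))
    vpl = float(upper[reachable].mean()) if reachable.any() else 0.0

    # local clustering: triangles through each node over possible neighbour pairs
    triangles = np.diag(b @ b @ b) / 2.0
    possible = degrees * (degrees - 1) / 2.0
    local = np.where(possible > 0, triangles / np.where(possible > 0, possible, 1), 0.0)
    cluster = float(local.mean())

    return NetworkFeatures(
        DVector=degrees,
        VDegree=vdegree,
        VPLength=vpl,
        Cluster=cluster,
        Pbar=pbar,
        n_unreachable_pairs=n_unreach,
    )


def ws_clustering_analytic(k_neighbors: int, p_rewire: float) -> float:
    """Closed-form small-world clustering reference, 3(K-2)/(4(K-1))*(1-P)^3."""
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be >= 2")
    if not 0 <= p_rewire <= 1:
        raise ValueError("p_rewire must be in [0, 1]")
    return 3 * (k_neighbors - 2) / (4 * (k_neighbors - 1)) * (1 - p_rewire) ** 3
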