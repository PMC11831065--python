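"""Welch auto-/cross-spectra and magnitude-squared coherence in named bands.

The magnitude-squared coherence (MSC) of channels x and y is

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) * P_yy(f))

with P_xx, P_yy the Welch auto-spectral densities and P_xy the cross-spectral
density.  Spectra are estimated from tapered, overlapping segments tiled
*within* each analysis epoch (segments never straddle epoch boundaries) and
averaged over all segments of all epochs of one condition, i.e. coherence is
computed per condition on the pooled segment set.

With K averaged segments the MSC of two independent Gaussian signals has
expectation ~ 1/K; the defaults (2-s Hann segments, 50 % overlap) give
Δf = 0.5 Hz — which resolves every default band boundary — and K ≈ 165 for
3 × 56-s epochs, so the bias floor is ~0.006.

Band aggregation uses half-open [low, high) bins so that sub-bands partition
their parent band without double counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .exceptions import ConfigurationError, DataError, NumericalError
from .preprocessing import EpochSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimation parameters.

    ``segment_s`` sets the frequency resolution (Δf = 1/segment_s); the
    defaults resolve all default band edges, which are multiples of 0.5 Hz.
    """

    segment_s: float = 2.0
    overlap_fraction: float = 0.5
    window: str = "hann"
    detrend: str = "constant"  # {"constant", "none"}

    def validate(self, fs: float) -> None:
        if self.segment_s * fs < 8:
            raise ConfigurationError("segment_s * fs must be >= 8 samples")
        if not 0 <= self.overlap_fraction < 1:
            raise ConfigurationError("overlap_fraction must be in [0, 1)")
        if self.detrend not in ("constant", "none"):
            raise ConfigurationError("detrend must be 'constant' or 'none'")

    def nperseg(self, fs: float) -> int:
        return int(round(self.segment_s * fs))

    def delta_f(self) -> float:
        return 1.0 / self.segment_s


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with half-open [low, high) bin convention."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ConfigurationError(f"band {self.name}: need 0 < low < high")

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        return (freqs >= self.low) & (freqs < self.high)


#: The 11 canonical resting-state bands (Hz, half-open).
DEFAULT_BANDS = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.5),
    BandDefinition("theta1", 4.0, 6.0),
    BandDefinition("theta2", 6.0, 7.5),
    BandDefinition("alpha", 7.5, 13.0),
    BandDefinition("alpha1", 7.5, 9.5),
    BandDefinition("alpha2", 9.5, 11.0),
    BandDefinition("alpha3", 11.0, 13.0),
    BandDefinition("beta", 13.0, 35.0),
    BandDefinition("beta1", 13.0, 20.0),
    BandDefinition("beta2", 20.0, 35.0),
)


def pair_list(n_channels: int) -> list[tuple[int, int]]:
    """All unordered channel pairs (i < j), the pair-index order used throughout."""
    i, j = np.triu_indices(n_channels, k=1)
    return list(zip(i.tolist(), j.tolist()))


def n_pairs(n_channels: int) -> int:
    """Number of unordered channel pairs, C(n, 2)."""
    return n_channels * (n_channels - 1) // 2


def pair_index(i: int, j: int, n_channels: int) -> int:
    """Row of pair (i, j) in the pair-indexed storage (i < j, 0-based)."""
    if i == j:
        raise ValueError("pair must join two distinct channels")
    if i > j:
        i, j = j, i
    if not 0 <= i < j < n_channels:
        raise ValueError("channel index out of range")
    return i * (2 * n_channels - i - 1) // 2 + (j - i - 1)


@dataclass
class SpectralEstimate:
    """Pooled Welch spectra of one subject/condition.

    ``Pxx`` is (n_channels, n_freqs) real; ``Pxy`` is pair-indexed
    (n_pairs, n_freqs) complex with rows ordered as :func:`pair_list`.
    """

    freqs: np.ndarray
    channels: tuple[str, ...]
    Pxx: np.ndarray
    Pxy: np.ndarray
    K: int

    def __post_init__(self) -> None:
        if np.any(self.Pxx < -1e-12):
            raise NumericalError("auto-spectra must be non-negative")
        if self.K < 1:
            raise NumericalError("need at least one averaged segment")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_row(self, ch: int | str) -> int:
        return ch if isinstance(ch, int) else self.channels.index(ch)


def _segment_ffts(
    epoch: np.ndarray, nperseg: int, step: int, win: np.ndarray, detrend: str
) -> np.ndarray:
    """Windowed rfft of all full segments of one epoch: (n_ch, n_seg, n_freq)."""
    segs = np.lib.stride_tricks.sliding_window_view(epoch, nperseg, axis=1)[:, ::step, :]
    if detrend == "constant":
        segs = segs - segs.mean(axis=2, keepdims=True)
    return np.fft.rfft(segs * win[None, None, :], axis=2)


def welch_spectra(es: EpochSet, cfg: WelchConfig | None = None) -> SpectralEstimate:
    """Pooled Welch auto- and cross-spectra across a condition's epochs.

    Segments are tiled within each epoch with the configured overlap and
    never straddle epoch boundaries; epochs shorter than one segment are
    skipped with a warning.  One-sided density normalization (unit:
    signal²/Hz).
    """
    cfg = cfg or WelchConfig()
    cfg.validate(es.fs)
    nperseg = cfg.nperseg(es.fs)
    step = max(1, nperseg - int(round(cfg.overlap_fraction * nperseg)))
    win = get_window(cfg.window, nperseg)
    n_ch = es.n_channels
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / es.fs)

    acc = np.zeros((n_ch, n_ch, len(freqs)), dtype=np.complex128)
    K = 0
    for e, epoch in enumerate(es.epochs):
        if epoch.shape[1] < nperseg:
            logger.warning(
                "%s/%s: epoch %d shorter than one segment (%d < %d samples), skipped",
                es.subject_id, es.condition, e, epoch.shape[1], nperseg,
            )
            continue
        X = _segment_ffts(epoch, nperseg, step, win, cfg.detrend)
        # scipy's csd convention: P_xy = E[conj(X) Y]
        acc += np.einsum("asf,bsf->abf", np.conj(X), X)
        K += X.shape[1]
    if K == 0:
        raise DataError("no epoch long enough for a single Welch segment")

    # one-sided density scaling: 1 / (fs * sum(win^2)), doubled except DC/Nyquist
    scale = np.full(len(freqs), 2.0 / (es.fs * float(np.sum(win**2))))
    scale[0] /= 2.0
    if nperseg % 2 == 0:
        scale[-1] /= 2.0
    acc *= scale[None, None, :] / K

    iu, ju = np.triu_indices(n_ch, k=1)
    return SpectralEstimate(
        freqs=freqs,
        channels=es.montage.labels,
        Pxx=np.real(acc[np.arange(n_ch), np.arange(n_ch), :]),
        Pxy=acc[iu, ju, :],
        K=K,
    )


def _msc_matrix(se: SpectralEstimate) -> np.ndarray:
    """Per-frequency MSC of every pair: (n_pairs, n_freqs), NaN where undefined."""
    iu, ju = np.triu_indices(se.n_channels, k=1)
    denom = se.Pxx[iu, :] * se.Pxx[ju, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(se.Pxy) ** 2 / denom
    c[denom <= 0] = np.nan
    return np.clip(c, 0.0, 1.0)


def msc(se: SpectralEstimate, pair: tuple) -> np.ndarray:
    """Magnitude-squared coherence of one unordered channel pair on the grid.

    Bins where either channel has zero power are NaN (undefined) and are
    excluded from band averages.  Requires K >= 2: a single-segment estimate
    is identically 1 and carries no information.
    """
    if se.K < 2:
        raise NumericalError("MSC from K=1 segment is degenerate (identically 1)")
    a = se.channel_row(pair[0])
    b = se.channel_row(pair[1])
    if a == b:
        out = np.ones_like(se.freqs)
        out[se.Pxx[a] <= 0] = np.nan
        return out
    row = pair_index(a, b, se.n_channels)
    denom = se.Pxx[a] * se.Pxx[b]
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(se.Pxy[row]) ** 2 / denom
    c[denom <= 0] = np.nan
    return np.clip(c, 0.0, 1.0)


def band_average(coh: np.ndarray, freqs: np.ndarray, band: BandDefinition) -> float:
    """Unweighted mean coherence over the band's [low, high) bins.

    Undefined (NaN) bins are excluded; an empty band on this grid is a
    configuration error (Welch resolution too coarse for the band).
    """
    m = band.mask(np.asarray(freqs))
    if not np.any(m):
        raise ConfigurationError(
            f"band {band.name} [{band.low}, {band.high}) contains no grid frequency"
        )
    vals = np.asarray(coh)[m]
    ok = ~np.isnan(vals)
    if not np.any(ok):
        raise NumericalError(f"band {band.name}: all bins undefined")
    return float(np.mean(vals[ok]))


@dataclass
class CoherenceProfile:
    """Per-subject, per-condition band-averaged coherence matrices.

    ``band_matrices[name]`` is a symmetric (n_ch, n_ch) matrix in [0, 1] with
    unit diagonal.
    """

    subject_id: str
    group: str
    condition: str
    channels: tuple[str, ...]
    band_matrices: dict[str, np.ndarray] = field(default_factory=dict)
    K: int = 0

    def bands(self) -> tuple[str, ...]:
        return tuple(self.band_matrices.keys())

    def value(self, band: str, ch_a: int | str, ch_b: int | str) -> float:
        a = ch_a if isinstance(ch_a, int) else self.channels.index(ch_a)
        b = ch_b if isinstance(ch_b, int) else self.channels.index(ch_b)
        return float(self.band_matrices[band][a, b])


def subject_coherence_profile(
    es: EpochSet,
    wcfg: WelchConfig | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> CoherenceProfile:
    """Band-averaged MSC matrices for one subject/condition."""
    se = welch_spectra(es, wcfg)
    if se.K < 2:
        raise NumericalError("need K >= 2 segments for coherence")
    c = _msc_matrix(se)  # (n_pairs, n_freqs)
    n_ch = se.n_channels
    iu, ju = np.triu_indices(n_ch, k=1)
    out: dict[str, np.ndarray] = {}
    for band in bands:
        m = band.mask(se.freqs)
        if not np.any(m):
            raise ConfigurationError(
                f"band {band.name} [{band.low}, {band.high}) contains no grid frequency"
            )
        with np.errstate(invalid="ignore"):
            vals = np.nanmean(c[:, m], axis=1)
        mat = np.ones((n_ch, n_ch))
        mat[iu, ju] = vals
        mat[ju, iu] = vals
        out[band.name] = mat
    return CoherenceProfile(
        subject_id=es.subject_id,
        group=es.group,
        condition=es.condition,
        channels=se.channels,
        band_matrices=out,
        K=se.K,
    )
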