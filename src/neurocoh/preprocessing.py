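"""Deterministic preprocessing chain for resting-state EEG.

Stages (in pipeline order): zero-phase band-pass filtering, kurtosis-based
bad-channel rejection, average re-referencing, and segmentation of the
annotated EO/EC blocks into analysis epochs with the leading seconds of each
block discarded (auditory cue transients).

An interactive cleaning step (e.g. ICA) is supported as a pluggable hook —
any callable mapping Recording -> Recording — and defaults to the identity.

Rejected channels are *dropped*, not interpolated: interpolated channels are
linear combinations of their neighbours and would fabricate coherence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable

import numpy as np
from scipy import signal, stats

from .exceptions import ConfigurationError, DataError
from .montage import Montage
from .synthetic import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``kurtosis_z_threshold`` applies to the z-score of each channel's excess
    kurtosis across channels (single pass).  ``discard_lead_s`` seconds are
    dropped from the start of every annotated block; the remainder is
    truncated to ``epoch_s`` if longer.
    """

    highpass: float = 0.5
    lowpass: float = 35.0
    kurtosis_z_threshold: float = 5.0
    discard_lead_s: float = 4.0
    epoch_s: float = 56.0
    filter_order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass < self.lowpass < fs / 2.0:
            raise ConfigurationError(
                f"need 0 < highpass < lowpass < Nyquist; got {self.highpass}, "
                f"{self.lowpass} at fs={fs}"
            )
        if self.kurtosis_z_threshold <= 0:
            raise ConfigurationError("kurtosis_z_threshold must be > 0")
        if self.discard_lead_s < 0:
            raise ConfigurationError("discard_lead_s must be >= 0")


@dataclass
class EpochSet:
    """One subject/condition's analysis epochs after preprocessing."""

    subject_id: str
    group: str
    condition: str
    epochs: list[np.ndarray]  # each (n_channels, n_samples_epoch)
    fs: float
    montage: Montage
    rejected_channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.epochs:
            n_ch = self.epochs[0].shape[0]
            if any(e.ndim != 2 or e.shape[0] != n_ch or e.shape[1] < 1 for e in self.epochs):
                raise DataError("epochs must share channel count and be non-empty")
            if n_ch != len(self.montage):
                raise DataError("epoch channel count must match montage")
        if set(self.rejected_channels) & set(self.montage.labels):
            raise DataError("rejected channels must not remain in the montage")

    @property
    def n_channels(self) -> int:
        return len(self.montage)


def bandpass_filter(rec: Recording, cfg: PreprocessConfig) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward–backward filtering doubles the effective order and cancels phase,
    so cross-spectra downstream are undistorted.  Length and annotations are
    preserved.
    """
    cfg.validate(rec.fs)
    sos = signal.butter(
        cfg.filter_order, [cfg.highpass, cfg.lowpass], btype="bandpass", fs=rec.fs, output="sos"
    )
    # sosfiltfilt needs some padding room; 3x the order-related edge length
    pad = 3 * (2 * cfg.filter_order + 1)
    if rec.n_samples <= pad:
        raise DataError(f"recording too short to filter ({rec.n_samples} samples)")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return rec.copy_with(data=np.ascontiguousarray(filtered))


def detect_bad_channels(rec: Recording, cfg: PreprocessConfig) -> list[str]:
    """Channels whose excess-kurtosis z-score across channels is extreme.

    Fisher excess kurtosis is computed per channel; z-scores are taken across
    channels; labels with ``|z| > kurtosis_z_threshold`` are returned.  Single
    pass — no re-iteration after removal.  If the channel kurtoses have zero
    spread the z-scores are undefined and nothing is rejected.
    """
    if len(rec.montage) < 3:
        raise DataError("kurtosis screening needs at least 3 channels")
    k = stats.kurtosis(rec.data, axis=1, fisher=True, bias=True)
    sd = float(np.std(k))
    if sd == 0.0:
        return []
    z = (k - float(np.mean(k))) / sd
    bad = [lab for lab, zi in zip(rec.montage.labels, z) if abs(zi) > cfg.kurtosis_z_threshold]
    for lab, zi in zip(rec.montage.labels, z):
        if abs(zi) > cfg.kurtosis_z_threshold:
            logger.info("%s: rejecting channel %s (kurtosis z=%.2f)", rec.subject_id, lab, zi)
    return bad


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over channels from every channel."""
    if len(rec.montage) < 2:
        raise DataError("average reference needs at least 2 channels")
    return rec.copy_with(data=rec.data - rec.data.mean(axis=0, keepdims=True))


def segment_conditions(
    rec: Recording, cfg: PreprocessConfig, rejected_channels: list[str] | None = None
) -> tuple[EpochSet, EpochSet]:
    """Split annotated blocks into EO and EC epoch sets.

    For each annotated interval, the first ``discard_lead_s`` seconds are
    dropped and the remainder — truncated to ``epoch_s`` if longer — becomes
    one epoch.  A remainder shorter than ``epoch_s`` is retained with a
    warning.  Channels in ``rejected_channels`` are excluded.
    """
    if not rec.annotations:
        raise DataError("recording has no condition annotations")
    rejected = list(rejected_channels or [])
    keep_rows = [i for i, lab in enumerate(rec.montage.labels) if lab not in set(rejected)]
    montage = rec.montage.drop(rejected) if rejected else rec.montage

    discard = int(round(cfg.discard_lead_s * rec.fs))
    target = int(round(cfg.epoch_s * rec.fs))
    epochs: dict[str, list[np.ndarray]] = {"EO": [], "EC": []}
    for cond, start, end in rec.annotations:
        if end - start <= discard:
            raise DataError(
                f"annotated interval of {(end - start) / rec.fs:.1f} s shorter than "
                f"discard_lead_s={cfg.discard_lead_s}"
            )
        a = start + discard
        b = min(end, a + target) if target > 0 else end
        if b - a < target:
            logger.warning(
                "%s/%s: epoch of %.1f s shorter than epoch_s=%.1f s (kept)",
                rec.subject_id, cond, (b - a) / rec.fs, cfg.epoch_s,
            )
        epochs[cond].append(rec.data[np.ix_(keep_rows, np.arange(a, b))])

    def _make(cond: str) -> EpochSet:
        return EpochSet(
            subject_id=rec.subject_id,
            group=rec.group,
            condition=cond,
            epochs=epochs[cond],
            fs=rec.fs,
            montage=montage,
            rejected_channels=rejected,
        )

    return _make("EO"), _make("EC")


CleaningHook = Callable[[Recording], Recording]


def preprocess_recording(
    rec: Recording,
    cfg: PreprocessConfig | None = None,
    cleaning_hook: CleaningHook | None = None,
) -> tuple[EpochSet, EpochSet]:
    """Run the full chain: filter → reject channels → re-reference → segment.

    ``cleaning_hook`` (Recording -> Recording) runs after re-referencing and
    defaults to the identity; it is the slot for interactive artifact removal
    such as ICA, which is outside this pipeline's scope.
    """
    cfg = cfg or PreprocessConfig()
    filtered = bandpass_filter(rec, cfg)
    bad = detect_bad_channels(filtered, cfg)
    if bad:
        keep = [lab for lab in filtered.montage.labels if lab not in set(bad)]
        rows = [filtered.montage.index(lab) for lab in keep]
        filtered = Recording(
            subject_id=filtered.subject_id,
            group=filtered.group,
            data=filtered.data[rows],
            fs=filtered.fs,
            montage=filtered.montage.subset(keep),
            annotations=list(filtered.annotations),
        )
    rereferenced = rereference_average(filtered)
    if cleaning_hook is not None:
        rereferenced = cleaning_hook(rereferenced)
    eo, ec = segment_conditions(rereferenced, cfg)
    for es in (eo, ec):
        es.rejected_channels = bad
    return eo, ec
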