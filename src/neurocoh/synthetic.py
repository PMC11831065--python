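"""Seeded synthetic resting-state EEG cohorts with known band-specific coherence.

The generator emulates a two-group resting-state study design: each subject
contributes one continuous multichannel recording made of alternating
eyes-open (EO) / eyes-closed (EC) blocks (by default 3 blocks of 60 s per
condition at 250 Hz).  Each channel is a sum of

* narrowband oscillatory *sources* — unit-variance Gaussian white noise
  band-pass filtered to ``center_freq ± bandwidth/2`` (zero-phase 4th-order
  Butterworth) — mixed into a subset of channels with per-channel gains, and
* independent ``1/f**exponent`` background noise (frequency-domain shaped
  white noise, exact target slope).

Because the model is linear with a single shared source per band and
independent additive noise, the population magnitude-squared coherence of any
channel pair is available in closed form (:func:`analytic_coherence`), which
makes the whole downstream pipeline verifiable against an analytic oracle.

Group and condition effects enter as multiplicative gain scales per source,
so a "case" group deficit in, say, 11–13 Hz frontal coupling is planted by
``group_gain_scale={"case": 0.4}`` on a frontal 11–13 Hz source.  Subjects are
not identical replicates: each subject draws one lognormal gain multiplier
per source (between-subject variability).

Everything is deterministic given ``(seed, subject_index, group)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import ConfigurationError, NumericalError
from .montage import Montage, default_montage

logger = logging.getLogger(__name__)

GROUPS = ("control", "case")
CONDITIONS = ("EO", "EC")


@dataclass(frozen=True)
class SourceSpec:
    """One shared narrowband source.

    Parameters
    ----------
    center_freq, bandwidth
        Pass band is ``[center_freq - bandwidth/2, center_freq + bandwidth/2]`` Hz.
    target_channels
        Montage labels the source is mixed into.
    gain
        Mixing amplitude per target channel (dimensionless; a scalar applies
        to all targets).
    group_gain_scale
        Multiplier on ``gain`` per group, e.g. ``{"case": 0.4}``; missing
        groups default to 1.
    condition_gain_scale
        Multiplier per condition, e.g. ``{"EC": 0.0}`` for an EO-only source.
    jitter_sigma
        Sigma of the per-subject lognormal gain multiplier (0.10 → roughly
        ±10 % between-subject spread).
    channel_gain_jitter_sigma
        If > 0, each (subject, target channel) additionally draws its own
        lognormal gain multiplier.  This models diffuse synchrony whose
        scalp pattern differs between subjects — without it, a source mixed
        uniformly into every channel would vanish under average
        re-referencing.
    """

    center_freq: float
    bandwidth: float
    target_channels: tuple[str, ...]
    gain: float = 1.0
    group_gain_scale: dict = field(default_factory=dict)
    condition_gain_scale: dict = field(default_factory=dict)
    jitter_sigma: float = 0.10
    channel_gain_jitter_sigma: float = 0.0

    def band_edges(self) -> tuple[float, float]:
        return (self.center_freq - self.bandwidth / 2.0, self.center_freq + self.bandwidth / 2.0)

    def scale_for(self, group: str, condition: str) -> float:
        return float(self.group_gain_scale.get(group, 1.0)) * float(
            self.condition_gain_scale.get(condition, 1.0)
        )

    def validate(self, montage: Montage, fs: float) -> None:
        lo, hi = self.band_edges()
        if lo <= 0:
            raise ConfigurationError(f"source band extends to {lo} Hz <= 0")
        if hi >= fs / 2.0:
            raise ConfigurationError(f"source band extends to {hi} Hz >= Nyquist ({fs / 2})")
        missing = set(self.target_channels) - set(montage.labels)
        if missing:
            raise ConfigurationError(f"source targets not in montage: {sorted(missing)}")
        if self.gain < 0 or self.jitter_sigma < 0 or self.channel_gain_jitter_sigma < 0:
            raise ConfigurationError("gains and jitter sigmas must be >= 0")
        for d in (self.group_gain_scale, self.condition_gain_scale):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError("gain scales must be >= 0")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic cohort.

    ``epoch_s`` is the duration of one annotated condition block and
    ``n_epochs`` the number of blocks per condition; the recording alternates
    EO/EC blocks, so its total length is ``2 * n_epochs * epoch_s`` seconds.
    """

    montage: Montage = field(default_factory=default_montage)
    n_per_group: int = 12
    sources: tuple[SourceSpec, ...] = ()
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    fs: float = 250.0
    epoch_s: float = 60.0
    n_epochs: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")
        n = self.epoch_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError("epoch_s * fs must be an integer sample count")
        if self.n_epochs < 1:
            raise ConfigurationError("n_epochs must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for src in self.sources:
            src.validate(self.montage, self.fs)

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_s * self.fs))

    @property
    def n_samples(self) -> int:
        return 2 * self.n_epochs * self.samples_per_epoch


@dataclass
class Recording:
    """One subject's multichannel time series with condition annotations.

    ``annotations`` is a list of ``(condition, start_sample, end_sample)``
    with half-open ``[start, end)`` sample intervals.
    """

    subject_id: str
    group: str
    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    montage: Montage
    annotations: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.montage):
            raise ConfigurationError("data must be (n_channels, n_samples) matching the montage")
        if self.fs <= 0:
            raise ConfigurationError("fs must be > 0")
        prev_end = None
        for cond, start, end in sorted(self.annotations, key=lambda a: a[1]):
            if cond not in CONDITIONS:
                raise ConfigurationError(f"unknown condition {cond!r}")
            if not (0 <= start < end <= self.data.shape[1]):
                raise ConfigurationError("annotation interval out of data bounds")
            if prev_end is not None and start < prev_end:
                raise ConfigurationError("annotations overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray | None = None, montage: Montage | None = None) -> "Recording":
        return Recording(
            subject_id=self.subject_id,
            group=self.group,
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            montage=self.montage if montage is None else montage,
            annotations=list(self.annotations),
        )


# ---------------------------------------------------------------------------
# signal building blocks


def _source_sos(spec: SourceSpec, fs: float):
    lo, hi = spec.band_edges()
    return signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")


def narrowband_source(rng: np.random.Generator, spec: SourceSpec, n: int, fs: float) -> np.ndarray:
    """Unit-variance white noise band-passed to the source band (zero-phase)."""
    white = rng.standard_normal(n)
    return signal.sosfiltfilt(_source_sos(spec, fs), white)


def source_psd(spec: SourceSpec, freqs: np.ndarray, fs: float) -> np.ndarray:
    """One-sided PSD of a unit-gain source realization at ``freqs``.

    The source is unit-variance white noise (one-sided PSD ``2/fs``) passed
    forward and backward through the 4th-order Butterworth band-pass, so its
    PSD is ``(2/fs) * |H(f)|**4``.
    """
    sos = _source_sos(spec, fs)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(np.asarray(freqs, dtype=float)), fs=fs)
    return (2.0 / fs) * np.abs(h) ** 4


def _powerlaw_shape(n: int, fs: float, exponent: float) -> tuple[np.ndarray, float]:
    """rfft-bin amplitude shape for 1/f**exponent noise and its variance norm.

    Returns ``(s, var)`` where ``s[k]`` multiplies the rfft of unit white
    noise and ``var`` is the variance of the resulting time series.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    s = np.zeros_like(freqs)
    s[1:] = freqs[1:] ** (-exponent / 2.0)
    # var(x) = (1/n) * (s_0^2 + 2*sum_mid(s_k^2) + s_nyq^2)  for even n
    if n % 2 == 0:
        var = (s[0] ** 2 + 2.0 * np.sum(s[1:-1] ** 2) + s[-1] ** 2) / n
    else:
        var = (s[0] ** 2 + 2.0 * np.sum(s[1:] ** 2)) / n
    return s, var


def powerlaw_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, sd: float, size: int = 1
) -> np.ndarray:
    """``size`` independent 1/f**exponent noise traces of length ``n``, std ``sd``."""
    s, var = _powerlaw_shape(n, fs, exponent)
    white = rng.standard_normal((size, n))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * s[None, :], n=n, axis=1)
    return shaped * (sd / np.sqrt(var))


def noise_psd(freqs: np.ndarray, config: SynthConfig) -> np.ndarray:
    """One-sided PSD of the background noise at ``freqs`` (Hz > 0)."""
    s, var = _powerlaw_shape(config.n_samples, config.fs, config.noise_exponent)
    c2 = config.noise_sd**2 / var
    f = np.asarray(freqs, dtype=float)
    return 2.0 * c2 * f ** (-config.noise_exponent) / config.fs


# ---------------------------------------------------------------------------
# analytic oracle


def analytic_coherence(
    gain_x: float, gain_y: float, source_psd: float, noise_psd_x: float, noise_psd_y: float
) -> float:
    """Population MSC of two channels sharing one source with independent noise.

    For ``x = g_x u + n_x`` and ``y = g_y u + n_y`` with source PSD ``S`` and
    noise PSDs ``N_x, N_y`` at one frequency, the magnitude-squared coherence
    ``|P_xy|^2 / (P_xx P_yy)`` evaluates to

    ``(g_x g_y S)^2 / ((g_x^2 S + N_x)(g_y^2 S + N_y))``.
    """
    if min(gain_x, gain_y, source_psd, noise_psd_x, noise_psd_y) < 0:
        raise ConfigurationError("all inputs must be >= 0")
    px = gain_x**2 * source_psd + noise_psd_x
    py = gain_y**2 * source_psd + noise_psd_y
    if px <= 0 or py <= 0:
        raise NumericalError("coherence undefined: zero total power on a channel")
    return (gain_x * gain_y * source_psd) ** 2 / (px * py)


def expected_coherence(
    config: SynthConfig, label_x: str, label_y: str, freq: float, group: str = "control",
    condition: str = "EO",
) -> float:
    """Population MSC of a generated channel pair at one frequency.

    Generalises :func:`analytic_coherence` to several independent shared
    sources: ``C = (sum_i gx_i gy_i S_i)^2 / (Pxx Pyy)``.  Between-subject
    gain jitter is evaluated at its median (multiplier 1).
    """
    nf = float(noise_psd(np.array([freq]), config)[0])
    cross = 0.0
    px = nf
    py = nf
    for src in config.sources:
        s = float(source_psd(src, np.array([freq]), config.fs)[0])
        g = src.gain * src.scale_for(group, condition)
        gx = g if label_x in src.target_channels else 0.0
        gy = g if label_y in src.target_channels else 0.0
        cross += gx * gy * s
        px += gx**2 * s
        py += gy**2 * s
    if px <= 0 or py <= 0:
        raise NumericalError("coherence undefined: zero total power on a channel")
    return cross**2 / (px * py)


# ---------------------------------------------------------------------------
# generation


def _subject_rngs(config: SynthConfig, subject_index: int, group: str):
    """Independent, reproducible RNG streams for one subject.

    Streams are keyed on (config seed, group, subject index) so cohorts are
    reproducible and subjects mutually independent.
    """
    group_code = GROUPS.index(group)
    ss = np.random.SeedSequence(config.seed, spawn_key=(group_code, subject_index))
    children = ss.spawn(len(config.sources) + 2)
    src_rngs = [np.random.default_rng(c) for c in children[: len(config.sources)]]
    noise_rng = np.random.default_rng(children[-2])
    jitter_rng = np.random.default_rng(children[-1])
    return src_rngs, noise_rng, jitter_rng


def _annotations(config: SynthConfig) -> list[tuple[str, int, int]]:
    spe = config.samples_per_epoch
    out = []
    for block in range(2 * config.n_epochs):
        cond = CONDITIONS[block % 2]  # EO first, alternating every block
        out.append((cond, block * spe, (block + 1) * spe))
    return out


def generate_subject(config: SynthConfig, subject_index: int, group: str) -> Recording:
    """Generate one subject's annotated multichannel recording.

    Deterministic given ``(config.seed, subject_index, group)``.
    """
    if group not in GROUPS:
        raise ConfigurationError(f"group must be one of {GROUPS}")
    if not 0 <= subject_index < config.n_per_group:
        raise ConfigurationError("subject_index out of range")

    n = config.n_samples
    n_ch = len(config.montage)
    annotations = _annotations(config)
    src_rngs, noise_rng, jitter_rng = _subject_rngs(config, subject_index, group)

    data = powerlaw_noise(
        noise_rng, n, config.fs, config.noise_exponent, config.noise_sd, size=n_ch
    )

    label_to_row = {lab: i for i, lab in enumerate(config.montage.labels)}
    for src, rng in zip(config.sources, src_rngs):
        wave = narrowband_source(rng, src, n, config.fs)
        jitter = float(np.exp(jitter_rng.normal(0.0, src.jitter_sigma)))
        if src.channel_gain_jitter_sigma > 0:
            ch_mult = np.exp(
                jitter_rng.normal(0.0, src.channel_gain_jitter_sigma, len(src.target_channels))
            )
        else:
            ch_mult = np.ones(len(src.target_channels))
        # per-sample condition scaling over the annotated blocks
        scaled = wave.copy()
        for cond, start, end in annotations:
            cscale = float(src.condition_gain_scale.get(cond, 1.0))
            if cscale != 1.0:
                scaled[start:end] *= cscale
        amp = src.gain * float(src.group_gain_scale.get(group, 1.0)) * jitter
        for lab, m in zip(src.target_channels, ch_mult):
            data[label_to_row[lab]] += amp * m * scaled

    return Recording(
        subject_id=f"{group}-{subject_index:02d}",
        group=group,
        data=data,
        fs=config.fs,
        montage=config.montage,
        annotations=annotations,
    )


def generate_cohort(config: SynthConfig) -> list[Recording]:
    """Generate the full two-group cohort (controls first, then cases)."""
    recs = [generate_subject(config, i, "control") for i in range(config.n_per_group)]
    recs += [generate_subject(config, i, "case") for i in range(config.n_per_group)]
    logger.info(
        "generated cohort: %d subjects (%d per group), %d channels, %.0f s each",
        len(recs), config.n_per_group, len(config.montage), config.n_samples / config.fs,
    )
    return recs


# ---------------------------------------------------------------------------
# canonical fixture cohorts

#: Channels carrying the planted upper-alpha deficit (right frontal + frontal midline,
#: mirroring a right-frontal-dominant connectivity reduction).
DEFICIT_CHANNELS = ("Fp2", "AF4", "F4", "F8", "FC6", "Fz")

_FRONTAL_MIDLINE = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC6", "Cz",
)
_POSTERIOR = ("P3", "Pz", "P4", "PO3", "PO4", "O1", "Oz", "O2")
_THETA_MIDLINE = ("Fz", "FC1", "FC2", "Cz")


def demo_config(
    n_per_group: int = 12,
    seed: int = 0,
    case_deficit_scale: float = 0.4,
    montage: Montage | None = None,
) -> SynthConfig:
    """The canonical planted-deficit cohort.

    Emulates the study design at desk scale: 32 channels, ``n_per_group``
    subjects per group, 3 alternating 60-s EO/EC blocks per condition at
    250 Hz.  Sources:

    * posterior alpha (7.5–10.5 Hz), stronger with eyes closed — the classic
      Berger effect; group-neutral;
    * frontal/midline background alpha (7.5–10.5 Hz), group-neutral, with
      large between-subject variability (resting alpha power varies widely
      across individuals);
    * midline theta (4–7 Hz), group-neutral;
    * diffuse upper-alpha synchrony (10.5–13.5 Hz) mixed into every channel
      with a subject-specific scalp pattern — group-neutral between-subject
      variability in exactly the range of the planted effect, which is what
      keeps tiny systematic artifacts (e.g. common-reference leakage of the
      deficit source) below the detection floor, as in real cohorts;
    * frontal 11.2–12.8 Hz coupling, present with eyes open only, whose gain
      is scaled by ``case_deficit_scale`` in the case group — the planted
      connectivity deficit the pipeline is meant to recover.
    """
    all_channels = (default_montage() if montage is None else montage).labels
    sources = (
        SourceSpec(
            center_freq=9.0, bandwidth=3.0, target_channels=_POSTERIOR,
            gain=1.35, condition_gain_scale={"EC": 1.6}, jitter_sigma=0.5,
        ),
        SourceSpec(
            center_freq=9.0, bandwidth=3.0, target_channels=_FRONTAL_MIDLINE,
            gain=1.9, jitter_sigma=0.5,
        ),
        SourceSpec(
            center_freq=5.5, bandwidth=3.0, target_channels=_THETA_MIDLINE,
            gain=1.2, jitter_sigma=0.3,
        ),
        SourceSpec(
            center_freq=12.0, bandwidth=3.0, target_channels=all_channels,
            gain=0.8, jitter_sigma=0.3, channel_gain_jitter_sigma=0.5,
        ),
        SourceSpec(
            center_freq=12.0, bandwidth=1.6, target_channels=DEFICIT_CHANNELS,
            gain=1.5, group_gain_scale={"case": case_deficit_scale},
            condition_gain_scale={"EC": 0.0}, jitter_sigma=0.10,
        ),
    )
    # NB: keeping the deficit source on a small minority of channels matters:
    # with an average reference, a source on k of n channels leaks a k/n copy
    # of itself into every channel, and a large k/n would smear the group
    # difference over the whole montage.
    return SynthConfig(
        montage=default_montage() if montage is None else montage,
        n_per_group=n_per_group,
        sources=sources,
        seed=seed,
    )


def null_config(n_per_group: int = 12, seed: int = 0, montage: Montage | None = None) -> SynthConfig:
    """Same generative law in both groups (no planted difference)."""
    return demo_config(
        n_per_group=n_per_group, seed=seed, case_deficit_scale=1.0, montage=montage
    )


_SMALL_LABELS = ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "C3", "Cz", "C4",
                 "P3", "Pz", "P4", "O1", "Oz", "O2")


def small_null_config(seed: int = 0, n_per_group: int = 10) -> SynthConfig:
    """A reduced null cohort for Monte-Carlo studies of the testing procedure.

    16 channels, 3 alternating 30-s blocks per condition: the same coherence
    structure in both groups (posterior and frontal alpha plus diffuse
    upper-alpha synchrony), small enough that many seeds can be run while
    still exercising realistic inter-channel dependence.
    """
    montage = default_montage().subset(list(_SMALL_LABELS))
    sources = (
        SourceSpec(
            center_freq=9.0, bandwidth=3.0,
            target_channels=("P3", "Pz", "P4", "O1", "Oz", "O2"),
            gain=1.35, condition_gain_scale={"EC": 1.6}, jitter_sigma=0.5,
        ),
        SourceSpec(
            center_freq=9.0, bandwidth=3.0,
            target_channels=("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
            gain=1.9, jitter_sigma=0.5,
        ),
        SourceSpec(
            center_freq=12.0, bandwidth=3.0, target_channels=montage.labels,
            gain=0.8, jitter_sigma=0.3, channel_gain_jitter_sigma=0.5,
        ),
    )
    return SynthConfig(
        montage=montage, n_per_group=n_per_group, sources=sources,
        epoch_s=30.0, n_epochs=3, seed=seed,
    )
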