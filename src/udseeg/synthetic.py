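"""Synthetic two-class EEG data with the statistical structure the analysis assumes.

Two fidelity levels are provided:

* **feature level** — per-channel SampEn values drawn from class-conditional
  Gaussians with the default profile moments (exact means/SDs), for testing
  everything downstream of feature extraction;
* **signal level** — multichannel epochs and marked continuous recordings
  built from MIX(p) processes (a periodic carrier whose samples are replaced
  by uniform noise with probability p), so that per-channel signal
  complexity, and therefore SampEn, is *ordered* between classes the way the
  profile means are ordered.  MIX has no closed-form SampEn, so signal-level
  means match the profiles in direction, not value.

Continuous recordings carry event markers, optional amplitude artifacts
(> +/-50 uV pulses) and linear baseline drift, exercising every
preprocessing rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .containers import ContinuousRecording, EpochSet, FeatureMatrix
from .profiles import NUDS, UDS, ChannelProfile, default_profiles

__all__ = [
    "GeneratorConfig",
    "mix_process",
    "mix_p_from_profiles",
    "generate_feature_table",
    "generate_epoch_signals",
    "generate_marked_recording",
]

#: EEG-scale amplitude (uV) applied to unit-variance MIX signals; the
#: implied peak (sqrt(3)*20 ~ 35 uV) stays inside the +/-50 uV artifact bound.
_SIGNAL_AMPLITUDE_UV = 20.0

#: Carrier frequency of the MIX process (alpha band).
_CARRIER_HZ = 10.0

#: Injected artifact pulses: 25 ms duration keeps the pulse band below the
#: 70 Hz low-pass edge so the excursion survives filtering.
_ARTIFACT_PULSE_MS = 25.0
# Pulse plateau (uV): large enough that the excursion still clears the
# +/-50 uV rejection bound after drift, filtering and baseline correction.
_ARTIFACT_AMP_RANGE_UV = (100.0, 150.0)


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults reproduce the recording conditions the analysis assumes:
    16 participants, 50 marked events per condition each, 1000 Hz sampling
    and 1-s epochs (100 ms pre-marker, 900 ms post).
    """

    n_subjects: int = 16
    events_per_condition: int = 50
    fs: float = 1000.0
    epoch_len: int = 1000
    seed: int = 0
    artifact_rate: float = 0.05          # probability per marker window
    drift_slope: float = 0.2             # uV/s linear baseline drift
    marker_spacing_s: float = 1.5
    mix_p_uds: float | Sequence[float] | None = None
    mix_p_nuds: float | Sequence[float] | None = None
    profiles: list[ChannelProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.n_subjects < 0 or self.events_per_condition < 0:
            raise ValueError("counts must be non-negative")
        if self.epoch_len <= 0:
            raise ValueError("epoch_len must be > 0")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be in [0, 1]")
        for p in (self.mix_p_uds, self.mix_p_nuds):
            if p is None:
                continue
            arr = np.atleast_1d(np.asarray(p, dtype=float))
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("mix probabilities must be in [0, 1]")

    @property
    def channel_labels(self) -> list[str]:
        return [p.channel_label for p in self.profiles]

    def resolved_mix_p(self, cls: str) -> np.ndarray:
        """Per-channel MIX replacement probability for class ``cls``."""
        override = self.mix_p_uds if cls == UDS else self.mix_p_nuds
        if override is None:
            return mix_p_from_profiles(self.profiles, cls)
        arr = np.atleast_1d(np.asarray(override, dtype=float))
        if arr.size == 1:
            return np.full(len(self.profiles), arr[0])
        if arr.size != len(self.profiles):
            raise ValueError("mix_p length must match the number of channels")
        return arr


def mix_process(
    n: int,
    p: float,
    rng: np.random.Generator,
    fs: float = 1000.0,
    freq: float = _CARRIER_HZ,
) -> np.ndarray:
    """MIX(p) benchmark signal of length ``n`` (unit amplitude / variance).

    A sinusoid at ``freq`` Hz whose samples are independently replaced, with
    probability ``p``, by uniform noise on [-sqrt(3), sqrt(3)] (unit
    variance).  Complexity — and SampEn — increases monotonically with p.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    t = np.arange(n) / fs
    x = np.sin(2.0 * np.pi * freq * t)
    mask = rng.random(n) < p
    x[mask] = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=int(mask.sum()))
    return x


def mix_p_from_profiles(
    profiles: Sequence[ChannelProfile], cls: str
) -> np.ndarray:
    """Map class-conditional SampEn means to MIX replacement probabilities.

    The map is affine and increasing (clipped to [0.05, 0.95]), so the
    between-class ordering of the profile means is preserved in p, and —
    because SampEn is increasing in p — in the SampEn of the generated
    signals.  Absolute SampEn values are not calibrated.
    """
    means = np.array(
        [p.uds_mean if cls == UDS else p.nuds_mean for p in profiles]
    )
    return np.clip(2.0 * (means - 0.25), 0.05, 0.95)


def _validate_profiles(profiles: Sequence[ChannelProfile]) -> None:
    if len(profiles) == 0:
        raise ValueError("profiles must be nonempty")
    labels = [p.channel_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    for p in profiles:
        if not (p.uds_sd > 0 and p.nuds_sd > 0):
            raise ValueError(f"channel {p.channel_label!r}: SD must be > 0")


def generate_feature_table(
    profiles: Sequence[ChannelProfile],
    n_per_class: int,
    seed: int,
    n_subjects: int = 16,
) -> FeatureMatrix:
    """Draw a labeled (2*n_per_class) x n_channels SampEn feature table.

    Column j of class c is sampled i.i.d. from Normal(mean_{j,c}, sd_{j,c})
    using the profile moments; rows are the UDS block followed by the NUDS
    block, with participant ids assigned round-robin within each class.
    """
    _validate_profiles(profiles)
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    labels = np.array([UDS] * n_per_class + [NUDS] * n_per_class, dtype=object)
    values = np.empty((2 * n_per_class, len(profiles)))
    for j, prof in enumerate(profiles):
        values[:n_per_class, j] = rng.normal(
            prof.uds_mean, prof.uds_sd, size=n_per_class
        )
        values[n_per_class:, j] = rng.normal(
            prof.nuds_mean, prof.nuds_sd, size=n_per_class
        )
    pids = np.concatenate(
        [np.arange(n_per_class) % max(n_subjects, 1)] * 2
    ) if n_per_class else np.array([], dtype=int)
    return FeatureMatrix(
        values, labels, [p.channel_label for p in profiles], pids
    )


def generate_epoch_signals(
    config: GeneratorConfig,
    profiles: Sequence[ChannelProfile] | None = None,
) -> EpochSet:
    """Generate class-labeled multichannel epochs directly (no continuous stage).

    Each (epoch, channel) series is an independent MIX(p) draw with p set by
    the channel/class calibration (or the explicit ``mix_p_*`` overrides),
    scaled to EEG amplitude.
    """
    if profiles is not None:
        config = GeneratorConfig(**{**config.__dict__, "profiles": list(profiles)})
    _validate_profiles(config.profiles)
    rng = np.random.default_rng(config.seed)
    n_chan = len(config.profiles)
    n_per_class = config.n_subjects * config.events_per_condition
    p_by_class = {UDS: config.resolved_mix_p(UDS), NUDS: config.resolved_mix_p(NUDS)}

    data = np.empty((2 * n_per_class, n_chan, config.epoch_len))
    labels = np.array([UDS] * n_per_class + [NUDS] * n_per_class, dtype=object)
    pids = np.empty(2 * n_per_class, dtype=int)
    for k, cls in enumerate((UDS, NUDS)):
        ps = p_by_class[cls]
        for e in range(n_per_class):
            row = k * n_per_class + e
            pids[row] = e // max(config.events_per_condition, 1)
            for c in range(n_chan):
                data[row, c] = _SIGNAL_AMPLITUDE_UV * mix_process(
                    config.epoch_len, ps[c], rng, fs=config.fs
                )
    pre_ms = 100.0
    post_ms = config.epoch_len * 1000.0 / config.fs - pre_ms
    return EpochSet(
        data, labels, pids, config.fs, config.channel_labels, (pre_ms, post_ms)
    )


def generate_marked_recording(
    config: GeneratorConfig,
    participant: int = 0,
    seed: int | None = None,
) -> ContinuousRecording:
    """Continuous recording for one participant with event markers.

    Layout: ``events_per_condition`` NUDS markers followed by the same
    number of UDS markers, spaced ``marker_spacing_s`` apart.  The 1-s
    window around each marker carries the class-specific MIX signal; the
    background between windows is MIX(0.5).  Linear drift
    (``drift_slope`` uV/s) is added to every channel, and with probability
    ``artifact_rate`` a marker window receives a rectangular >50 uV pulse
    on one random channel; pulse positions are recorded in ``artifacts``.
    """
    _validate_profiles(config.profiles)
    fs = config.fs
    pre = int(round(0.100 * fs))
    post = int(round(0.900 * fs))
    span = pre + post
    spacing = int(round(config.marker_spacing_s * fs))
    if spacing < span:
        raise ValueError(
            f"marker spacing ({spacing} samples) must be >= epoch span ({span})"
        )
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_events = config.events_per_condition
    n_chan = len(config.profiles)
    n_markers = 2 * n_events
    n_samples = spacing * (n_markers + 1)

    data = np.empty((n_chan, n_samples))
    for c in range(n_chan):
        data[c] = _SIGNAL_AMPLITUDE_UV * mix_process(n_samples, 0.5, rng, fs=fs)

    markers: list[tuple[int, str]] = []
    artifacts: list[tuple[int, int]] = []
    p_by_class = {UDS: config.resolved_mix_p(UDS), NUDS: config.resolved_mix_p(NUDS)}
    pulse_len = max(1, int(round(_ARTIFACT_PULSE_MS / 1000.0 * fs)))
    for k in range(n_markers):
        cls = NUDS if k < n_events else UDS
        onset = spacing * (k + 1)
        markers.append((onset, cls))
        lo, hi = onset - pre, onset + post
        ps = p_by_class[cls]
        for c in range(n_chan):
            data[c, lo:hi] = _SIGNAL_AMPLITUDE_UV * mix_process(
                span, ps[c], rng, fs=fs
            )
        if rng.random() < config.artifact_rate:
            chan = int(rng.integers(n_chan))
            start = int(rng.integers(lo, hi - pulse_len))
            amp = rng.uniform(*_ARTIFACT_AMP_RANGE_UV) * rng.choice([-1.0, 1.0])
            data[chan, start : start + pulse_len] = amp
            artifacts.append((chan, start))

    if config.drift_slope != 0.0:
        data += config.drift_slope * (np.arange(n_samples) / fs)

    return ContinuousRecording(
        data, fs, config.channel_labels, markers, artifacts
    )
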