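"""Per-channel sample-entropy profiles for the two driving states.

The 30 scalp channels follow the International 10-20 montage in the fixed
order used throughout the package (FP1 first, O2 last).  Each channel
carries class-conditional SampEn moments (mean, SD) for the unfavorable
driving state (UDS) and the non-unfavorable driving state (NUDS); the
default profile set reproduces the empirical statistics of a 16-participant
driving-simulator study (800 one-second epochs per class) and is the basis
of the feature-level synthetic generator.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ChannelProfile",
    "CHANNELS_10_20",
    "default_profiles",
    "separated_profiles",
    "UDS",
    "NUDS",
]

#: Class labels. UDS (unfavorable driving state) is the positive class.
UDS = "UDS"
NUDS = "NUDS"

#: 10-20 montage channel order used for every feature matrix column layout.
CHANNELS_10_20 = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8", "FT7", "FC3", "FCZ",
    "FC4", "FT8", "T7", "C3", "CZ", "C4", "T8", "TP7", "CP3", "CPZ",
    "CP4", "TP8", "P7", "P3", "PZ", "P4", "P8", "O1", "OZ", "O2",
)


@dataclass(frozen=True)
class ChannelProfile:
    """Class-conditional SampEn moments for one channel.

    Attributes
    ----------
    channel_label : str
        10-20 montage name (e.g. ``"C3"``).
    uds_mean, uds_sd : float
        Mean and standard deviation of SampEn in the unfavorable state.
    nuds_mean, nuds_sd : float
        Mean and standard deviation in the non-unfavorable state.
    """

    channel_label: str
    uds_mean: float
    uds_sd: float
    nuds_mean: float
    nuds_sd: float

    def __post_init__(self) -> None:
        if not (self.uds_sd > 0 and self.nuds_sd > 0):
            raise ValueError(
                f"channel {self.channel_label!r}: SD values must be > 0"
            )


# channel -> (uds_mean, uds_sd, nuds_mean, nuds_sd).  In 25 of 30 channels
# SampEn is lower in the unfavorable state; FP2 (marginally), F4, FC4,
# CP3 and CP4 reverse.
_DEFAULT_PARAMS = {
    "FP1": (0.488, 0.141, 0.495, 0.134),
    "FP2": (0.553, 0.131, 0.551, 0.122),
    "F7": (0.436, 0.143, 0.483, 0.168),
    "F3": (0.447, 0.129, 0.511, 0.193),
    "FZ": (0.411, 0.133, 0.482, 0.140),
    "F4": (0.569, 0.157, 0.512, 0.136),
    "F8": (0.486, 0.141, 0.521, 0.164),
    "FT7": (0.432, 0.148, 0.487, 0.164),
    "FC3": (0.474, 0.144, 0.526, 0.197),
    "FCZ": (0.394, 0.147, 0.445, 0.137),
    "FC4": (0.519, 0.161, 0.509, 0.153),
    "FT8": (0.482, 0.136, 0.504, 0.148),
    "T7": (0.462, 0.154, 0.522, 0.155),
    "C3": (0.424, 0.127, 0.534, 0.159),
    "CZ": (0.424, 0.143, 0.453, 0.142),
    "C4": (0.505, 0.128, 0.571, 0.182),
    "T8": (0.532, 0.141, 0.575, 0.128),
    "TP7": (0.447, 0.154, 0.527, 0.167),
    "CP3": (0.527, 0.150, 0.516, 0.169),
    "CPZ": (0.393, 0.154, 0.458, 0.163),
    "CP4": (0.586, 0.156, 0.525, 0.145),
    "TP8": (0.533, 0.158, 0.553, 0.129),
    "P7": (0.480, 0.169, 0.496, 0.146),
    "P3": (0.411, 0.133, 0.506, 0.154),
    "PZ": (0.414, 0.163, 0.493, 0.159),
    "P4": (0.520, 0.137, 0.555, 0.154),
    "P8": (0.541, 0.158, 0.568, 0.157),
    "O1": (0.459, 0.146, 0.465, 0.122),
    "OZ": (0.453, 0.143, 0.532, 0.139),
    "O2": (0.485, 0.146, 0.505, 0.152),
}

#: Channels whose UDS mean exceeds the NUDS mean in the default profiles.
REVERSED_CHANNELS = ("FP2", "F4", "FC4", "CP3", "CP4")

#: Channels whose two-sample comparison is expected at p < 0.001 with
#: 800 epochs per class under the default profiles.
STRONG_CHANNELS = ("FZ", "FCZ", "C3", "TP7", "CPZ", "P3", "PZ", "OZ")


def default_profiles() -> list[ChannelProfile]:
    """Return the default 30-channel profile set, montage order."""
    return [
        ChannelProfile(ch, *_DEFAULT_PARAMS[ch]) for ch in CHANNELS_10_20
    ]


def separated_profiles(shift_sd: float = 10.0) -> list[ChannelProfile]:
    """Profile set with the NUDS means shifted away from the UDS means.

    Shifting every channel by ``shift_sd`` pooled SDs makes the two classes
    (near-)linearly separable; used as a stress preset for classifier
    sanity checks, not as a model of real data.
    """
    out = []
    for ch in CHANNELS_10_20:
        um, us, nm, ns = _DEFAULT_PARAMS[ch]
        out.append(ChannelProfile(ch, um, us, um + shift_sd * us, ns))
    return out
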