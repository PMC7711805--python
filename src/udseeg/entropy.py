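"""Signal-complexity features: sample entropy, approximate entropy and
spectral entropy, plus batch extraction over an epoch set.

Sample entropy (SampEn) of a series u(1..N) with embedding dimension m and
tolerance r is

    SampEn(m, r, N) = -ln(A / B),

where B counts pairs of distinct m-length templates X(i), X(j) (i != j,
i, j in 1..N-m) whose Chebyshev distance — the maximum absolute
coordinate difference — is <= r, and A counts the same pairs at length
m + 1.  Self-matches are excluded, which removes the regularity bias of
approximate entropy (ApEn), the self-match-*inclusive* predecessor also
provided here for comparison.  Lower SampEn means a more self-similar
(regular) series; noisier series score higher.

Tolerance convention: r is conventionally a fraction of the series SD
(``r_mode="sd_fraction"``, default 0.2), which makes SampEn invariant
under affine rescaling of the signal; an absolute tolerance is available
for pre-normalized data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .containers import EpochSet, FeatureMatrix

__all__ = [
    "EntropyParams",
    "sample_entropy",
    "approximate_entropy",
    "spectral_entropy",
    "extract_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EntropyParams:
    """Estimator choice and its parameters.

    m >= 1 is the embedding dimension; r > 0 the similarity tolerance,
    interpreted per ``r_mode``.  ``fs`` is only used by the spectral
    estimator.
    """

    estimator: str = "sampen"            # sampen | apen | spectral
    m: int = 2
    r: float = 0.2
    r_mode: str = "sd_fraction"          # sd_fraction | absolute
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if self.estimator not in ("sampen", "apen", "spectral"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.r_mode not in ("sd_fraction", "absolute"):
            raise ValueError(f"unknown r_mode {self.r_mode!r}")


def _resolve_r(x: np.ndarray, r: float, r_mode: str) -> float:
    if r_mode == "absolute":
        return r
    sd = float(np.std(x))
    return r * sd


def _chebyshev_match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Pairs of matching templates at lengths m and m+1 over i,j in [0, N-m).

    Vectorized over the full pairwise |x_i - x_j| <= r boolean matrix; a
    length-k template pair matches iff all k diagonal-shifted entries
    match, so the m- and (m+1)-length counts come from running logical
    ANDs of shifted views of one matrix.
    """
    n = x.shape[0]
    nm = n - m  # templates of length m usable at both lengths
    close = np.abs(x[:, None] - x[None, :]) <= r
    acc = close[:nm, :nm].copy()
    for k in range(1, m):
        acc &= close[k : k + nm, k : k + nm]
    b_total = (int(acc.sum()) - nm) // 2  # unordered pairs, diagonal removed
    acc &= close[m : m + nm, m : m + nm]
    a_total = (int(acc.sum()) - nm) // 2
    return a_total, b_total


def sample_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                   r_mode: str = "sd_fraction") -> float:
    """SampEn(m, r) of a 1-D series; NaN when no template pair matches.

    Returns -ln(A/B) with self-matches excluded.  A zero count at either
    length leaves the statistic undefined; NaN is returned (and the batch
    extractor excludes such rows) rather than an arbitrary large number.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m+1 = {m + 1}")
    r_abs = _resolve_r(x, r, r_mode)
    if r_abs <= 0:  # constant series under sd_fraction: every pair matches
        return 0.0 if np.ptp(x) == 0 else np.nan
    a, b = _chebyshev_match_counts(x, m, r_abs)
    if a == 0 or b == 0:
        return np.nan
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float = 0.2,
                        r_mode: str = "sd_fraction") -> float:
    """ApEn(m, r): Phi^m - Phi^(m+1) with self-matches included.

    Phi^k = (N-k+1)^{-1} sum_i ln C_i^k, where C_i^k is the fraction of the
    N-k+1 length-k templates within r of template i (itself included, so
    every count is positive and ApEn is always finite).
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.shape[0]
    if n <= m + 1:
        raise ValueError(f"series length {n} must exceed m+1 = {m + 1}")
    r_abs = _resolve_r(x, r, r_mode)
    if r_abs <= 0:
        return 0.0 if np.ptp(x) == 0 else np.nan
    close = np.abs(x[:, None] - x[None, :]) <= r_abs

    def phi(k: int) -> float:
        nk = n - k + 1
        acc = close[:nk, :nk].copy()
        for s in range(1, k):
            acc &= close[s : s + nk, s : s + nk]
        counts = acc.sum(axis=1)  # includes the self-match
        return float(np.mean(np.log(counts / nk)))

    return phi(m) - phi(m + 1)


def spectral_entropy(x: np.ndarray, fs: float, band: tuple[float, float] = (0.5, 70.0)) -> float:
    """Normalized Shannon entropy of the periodogram PSD, in [0, 1].

    The PSD is restricted to ``band`` (Hz, clipped to Nyquist), normalized
    to a probability distribution, and its base-2 entropy is divided by
    log2 of the number of retained bins.  0 marks a single spectral line,
    1 a flat (white) spectrum; the value is invariant under amplitude
    scaling.  An all-zero signal has no spectrum: NaN is returned.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] < 8:
        raise ValueError("series too short for a spectral estimate")
    freqs, psd = sps.periodogram(x, fs=fs, detrend=False)
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= min(hi, fs / 2.0))
    psd = psd[sel]
    total = psd.sum()
    if total <= 0 or psd.size < 2:
        return np.nan
    p = psd / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h / float(np.log2(p.size))


_ESTIMATORS = {
    "sampen": lambda x, prm: sample_entropy(x, prm.m, prm.r, prm.r_mode),
    "apen": lambda x, prm: approximate_entropy(x, prm.m, prm.r, prm.r_mode),
    "spectral": lambda x, prm: spectral_entropy(x, prm.fs),
}


def extract_features(epochs: EpochSet, params: EntropyParams | None = None) -> FeatureMatrix:
    """One entropy value per (epoch, channel); undefined rows are dropped.

    With ``r_mode="sd_fraction"`` the tolerance is resolved from each
    individual epoch-channel series.  Rows containing any undefined value
    (NaN) are excluded and their count logged, so the returned matrix is
    complete.
    """
    params = params or EntropyParams(fs=epochs.fs)
    fn = _ESTIMATORS[params.estimator]
    n_ep, n_ch, _ = epochs.data.shape
    values = np.empty((n_ep, n_ch))
    for e in range(n_ep):
        for c in range(n_ch):
            values[e, c] = fn(epochs.data[e, c], params)
    good = ~np.isnan(values).any(axis=1)
    n_bad = int((~good).sum())
    if n_bad:
        logger.warning(
            "%d of %d epochs had undefined %s values and were excluded",
            n_bad, n_ep, params.estimator,
        )
    return FeatureMatrix(
        values[good],
        epochs.labels[good],
        list(epochs.channel_labels),
        epochs.participant_ids[good],
    )
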