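"""The 16-feature set computed per windowed EMG segment.

Four families, mirroring how facial-EMG classification work summarises a
window by amplitude, frequency, predictability and variability:

amplitude    mav, mavfd, mavsd, peak, rms
frequency    zc, fmed, fmode, fmean, cf
predictability  fuzzy_en, ap_en
variability  var, std, range, intrange

Units: amplitude/variability features inherit the signal unit (microvolts;
var is µV²), spectral features are in Hz, zc is a count, the entropies are
dimensionless.  One channel yields a 16-dimensional vector; the two-muscle
montage yields 32 dimensions with ``corr_``/``zyg_`` column prefixes.

Conventions that the definitions leave open are fixed here and documented:
the median frequency bisects the *power* spectrum while the mode and mean
frequency operate on the *magnitude* spectrum; the bandwidth edges behind
``cf`` are the half-power (-3 dB relative to the spectral peak) frequencies;
approximate entropy includes self-matches while fuzzy entropy excludes them;
exact-zero samples carry the previous sign in the zero-crossing count; the
entropy tolerance ``r`` is a fraction of the segment's population SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .windowing import LabeledSegment

__all__ = [
    "FEATURE_NAMES",
    "CHANNEL_PREFIXES",
    "EntropyParams",
    "Spectrum",
    "DegenerateInputError",
    "amplitude_features",
    "spectrum",
    "frequency_features",
    "zero_crossings",
    "approximate_entropy",
    "fuzzy_entropy",
    "variability_features",
    "feature_vector",
    "extract_feature_table",
    "feature_columns",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mav", "mavfd", "mavsd", "peak", "rms",
    "zc", "fmed", "fmode", "fmean", "cf",
    "fuzzy_en", "ap_en",
    "var", "std", "range", "intrange",
)

CHANNEL_PREFIXES = {"corrugator": "corr", "zygomaticus": "zyg"}

META_COLUMNS = ("subject", "condition", "class", "block_index")


class DegenerateInputError(ValueError):
    """Raised for inputs with no usable structure (all-zero spectrum, ...)."""


@dataclass(frozen=True)
class EntropyParams:
    """Embedding dimension ``m``, tolerance ``r`` (fraction of the segment SD)
    and fuzzy-membership exponent ``n``."""

    m: int = 2
    r: float = 0.2
    n: float = 2.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.r <= 0 or self.n < 1:
            raise ValueError("require m >= 1, r > 0, n >= 1")


@dataclass
class Spectrum:
    """One-sided discrete Fourier spectrum on the grid ``k * fs / N``."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    power: np.ndarray


def amplitude_features(x: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mav, mavfd, mavsd, peak, rms): mean |x|, mean |Δx|, mean |Δ²x|,
    max(x), root-mean-square."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for the second difference")
    mav = float(np.mean(np.abs(x)))
    mavfd = float(np.mean(np.abs(np.diff(x))))
    mavsd = float(np.mean(np.abs(np.diff(x, n=2))))
    peak = float(np.max(x))
    rms = float(np.sqrt(np.mean(x**2)))
    return mav, mavfd, mavsd, peak, rms


def spectrum(x: np.ndarray, fs: float) -> Spectrum:
    """One-sided DFT magnitude/power spectrum of the raw (unwindowed) segment."""
    x = np.asarray(x, dtype=float)
    if len(x) < 8:
        raise ValueError("need at least 8 samples")
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    mag = np.abs(X)
    return Spectrum(frequencies=freqs, magnitudes=mag, power=mag**2)


def frequency_features(sp: Spectrum) -> tuple[float, float, float, float]:
    """(fmed, fmode, fmean, cf) from a one-sided spectrum.

    fmed: smallest grid frequency at which cumulative power reaches half the
    total.  fmode: frequency of the magnitude maximum (lowest frequency wins
    ties).  fmean: magnitude-weighted mean frequency.  cf: half the width
    between the half-power band edges around the spectral peak.
    """
    total = float(np.sum(sp.power))
    if total <= 0 or float(np.sum(sp.magnitudes)) <= 0:
        raise DegenerateInputError("all-zero spectrum")
    cum = np.cumsum(sp.power)
    fmed = float(sp.frequencies[np.searchsorted(cum, 0.5 * total)])
    fmode = float(sp.frequencies[int(np.argmax(sp.magnitudes))])
    fmean = float(np.sum(sp.magnitudes * sp.frequencies) / np.sum(sp.magnitudes))
    half = float(np.max(sp.power)) / 2.0
    in_band = np.where(sp.power >= half)[0]
    fl = float(sp.frequencies[in_band[0]])
    fh = float(sp.frequencies[in_band[-1]])
    cf = (fh - fl) / 2.0
    return fmed, fmode, fmean, cf


def zero_crossings(x: np.ndarray) -> int:
    """Count of adjacent sample pairs with strictly opposite signs.

    Exact zeros inherit the previous nonzero sign, so a touch of zero is not
    double-counted; leading zeros carry no sign and cannot cross.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    s = np.sign(x).astype(int)
    nz = s != 0
    # forward-fill the previous nonzero sign into exact zeros
    idx = np.where(nz, np.arange(len(s)), -1)
    idx = np.maximum.accumulate(idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0)
    return int(np.sum(filled[:-1] * filled[1:] < 0))


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def approximate_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """ApEn(m, r): regularity of the series via template self-similarity.

    phi^m is the mean log fraction of m-length embedding vectors within
    Chebyshev distance ``r * SD`` of each template (self-match included);
    the statistic is ``phi^m - phi^{m+1}``.  Perfectly regular series score
    0; irregular series score higher.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= p.m + 1:
        raise ValueError("series too short: need N > m + 1")
    r_abs = p.r * float(np.std(x))
    def phi(m: int) -> float:
        emb = _embed(x, m)
        d = cdist(emb, emb, metric="chebyshev")
        c = np.mean(d <= r_abs, axis=1)  # self-match included
        return float(np.mean(np.log(c)))
    return phi(p.m) - phi(p.m + 1)


def fuzzy_entropy(x: np.ndarray, p: EntropyParams = EntropyParams()) -> float:
    """Fuzzy entropy: sample-entropy scheme with a smooth similarity kernel.

    Embedding vectors are mean-removed; similarity between two templates is
    ``exp(-(d / (r * SD))^n)`` with Chebyshev distance ``d``; self-matches
    are excluded; both template lengths use the same N - m vector count.
    Returns ``ln(Phi^m / Phi^{m+1})``; 0 for a constant series.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= p.m + 1:
        raise ValueError("series too short: need N > m + 1")
    r_abs = p.r * float(np.std(x))
    if r_abs == 0.0:
        return 0.0  # constant series: every template identical
    n_templates = len(x) - p.m
    def phi(m: int) -> float:
        emb = _embed(x, m)[:n_templates]
        emb = emb - emb.mean(axis=1, keepdims=True)
        d = cdist(emb, emb, metric="chebyshev")
        mu = np.exp(-((d / r_abs) ** p.n))
        np.fill_diagonal(mu, 0.0)
        return float(np.sum(mu) / (n_templates * (n_templates - 1)))
    phi_m, phi_m1 = phi(p.m), phi(p.m + 1)
    if phi_m1 <= 0 or phi_m <= 0:
        raise DegenerateInputError("no similarity mass at this tolerance")
    return float(np.log(phi_m / phi_m1))


def variability_features(x: np.ndarray) -> tuple[float, float, float, float]:
    """(var, std, range, intrange): sample variance (N-1), its root,
    max - min, and the semi-interquartile range with linearly interpolated
    quartiles."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    var = float(np.var(x, ddof=1))
    std = float(np.sqrt(var))
    rng = float(np.max(x) - np.min(x))
    q1, q3 = np.percentile(x, [25, 75])
    return var, std, rng, float((q3 - q1) / 2.0)


def feature_vector(
    x: np.ndarray, fs: float, params: EntropyParams = EntropyParams()
) -> dict[str, float]:
    """All 16 features of one segment, keyed by canonical feature name."""
    mav, mavfd, mavsd, peak, rms = amplitude_features(x)
    sp = spectrum(x, fs)
    fmed, fmode, fmean, cf = frequency_features(sp)
    var, std, rng, intrange = variability_features(x)
    return {
        "mav": mav, "mavfd": mavfd, "mavsd": mavsd, "peak": peak, "rms": rms,
        "zc": float(zero_crossings(x)),
        "fmed": fmed, "fmode": fmode, "fmean": fmean, "cf": cf,
        "fuzzy_en": fuzzy_entropy(x, params),
        "ap_en": approximate_entropy(x, params),
        "var": var, "std": std, "range": rng, "intrange": intrange,
    }


def feature_columns(channel_set: str) -> list[str]:
    """Ordered feature column names for a channel set."""
    if channel_set == "both":
        chans = ("corrugator", "zygomaticus")
    elif channel_set in CHANNEL_PREFIXES:
        chans = (channel_set,)
    else:
        raise ValueError(f"unknown channel_set {channel_set!r}")
    return [f"{CHANNEL_PREFIXES[c]}_{f}" for c in chans for f in FEATURE_NAMES]


def extract_feature_table(
    segments: list[LabeledSegment],
    fs: float,
    params: EntropyParams = EntropyParams(),
    channel_set: str = "both",
) -> pd.DataFrame:
    """One labelled row per (subject, window) with 16 features per channel.

    Rows are keyed by (subject, class, block_index, window start); the
    requested channels' features are laid out side by side with ``corr_``/
    ``zyg_`` prefixes in a fixed column order.
    """
    if not segments:
        raise ValueError("no segments supplied")
    wanted = feature_columns(channel_set)
    needed_channels = (
        ("corrugator", "zygomaticus") if channel_set == "both" else (channel_set,)
    )
    rows: dict[tuple, dict] = {}
    for seg in segments:
        if seg.channel not in needed_channels:
            continue
        key = (seg.subject, seg.condition, seg.label, seg.block_index, seg.start_s)
        row = rows.setdefault(
            key,
            {
                "subject": seg.subject,
                "condition": seg.condition,
                "class": seg.label,
                "block_index": seg.block_index,
            },
        )
        prefix = CHANNEL_PREFIXES[seg.channel]
        for name, value in feature_vector(seg.samples, fs, params).items():
            row[f"{prefix}_{name}"] = value
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: (r["subject"], r["block_index"], r["class"])))
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(
            f"channel_set {channel_set!r} requested but segments lack channels "
            f"for columns {missing[:3]}..."
        )
    df = df[list(META_COLUMNS) + wanted]
    if df[wanted].isna().any().any():
        raise ValueError("incomplete channel coverage: some windows miss a channel")
    return df.reset_index(drop=True)
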