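"""Acoustic low-level descriptors and functional statistics.

The built-in extractor computes a demonstrative cycle-level LLD (shimmer,
the relative variation of consecutive peak amplitudes) and summarizes any
LLD series with a fixed-order vector of functional statistics, so series
of different lengths always map to the same feature dimensionality.
High-dimensional externally computed acoustic tables (e.g. a ComParE-style
export) are imported through :func:`load_acoustic_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile

from .blocks import FeatureBlock

logger = logging.getLogger(__name__)

__all__ = [
    "Waveform",
    "LLDSeries",
    "FunctionalVector",
    "FUNCTIONAL_NAMES",
    "detect_peaks",
    "compute_shimmer",
    "summarize_functionals",
    "extract_shimmer_functionals",
    "load_acoustic_table",
    "write_wav",
    "read_wav",
]

_EPS = 1e-12


class UndefinedShimmerError(ValueError):
    """Raised when fewer than two peaks make shimmer undefined."""


@dataclass
class Waveform:
    """Mono audio samples at a fixed rate.

    ``peak_amplitudes`` optionally carries generator ground truth (the
    per-cycle amplitudes a synthetic waveform was built with), used only
    by tests; real recordings leave it ``None``.
    """

    samples: np.ndarray
    rate: int = 16000
    peak_amplitudes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("waveform must be a 1-D sequence of length >= 2")


@dataclass
class LLDSeries:
    """One value per cycle/frame of a low-level descriptor."""

    values: np.ndarray
    lld_name: str = "shimmer"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LLD values must be finite")


# Fixed functional order: identical length and order for every series.
FUNCTIONAL_NAMES: tuple[str, ...] = (
    "sma_mean",
    "diff_mean",
    "diff_sd",
    "iqr",
    "min_positive",
    "peak_dist_mean",
    "peak_dist_sd",
    "peak_rel_height_mean",
    "flatness",
    "rise_time",
    "skewness",
    "centroid",
    "left_center_time",
)


@dataclass
class FunctionalVector:
    """Fixed-order named statistics of one LLD series."""

    values: dict[str, float]
    lld_name: str = "shimmer"

    def __post_init__(self) -> None:
        if tuple(self.values) != FUNCTIONAL_NAMES:
            raise ValueError("functional vector must follow the canonical name order")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FUNCTIONAL_NAMES])

    def feature_names(self) -> list[str]:
        return [f"{self.lld_name}_{n}" for n in FUNCTIONAL_NAMES]


def detect_peaks(w: Waveform, prominence_fraction: float = 0.05) -> list[tuple[int, float]]:
    """Local maxima above a relative prominence floor.

    The floor defaults to 5% of the signal's amplitude range, which
    suppresses noise ripples; a flat signal yields an empty list.
    """
    if w.samples.size < 3:
        raise ValueError("need at least 3 samples for peak detection")
    span = float(w.samples.max() - w.samples.min())
    if span <= _EPS:
        return []
    idx, _ = sps.find_peaks(w.samples, prominence=prominence_fraction * span)
    return [(int(i), float(w.samples[i])) for i in idx]


def compute_shimmer(peaks: list[tuple[int, float]]) -> LLDSeries:
    """Local shimmer: |a(k+1) - a(k)| / ((a(k+1) + a(k)) / 2).

    Normalizing each consecutive-amplitude difference by the pair mean
    makes the series invariant to overall gain.
    """
    if len(peaks) < 2:
        raise UndefinedShimmerError(f"shimmer needs >= 2 peaks, got {len(peaks)}")
    amps = np.array([a for _, a in peaks], dtype=float)
    pair_mean = (amps[1:] + amps[:-1]) / 2.0
    vals = np.abs(np.diff(amps)) / np.where(np.abs(pair_mean) > _EPS, pair_mean, _EPS)
    return LLDSeries(vals, "shimmer")


def _series_peaks(x: np.ndarray) -> np.ndarray:
    idx, _ = sps.find_peaks(x)
    return idx


def summarize_functionals(series: LLDSeries, set_name: str = "default") -> FunctionalVector:
    """Fixed-order functional statistics of one LLD series.

    Undefined statistics on degenerate input (skewness of a constant
    series, peak statistics with too few peaks, minimum positive value of
    a nonpositive series) return 0 by convention and are logged.

    Definitions fixed here: SDs are population (ddof=0) SDs; quantiles use
    linear interpolation between order statistics; ``rise_time`` is the
    fractional position of the series maximum; ``centroid`` is the
    magnitude-weighted mean fractional position; ``left_center_time`` is
    the same restricted to positions at or left of the maximum;
    ``flatness`` is the geometric/arithmetic mean ratio of magnitudes.
    """
    x = series.values
    n = x.size
    if n == 0:
        raise ValueError("empty LLD series")
    pos = np.arange(n, dtype=float)
    frac = pos / (n - 1) if n > 1 else pos

    window = min(5, n)
    sma = np.convolve(x, np.ones(window) / window, mode="valid")

    diffs = np.diff(x) if n > 1 else np.zeros(1)

    positive = x[x > 0]
    if positive.size == 0:
        logger.debug("no positive values in %s series; min_positive -> 0", series.lld_name)
        min_positive = 0.0
    else:
        min_positive = float(positive.min())

    peaks = _series_peaks(x)
    if peaks.size >= 2:
        dists = np.diff(peaks).astype(float)
        peak_dist_mean = float(dists.mean())
        peak_dist_sd = float(dists.std(ddof=0))
    else:
        logger.debug("fewer than 2 series peaks; peak-distance functionals -> 0")
        peak_dist_mean = peak_dist_sd = 0.0
    span = float(x.max() - x.min())
    if peaks.size >= 1 and span > _EPS:
        peak_rel_height = float(np.mean((x[peaks] - x.min()) / span))
    else:
        peak_rel_height = 0.0

    mags = np.abs(x)
    arith = float(mags.mean())
    flatness = float(np.exp(np.mean(np.log(mags + _EPS))) / (arith + _EPS))

    argmax = int(np.argmax(x))
    rise_time = float(frac[argmax]) if n > 1 else 0.0

    sd = float(x.std(ddof=0))
    if sd > _EPS:
        sk = float(np.mean((x - x.mean()) ** 3) / sd**3)
    else:
        logger.debug("skewness undefined (constant series); -> 0")
        sk = 0.0

    if mags.sum() > _EPS:
        centroid = float(np.sum(frac * mags) / mags.sum())
        left = slice(0, argmax + 1)
        left_mags = mags[left]
        if left_mags.sum() > _EPS:
            left_center = float(np.sum(frac[left] * left_mags) / left_mags.sum())
        else:
            left_center = 0.0
    else:
        logger.debug("all-zero series; centroid -> midpoint")
        centroid = 0.5 if n > 1 else 0.0
        left_center = 0.0

    values = {
        "sma_mean": float(sma.mean()),
        "diff_mean": float(diffs.mean()),
        "diff_sd": float(diffs.std(ddof=0)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "min_positive": min_positive,
        "peak_dist_mean": peak_dist_mean,
        "peak_dist_sd": peak_dist_sd,
        "peak_rel_height_mean": peak_rel_height,
        "flatness": flatness,
        "rise_time": rise_time,
        "skewness": sk,
        "centroid": centroid,
        "left_center_time": left_center,
    }
    return FunctionalVector(values, series.lld_name)


def extract_shimmer_functionals(waveforms: dict[str, Waveform]) -> FeatureBlock:
    """End-to-end built-in extraction: waveform -> peaks -> shimmer -> functionals."""
    ids, rows = [], []
    names: list[str] | None = None
    for pid, w in waveforms.items():
        fv = summarize_functionals(compute_shimmer(detect_peaks(w)))
        ids.append(pid)
        rows.append(fv.as_array())
        names = fv.feature_names()
    if names is None:
        raise ValueError("no waveforms supplied")
    return FeatureBlock(np.vstack(rows), names, ids, "acoustic")


def load_acoustic_table(path, participant_ids: list[str] | None = None) -> FeatureBlock:
    """Import an externally computed acoustic feature table (CSV/TSV).

    The table needs an ``id`` column plus numeric feature columns — the
    shape a ComParE-style extractor exports.  When ``participant_ids`` is
    given, rows are realigned to that order and missing ids raise.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep)
    if "id" not in frame.columns:
        raise ValueError("acoustic table needs an 'id' column")
    frame["id"] = frame["id"].astype(str)
    if frame["id"].duplicated().any():
        dupes = sorted(frame.loc[frame["id"].duplicated(), "id"].unique())
        raise ValueError(f"duplicate ids in acoustic table: {dupes}")
    if participant_ids is not None:
        wanted = [str(i) for i in participant_ids]
        missing = sorted(set(wanted) - set(frame["id"]))
        if missing:
            raise ValueError(f"acoustic table is missing participant ids: {missing}")
        frame = frame.set_index("id").loc[wanted].reset_index()
    return FeatureBlock.from_frame(frame, "acoustic")


def write_wav(path, w: Waveform) -> None:
    """Write PCM 16-bit mono, scaling to 90% full scale."""
    peak = float(np.max(np.abs(w.samples)))
    scaled = w.samples / peak * 0.9 if peak > 0 else w.samples
    wavfile.write(path, int(w.rate), (scaled * 32767).astype(np.int16))


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    return Waveform(data.astype(float) / 32767.0, int(rate))
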