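"""R-peak detection on lead II and heart-rate-variability indices.

The detector is a Pan–Tompkins-style chain: band-pass (5–15 Hz) →
derivative → squaring → moving-window integration → adaptive-threshold
peak picking with a 200 ms refractory period, followed by refinement of
each peak to the local maximum of the band-passed lead. From the R-peak
train the module computes nine HRV indices: SDNN, maximum / minimum /
mean RR interval, pNN50 (fraction of successive RR differences strictly
greater than 50 ms), R-wave density (peaks per second), RMSSD, and the
sample entropy of the RR series at embedding dimensions m=1 and m=2
(tolerance r = 0.2 x SD of the series).

SDNN uses the population (1/N) variance. Records on which fewer than
two beats are found yield the all-zero feature sentinel with
``valid=False`` so downstream fusion never fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import ECGRecord

__all__ = [
    "RRSeries",
    "HRVFeatures",
    "HRV_FEATURE_NAMES",
    "InsufficientBeatsError",
    "detect_rpeaks",
    "hrv_features",
    "hrv_features_for_record",
    "sample_entropy",
]

HRV_FEATURE_NAMES = (
    "sdnn",
    "rr_max",
    "rr_min",
    "rr_mean",
    "pnn50",
    "r_density",
    "rmssd",
    "sampen_m1",
    "sampen_m2",
)

_REFRACTORY_S = 0.2
_MWI_WINDOW_S = 0.15


class InsufficientBeatsError(ValueError):
    """Fewer than two R peaks found: no RR interval can be formed."""


@dataclass(frozen=True)
class RRSeries:
    """Detected R peaks and the inter-beat intervals they imply."""

    rr_ms: np.ndarray
    r_peak_indices: np.ndarray
    fs: float
    duration_s: float

    def __post_init__(self) -> None:
        rr = np.asarray(self.rr_ms, dtype=np.float64)
        idx = np.asarray(self.r_peak_indices, dtype=np.int64)
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "r_peak_indices", idx)
        if len(rr) != len(idx) - 1:
            raise ValueError("need len(rr_ms) == len(r_peak_indices) - 1")
        if len(rr) and rr.min() <= 0:
            raise ValueError("RR intervals must be positive")

    @classmethod
    def from_peaks(
        cls, indices: np.ndarray, fs: float, duration_s: float
    ) -> "RRSeries":
        indices = np.asarray(indices, dtype=np.int64)
        rr_ms = np.diff(indices) / fs * 1000.0
        return cls(rr_ms, indices, fs, duration_s)

    @property
    def n_peaks(self) -> int:
        return len(self.r_peak_indices)


@dataclass(frozen=True)
class HRVFeatures:
    sdnn: float
    rr_max: float
    rr_min: float
    rr_mean: float
    pnn50: float
    r_density: float
    rmssd: float
    sampen_m1: float
    sampen_m2: float
    valid: bool = True

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in HRV_FEATURE_NAMES])

    @classmethod
    def neutral(cls) -> "HRVFeatures":
        """All-zero sentinel for records where detection failed."""
        return cls(*([0.0] * len(HRV_FEATURE_NAMES)), valid=False)


def detect_rpeaks(lead2: np.ndarray, fs: float) -> RRSeries:
    """Detect R peaks in one lead; raises if fewer than two are found."""
    lead2 = np.asarray(lead2, dtype=np.float64)
    if lead2.ndim != 1:
        raise ValueError("detector expects a single lead")
    if lead2.shape[0] < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    duration_s = lead2.shape[0] / fs

    nyq = fs / 2.0
    high = min(15.0, 0.9 * nyq)
    sos = sps.butter(2, [5.0 / nyq, high / nyq], btype="band", output="sos")
    band = sps.sosfiltfilt(sos, lead2)
    energy = np.gradient(band) ** 2
    window = max(int(round(_MWI_WINDOW_S * fs)), 1)
    mwi = np.convolve(energy, np.ones(window) / window, mode="same")

    refractory = max(int(round(_REFRACTORY_S * fs)), 1)
    candidates, _ = sps.find_peaks(mwi, distance=refractory)
    if len(candidates) < 2:
        raise InsufficientBeatsError("fewer than two QRS candidates")
    # adaptive threshold anchored on the strong-candidate height scale
    threshold = 0.25 * np.percentile(mwi[candidates], 90)
    peaks = candidates[mwi[candidates] >= threshold]
    if len(peaks) < 2:
        raise InsufficientBeatsError("fewer than two peaks above threshold")

    # refine each peak to the local extremum of the band-passed lead
    halfwin = max(int(round(0.075 * fs)), 1)
    refined = []
    for p in peaks:
        lo, hi = max(p - halfwin, 0), min(p + halfwin + 1, len(band))
        refined.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    refined = np.unique(refined)
    # re-enforce the refractory period after refinement
    kept = [int(refined[0])]
    for p in refined[1:]:
        if p - kept[-1] >= refractory:
            kept.append(int(p))
        elif np.abs(band[p]) > np.abs(band[kept[-1]]):
            kept[-1] = int(p)
    if len(kept) < 2:
        raise InsufficientBeatsError("fewer than two peaks after refinement")
    return RRSeries.from_peaks(np.asarray(kept), fs, duration_s)


def sample_entropy(series: np.ndarray, m: int, r: float) -> float:
    """Sample entropy ``-log(A/B)`` of a series.

    B counts ordered pairs of distinct length-``m`` templates within
    Chebyshev distance ``r``; A the same for length ``m+1``. Both counts
    use templates starting at the first ``N - m`` positions so they are
    comparable. Returns ``inf`` when no (m+1)-template pair matches.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1 or series.shape[0] <= m + 1:
        raise ValueError("series length must exceed m + 1")
    if r <= 0:
        raise ValueError("tolerance r must be positive")

    def pair_count(length: int, n_templates: int) -> int:
        win = np.lib.stride_tricks.sliding_window_view(series, length)[:n_templates]
        dist = np.abs(win[:, None, :] - win[None, :, :]).max(axis=2)
        matches = (dist <= r).sum() - n_templates  # drop self-matches
        return int(matches)

    n_templates = series.shape[0] - m
    b = pair_count(m, n_templates)
    a = pair_count(m + 1, n_templates)
    if b == 0 or a == 0:
        return np.inf
    return float(-np.log(a / b))


def hrv_features(rr: RRSeries) -> HRVFeatures:
    """The nine HRV indices of an RR series (needs >= 2 intervals)."""
    x = rr.rr_ms
    if len(x) < 2:
        raise ValueError("need at least two RR intervals")
    diffs = np.diff(x)
    sd = float(np.std(x))  # population SD
    if sd > 0:
        tol = 0.2 * sd
        sampen1 = sample_entropy(x, 1, tol) if len(x) > 2 else 0.0
        sampen2 = sample_entropy(x, 2, tol) if len(x) > 3 else 0.0
    else:
        sampen1 = 0.0  # constant series: all templates match
        sampen2 = 0.0
    # cap the unmatched-template sentinel so feature vectors stay finite
    sampen1 = float(min(sampen1, 10.0))
    sampen2 = float(min(sampen2, 10.0))
    return HRVFeatures(
        sdnn=sd,
        rr_max=float(x.max()),
        rr_min=float(x.min()),
        rr_mean=float(x.mean()),
        pnn50=float(np.mean(np.abs(diffs) > 50.0)),
        r_density=rr.n_peaks / rr.duration_s,
        rmssd=float(np.sqrt(np.mean(diffs**2))),
        sampen_m1=sampen1,
        sampen_m2=sampen2,
    )


def hrv_features_for_record(rec: ECGRecord) -> HRVFeatures:
    """Lead-II HRV features; the zero sentinel when detection fails."""
    try:
        rr = detect_rpeaks(rec.lead("II"), rec.fs)
        if len(rr.rr_ms) < 2:
            return HRVFeatures.neutral()
        return hrv_features(rr)
    except (InsufficientBeatsError, ValueError, KeyError):
        return HRVFeatures.neutral()
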