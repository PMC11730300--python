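"""Signal quality, R-peak detection, multi-lead consensus, beat segmentation.

The quality score is a spectral signal-to-noise ratio: power inside the
heart-rate band 0.66-2.5 Hz (40-150 bpm fundamentals) against power outside
it, in decibels.  R-peaks are detected per lead with a Pan-Tompkins-style
envelope detector behind a pluggable contract, merged across leads by a
majority vote (>= 7 of 12 leads within 10 ms), and beats are cut into
fixed-length 650 ms segments (250 ms before / 400 ms after the R-peak) with
overlapping segments excluded so every analysed heartbeat is independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import EcgRecord

__all__ = [
    "SnrResult",
    "BeatSegment",
    "WaveformWindows",
    "compute_snr",
    "detect_rpeaks_lead",
    "detect_rpeaks",
    "consensus_rpeaks",
    "segment_beats",
    "default_windows",
]

SNR_BAND_HZ = (0.66, 2.5)
ZERO_LEAD_SNR_DB = -200.0  # documented sentinel for an all-zero lead


@dataclass
class SnrResult:
    per_lead_db: np.ndarray  # 12 values
    record_db: float
    band: tuple[float, float]


def compute_snr(
    record: EcgRecord,
    band: tuple[float, float] = SNR_BAND_HZ,
    window: str | None = "hann",
) -> SnrResult:
    """Spectral SNR per lead: 10*log10(in-band power / out-of-band power).

    The DC bin is excluded from the noise total; a Hann taper is applied
    before the FFT by default (``window=None`` disables it).  An all-zero
    lead yields the sentinel ``ZERO_LEAD_SNR_DB`` instead of -inf.
    """
    if record.duration < 4.0:
        raise ValueError("record must be at least 4 s for adequate frequency resolution")
    x = record.signals
    n = record.n_samples
    taper = sps.get_window(window, n) if window else np.ones(n)
    spec = np.abs(np.fft.rfft(x * taper, axis=1)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / record.fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    out_band = ~in_band
    out_band[0] = False  # DC excluded from the noise power

    p_sig = spec[:, in_band].sum(axis=1)
    p_noise = spec[:, out_band].sum(axis=1)
    per_lead = np.full(12, ZERO_LEAD_SNR_DB)
    ok = (p_sig > 0) & (p_noise > 0)
    per_lead[ok] = 10.0 * np.log10(p_sig[ok] / p_noise[ok])
    per_lead[(p_sig > 0) & (p_noise == 0)] = -ZERO_LEAD_SNR_DB
    return SnrResult(per_lead_db=per_lead, record_db=float(per_lead.mean()), band=band)


REFRACTORY_S = 0.200


def detect_rpeaks_lead(x: np.ndarray, fs: float) -> np.ndarray:
    """Pan-Tompkins-style single-lead R-peak times (seconds).

    Bandpass -> derivative -> squaring -> moving-window integration, adaptive
    threshold at a fraction of a robust envelope maximum, 200 ms refractory
    period.  Squaring makes detection polarity-insensitive.  Peak times are
    refined to the local extremum of the bandpassed signal.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if x.size < fs:  # under a second of data
        return np.array([])
    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, min(25.0, 0.9 * nyq) / nyq], btype="band")
    bp = sps.filtfilt(b, a, x)
    env = np.convolve(np.gradient(bp) ** 2, np.ones(int(0.150 * fs)) / int(0.150 * fs), "same")
    ceiling = np.percentile(env, 99.5)
    if ceiling <= 0:
        return np.array([])
    peaks, _ = sps.find_peaks(env, height=0.2 * ceiling, distance=max(1, int(REFRACTORY_S * fs)))
    # refine to the extremum of |bandpassed| within +/-50 ms
    half = int(0.05 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    times = np.unique(np.asarray(refined)) / fs
    # enforce the refractory period after refinement
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= REFRACTORY_S:
            kept.append(float(t))
    return np.asarray(kept)


def detect_rpeaks(record: EcgRecord, detector=detect_rpeaks_lead) -> list[np.ndarray]:
    """Per-lead peak times for all 12 leads; any conforming detector plugs in."""
    return [detector(record.signals[i], record.fs) for i in range(12)]


def consensus_rpeaks(
    per_lead_peaks: list[np.ndarray],
    tolerance: float = 0.010,
    min_leads: int = 7,
    fs: float | None = None,
) -> np.ndarray:
    """Majority-vote consensus R-peaks across leads.

    Peaks from all leads are pooled and clustered by single linkage
    (consecutive gap <= tolerance).  Within a cluster each lead contributes at
    most one peak (the one closest to the cluster median); clusters backed by
    at least ``min_leads`` distinct leads emit the median of the contributing
    times.  When ``fs`` is given, times are quantised to samples first so
    comparisons are exact.
    """
    items = []
    for lead, peaks in enumerate(per_lead_peaks):
        for t in np.asarray(peaks, dtype=float):
            tq = round(t * fs) / fs if fs else t
            items.append((tq, lead))
    if not items:
        return np.array([])
    items.sort()
    times = np.array([t for t, _ in items])
    breaks = np.nonzero(np.diff(times) > tolerance + 1e-12)[0] + 1
    out = []
    for chunk in np.split(np.arange(len(items)), breaks):
        med0 = float(np.median(times[chunk]))
        best: dict[int, float] = {}
        for i in chunk:
            t, lead = items[i]
            if lead not in best or abs(t - med0) < abs(best[lead] - med0):
                best[lead] = t
        if len(best) >= min_leads:
            out.append(float(np.median(list(best.values()))))
    return np.asarray(sorted(out))


SEGMENT_PRE_S = 0.250
SEGMENT_POST_S = 0.400


@dataclass
class BeatSegment:
    """One fixed-length beat window [r - pre, r + post), half-open in samples."""

    subject_id: int
    r_time: float
    start_sample: int
    n_samples: int
    samples: np.ndarray  # (12, n_samples)
    valid: bool


def segment_beats(
    record: EcgRecord,
    consensus_times: np.ndarray,
    pre: float = SEGMENT_PRE_S,
    post: float = SEGMENT_POST_S,
) -> list[BeatSegment]:
    """Cut fixed-length beat windows; flag overlapping neighbours invalid.

    Windows are half-open ``[r - pre, r + post)`` so beats at an RR interval
    of exactly ``pre + post`` touch without intersecting and are retained.
    When two neighbouring windows intersect, both are excluded.  Windows that
    do not fit inside the record are dropped outright.
    """
    fs = record.fs
    L = int(round((pre + post) * fs))
    starts, times = [], []
    for r in np.asarray(consensus_times, dtype=float):
        s = int(round((r - pre) * fs))
        if s >= 0 and s + L <= record.n_samples:
            starts.append(s)
            times.append(r)
    valid = [True] * len(starts)
    for i in range(len(starts) - 1):
        if starts[i + 1] < starts[i] + L:  # nonempty intersection of half-open windows
            valid[i] = valid[i + 1] = False
    return [
        BeatSegment(
            subject_id=record.subject_id,
            r_time=times[i],
            start_sample=starts[i],
            n_samples=L,
            samples=record.signals[:, starts[i] : starts[i] + L],
            valid=valid[i],
        )
        for i in range(len(starts))
    ]


@dataclass
class WaveformWindows:
    """Named half-open intervals in ms relative to the R-peak."""

    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "P": (-250.0, -120.0),
            "PQ": (-120.0, -60.0),
            "QRS": (-60.0, 100.0),
            "ST_T": (100.0, 400.0),
        }
    )

    def __post_init__(self) -> None:
        spans = sorted(self.windows.values())
        for lo, hi in spans:
            if hi <= lo:
                raise ValueError("every window must have positive length")
            if lo < -250.0 or hi > 400.0:
                raise ValueError("windows must lie within [-250, 400) ms")
        for (_, hi_prev), (lo_next, _) in zip(spans, spans[1:]):
            if lo_next < hi_prev:
                raise ValueError("windows must not overlap")

    def sample_slices(self, fs: float, pre: float = SEGMENT_PRE_S) -> dict[str, slice]:
        """Window slices into a beat segment whose sample 0 sits at ``-pre``."""
        out = {}
        for name, (lo, hi) in self.windows.items():
            a = int(round((lo / 1000.0 + pre) * fs))
            b = int(round((hi / 1000.0 + pre) * fs))
            out[name] = slice(a, b)
        return out


def default_windows() -> WaveformWindows:
    """Physiological P / PQ / QRS / ST-T boundaries around the R-peak."""
    return WaveformWindows()
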