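"""Cardiac IBI and respiratory-rate extraction from 1 kHz traces.

Cardiac peaks come from a 0.3-9 Hz band-passed pulse trace via a
two-pass detector: pass 1 takes local maxima above 40 % of normalized
amplitude with a fixed minimum spacing (60/90 s, i.e. the spacing of a
90 bpm rhythm); pass 2 re-detects with a spacing window adapted to the
pass-1 mean rate.  Respiratory peaks come from a 1 Hz low-passed belt
trace, local maxima in a sliding 500 ms window, with excursions below
0.5 SD of run-wide belt tension rejected as too small.

Instantaneous rates are smoothed with a 6 s rolling average and
down-sampled to the scan TR; heart rate is converted to IBI (60 / HR)
only after smoothing and down-sampling.  Quality classes (high / noisy /
unusable) follow per-minute artifact and plausibility rules; only
high-quality traces enter analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

CARDIAC_BAND_HZ = (0.3, 9.0)
RESP_LOWPASS_HZ = 1.0
PASS1_MIN_SPACING_S = 60.0 / 90.0  # spacing of a 90 bpm rhythm
PASS1_HEIGHT_FRACTION = 0.40
RESP_WINDOW_S = 0.5
RESP_MIN_EXCURSION_SD = 0.5
SMOOTH_WINDOW_S = 6.0
IBI_BOUNDS_S = (0.3, 2.0)
RR_TYPICAL_BPM = (7.0, 20.0)
ARTIFACT_SD = 5.0


@dataclass
class PhysioSeries:
    """A 1 kHz physiological trace with derived peak/TR-level fields."""

    kind: str  # "cardiac" | "respiratory"
    samples: np.ndarray
    fs_hz: float = 1000.0
    peaks: np.ndarray | None = None
    tr_series: np.ndarray | None = None
    quality: str | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass
class EpochChange:
    """Per-subject epoch means and task-minus-fixation change scores."""

    mean_fixation: float
    mean_1back: float
    mean_3back: float

    @property
    def delta_1back(self) -> float:
        return self.mean_1back - self.mean_fixation

    @property
    def delta_3back(self) -> float:
        return self.mean_3back - self.mean_fixation


def _bandpass(samples: np.ndarray, fs: float,
              band: tuple[float, float] = CARDIAC_BAND_HZ) -> np.ndarray:
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, samples)


def _lowpass(samples: np.ndarray, fs: float,
             cutoff: float = RESP_LOWPASS_HZ) -> np.ndarray:
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, samples)


def detect_cardiac_peaks(trace: PhysioSeries) -> np.ndarray:
    """Two-pass systolic peak detection on the band-passed pulse trace."""
    fs = trace.fs_hz
    if trace.duration_s < 10:
        raise ValueError("need at least 10 s of cardiac data")
    x = _bandpass(np.asarray(trace.samples, dtype=float), fs)
    peak_amp = x.max()
    if peak_amp <= 0 or np.ptp(x) < 1e-12:
        trace.peaks = np.array([], dtype=int)
        trace.quality = "unusable"
        return trace.peaks
    xn = x / peak_amp
    pass1, _ = signal.find_peaks(
        xn,
        height=PASS1_HEIGHT_FRACTION,
        distance=max(int(PASS1_MIN_SPACING_S * fs), 1),
    )
    if len(pass1) < 2:
        trace.peaks = pass1.astype(int)
        trace.quality = "unusable" if len(pass1) == 0 else trace.quality
        return trace.peaks
    mean_ibi = float(np.mean(np.diff(pass1))) / fs
    adaptive = np.clip(0.6 * mean_ibi, 0.25, 1.8)
    peaks, _ = signal.find_peaks(
        xn, height=PASS1_HEIGHT_FRACTION, distance=max(int(adaptive * fs), 1)
    )
    trace.peaks = peaks.astype(int)
    if len(peaks) == 0:
        trace.quality = "unusable"
    return trace.peaks


def detect_respiratory_peaks(trace: PhysioSeries) -> np.ndarray:
    """Sliding-window breath peaks on the low-passed belt trace."""
    fs = trace.fs_hz
    if trace.duration_s < 10:
        raise ValueError("need at least 10 s of respiratory data")
    x = _lowpass(np.asarray(trace.samples, dtype=float), fs)
    sd = x.std()
    if sd < 1e-12:
        trace.peaks = np.array([], dtype=int)
        trace.quality = "unusable"
        return trace.peaks
    peaks, _ = signal.find_peaks(
        x,
        distance=max(int(RESP_WINDOW_S * fs), 1),
        prominence=RESP_MIN_EXCURSION_SD * sd,
    )
    trace.peaks = peaks.astype(int)
    if len(peaks) == 0:
        trace.quality = "unusable"
    return trace.peaks


def series_to_tr(
    peaks: np.ndarray,
    kind: str,
    tr: float,
    n_volumes: int,
    fs: float = 1000.0,
    n_samples: int | None = None,
) -> np.ndarray:
    """Instantaneous rate -> 6 s rolling mean -> sample at TR midpoints.

    Cardiac output is converted from smoothed heart rate (bpm) to IBI in
    seconds *after* smoothing and down-sampling; respiratory output stays
    in breaths/min.
    """
    peaks = np.asarray(peaks)
    if len(peaks) < 2:
        raise ValueError("need at least 2 peaks")
    if n_samples is not None and n_volumes * tr > n_samples / fs + tr:
        raise ValueError("requested run is longer than the trace")
    t_peaks = peaks / fs
    intervals = np.diff(t_peaks)
    rate_bpm = 60.0 / intervals  # bpm (cardiac) or breaths/min (respiratory)
    t_mid = 0.5 * (t_peaks[:-1] + t_peaks[1:])

    grid_dt = 0.1
    grid = np.arange(0, n_volumes * tr + grid_dt, grid_dt)
    rate = np.interp(grid, t_mid, rate_bpm)
    win = max(int(round(SMOOTH_WINDOW_S / grid_dt)), 1)
    kernel = np.ones(win) / win
    pad = win // 2
    padded = np.pad(rate, pad, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")[pad:pad + len(grid)]

    tr_mid = (np.arange(n_volumes) + 0.5) * tr
    sampled = np.interp(tr_mid, grid, smoothed)
    if kind == "cardiac":
        return 60.0 / sampled  # IBI in seconds
    return sampled


def classify_quality(
    trace: PhysioSeries,
    peaks: np.ndarray | None = None,
    kind: str | None = None,
) -> str:
    """Quality class from per-minute artifact fraction and plausibility.

    high: every 1-min segment has near-zero artifact fraction and
    physiologically plausible intervals (IBI in [0.3, 2] s; RR within
    7-20 breaths/min).  noisy: artifacts below 50 % of every segment, or
    rates out of the typical range.  unusable: otherwise (or no peaks).
    """
    kind = kind or trace.kind
    peaks = trace.peaks if peaks is None else np.asarray(peaks)
    fs = trace.fs_hz
    if peaks is None or len(peaks) < 2:
        trace.quality = "unusable"
        return trace.quality
    x = (_bandpass if kind == "cardiac" else _lowpass)(
        np.asarray(trace.samples, dtype=float), fs
    )
    # sparse artifacts: seconds whose local SD towers over the typical
    # per-second SD (heavy contamination masks this, but then the
    # interval-regularity rule below catches it)
    sec = int(fs)
    n_sec = max(len(x) // sec, 1)
    sec_sd = np.array([x[s * sec:(s + 1) * sec].std() for s in range(n_sec)])
    ref = np.median(sec_sd)
    affected_sec = sec_sd > ARTIFACT_SD * ref if ref > 0 else np.ones(n_sec, bool)
    n_seg = max(n_sec // 60, 1)
    frac = np.array([
        affected_sec[s * 60:(s + 1) * 60].mean() for s in range(n_seg)
    ])

    t_peaks = peaks / fs
    plausible, regular = [], []
    for s in range(n_seg):
        lo, hi = s * 60.0, (s + 1) * 60.0
        seg_peaks = t_peaks[(t_peaks >= lo) & (t_peaks < hi)]
        if len(seg_peaks) < 3:
            plausible.append(False)
            regular.append(False)
            continue
        iv = np.diff(seg_peaks)
        if kind == "cardiac":
            ok = np.all((iv >= IBI_BOUNDS_S[0]) & (iv <= IBI_BOUNDS_S[1]))
        else:
            rr = 60.0 / iv
            ok = np.all((rr >= RR_TYPICAL_BPM[0]) & (rr <= RR_TYPICAL_BPM[1]))
        plausible.append(bool(ok))
        regular.append(bool(iv.std() / iv.mean() <= 0.5))

    if np.mean(regular) < 0.5 or frac.max() >= 0.5:
        trace.quality = "unusable"
    elif all(plausible) and all(regular) and frac.max() <= 0.05:
        trace.quality = "high"
    else:
        trace.quality = "noisy"
    return trace.quality


def compute_epoch_changes(
    tr_series: np.ndarray,
    schedule,
    tr: float,
    cue_in_task: bool = True,
) -> EpochChange:
    """Epoch means (fixation / 1-back / 3-back) and change scores.

    A TR belongs to an epoch if its midpoint falls inside the epoch
    interval; block cues count with their block's task epoch by default.
    Raises if any epoch captured no TRs.
    """
    tr_series = np.asarray(tr_series, dtype=float)
    n = len(tr_series)
    mid = (np.arange(n) + 0.5) * tr
    labels = np.full(n, "fixation", dtype=object)
    for _, row in schedule.block_intervals().iterrows():
        start = row["start_s"] if cue_in_task else row["start_s"] + schedule.cue_duration_s
        sel = (mid >= start) & (mid < row["end_s"])
        labels[sel] = f"{int(row['condition'])}back"
    means = {}
    for name in ("fixation", "1back", "3back"):
        sel = labels == name
        if not sel.any():
            raise ValueError(f"epoch {name!r} captured no TRs")
        means[name] = float(tr_series[sel].mean())
    return EpochChange(
        mean_fixation=means["fixation"],
        mean_1back=means["1back"],
        mean_3back=means["3back"],
    )
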