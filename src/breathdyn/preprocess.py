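"""Raw belt signal -> breath-by-breath rate and amplitude series.

The pipeline is: zero-phase band-pass (0.05-3 Hz by default), extrema
detection by a zero-crossing rule (the maximum between an upward and the
next downward zero crossing is an inhalation peak; the minimum between a
downward and the next upward crossing is an exhalation trough), pruning of
low-excursion peak/trough pairs, then conversion of peak-to-peak intervals
into an instantaneous rate series (breaths/min) and peak-minus-preceding-
trough values into an amplitude series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import BreathRecording

#: fraction of the median peak-trough excursion below which a pair is pruned
DEFAULT_AMP_MIN_FRAC = 0.3


@dataclass
class BreathEvents:
    """Indices of detected inhalation peaks and exhalation troughs.

    Invariant: strictly increasing, peaks and troughs strictly alternate
    starting with a trough, counts differ by at most one.
    """

    peak_indices: np.ndarray
    trough_indices: np.ndarray
    n_pruned: int = 0

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.trough_indices = np.asarray(self.trough_indices, dtype=int)
        for name, idx in (("peaks", self.peak_indices), ("troughs", self.trough_indices)):
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"{name} not strictly increasing")
        if abs(self.peak_indices.size - self.trough_indices.size) > 1:
            raise ValueError("peak/trough counts differ by more than 1")
        if self.peak_indices.size and self.trough_indices.size:
            if self.trough_indices[0] > self.peak_indices[0]:
                raise ValueError("event sequence must start with a trough")
            merged = np.sort(np.concatenate([self.peak_indices, self.trough_indices]))
            kinds = np.isin(merged, self.peak_indices)
            if np.any(kinds[:-1] == kinds[1:]):
                raise ValueError("peaks and troughs must strictly alternate")


@dataclass
class BreathSeries:
    """Per-breath rate (breaths/min) and amplitude (a.u.) sequences.

    Both series are aligned on peaks 2..n: rate_i is 60 over the interval
    ending at peak i, amplitude_i is peak i minus its preceding trough.
    """

    rate: np.ndarray
    amplitude: np.ndarray
    breath_times: np.ndarray
    n_pruned: int = 0

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.breath_times = np.asarray(self.breath_times, dtype=float)
        if self.rate.size != self.amplitude.size:
            raise ValueError("rate and amplitude series must have equal length")
        if self.rate.size:
            if np.any(self.rate <= 0) or np.any(self.rate >= 180):
                raise ValueError("rates must lie in (0, 180) breaths/min")
            if np.any(self.amplitude <= 0):
                raise ValueError("amplitudes must be positive")

    @property
    def n_breaths(self) -> int:
        return self.rate.size


@dataclass
class QualitySummary:
    n_breaths: int
    rate_min: float
    rate_max: float
    frac_pruned: float
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def bandpass_filter(
    rec: BreathRecording, low: float = 0.05, high: float = 3.0
) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass of the belt signal.

    Forward-backward filtering preserves extrema timing; the pass band
    removes drift below ``low`` and noise above ``high``. The input mean is
    subtracted first so a constant signal maps exactly to zero.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= nyq:
        raise ValueError(f"high cut-off {high} Hz >= Nyquist {nyq} Hz")
    if rec.duration <= 3.0 / low:
        raise ValueError(
            f"recording of {rec.duration:.1f} s too short for a {low} Hz high-pass "
            f"(need > {3.0 / low:.0f} s)"
        )
    sos = sps.butter(2, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    x = rec.samples - rec.samples.mean()
    y = sps.sosfiltfilt(sos, x)
    # edge transients can leave a tiny residual mean; the zero-crossing
    # detector downstream assumes an exactly zero baseline
    return y - y.mean() if y.any() else y


def _zero_crossing_extrema(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Raw alternating extrema from sign changes around the zero baseline."""
    s = x < 0
    # crossing between i and i+1
    up = np.flatnonzero(s[:-1] & ~s[1:]) + 1      # first index at/above 0
    down = np.flatnonzero(~s[:-1] & s[1:]) + 1    # first index below 0
    if up.size == 0 or down.size == 0:
        raise ValueError("no zero crossings in filtered signal")
    peaks: list[int] = []
    troughs: list[int] = []
    # peaks live between an up-crossing and the next down-crossing
    for u in up:
        nxt = down[down > u]
        if nxt.size:
            seg = slice(u, nxt[0])
            peaks.append(int(seg.start + np.argmax(x[seg])))
    for d in down:
        nxt = up[up > d]
        if nxt.size:
            seg = slice(d, nxt[0])
            troughs.append(int(seg.start + np.argmin(x[seg])))
    return peaks, troughs


def _refine_extrema(x: np.ndarray, idx: np.ndarray, half: int, find_max: bool) -> np.ndarray:
    """Least-squares quadratic vertices around each index, on the grid.

    Breath tops are locally flat, so the raw argmax/argmin wanders under
    noise; fitting a parabola over +-half samples averages the noise out
    while keeping the returned indices on the sample grid. Extrema whose
    window is truncated by the signal edge, or whose fit has the wrong
    curvature or an out-of-window vertex, keep their raw index.
    """
    idx = np.asarray(idx, dtype=int)
    out = idx.copy()
    interior = (idx >= half) & (idx < x.size - half)
    if not interior.any():
        return out
    ii = idx[interior]
    t = np.arange(-half, half + 1, dtype=float)
    A = np.stack([t ** 2, t, np.ones_like(t)], axis=1)
    P = np.linalg.pinv(A)                       # 3 x window
    win = x[ii[:, None] + t.astype(int)[None, :]]
    a, b, _ = P @ win.T                         # per-extremum coefficients
    shift = np.where(a != 0, -b / (2 * np.where(a == 0, 1, a)), 0.0)
    good = ((a < 0) if find_max else (a > 0)) & (np.abs(shift) <= half)
    refined = ii + np.round(np.where(good, shift, 0.0)).astype(int)
    out[interior] = refined
    return out


def detect_breath_extrema(
    filtered: np.ndarray, fs: float, amp_min_frac: float = DEFAULT_AMP_MIN_FRAC
) -> BreathEvents:
    """Detect alternating breath peaks/troughs in a zero-mean signal.

    Raw extrema come from the zero-crossing rule; adjacent peak/trough
    pairs whose vertical distance falls below ``amp_min_frac`` times the
    median trough-to-peak excursion are treated as noise ripple and
    removed smallest-first, which merges the spuriously split breath
    back together while preserving alternation. Surviving extremum
    indices are then refined by a local quadratic fit. Partial first and
    last cycles are discarded by construction (only complete
    crossing-bracketed segments yield extrema).
    """
    filtered = np.asarray(filtered, dtype=float)
    if filtered.size < 4 or np.ptp(filtered) == 0:
        raise ValueError("signal too short or zero-variance")
    peaks, troughs = _zero_crossing_extrema(filtered)
    # merged alternating event list as (index, is_peak)
    events = sorted([(i, True) for i in peaks] + [(i, False) for i in troughs])
    # collapse any same-type runs to the most extreme member
    cleaned: list[tuple[int, bool]] = []
    for idx, is_peak in events:
        if cleaned and cleaned[-1][1] == is_peak:
            prev = cleaned[-1][0]
            better = (filtered[idx] > filtered[prev]) if is_peak else (filtered[idx] < filtered[prev])
            if better:
                cleaned[-1] = (idx, is_peak)
        else:
            cleaned.append((idx, is_peak))
    if len(cleaned) < 4:
        raise ValueError("fewer than 2 breaths detected")
    # reference excursion: median over trough->peak adjacent distances
    vals = np.array([filtered[i] for i, _ in cleaned])
    ref = float(np.median(np.abs(np.diff(vals))))
    threshold = amp_min_frac * ref
    n_pruned = 0
    # iteratively drop the smallest adjacent pair below threshold
    while len(cleaned) >= 4:
        v = np.array([filtered[i] for i, _ in cleaned])
        gaps = np.abs(np.diff(v))
        j = int(np.argmin(gaps))
        if gaps[j] >= threshold:
            break
        del cleaned[j : j + 2]   # one peak + one trough: alternation kept
        n_pruned += 1
    peaks_l = [i for i, p in cleaned if p]
    troughs_l = [i for i, p in cleaned if not p]
    # enforce trough-first and balanced counts
    if peaks_l and troughs_l and peaks_l[0] < troughs_l[0]:
        peaks_l = peaks_l[1:]
    n = min(len(peaks_l), len(troughs_l))
    if n < 2:
        raise ValueError(f"fewer than 2 breaths after amplitude pruning ({n})")
    peaks_a, troughs_a = np.asarray(peaks_l[:n]), np.asarray(troughs_l[:n])
    # refine extremum timing on the locally flat tops/bottoms
    spacing = float(np.median(np.diff(peaks_a))) if peaks_a.size > 1 else 10.0
    half = int(np.clip(round(0.15 * spacing), 2, 20))
    # refine only when sample noise is material: on a clean waveform the
    # raw argmax is already exact, and the parabola vertex would pick up
    # a small bias from asymmetric breath flanks
    d2 = np.diff(filtered, 2)
    noise_hat = 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)
    if noise_hat > 0.02 * float(np.std(filtered)):
        peaks_r = _refine_extrema(filtered, peaks_a, half, True)
        troughs_r = _refine_extrema(filtered, troughs_a, half, False)
    else:
        peaks_r, troughs_r = peaks_a, troughs_a
    # refinement must not break the alternating order; revert if it would
    merged = np.empty(2 * n, dtype=int)
    merged[0::2], merged[1::2] = troughs_r, peaks_r
    if np.any(np.diff(merged) <= 0):
        troughs_r, peaks_r = troughs_a, peaks_a
    return BreathEvents(
        peak_indices=peaks_r, trough_indices=troughs_r, n_pruned=n_pruned,
    )


def extract_breath_series(
    filtered: np.ndarray, events: BreathEvents, fs: float
) -> BreathSeries:
    """Per-breath rate and amplitude from detected extrema.

    For consecutive peaks at times t_i, t_{i+1}: rate = 60/(t_{i+1}-t_i)
    assigned to the later peak; amplitude = peak value minus the
    immediately preceding trough value. Both series therefore share
    indices 2..n of the peak sequence.
    """
    filtered = np.asarray(filtered, dtype=float)
    peaks = events.peak_indices
    if peaks.size < 3:
        raise ValueError(f"need at least 3 peaks, got {peaks.size}")
    t_peaks = peaks / fs
    intervals = np.diff(t_peaks)
    if np.any(intervals <= 0):
        raise ValueError("non-positive peak-to-peak interval")
    rate = 60.0 / intervals
    # trough immediately preceding each of peaks 2..n
    troughs = events.trough_indices
    prev_trough = np.searchsorted(troughs, peaks[1:], side="left") - 1
    if np.any(prev_trough < 0):
        raise ValueError("peak without preceding trough")

    def _value(idx: np.ndarray) -> np.ndarray:
        # small local average suppresses sample noise at the extremum
        win = np.clip(idx[:, None] + np.arange(-2, 3)[None, :], 0, filtered.size - 1)
        return filtered[win].mean(axis=1)

    amplitude = _value(peaks[1:]) - _value(troughs[prev_trough])
    if np.any(amplitude <= 0):
        raise ValueError("non-positive breath amplitude after filtering")
    return BreathSeries(
        rate=rate, amplitude=amplitude, breath_times=t_peaks[1:],
        n_pruned=events.n_pruned,
    )


def quality_summary(series: BreathSeries, min_breaths: int = 20) -> QualitySummary:
    """Basic sufficiency checks before dynamics metrics are trusted."""
    flags = []
    if series.n_breaths < min_breaths:
        flags.append("short recording")
    n_total = series.n_breaths + series.n_pruned
    frac = series.n_pruned / n_total if n_total else 0.0
    return QualitySummary(
        n_breaths=series.n_breaths,
        rate_min=float(series.rate.min()) if series.n_breaths else float("nan"),
        rate_max=float(series.rate.max()) if series.n_breaths else float("nan"),
        frac_pruned=frac,
        flags=flags,
    )


def events_table(
    rec: BreathRecording, filtered: np.ndarray, events: BreathEvents
):
    """Long-format extrema export: one row per detected peak/trough.

    Columns: subject, condition, kind (peak|trough), index, time_s, value.
    """
    import pandas as pd

    rows = []
    for kind, idx in (("peak", events.peak_indices), ("trough", events.trough_indices)):
        for i in idx:
            rows.append({
                "subject": rec.subject_id, "condition": rec.condition,
                "kind": kind, "index": int(i),
                "time_s": rec.t0 + i / rec.fs, "value": float(filtered[i]),
            })
    return pd.DataFrame(rows).sort_values("index", kind="mergesort").reset_index(drop=True)


def process_recording(
    rec: BreathRecording,
    low: float = 0.05,
    high: float = 3.0,
    amp_min_frac: float = DEFAULT_AMP_MIN_FRAC,
) -> BreathSeries:
    """Convenience chain: band-pass -> extrema -> breath series."""
    filt = bandpass_filter(rec, low, high)
    events = detect_breath_extrema(filt, rec.fs, amp_min_frac)
    series = extract_breath_series(filt, events, rec.fs)
    return series
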