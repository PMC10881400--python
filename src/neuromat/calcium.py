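"""Calcium-imaging quantification: dF/F0, spikes, synchrony, NMDA/AMPA.

Raw GCaMP fluorescence per region of interest (ROI) is normalized to a
running baseline (dF/F0), calcium transients are detected as thresholded
local maxima, and per-neuron amplitude (mean dF/F0 of detected spikes)
and frequency (spikes per minute) are reported.  Network activity is
summarized as the synchronous firing rate: the number of windows in which
a sufficient fraction of ROIs fire together, per minute of recording.
The module also computes the NMDA/AMPA current ratio from paired mEPSC
traces (+40 mV current read 20 ms after onset, divided by the peak
-70 mV current).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

_MAD_TO_SD = 0.6745  # MAD of a Gaussian = 0.6745 sigma


@dataclass
class TraceSet:
    """ROI x frame fluorescence with a common time base."""

    time_s: np.ndarray
    F: pd.DataFrame  # rows = ROIs, columns = frame indices
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if len(self.time_s) != self.F.shape[1]:
            raise ValueError("time axis length does not match the frame count")
        if len(self.time_s) > 1 and not (np.diff(self.time_s) > 0).all():
            raise ValueError("time must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(len(self.time_s) / self.frame_rate_hz)


@dataclass
class SpikeTrainSet:
    """Per-ROI detected event times (s) and amplitudes (dF/F0 units)."""

    events: dict[str, pd.DataFrame]  # columns: time_s, amplitude
    duration_s: float

    def __post_init__(self) -> None:
        for roi, ev in self.events.items():
            t = ev["time_s"].to_numpy()
            if len(t) and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError(f"event outside the recording for {roi}")
            if (ev["amplitude"].to_numpy() <= 0).any():
                raise ValueError(f"non-positive amplitude for {roi}")

    @property
    def rois(self) -> list[str]:
        return list(self.events)


@dataclass
class SynchronyResult:
    sync_event_times: np.ndarray
    rate_per_min: float
    participation_threshold: float
    window_s: float


@dataclass
class EphysEventPair:
    """Paired mEPSC traces at +40 mV and -70 mV around one event onset."""

    time_s: np.ndarray
    trace_plus40_pA: np.ndarray
    trace_minus70_pA: np.ndarray
    onset_s: float

    def __post_init__(self) -> None:
        dt = np.diff(self.time_s)
        if len(dt) and dt.max() > 1e-3 + 1e-12:
            raise ValueError("sampling interval must be <= 1 ms for the 20 ms read-out")


def compute_dff(
    traces: TraceSet,
    method: str = "running_percentile",
    percentile: float = 10.0,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Baseline-normalized fluorescence dF/F0 = (F - F0) / F0.

    The default baseline F0 is a running ``percentile`` (10th) of the raw
    trace over a centred ``window_s`` (30 s) window, which tracks slow
    drift while ignoring transients.  ``method="global_percentile"`` uses
    a single per-ROI percentile instead.  A constant trace maps to zeros.
    """
    F = traces.F.to_numpy(dtype=float)
    n = F.shape[1]
    if method == "global_percentile":
        F0 = np.percentile(F, percentile, axis=1, keepdims=True)
        F0 = np.broadcast_to(F0, F.shape)
    elif method == "running_percentile":
        half = max(1, int(round(window_s * traces.frame_rate_hz / 2)))
        F0 = np.empty_like(F)
        for j in range(n):
            lo, hi = max(0, j - half), min(n, j + half + 1)
            F0[:, j] = np.percentile(F[:, lo:hi], percentile, axis=1)
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    bad = (F0 <= 0).any(axis=1)
    if bad.any():
        rois = [traces.F.index[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"non-positive baseline F0 for ROI(s): {rois[:5]}")
    return pd.DataFrame((F - F0) / F0, index=traces.F.index, columns=traces.F.columns)


def _robust_noise_sd(x: np.ndarray) -> float:
    """Noise sigma from the MAD of the first-differenced (detrended) trace."""
    d = np.diff(x)
    if len(d) == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / (_MAD_TO_SD * np.sqrt(2.0)))


def detect_spikes(
    dff: pd.DataFrame,
    frame_rate_hz: float,
    threshold_sd: float = 3.0,
    min_amplitude: float = 0.2,
    refractory_s: float = 1.0,
    smooth_s: float = 1.0,
) -> SpikeTrainSet:
    """Detect calcium transients as thresholded local maxima.

    Each ROI trace is boxcar-smoothed over ``smooth_s`` seconds (set 0 to
    disable) and local maxima of the smoothed trace exceeding
    ``max(min_amplitude, threshold_sd * sigma)`` are kept, where sigma is
    the robust noise level of the smoothed trace (MAD of its first
    differences).  Peaks closer than ``refractory_s`` are merged, keeping
    the larger.  The reported event amplitude is the raw dF/F0 maximum
    in the neighbourhood of the smoothed peak.
    """
    if refractory_s <= 0 or threshold_sd <= 0:
        raise ValueError("refractory_s and threshold_sd must be > 0")
    X = dff.to_numpy(dtype=float)
    n = X.shape[1]
    duration = n / frame_rate_hz
    width = max(1, int(round(smooth_s * frame_rate_hz))) if smooth_s > 0 else 1
    kernel = np.ones(width) / width
    distance = max(1, int(round(refractory_s * frame_rate_hz)))
    events: dict[str, pd.DataFrame] = {}
    for i, roi in enumerate(dff.index):
        x = np.convolve(X[i], kernel, mode="same") if width > 1 else X[i]
        # white-noise sigma estimated on the raw trace, attenuated by the
        # boxcar to the smoothed scale (first differences of a smoothed
        # trace underestimate its marginal noise)
        sigma = _robust_noise_sd(X[i]) / np.sqrt(width)
        # thresholding relative to the smoothed-trace median makes the
        # detector robust to residual baseline offset after dF/F0
        offset = float(np.median(x))
        excursion = max(min_amplitude, threshold_sd * sigma)
        # the prominence requirement rejects noise bumps riding on the
        # decaying tail of an earlier transient, which clear the absolute
        # height threshold but rise only by the noise scale
        padded = np.concatenate([[-np.inf], x, [-np.inf]])
        peaks, _ = find_peaks(
            padded, height=offset + excursion, distance=distance, prominence=excursion
        )
        peaks -= 1
        times, amps = [], []
        half = width // 2 + 1  # smoothing shifts the peak by at most ~1 frame
        for p in peaks:
            lo, hi = max(0, p - half), min(n, p + half + 1)
            j = lo + int(np.argmax(X[i, lo:hi]))
            times.append(j / frame_rate_hz)
            amps.append(X[i, j])
        ev = pd.DataFrame({"time_s": times, "amplitude": amps})
        ev = ev[ev["amplitude"] > 0].reset_index(drop=True)
        events[roi] = ev
    return SpikeTrainSet(events=events, duration_s=duration)


def spike_statistics(spikes: SpikeTrainSet) -> pd.DataFrame:
    """Per-ROI mean event amplitude (dF/F0) and frequency (events/min).

    Amplitude is reported as missing (NaN) for ROIs without events.
    """
    if spikes.duration_s <= 0:
        raise ValueError("duration must be > 0")
    rows = []
    for roi, ev in spikes.events.items():
        n_ev = len(ev)
        amp = float(ev["amplitude"].mean()) if n_ev else np.nan
        freq = 60.0 * n_ev / spikes.duration_s
        rows.append((roi, n_ev, amp, freq))
    return pd.DataFrame(rows, columns=["roi", "n_events", "amplitude", "frequency_per_min"]).set_index("roi")


def synchronous_firing_rate(
    spikes: SpikeTrainSet,
    window_s: float = 0.5,
    participation: float = 0.8,
) -> SynchronyResult:
    """Network synchronous events per minute of recording.

    A candidate window of width ``window_s`` qualifies when at least
    ``participation`` of the ROIs have an event inside it; overlapping
    qualifying windows merge into a single synchronous event timed at the
    median participant spike time (ties: earliest).
    """
    if not 0 < participation <= 1:
        raise ValueError(f"participation must be in (0, 1], got {participation}")
    rois = spikes.rois
    if len(rois) < 2:
        raise ValueError("synchrony needs >= 2 ROIs")
    all_spikes = sorted(
        (t, roi)
        for roi in rois
        for t in spikes.events[roi]["time_s"].to_numpy()
    )
    needed = participation * len(rois)
    qualifying: list[tuple[float, float]] = []  # [start, start+window]
    times = np.array([t for t, _ in all_spikes])
    roi_ids = [r for _, r in all_spikes]
    for k, t0 in enumerate(times):
        hi = np.searchsorted(times, t0 + window_s, side="right")
        distinct = len(set(roi_ids[k:hi]))
        if distinct >= needed:
            qualifying.append((t0, t0 + window_s))
    merged: list[tuple[float, float]] = []
    for lo, hi in qualifying:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    event_times = []
    for lo, hi in merged:
        inside = times[(times >= lo) & (times <= hi)]
        event_times.append(float(np.sort(inside)[(len(inside) - 1) // 2]))
    rate = 60.0 * len(event_times) / spikes.duration_s
    return SynchronyResult(
        sync_event_times=np.asarray(event_times),
        rate_per_min=rate,
        participation_threshold=participation,
        window_s=window_s,
    )


def nmda_ampa_ratio(pair: EphysEventPair, nmda_delay_s: float = 0.020) -> float:
    """NMDA/AMPA current ratio from a paired mEPSC recording.

    The NMDA component is the +40 mV current amplitude read (by linear
    interpolation) ``nmda_delay_s`` after event onset, when AMPA
    receptors are desensitized; the AMPA component is the peak absolute
    -70 mV current within the event.
    """
    t_read = pair.onset_s + nmda_delay_s
    if t_read < pair.time_s[0] or t_read > pair.time_s[-1]:
        raise ValueError("traces do not cover onset + 20 ms")
    nmda = abs(float(np.interp(t_read, pair.time_s, pair.trace_plus40_pA)))
    in_event = pair.time_s >= pair.onset_s
    ampa = float(np.max(np.abs(pair.trace_minus70_pA[in_event])))
    if ampa == 0:
        raise ZeroDivisionError("AMPA peak current is zero")
    return nmda / ampa
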