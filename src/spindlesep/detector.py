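"""Individualized amplitude-threshold spindle detection.

Per channel and spindle class, the Laplacian-transformed signal is
zero-phase filtered in the subject's 1.3 Hz sigma band (least-squares FIR,
order 3000, 0.5 Hz transition zones), the Hilbert envelope is smoothed
with a 200 ms moving average, and events are delimited by an upper/lower
threshold pair set from the N2 envelope (mean + 3 SD and mean + 1 SD).
The same N2-anchored thresholds are reused for N3 so that stage
differences in sigma power cannot confound detection. Candidate events
must last 0.4-3.0 s; events with broadband (20-80 Hz) power exceeding
sigma-band power, or with outlying mean envelope amplitude (> 4 SD above
that channel's event mean), are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import next_fast_len

from .bands import SigmaBand, TRANSITION
from .eeg_io import SpindleEvent
from .ged import filter_zero_phase

MIN_DURATION = 0.4
MAX_DURATION = 3.0
DEFAULT_ORDER = 3000
SMOOTH_S = 0.2


def design_detection_filter(center: float, fs: float,
                            order: int = DEFAULT_ORDER,
                            half_width: float = 0.65,
                            transition: float = TRANSITION) -> np.ndarray:
    """Least-squares linear-phase FIR band-pass around ``center``.

    Passband center +/- 0.65 Hz with 0.5 Hz transition zones; order+1 taps.
    """
    lo, hi = center - half_width, center + half_width
    if lo - transition <= 0 or hi + transition >= fs / 2:
        raise ValueError("band (including transitions) outside (0, fs/2)")
    if order % 2:
        raise ValueError("filter order must be even")
    bands = [0.0, lo - transition, lo, hi, hi + transition, fs / 2]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return sps.firls(order + 1, bands, desired, fs=fs)


def sigma_envelope(filtered: np.ndarray, fs: float,
                   smooth_s: float = SMOOTH_S) -> np.ndarray:
    """Smoothed Hilbert amplitude envelope of a band-filtered signal.

    The analytic-signal magnitude is averaged with a centered moving window
    of ~200 ms (rounded to an odd number of samples). Accepts 1-D or
    (channels x samples) input.
    """
    x = np.atleast_2d(np.asarray(filtered, float))
    n = x.shape[1]
    nfft = next_fast_len(n)
    env = np.abs(sps.hilbert(x, N=nfft, axis=1))[:, :n]
    w = int(round(smooth_s * fs))
    w = max(1, w + (1 - w % 2))  # odd
    kernel = np.ones(w) / w
    pad = w // 2
    ep = np.pad(env, [(0, 0), (pad, pad)], mode="edge")
    sm = sps.fftconvolve(ep, kernel[None, :], mode="same", axes=1)[:, pad:pad + n]
    return sm[0] if np.asarray(filtered).ndim == 1 else sm


@dataclass
class ChannelThresholds:
    channel: str
    klass: str
    mean: float
    sd: float

    @property
    def upper(self) -> float:
        return self.mean + 3.0 * self.sd

    @property
    def lower(self) -> float:
        return self.mean + 1.0 * self.sd


def channel_thresholds(n2_envelope: np.ndarray, channel: str = "",
                       klass: str = "", ddof: int = 1) -> ChannelThresholds:
    """Upper/lower thresholds (mean + 3 SD / + 1 SD) from all artifact-free
    N2 envelope samples. Sample SD (ddof=1) by default."""
    env = np.asarray(n2_envelope, float)
    if env.size == 0:
        raise ValueError("empty N2 envelope")
    mu = float(env.mean())
    sd = float(env.std(ddof=ddof))
    if sd <= 0:
        raise ValueError("degenerate (constant) envelope")
    return ChannelThresholds(channel=channel, klass=klass, mean=mu, sd=sd)


def detect_events(envelope: np.ndarray, thr: ChannelThresholds, fs: float,
                  t_offset: float = 0.0) -> list[tuple[float, float, float, float]]:
    """Threshold-crossing event delimitation on one channel's envelope.

    Each upper-threshold excursion is expanded to the nearest preceding and
    following lower-threshold crossings; detections sharing a [start, end)
    are merged; events must last 0.4-3.0 s. Returns
    (onset_s, duration_s, peak_amp, mean_amp) tuples; onsets are relative to
    the envelope start plus ``t_offset``. Excursions whose delimiting
    lower crossing falls outside the record are discarded.
    """
    env = np.asarray(envelope, float)
    above_up = env >= thr.upper
    if not above_up.any():
        return []
    below_low = env < thr.lower
    out: list[tuple[float, float, float, float]] = []
    seen: set[tuple[int, int]] = set()
    runs = _runs(above_up)  # contiguous upper-threshold excursions
    low_idx = np.flatnonzero(below_low)
    for r0, r1 in runs:
        prev = low_idx[low_idx < r0]
        nxt = low_idx[low_idx > r1]
        if len(prev) == 0 or len(nxt) == 0:
            continue  # cannot delimit against the record edge
        a = int(prev[-1]) + 1  # first sample at/above the lower threshold
        b = int(nxt[0])        # one past the last sample above it
        if (a, b) in seen:
            continue
        seen.add((a, b))
        dur = (b - a) / fs
        if MIN_DURATION - 1e-9 <= dur <= MAX_DURATION + 1e-9:
            seg = env[a:b]
            out.append((t_offset + a / fs, dur, float(seg.max()),
                        float(seg.mean())))
    out.sort()
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end] index pairs of True runs."""
    m = np.asarray(mask, bool).astype(np.int8)
    d = np.diff(np.concatenate([[0], m, [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def broadband_reject(raw_segment: np.ndarray, fs: float, band: SigmaBand,
                     pad_to_s: float = 2.0) -> bool:
    """True if the event shows a broadband power increase: max periodogram
    power in any 20-80 Hz bin >= min power across the subject's sigma band.

    The unfiltered (Laplacian) segment is zero-padded to ``pad_to_s``
    seconds for 0.5 Hz bin spacing regardless of event length.
    """
    x = np.asarray(raw_segment, float)
    x = x - x.mean()
    nfft = max(len(x), int(round(pad_to_s * fs)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    psd = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    hi = psd[(freqs >= 20.0) & (freqs <= 80.0)]
    sig = psd[(freqs >= band.lo - 1e-9) & (freqs <= band.hi + 1e-9)]
    if len(sig) == 0 or len(hi) == 0:
        return False
    return bool(hi.max() >= sig.min())


def reject_artifacts(events: list[SpindleEvent], rec_data: np.ndarray,
                     channel_index: dict[str, int], fs: float,
                     band: SigmaBand, outlier_sd: float = 4.0,
                     ddof: int = 1) -> list[SpindleEvent]:
    """Drop broadband-contaminated events, then per-channel amplitude
    outliers (mean envelope amplitude > ``outlier_sd`` SD above that
    channel's event mean). With fewer than two events on a channel the
    outlier rule is vacuous and events are kept."""
    kept: list[SpindleEvent] = []
    for e in events:
        ch = channel_index[e.channel]
        i0 = int(round(e.onset * fs))
        i1 = int(round((e.onset + e.duration) * fs))
        if not broadband_reject(rec_data[ch, i0:i1], fs, band):
            kept.append(e)
    by_ch: dict[str, list[SpindleEvent]] = {}
    for e in kept:
        by_ch.setdefault(e.channel, []).append(e)
    out: list[SpindleEvent] = []
    for ch, evs in by_ch.items():
        if len(evs) < 2:
            out.extend(evs)
            continue
        amps = np.array([e.mean_amp for e in evs])
        mu, sd = amps.mean(), amps.std(ddof=ddof)
        cut = mu + outlier_sd * sd if sd > 0 else np.inf
        out.extend(e for e, a in zip(evs, amps) if a <= cut)
    out.sort(key=lambda e: (e.channel, e.onset))
    return out


def detect_spindles(rec_data: np.ndarray, fs: float, labels: list[str],
                    band: SigmaBand, n2_slices: list[slice],
                    stage_slices: dict[str, list[slice]],
                    subject: str = "", night: int = 1,
                    order: int = DEFAULT_ORDER,
                    reject: bool = True) -> list[SpindleEvent]:
    """Full detection pass for one subject, class and night over all channels.

    ``n2_slices`` are sample slices of artifact-free N2 (threshold
    estimation); ``stage_slices`` maps each stage to the slices to scan.
    Filtering and envelope extraction run once over the continuous record;
    thresholds and event scans use only the stated slices.
    """
    kernel = design_detection_filter(band.center, fs, order=order)
    filt = filter_zero_phase(rec_data, kernel)
    env = sigma_envelope(filt, fs)
    events: list[SpindleEvent] = []
    for ci, ch in enumerate(labels):
        n2_env = np.concatenate([env[ci, sl] for sl in n2_slices])
        thr = channel_thresholds(n2_env, channel=ch, klass=band.klass)
        for stage, slices in stage_slices.items():
            for sl in slices:
                for onset, dur, pk, mn in detect_events(
                    env[ci, sl], thr, fs, t_offset=(sl.start or 0) / fs
                ):
                    events.append(SpindleEvent(
                        subject=subject, night=night, stage=stage,
                        klass=band.klass, channel=ch, onset=onset,
                        duration=dur, peak_amp=pk, mean_amp=mn,
                    ))
    if reject:
        index = {ch: i for i, ch in enumerate(labels)}
        events = reject_artifacts(events, rec_data, index, fs, band)
    events.sort(key=lambda e: (e.channel, e.onset))
    return events


def spindle_metrics(events: list[SpindleEvent], minutes: float,
                    labels: list[str]) -> dict[str, dict[str, float]]:
    """Per-channel spindle density (events/min) and mean peak amplitude.

    Channels without events get density 0 and amplitude NaN ("missing").
    """
    if minutes <= 0:
        raise ValueError("minutes must be positive")
    out = {ch: {"density": 0.0, "amplitude": float("nan"), "n_events": 0}
           for ch in labels}
    by_ch: dict[str, list[SpindleEvent]] = {}
    for e in events:
        by_ch.setdefault(e.channel, []).append(e)
    for ch, evs in by_ch.items():
        out[ch] = {
            "density": len(evs) / minutes,
            "amplitude": float(np.mean([e.peak_amp for e in evs])),
            "n_events": len(evs),
        }
    return out
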