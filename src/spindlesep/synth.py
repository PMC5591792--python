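"""Synthetic NREM EEG with planted slow/fast sleep-spindle sources.

The generator emulates the features the separation pipeline depends on:
spatially correlated 1/f^alpha background, high-amplitude ~0.8 Hz slow
oscillations during N3, and two sigma-band oscillators (slow ~9.5-12 Hz,
fast ~12.6-15 Hz) with distinct, subject-specific scalp topographies,
occurring as discrete Hann-windowed bursts at realistic densities. Every
planted quantity (frequencies, mixing maps, event times) is returned as
ground truth so downstream stages can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .eeg_io import Hypnogram, Montage, Recording

#: 58 10-10 positions kept after dropping non-EEG channels and mastoids,
#: including the frontal/parietal midline sites Fz and Pz.
STANDARD_1020_58 = (
    "Fp1 Fpz Fp2 AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO3 POz PO4 O1 O2"
).split()


def make_montage(n_channels: int, layout: str = "standard_1020_58") -> Montage:
    """Electrode montage on the unit sphere.

    ``standard_1020_58`` uses the 10-10 positions of the 58-channel analysis
    set (requires n_channels == 58); ``fibonacci_sphere`` places any number
    of near-equidistant points for small test problems.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 electrodes")
    if layout == "standard_1020_58":
        if n_channels != 58:
            raise ValueError("standard_1020_58 layout defines exactly 58 channels")
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            std = mne.channels.make_standard_montage("standard_1020")
        pos = std.get_positions()["ch_pos"]
        xyz = np.array([pos[lab] for lab in STANDARD_1020_58])
        xyz = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
        return Montage(labels=list(STANDARD_1020_58), xyz=xyz)
    if layout == "fibonacci_sphere":
        i = np.arange(n_channels, dtype=float)
        golden = np.pi * (3.0 - np.sqrt(5.0))
        z = 1.0 - 2.0 * (i + 0.5) / n_channels
        r = np.sqrt(1.0 - z**2)
        theta = golden * i
        xyz = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        labels = [f"E{k + 1}" for k in range(n_channels)]
        return Montage(labels=labels, xyz=xyz)
    raise ValueError(f"unknown layout {layout!r}")


@dataclass
class SynthParams:
    """Generative settings for one subject.

    Topographies are nonnegative per-channel mixing weights (max-normalized
    at simulation time); densities are events per minute of eligible sleep;
    amplitudes are uV at the strongest channel.
    """

    n_channels: int = 58
    fs: float = 400.0
    slow_freq: float = 10.9
    fast_freq: float = 13.5
    slow_topo: np.ndarray | None = None
    fast_topo: np.ndarray | None = None
    slow_density: float = 3.0
    fast_density: float = 3.0
    event_duration_range: tuple[float, float] = (0.5, 2.0)
    event_amplitude: float = 15.0
    slow_amplitude: float | None = None  # defaults to event_amplitude
    fast_amplitude: float | None = None
    background_alpha: float = 2.0
    background_sd: float = 10.0
    shared_mode_sd: float = 5.0
    n_shared_modes: int = 3
    so_freq: float = 0.8
    so_amplitude: float = 40.0
    minutes_n2: float = 5.0
    minutes_n3: float = 5.0
    epoch_len: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 2.0 * (self.fast_freq + 2.0):
            raise ValueError("sampling rate violates Nyquist margin for fast_freq")
        if not (9.0 <= self.slow_freq <= 12.5 <= self.fast_freq <= 16.0):
            raise ValueError("planted frequencies outside slow/fast sigma ranges")
        if self.slow_density < 0 or self.fast_density < 0:
            raise ValueError("densities must be nonnegative")
        if self.minutes_n2 + self.minutes_n3 <= 0:
            raise ValueError("total duration is zero")
        lo, hi = self.event_duration_range
        if not (0 < lo <= hi):
            raise ValueError("bad event_duration_range")
        for topo in (self.slow_topo, self.fast_topo):
            if topo is not None:
                t = np.asarray(topo, float)
                if t.shape != (self.n_channels,) or np.any(t < 0) or t.max() <= 0:
                    raise ValueError(
                        "topographies must be nonnegative with at least one "
                        "strictly positive weight"
                    )


@dataclass
class PlantedEvent:
    klass: str
    onset: float
    duration: float
    freq: float
    stage: str
    channel_region: str  # label of the maximal-weight channel


@dataclass
class GroundTruth:
    slow_freq: float
    fast_freq: float
    slow_topo: np.ndarray
    fast_topo: np.ndarray
    events: list[PlantedEvent]
    stages: np.ndarray
    params: SynthParams = field(repr=False, default=None)


def gaussian_bump_topo(montage: Montage, center_xyz: np.ndarray,
                       width: float) -> np.ndarray:
    """Nonnegative mixing map exp(-theta^2 / (2 width^2)) of the angular
    distance to ``center_xyz`` (width in radians), max-normalized."""
    c = np.asarray(center_xyz, float)
    c = c / np.linalg.norm(c)
    ang = np.arccos(np.clip(montage.xyz @ c, -1.0, 1.0))
    topo = np.exp(-0.5 * (ang / width) ** 2)
    return topo / topo.max()


def _one_over_f_noise(rng: np.random.Generator, n_samples: int, fs: float,
                      alpha: float, n_series: int) -> np.ndarray:
    """Gaussian 1/f^alpha noise, unit variance per row."""
    nf = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shape = np.zeros(nf)
    shape[1:] = freqs[1:] ** (-alpha / 2.0)
    z = rng.standard_normal((n_series, 2, nf))
    spec = (z[:, 0] + 1j * z[:, 1]) * shape
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    # analytic unit-variance normalization (Parseval; irfft scales by 1/n)
    w = 4.0 * shape[1:]**2
    if n_samples % 2 == 0:
        w[-1] = 2.0 * shape[-1]**2
    sd = np.sqrt(w.sum()) / n_samples
    return x / sd


def _draw_events(rng: np.random.Generator, stages: np.ndarray, epoch_len: float,
                 density_per_min: float, dur_range: tuple[float, float],
                 eligible: tuple[str, ...] = ("N2", "N3")) -> list[tuple[float, float, str]]:
    """Poisson event onsets within eligible epochs, non-overlapping within the
    stream; returns (onset, duration, stage) triples sorted by onset."""
    out: list[tuple[float, float, str]] = []
    rate = density_per_min / 60.0  # events per second
    last_end = -np.inf
    for i, st in enumerate(stages):
        if st not in eligible:
            continue
        t0 = i * epoch_len
        n = rng.poisson(rate * epoch_len)
        onsets = np.sort(rng.uniform(0.0, epoch_len, size=n)) + t0
        durs = rng.uniform(dur_range[0], dur_range[1], size=n)
        for on, du in zip(onsets, durs):
            if on < last_end or on + du > t0 + epoch_len:
                continue  # keep events non-overlapping and inside their epoch
            out.append((float(on), float(du), st))
            last_end = on + du
    return out


def simulate_subject(params: SynthParams, montage: Montage
                     ) -> tuple[Recording, Hypnogram, GroundTruth]:
    """Simulate one night for one subject. Identical params give bit-identical
    output (all randomness flows from ``params.seed`` through fixed substreams)."""
    params.validate()
    if montage.n_channels != params.n_channels:
        raise ValueError("montage size does not match n_channels")
    fs, epoch_len = params.fs, params.epoch_len
    n_ep_n2 = int(round(params.minutes_n2 * 60.0 / epoch_len))
    n_ep_n3 = int(round(params.minutes_n3 * 60.0 / epoch_len))
    stages = np.array(["N2"] * n_ep_n2 + ["N3"] * n_ep_n3, dtype=object)
    n_epochs = len(stages)
    if n_epochs == 0:
        raise ValueError("duration of zero")
    spe = int(round(epoch_len * fs))  # samples per epoch
    n_samples = n_epochs * spe

    ss = np.random.SeedSequence(params.seed)
    rng_bg, rng_mode, rng_slow, rng_fast, rng_so = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    # background: independent per-channel 1/f^alpha ...
    data = params.background_sd * _one_over_f_noise(
        rng_bg, n_samples, fs, params.background_alpha, params.n_channels
    )
    # ... plus a few shared smooth spatial modes for non-diagonal covariance
    for _ in range(params.n_shared_modes):
        center = rng_mode.standard_normal(3)
        width = rng_mode.uniform(0.8, 1.6)
        mode = gaussian_bump_topo(montage, center, width)
        mode *= rng_mode.choice([-1.0, 1.0])
        tc = _one_over_f_noise(rng_mode, n_samples, fs, params.background_alpha, 1)[0]
        data += params.shared_mode_sd * np.outer(mode, tc)

    # N3 slow oscillations: ~0.8 Hz sinusoid, fresh random phase per epoch
    t_epoch = np.arange(spe) / fs
    for i, st in enumerate(stages):
        if st == "N3":
            phase = rng_so.uniform(0, 2 * np.pi)
            so = params.so_amplitude * np.sin(
                2 * np.pi * params.so_freq * t_epoch + phase
            )
            data[:, i * spe : (i + 1) * spe] += so[None, :]

    slow_topo = (np.asarray(params.slow_topo, float) if params.slow_topo is not None
                 else gaussian_bump_topo(montage, _site_xyz(montage, "frontal"), 0.9))
    fast_topo = (np.asarray(params.fast_topo, float) if params.fast_topo is not None
                 else gaussian_bump_topo(montage, _site_xyz(montage, "parietal"), 0.9))
    slow_topo = slow_topo / slow_topo.max()
    fast_topo = fast_topo / fast_topo.max()

    events: list[PlantedEvent] = []
    for klass, freq, topo, dens, amp, rng_ev in (
        ("slow", params.slow_freq, slow_topo, params.slow_density,
         params.slow_amplitude, rng_slow),
        ("fast", params.fast_freq, fast_topo, params.fast_density,
         params.fast_amplitude, rng_fast),
    ):
        amp = params.event_amplitude if amp is None else amp
        region = montage.labels[int(np.argmax(topo))]
        for onset, dur, st in _draw_events(
            rng_ev, stages, epoch_len, dens, params.event_duration_range
        ):
            i0 = int(round(onset * fs))
            n = int(round(dur * fs))
            tt = np.arange(n) / fs
            phase = rng_ev.uniform(0, 2 * np.pi)
            burst = amp * np.hanning(n) * np.sin(2 * np.pi * freq * tt + phase)
            data[:, i0 : i0 + n] += topo[:, None] * burst[None, :]
            events.append(PlantedEvent(klass, onset, dur, freq, st, region))

    rec = Recording(data=data, fs=fs, labels=list(montage.labels))
    hyp = Hypnogram(stages=stages, epoch_len=epoch_len)
    gt = GroundTruth(
        slow_freq=params.slow_freq, fast_freq=params.fast_freq,
        slow_topo=slow_topo, fast_topo=fast_topo, events=events,
        stages=stages, params=params,
    )
    return rec, hyp, gt


def _site_xyz(montage: Montage, site: str) -> np.ndarray:
    """Canonical frontal (Fz-like) / parietal (Pz-like) direction."""
    names = {"frontal": "Fz", "parietal": "Pz"}
    lab = names[site]
    if lab in montage.labels:
        return montage.xyz[montage.labels.index(lab)]
    # unlabeled montage: pick a forward/backward upper-hemisphere direction
    vec = {"frontal": np.array([0.0, 0.7, 0.7]),
           "parietal": np.array([0.0, -0.7, 0.7])}[site]
    return vec / np.linalg.norm(vec)


def topo_cosine(a: np.ndarray, b: np.ndarray) -> float:
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


def default_cohort_sampler(rng: np.random.Generator, montage: Montage,
                           base: SynthParams | None = None,
                           min_separation: float = 1.3,
                           overlap_range: tuple[float, float] = (0.5, 0.8),
                           bump_width_range: tuple[float, float] = (0.8, 1.2),
                           jitter: float = 0.35) -> SynthParams:
    """Per-subject parameter draw used for simulated cohorts.

    Slow frequency ~ U(9.5, 12.0), fast ~ U(12.6, 15.0), redrawn until
    fast - slow >= ``min_separation``. Topographies are Gaussian bumps around
    jittered frontal (slow) and parietal (fast) sites, redrawn until their
    cosine similarity falls inside ``overlap_range`` — the spatial-overlap
    regime in which channel-averaged spectra tend to merge the two sigma
    peaks while the spatial-filter approach must still separate them.
    """
    base = base if base is not None else SynthParams(n_channels=montage.n_channels)
    for _ in range(1000):
        slow = rng.uniform(9.5, 12.0)
        fast = rng.uniform(12.6, 15.0)
        if fast - slow >= min_separation:
            break
    else:  # pragma: no cover - U(9.5,12)/U(12.6,15) almost always separates
        raise RuntimeError("sampler failed to separate slow and fast frequencies")
    for _ in range(1000):
        w_s = rng.uniform(*bump_width_range)
        w_f = rng.uniform(*bump_width_range)
        c_s = _jittered(rng, _site_xyz(montage, "frontal"), jitter)
        c_f = _jittered(rng, _site_xyz(montage, "parietal"), jitter)
        slow_topo = gaussian_bump_topo(montage, c_s, w_s)
        fast_topo = gaussian_bump_topo(montage, c_f, w_f)
        if overlap_range[0] <= topo_cosine(slow_topo, fast_topo) <= overlap_range[1]:
            break
    else:
        raise RuntimeError(
            "sampler could not reach the requested topography overlap; "
            "widen overlap_range or bump_width_range"
        )
    return replace(base, slow_freq=float(slow), fast_freq=float(fast),
                   slow_topo=slow_topo, fast_topo=fast_topo)


def _jittered(rng: np.random.Generator, center: np.ndarray, jitter: float
              ) -> np.ndarray:
    v = center + jitter * rng.standard_normal(3)
    return v / np.linalg.norm(v)


@dataclass
class SubjectBundle:
    subject: str
    params: SynthParams
    recording: Recording
    hypnogram: Hypnogram
    ground_truth: GroundTruth


def simulate_cohort(n_subjects: int, montage: Montage, seed: int,
                    param_sampler=default_cohort_sampler,
                    base: SynthParams | None = None,
                    night: int = 1) -> list[SubjectBundle]:
    """Simulate ``n_subjects`` independent subjects.

    Per-subject seeds come from independent substreams of the master seed, so
    subject i is identical no matter how many subjects are requested. A second
    night for the same subjects (same planted frequencies and topographies,
    fresh noise and event times) is obtained by calling again with the same
    master seed and ``night=2``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(seed)
    bundles = []
    for i, child in enumerate(master.spawn(n_subjects)):
        sampler_rng = np.random.default_rng(child)
        params = param_sampler(sampler_rng, montage, base=base)
        if params.slow_freq >= params.fast_freq:
            raise ValueError("param_sampler emitted slow_freq >= fast_freq")
        # subject traits (frequencies, topographies) are night-invariant;
        # the realization seed differs per night
        night_seed = int(
            np.random.SeedSequence([seed, i, night]).generate_state(1)[0] % (2**31)
        )
        params = replace(params, seed=night_seed)
        rec, hyp, gt = simulate_subject(params, montage)
        bundles.append(SubjectBundle(f"S{i + 1:02d}", params, rec, hyp, gt))
    return bundles
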