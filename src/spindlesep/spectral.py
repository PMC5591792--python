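"""Derivative-Welch power spectra, normalization and peak detection.

Spectra are estimated from the temporal first difference of the (Laplacian-
transformed) signal rather than the signal itself: differencing multiplies
power at each frequency by the difference-filter gain |1 - e^{-i w dt}|^2,
which rises ~w^2 at low frequencies and so counteracts the 1/f trend,
making sigma peaks easier to resolve against their surround. Welch
estimation uses 5 s Hamming windows with 50% overlap (0.2 Hz resolution),
averaged within and then across 30 s stage epochs.

Per-electrode spectra of both N2 and N3 are normalized by that electrode's
mean N2 power in the 0-4 Hz band, giving the two stages a common baseline.
For peak detection, spectra are rescaled to [0, 1] over 0-20 Hz and local
maxima are ranked by topographic prominence (the height of a peak above
the higher of the saddle points separating it from larger peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .eeg_io import Hypnogram, Recording

SIGMA_RANGE = (9.0, 16.0)
SLOW_FAST_BOUNDARY = 12.5


@dataclass
class SpectrumSet:
    """Power spectra on a uniform frequency grid.

    ``power`` is (sources x bins); sources are electrodes or spatial-filter
    components. ``normalization`` is "none" or "n2_delta" (divided by the
    per-electrode mean N2 power over 0-4 Hz).
    """

    freqs: np.ndarray
    power: np.ndarray
    sources: list[str]
    normalization: str = "none"
    stage: str = ""
    night: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, float)
        self.power = np.atleast_2d(np.asarray(self.power, float))
        if self.power.shape != (len(self.sources), len(self.freqs)):
            raise ValueError("power must be (n_sources, n_freqs)")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.freqs >= lo - 1e-9) & (self.freqs <= hi + 1e-9)

    def source_index(self, name: str) -> int:
        return self.sources.index(name)


@dataclass
class Peak:
    freq: float
    prominence: float
    source: str = ""
    stage: str = ""
    night: int = 1
    klass: str = ""


def epoch_matrix(rec: Recording, hyp: Hypnogram, stage: str) -> np.ndarray:
    """Artifact-free epochs of one stage as (n_epochs, channels, samples).

    Selection never mutates the recording; artifact epochs are simply not
    returned.
    """
    spe = int(round(hyp.epoch_len * rec.fs))
    idx = hyp.epochs_of(stage)
    idx = idx[(idx + 1) * spe <= rec.n_samples]
    if len(idx) == 0:
        raise ValueError(f"no clean {stage} epochs available")
    return np.stack([rec.data[:, i * spe : (i + 1) * spe] for i in idx])


def stage_samples(rec: Recording, hyp: Hypnogram, stage: str) -> np.ndarray:
    """Concatenated artifact-free samples (channels x time) of one stage."""
    ep = epoch_matrix(rec, hyp, stage)
    return np.concatenate(list(ep), axis=1)


def _welch_batch(x: np.ndarray, fs: float, nperseg: int, noverlap: int,
                 window: str = "hamming") -> tuple[np.ndarray, np.ndarray]:
    """Batched Welch PSD (Hamming taper, constant detrend per segment,
    one-sided density scaling), equivalent to scipy.signal.welch but
    vectorized over leading axes with bounded working memory."""
    step = nperseg - noverlap
    win = sps.get_window(window, nperseg)
    n = x.shape[-1]
    n_seg = (n - nperseg) // step + 1
    if n_seg < 1:
        raise ValueError("signal shorter than one Welch window")
    rows = x.reshape(-1, n)
    nf = nperseg // 2 + 1
    psd = np.empty((rows.shape[0], nf))
    chunk = max(1, 4_000_000 // (n_seg * nperseg))
    for i in range(0, rows.shape[0], chunk):
        segs = np.lib.stride_tricks.sliding_window_view(
            rows[i : i + chunk], nperseg, axis=-1)[:, ::step, :]
        segs = segs - segs.mean(axis=-1, keepdims=True)
        spec = np.fft.rfft(segs * win, axis=-1)
        psd[i : i + chunk] = (np.abs(spec) ** 2).mean(axis=1)
    psd /= fs * (win**2).sum()
    psd[:, 1 : -1 if nperseg % 2 == 0 else None] *= 2.0
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, psd.reshape(x.shape[:-1] + (nf,))


def derivative_welch_psd(epochs: np.ndarray, fs: float,
                         sources: list[str] | None = None,
                         window_s: float = 5.0, stage: str = "",
                         night: int = 1) -> SpectrumSet:
    """Welch PSD of the first difference, per source, averaged over epochs.

    ``epochs`` is (n_epochs, n_sources, n_samples) or (n_sources, n_samples).
    """
    epochs = np.asarray(epochs, float)
    if epochs.ndim == 2:
        epochs = epochs[None]
    n_ep, n_src, n_samp = epochs.shape
    nperseg = int(round(window_s * fs))
    if n_samp - 1 < nperseg:
        raise ValueError("epoch shorter than one Welch window")
    dx = np.diff(epochs, axis=-1)
    freqs, psd = _welch_batch(dx, fs, nperseg, nperseg // 2)
    power = psd.mean(axis=0)
    if sources is None:
        sources = [f"src{i}" for i in range(n_src)]
    return SpectrumSet(freqs=freqs, power=power, sources=list(sources),
                       stage=stage, night=night)


def difference_filter_gain(freqs: np.ndarray, fs: float) -> np.ndarray:
    """|1 - e^{-i 2 pi f / fs}|^2: the PSD gain of the first difference."""
    return np.abs(1.0 - np.exp(-2j * np.pi * np.asarray(freqs) / fs)) ** 2


def delta_reference(n2_spectra: SpectrumSet, band: tuple[float, float] = (0.0, 4.0)
                    ) -> np.ndarray:
    """Per-electrode scalar: mean N2 power over the 0-4 Hz band."""
    mask = n2_spectra.band_mask(*band)
    ref = n2_spectra.power[:, mask].mean(axis=1)
    if np.any(ref <= 0):
        raise ValueError("zero reference power in the 0-4 Hz N2 band")
    return ref


def normalize_psd(spectra: SpectrumSet, n2_reference: SpectrumSet) -> SpectrumSet:
    """Divide each electrode's spectrum by its mean N2 power in 0-4 Hz.

    The same N2-based scalars normalize N3, giving both stages a common
    baseline.
    """
    if spectra.sources != n2_reference.sources:
        raise ValueError("spectra and reference must share the same sources")
    ref = delta_reference(n2_reference)
    return replace(spectra, power=spectra.power / ref[:, None],
                   normalization="n2_delta")


def channel_average(spectra: SpectrumSet) -> SpectrumSet:
    if spectra.power.shape[0] == 0:
        raise ValueError("no channels to average")
    return replace(spectra, power=spectra.power.mean(axis=0, keepdims=True),
                   sources=["channel-average"])


def rescale_01(spectra: SpectrumSet, f_range: tuple[float, float] = (0.0, 20.0)
               ) -> SpectrumSet:
    """Restrict to ``f_range`` and map each source's min->0, max->1."""
    mask = spectra.band_mask(*f_range)
    p = spectra.power[:, mask]
    lo = p.min(axis=1, keepdims=True)
    hi = p.max(axis=1, keepdims=True)
    if np.any(hi - lo <= 0):
        raise ValueError("flat spectrum cannot be rescaled")
    return replace(spectra, freqs=spectra.freqs[mask], power=(p - lo) / (hi - lo))


def detect_peaks(spectra: SpectrumSet, search_range: tuple[float, float],
                 min_prominence: float = 0.01, source: str | None = None,
                 ) -> list[Peak]:
    """Local maxima with prominence >= ``min_prominence``.

    Prominence is computed over the full (rescaled) grid first; the frequency
    restriction to ``search_range`` is applied afterwards, so range edges
    cannot inflate prominence. An empty list is a valid result.
    """
    rows = range(len(spectra.sources)) if source is None \
        else [spectra.source_index(source)]
    out: list[Peak] = []
    for r in rows:
        x = spectra.power[r]
        idx, props = sps.find_peaks(x, prominence=min_prominence)
        for i, prom in zip(idx, props["prominences"]):
            f = spectra.freqs[i]
            if search_range[0] - 1e-9 <= f <= search_range[1] + 1e-9:
                out.append(Peak(freq=float(f), prominence=float(prom),
                                source=spectra.sources[r], stage=spectra.stage,
                                night=spectra.night))
    return out


def classify_peaks(peaks: list[Peak], boundary: float = SLOW_FAST_BOUNDARY
                   ) -> dict[str, Peak | None]:
    """Label sigma peaks slow (< boundary) or fast (>= boundary) and keep the
    most prominent peak per class."""
    best: dict[str, Peak | None] = {"slow": None, "fast": None}
    for p in peaks:
        klass = "slow" if p.freq < boundary else "fast"
        if best[klass] is None or p.prominence > best[klass].prominence:
            best[klass] = replace(p, klass=klass)
    return best


def resolve_boundary_peak(peak: Peak, other_stage_best: dict[str, Peak | None],
                          boundary: float = SLOW_FAST_BOUNDARY) -> str:
    """Class of a peak sitting exactly on the slow/fast boundary.

    A boundary peak inherits the side of the same subject's corresponding
    peak in the other sleep stage when one exists (a record whose N3 peak
    sits at the boundary but whose N2 peak is clearly fast is counted fast,
    and vice versa); without cross-stage context it defaults to fast.
    """
    if abs(peak.freq - boundary) > 1e-9:
        return "slow" if peak.freq < boundary else "fast"
    for klass in ("fast", "slow"):
        other = other_stage_best.get(klass)
        if other is not None and abs(other.freq - boundary) > 1e-9:
            return klass
    return "fast"
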