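"""Slow/fast sigma separation by generalized eigendecomposition (GED).

The multichannel (Laplacian-transformed) EEG is band-pass filtered in a
slow (9-12 Hz) and a fast (12-16 Hz) sigma range with steep zero-phase FIR
filters, yielding covariance matrices S and F. Solving S W = W F Lambda
gives spatial filters ordered by how strongly they favor slow over fast
sigma power: the top eigenvector maximally enhances slow relative to fast
sigma activity, the bottom one the reverse. Projecting the *broadband*
data through all filters and taking derivative-Welch spectra of the
components then lets one read off a subject's slow and fast sigma peak
frequencies from the cleanest components — including subjects whose
channel-level spectra show only a single merged sigma peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import signal as sps

from .eeg_io import Recording
from .spectral import Peak, SpectrumSet, derivative_welch_psd, rescale_01

DEFAULT_SLOW_BAND = (9.0, 12.0)
DEFAULT_FAST_BAND = (12.0, 16.0)
DEFAULT_FIR_ORDER = 13200


def design_fir_bandpass(lo: float, hi: float, fs: float,
                        order: int = DEFAULT_FIR_ORDER) -> np.ndarray:
    """Hamming-windowed sinc band-pass of the given (even) order.

    The kernel has order+1 taps and linear phase; applied with
    :func:`filter_zero_phase` the group delay cancels exactly.
    """
    if not (0 < lo < hi < fs / 2):
        raise ValueError("band edges must satisfy 0 < lo < hi < fs/2")
    if order % 2:
        raise ValueError("filter order must be even")
    # difference of two unity-DC low-passes: exact DC null, ~unity passband
    k_hi = sps.firwin(order + 1, hi, window="hamming", fs=fs)
    k_lo = sps.firwin(order + 1, lo, window="hamming", fs=fs)
    return k_hi - k_lo


def filter_zero_phase(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-phase filtering: 'same'-mode convolution with the symmetric
    linear-phase kernel (group-delay compensation by centering). Works on
    (channels x samples) or 1-D input; edges are padded by reflection."""
    x = np.atleast_2d(np.asarray(data, float))
    n = x.shape[1]
    if len(kernel) > n:
        raise ValueError("filter order exceeds signal length")
    half = (len(kernel) - 1) // 2
    pad = min(half, n - 1)
    xp = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    y = sps.fftconvolve(xp, kernel[None, :], mode="same", axes=1)
    y = y[:, pad : pad + n]
    return y[0] if np.asarray(data).ndim == 1 else y


def band_covariances(rec: Recording, stage_data: np.ndarray,
                     slow_band: tuple[float, float] = DEFAULT_SLOW_BAND,
                     fast_band: tuple[float, float] = DEFAULT_FAST_BAND,
                     order: int = DEFAULT_FIR_ORDER,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Slow- and fast-band channel covariance matrices.

    ``stage_data`` is the concatenated artifact-free data (channels x time)
    of one stage and night. Each channel's mean is removed after filtering;
    the first and last order/2 samples are excluded from the covariance to
    avoid filter edge transients.
    """
    import warnings

    n = stage_data.shape[1]
    if n <= order:
        raise ValueError("stage data shorter than the filter kernel")
    if n < 3 * (order // 2):
        order = 2 * (n // 3)  # keep at least a third of the data after trimming
    if stage_data.shape[1] - order < stage_data.shape[0]:
        warnings.warn("fewer usable samples than channels; covariance will be "
                      "rank deficient (GED shrinkage will regularize)")
    covs = []
    for band in (slow_band, fast_band):
        k = design_fir_bandpass(band[0], band[1], rec.fs, order)
        y = filter_zero_phase(stage_data, k)
        half = order // 2
        y = y[:, half : n - half]
        y = y - y.mean(axis=1, keepdims=True)
        covs.append((y @ y.T) / y.shape[1])
    return covs[0], covs[1]


@dataclass
class Selection:
    component: int  # column index into W (descending-eigenvalue order)
    freq: float
    prominence: float


@dataclass
class GedModel:
    S: np.ndarray
    F: np.ndarray
    W: np.ndarray  # columns = spatial filters, descending eigenvalue order
    eigenvalues: np.ndarray
    shrinkage: float
    component_spectra: SpectrumSet | None = None
    selected_slow: Selection | None = None
    selected_fast: Selection | None = None
    slow_band: tuple[float, float] = DEFAULT_SLOW_BAND
    fast_band: tuple[float, float] = DEFAULT_FAST_BAND


def ged(S: np.ndarray, F: np.ndarray, shrinkage: float = 0.01) -> GedModel:
    """Solve S W = W F Lambda for spatial filters.

    F is shrunk toward a scaled identity, (1-g) F + g tr(F)/n I, to guard
    against rank deficiency on short records; g=0 reproduces the literal
    unregularized decomposition. Eigenpairs are sorted by descending
    eigenvalue; each filter is unit-normalized with its largest-magnitude
    weight made positive, fixing the arbitrary sign/scale reproducibly.
    """
    S = np.asarray(S, float)
    F = np.asarray(F, float)
    if S.shape != F.shape or S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S and F must be square matrices of equal size")
    if not (np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max()))
            and np.allclose(F, F.T, atol=1e-10 * max(1.0, np.abs(F).max()))):
        raise ValueError("S and F must be symmetric")
    n = S.shape[0]
    if np.all(F == 0):
        raise ValueError("F is identically zero")
    Freg = (1.0 - shrinkage) * F + shrinkage * (np.trace(F) / n) * np.eye(n)
    evals, evecs = sla.eigh(0.5 * (S + S.T), 0.5 * (Freg + Freg.T))
    idx = np.argsort(evals)[::-1]
    evals = evals[idx]
    W = evecs[:, idx]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(n)])
    signs[signs == 0] = 1.0
    W = W * signs
    return GedModel(S=S, F=F, W=W, eigenvalues=evals, shrinkage=shrinkage)


def component_spectra(model: GedModel, stage_epochs: np.ndarray, fs: float,
                      stage: str = "", night: int = 1,
                      components: list[int] | None = None) -> SpectrumSet:
    """Derivative-Welch spectra of the broadband data projected through the
    spatial filters, each rescaled to [0, 1] over 0-20 Hz.

    ``stage_epochs`` is (n_epochs, channels, samples) of *unfiltered*
    Laplacian-transformed data. ``components`` restricts the projection to a
    subset of filter columns (e.g. the first/last ten the automatic
    selection policy scans); the default projects through the full matrix.
    """
    ep = np.asarray(stage_epochs, float)
    if ep.ndim == 2:
        ep = ep[None]
    if ep.shape[1] != model.W.shape[0]:
        raise ValueError("epoch channel count does not match W")
    if components is None:
        components = list(range(model.W.shape[1]))
    comps = np.einsum("cw,ecs->ews", model.W[:, components], ep)
    names = [f"comp{i}" for i in components]
    spec = derivative_welch_psd(comps, fs, sources=names, stage=stage,
                                night=night)
    rescaled = rescale_01(spec)
    model.component_spectra = rescaled
    model._raw_component_spectra = spec  # kept for contrast gating
    return rescaled


def _raw_contrast(raw: SpectrumSet, row: int, freq: float,
                  tol_bins: float = 0.5, exclude_hz: float = 0.5,
                  surround_hz: float = 2.5) -> float:
    """Peak height of the un-rescaled component spectrum relative to its
    local background: x[peak] / background - 1, where the background is the
    lower quartile of the power in the surrounding 0.5-2.5 Hz annulus.

    The local maximum nearest ``freq`` (within ``tol_bins`` grid steps) is
    evaluated. The lower quartile makes the background robust both to the
    peak's own skirts and to a second nearby peak occupying part of the
    surround, while a sampling fluctuation of a few tens of percent cannot
    reach a contrast of 1 (a 2x excursion) against it.
    """
    x = raw.power[row]
    idx, _ = sps.find_peaks(x)
    if len(idx) == 0:
        return 0.0
    j = int(np.argmin(np.abs(raw.freqs[idx] - freq)))
    if abs(raw.freqs[idx[j]] - freq) > tol_bins * raw.df + 1e-9:
        return 0.0
    i = idx[j]
    df = np.abs(raw.freqs - raw.freqs[i])
    ring = (df > exclude_hz) & (df <= surround_hz)
    if not ring.any():
        return 0.0
    background = float(np.quantile(x[ring], 0.25))
    if background <= 0:
        return np.inf
    return float(x[i] / background - 1.0)


def select_components(model: GedModel,
                      slow_range: tuple[float, float] = (9.0, 12.5),
                      fast_range: tuple[float, float] = (12.5, 16.0),
                      n_scan: int = 10, min_prominence: float = 0.05,
                      min_contrast: float = 1.0,
                      policy: str = "auto",
                      manual_slow: int | None = None,
                      manual_fast: int | None = None,
                      ) -> tuple[Selection | None, Selection | None]:
    """Pick one slow and one fast component peak, or report absence.

    Auto policy: scan components in descending-eigenvalue order for slow
    (ascending for fast), limited to the first ``n_scan`` of each ordering.
    Accept the first component with a peak of prominence >=
    ``min_prominence`` (on its rescaled spectrum) inside the class range
    whose in-band prominence beats every out-of-band sigma peak of the same
    component, and which stands at least ``min_contrast`` above its base in
    the un-rescaled held-out spectrum as well as in the training-half
    spectrum at the same frequency (+/-1 bin). The contrast pair is a
    scale-free reliability gate: rescaled prominences on a near-flat noise
    spectrum can look large, an overfitted filter direction shows a peak in
    its training half only, and a sampling fluctuation shows one in a single
    half only — a genuine rhythm must survive both. Returning None for a
    class is a valid outcome.
    """
    if model.component_spectra is None:
        raise ValueError("call component_spectra() first")
    spec = model.component_spectra
    raw = getattr(model, "_raw_component_spectra", None)
    raw_train = getattr(model, "_train_component_spectra", None)
    n = model.W.shape[1]
    row_of = {int(name[4:]): r for r, name in enumerate(spec.sources)}
    sigma_lo, sigma_hi = slow_range[0], fast_range[1]
    boundary = slow_range[1]

    def in_class(f: float, klass: str) -> bool:
        if not (sigma_lo - 1e-9 <= f <= sigma_hi + 1e-9):
            return False
        return (f < boundary) if klass == "slow" else (f >= boundary)

    def pick(order: list[int], klass: str) -> Selection | None:
        candidates: list[tuple[float, int, Selection]] = []
        for rank, comp in enumerate(order[:n_scan]):
            row = row_of.get(comp)
            if row is None:
                continue
            idx, props = sps.find_peaks(spec.power[row],
                                        prominence=min_prominence)
            if len(idx) == 0:
                continue
            freqs = spec.freqs[idx]
            proms = props["prominences"]
            in_band = [(f, p) for f, p in zip(freqs, proms) if in_class(f, klass)]
            if not in_band:
                continue
            out_band = [p for f, p in zip(freqs, proms)
                        if sigma_lo - 1e-9 <= f <= sigma_hi + 1e-9
                        and not in_class(f, klass)]
            f_best, p_best = max(in_band, key=lambda t: t[1])
            if out_band and p_best <= max(out_band):
                continue
            contrast = np.inf
            if raw is not None and min_contrast > 0:
                contrast = _raw_contrast(raw, row, f_best)
                if contrast < min_contrast:
                    continue
                # reliability: the peak must also stand out, at the same
                # frequency (+/-1 bin), in the spectra of the training half
                if raw_train is not None and _raw_contrast(
                        raw_train, row, f_best, tol_bins=1.5) < min_contrast:
                    continue
            candidates.append((contrast, rank,
                               Selection(component=comp, freq=float(f_best),
                                         prominence=float(p_best))))
        if not candidates:
            return None
        # prefer the most reliable peak (largest held-out contrast); ties
        # fall back to the earliest component in scan order
        candidates.sort(key=lambda t: (-t[0], t[1]))
        return candidates[0][2]

    def forced(comp: int, klass: str) -> Selection | None:
        row = row_of.get(comp)
        if row is None:
            raise ValueError(
                f"component {comp} has no computed spectrum; recompute "
                "component_spectra with that component included"
            )
        idx, props = sps.find_peaks(spec.power[row], prominence=0.0)
        cands = [(f, p) for f, p in zip(spec.freqs[idx], props["prominences"])
                 if in_class(f, klass)]
        if not cands:
            return None
        f, p = max(cands, key=lambda t: t[1])
        return Selection(component=comp, freq=float(f), prominence=float(p))

    if policy == "manual":
        slow = forced(manual_slow, "slow") if manual_slow is not None else None
        fast = forced(manual_fast, "fast") if manual_fast is not None else None
    elif policy == "auto":
        slow = pick(list(range(n)), "slow")
        fast = pick(list(range(n - 1, -1, -1)), "fast")
    else:
        raise ValueError(f"unknown selection policy {policy!r}")
    model.selected_slow = slow
    model.selected_fast = fast
    return slow, fast


def fit_ged(rec: Recording, stage_epochs: np.ndarray,
            slow_band: tuple[float, float] = DEFAULT_SLOW_BAND,
            fast_band: tuple[float, float] = DEFAULT_FAST_BAND,
            order: int = DEFAULT_FIR_ORDER, shrinkage: float = 0.01,
            stage: str = "", night: int = 1, split_half: bool = True,
            **select_kw) -> GedModel:
    """Covariances -> GED -> component spectra -> peak selection in one call.

    ``stage_epochs`` is (n_epochs, channels, samples) of broadband
    Laplacian-transformed data for one stage and night.

    With ``split_half`` (default), the covariance matrices are estimated on
    the odd-numbered epochs and the component spectra on the held-out
    even-numbered epochs. A generalized eigendecomposition is free to
    overfit sampling noise — a filter can concentrate whatever narrowband
    noise happened to be strongest in its training band, which masquerades
    as a spectral peak. Genuine oscillatory sources keep their peak on
    held-out data; overfitted noise directions do not, so split-half
    estimation is what lets the selection step report "no peak" honestly on
    records without a real rhythm.
    """
    if not rec.laplacian_applied:
        raise ValueError("GED expects Laplacian-transformed input")
    ep = np.asarray(stage_epochs, float)
    if ep.ndim == 2:
        ep = ep[None]
    if split_half and len(ep) >= 2:
        train, ep = ep[0::2], ep[1::2]
    else:
        train = ep
    stage_data = np.concatenate(list(train), axis=1)
    S, F = band_covariances(rec, stage_data, slow_band, fast_band, order)
    model = ged(S, F, shrinkage)
    model.slow_band, model.fast_band = slow_band, fast_band
    n = model.W.shape[1]
    n_scan = select_kw.get("n_scan", 10)
    if select_kw.get("policy", "auto") == "auto":
        scan = sorted(set(range(min(n_scan, n)))
                      | set(range(max(n - n_scan, 0), n)))
    else:
        scan = None  # manual choice may point anywhere
    component_spectra(model, ep, rec.fs, stage=stage, night=night,
                      components=scan)
    if train is not ep:
        held = (model.component_spectra, model._raw_component_spectra)
        component_spectra(model, train, rec.fs, stage=stage, night=night,
                          components=scan)
        model._train_component_spectra = model._raw_component_spectra
        model.component_spectra, model._raw_component_spectra = held
    select_components(model, **select_kw)
    return model


def selection_summary(model: GedModel) -> dict:
    """JSON-ready record of a fitted model's selections."""
    def sel(s: Selection | None):
        return None if s is None else {
            "component": int(s.component), "freq_hz": s.freq,
            "prominence": s.prominence,
        }
    return {
        "slow": sel(model.selected_slow),
        "fast": sel(model.selected_fast),
        "slow_band": list(model.slow_band),
        "fast_band": list(model.fast_band),
        "eigenvalues": [float(v) for v in model.eigenvalues],
        "shrinkage": model.shrinkage,
    }
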