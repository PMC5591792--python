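"""Containers and on-disk formats for the spindle-separation pipeline.

A :class:`Recording` is a plain channels x samples matrix in microvolts
(or uV/cm^2 once the surface Laplacian has been applied), a
:class:`Hypnogram` is the 30 s sleep-stage sequence, and a
:class:`Montage` holds electrode labels with unit-sphere coordinates.
EDF is used for signals; everything else travels as TSV/JSON so that
pipeline artifacts stay diffable and byte-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

VALID_STAGES = ("W", "N1", "N2", "N3", "REM")

# fixed float format shared by all TSV writers (6 significant digits)
_FLOAT_FMT = "%.6g"


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples, physical units uV
    (uV/cm^2 after the Laplacian)."""

    data: np.ndarray
    fs: float
    labels: list[str]
    laplacian_applied: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains NaN or Inf samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def units(self) -> str:
        return "uV/cm^2" if self.laplacian_applied else "uV"


@dataclass
class Hypnogram:
    """Per-epoch stage labels plus artifact flags (30 s epochs by default)."""

    stages: np.ndarray
    artifact: np.ndarray | None = None
    epoch_len: float = 30.0

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=object)
        bad = sorted({s for s in self.stages if s not in VALID_STAGES})
        if bad:
            raise ValueError(f"unknown stage token(s): {bad}")
        if self.artifact is None:
            self.artifact = np.zeros(len(self.stages), dtype=bool)
        self.artifact = np.asarray(self.artifact, dtype=bool)
        if len(self.artifact) != len(self.stages):
            raise ValueError("artifact flags must match number of epochs")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def epochs_of(self, stage: str, clean_only: bool = True) -> np.ndarray:
        """Indices of epochs in `stage`, excluding artifact epochs by default."""
        mask = self.stages == stage
        if clean_only:
            mask &= ~self.artifact
        return np.flatnonzero(mask)

    def minutes_of(self, stage: str, clean_only: bool = True) -> float:
        return len(self.epochs_of(stage, clean_only)) * self.epoch_len / 60.0


@dataclass
class Montage:
    labels: list[str]
    xyz: np.ndarray  # (n, 3) on the unit sphere

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.shape != (len(self.labels), 3):
            raise ValueError("xyz must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate electrode labels")
        norms = np.linalg.norm(self.xyz, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length electrode position")
        if np.any(np.abs(norms - 1.0) > 1e-3):
            warnings.warn("montage coordinates off the unit sphere; renormalizing")
        self.xyz = self.xyz / norms[:, None]

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class SpindleEvent:
    subject: str
    night: int
    stage: str
    klass: str  # "slow" | "fast"
    channel: str
    onset: float  # s from recording start, half-open [onset, onset+duration)
    duration: float
    peak_amp: float
    mean_amp: float = float("nan")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_header_fields(path: Path) -> tuple[int, int, float, list[str], list[int]]:
    """Light header scan: (n_records, n_signals, record_dur, labels, n_samps)."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise ValueError(f"unreadable EDF header in {path}")
        try:
            n_records = int(hdr[236:244].decode("ascii").strip())
            record_dur = float(hdr[244:252].decode("ascii").strip())
            n_signals = int(hdr[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"unreadable EDF header in {path}: {exc}") from exc
        sig_hdr = f.read(256 * n_signals)
    labels = [
        sig_hdr[16 * i : 16 * (i + 1)].decode("ascii", "replace").strip()
        for i in range(n_signals)
    ]
    ns_off = 216 * n_signals
    n_samps = [
        int(sig_hdr[ns_off + 8 * i : ns_off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(n_signals)
    ]
    return n_records, n_signals, record_dur, labels, n_samps


def read_edf(path: str | Path) -> Recording:
    """Read an EDF/EDF+ file into a Recording (physical units uV).

    All kept channels must share one sampling rate; mixed rates are rejected
    with a message naming the offending channels.
    """
    path = Path(path)
    _, _, record_dur, labels, n_samps = _edf_header_fields(path)
    rates = {}
    for lab, ns in zip(labels, n_samps):
        rates.setdefault(ns / record_dur, []).append(lab)
    if len(rates) > 1:
        desc = "; ".join(
            f"{r:g} Hz: {', '.join(chs)}" for r, chs in sorted(rates.items())
        )
        raise ValueError(f"mixed sampling rates in {path.name} ({desc})")

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return Recording(data=data, fs=float(raw.info["sfreq"]), labels=list(raw.ch_names))


def write_edf(rec: Recording, path: str | Path, record_dur: float = 1.0) -> None:
    """Write a Recording as 16-bit EDF with per-channel auto-scaled physical
    ranges. The sample count is truncated to whole data records."""
    path = Path(path)
    spr = int(round(rec.fs * record_dur))
    if spr <= 0:
        raise ValueError("record duration too short for sampling rate")
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record")
    data = rec.data[:, : n_records * spr]
    nch = rec.n_channels

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    def pad(s: str, n: int) -> bytes:
        b = s.encode("ascii", "replace")[:n]
        return b + b" " * (n - len(b))

    hdr = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("synthetic recording", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (1 + nch)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad(f"{record_dur:g}", 8),
            pad(str(nch), 4),
        ]
    )
    unit = rec.units
    sig = b"".join(pad(lab, 16) for lab in rec.labels)
    sig += b"".join(pad("EEG", 80) for _ in range(nch))
    sig += b"".join(pad(unit, 8) for _ in range(nch))
    sig += b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_min)
    sig += b"".join(pad(f"{v:.6g}"[:8], 8) for v in phys_max)
    sig += b"".join(pad(str(dig_min), 8) for _ in range(nch))
    sig += b"".join(pad(str(dig_max), 8) for _ in range(nch))
    sig += b"".join(pad("", 80) for _ in range(nch))
    sig += b"".join(pad(str(spr), 8) for _ in range(nch))
    sig += b"".join(pad("", 32) for _ in range(nch))

    # re-read the 8-char physical range strings so digitization uses exactly
    # what a reader will parse from the header
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    pmax = np.where(pmax - pmin <= 0, pmin + 1.0, pmax)
    scale = (dig_max - dig_min) / (pmax - pmin)
    dig = np.rint((data - pmin[:, None]) * scale[:, None] + dig_min)
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(hdr)
        f.write(sig)
        for r in range(n_records):
            block = dig[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())


def edf_quantization_step(rec: Recording) -> np.ndarray:
    """Per-channel physical value of one 16-bit step for `write_edf` output."""
    lo = rec.data.min(axis=1)
    hi = rec.data.max(axis=1)
    hi = np.where(hi - lo <= 0, lo + 1.0, hi)
    return (hi - lo) / 65535.0


# ---------------------------------------------------------------------------
# TSV artifacts
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_montage(path: str | Path) -> Montage:
    df = pd.read_csv(path, sep="\t")
    need = {"label", "x", "y", "z"}
    if not need.issubset(df.columns):
        raise ValueError(f"montage TSV must have columns {sorted(need)}")
    labels = [str(x) for x in df["label"]]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate electrode labels in montage file")
    return Montage(labels=labels, xyz=df[["x", "y", "z"]].to_numpy(float))


def write_montage(montage: Montage, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "label": montage.labels,
            "x": montage.xyz[:, 0],
            "y": montage.xyz[:, 1],
            "z": montage.xyz[:, 2],
        }
    )
    _write_tsv(df, path)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    need = {"epoch_index", "stage", "artifact_flag"}
    if not need.issubset(df.columns):
        raise ValueError(f"hypnogram TSV must have columns {sorted(need)}")
    df = df.sort_values("epoch_index")
    return Hypnogram(
        stages=df["stage"].to_numpy(object),
        artifact=df["artifact_flag"].to_numpy(int).astype(bool),
    )


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(hyp.n_epochs),
            "stage": hyp.stages,
            "artifact_flag": hyp.artifact.astype(int),
        }
    )
    _write_tsv(df, path)


_EVENT_COLS = [
    "subject", "night", "stage", "class", "channel",
    "onset_s", "duration_s", "peak_amp", "mean_amp",
]


def write_events(events: list[SpindleEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (e.subject, e.night, e.stage, e.klass, e.channel,
             e.onset, e.duration, e.peak_amp, e.mean_amp)
            for e in events
        ],
        columns=_EVENT_COLS,
    )
    _write_tsv(df, path)


def read_events(path: str | Path) -> list[SpindleEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        SpindleEvent(
            subject=str(r["subject"]), night=int(r["night"]), stage=str(r["stage"]),
            klass=str(r["class"]), channel=str(r["channel"]),
            onset=float(r["onset_s"]), duration=float(r["duration_s"]),
            peak_amp=float(r["peak_amp"]), mean_amp=float(r["mean_amp"]),
        )
        for _, r in df.iterrows()
    ]


def write_table(matrix: np.ndarray, path: str | Path,
                columns: list[str] | None = None,
                index: list | None = None, index_name: str = "row") -> None:
    """Generic deterministic TSV dump of a 2-D array."""
    matrix = np.asarray(matrix)
    df = pd.DataFrame(matrix, columns=columns)
    if index is not None:
        df.insert(0, index_name, index)
    _write_tsv(df, path)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, sort_keys=True)
        f.write("\n")
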