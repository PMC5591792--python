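"""End-to-end workflow: preprocess -> spectra -> GED peaks -> bands ->
spindle detection -> topographic maps, for one subject or a cohort.

The pipeline consumes a recording + hypnogram + montage per subject/night,
applies the surface Laplacian once, derives stage spectra and GED
component peaks, assembles individualized sigma bands with the exclusion
rules, runs the spindle detector in those bands, and produces per-
electrode sigma-power/density/amplitude maps. All artifacts are plain
TSV/JSON; reruns with the same inputs and configuration are byte-
identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import bands as bands_mod
from . import detector as det_mod
from . import eeg_io, spectral, topo as topo_mod
from .ged import (DEFAULT_FAST_BAND, DEFAULT_FIR_ORDER,
                  DEFAULT_SLOW_BAND, GedModel, fit_ged, selection_summary)
from .eeg_io import Hypnogram, Montage, Recording
from .laplacian import apply_csd, build_csd_transform


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = ("N2", "N3")
    # surface Laplacian
    csd_m: int = 4
    csd_lambda: float = 1e-5
    csd_n_legendre: int = 50
    # GED
    ged_slow_band: tuple[float, float] = DEFAULT_SLOW_BAND
    ged_fast_band: tuple[float, float] = DEFAULT_FAST_BAND
    ged_order: int = DEFAULT_FIR_ORDER
    ged_shrinkage: float = 0.01
    ged_split_half: bool = True
    # component selection
    select_n_scan: int = 10
    select_min_prominence: float = 0.05
    select_min_contrast: float = 1.0
    manual_slow_component: int | None = None
    manual_fast_component: int | None = None
    # bands / exclusions
    overlap_with_transitions: bool = False
    # detection
    detection_order: int = det_mod.DEFAULT_ORDER
    # misc
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        for key in ("stages", "ged_slow_band", "ged_fast_band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("stages", "ged_slow_band", "ged_fast_band"):
            d[key] = list(d[key])
        return d


@dataclass
class SubjectResult:
    subject: str
    night: int
    laplacian: Recording
    channel_spectra: dict[str, spectral.SpectrumSet]  # normalized, per stage
    ged_models: dict[str, GedModel]
    peaks: dict[str, dict[str, float | None]]  # klass -> stage_night -> Hz
    slow_band: bands_mod.SigmaBand | None
    fast_band: bands_mod.SigmaBand | None
    flags: bands_mod.InclusionFlags
    events: list[eeg_io.SpindleEvent] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    sigma_maps: dict = field(default_factory=dict)


def _stage_slices(hyp: Hypnogram, fs: float, stage: str) -> list[slice]:
    spe = int(round(hyp.epoch_len * fs))
    return [slice(i * spe, (i + 1) * spe) for i in hyp.epochs_of(stage)]


def ged_peaks_for_stages(lap: Recording, hyp: Hypnogram, cfg: PipelineConfig,
                         night: int = 1) -> dict[str, GedModel]:
    """Fit one GED model per available sleep stage."""
    models: dict[str, GedModel] = {}
    for stage in cfg.stages:
        if len(hyp.epochs_of(stage)) == 0:
            continue
        ep = spectral.epoch_matrix(lap, hyp, stage)
        models[stage] = fit_ged(
            lap, ep, slow_band=cfg.ged_slow_band, fast_band=cfg.ged_fast_band,
            order=cfg.ged_order, shrinkage=cfg.ged_shrinkage, stage=stage,
            night=night, split_half=cfg.ged_split_half,
            n_scan=cfg.select_n_scan,
            min_prominence=cfg.select_min_prominence,
            min_contrast=cfg.select_min_contrast,
            policy="manual" if (cfg.manual_slow_component is not None
                                or cfg.manual_fast_component is not None)
            else "auto",
            manual_slow=cfg.manual_slow_component,
            manual_fast=cfg.manual_fast_component,
        )
    return models


def assemble_subject_bands(peaks: dict[str, dict[str, float | None]],
                           subject: str, cfg: PipelineConfig
                           ) -> tuple[bands_mod.SigmaBand | None,
                                      bands_mod.SigmaBand | None,
                                      bands_mod.InclusionFlags]:
    def build(klass: str):
        avail = {k: v for k, v in peaks[klass].items() if v is not None}
        if not avail:
            return None
        return bands_mod.assemble_band(avail, subject, klass)

    slow_band = build("slow")
    fast_band = build("fast")
    flags = bands_mod.apply_exclusions(
        peaks["slow"], peaks["fast"], slow_band, fast_band,
        overlap_with_transitions=cfg.overlap_with_transitions,
    )
    return slow_band, fast_band, flags


def process_subject(rec: Recording, hyp: Hypnogram, montage: Montage,
                    subject: str, cfg: PipelineConfig | None = None,
                    night: int = 1, detect: bool = True) -> SubjectResult:
    """Run the full per-subject pipeline for one night."""
    cfg = cfg or PipelineConfig()
    op = build_csd_transform(montage, m=cfg.csd_m, lam=cfg.csd_lambda,
                             n_legendre=cfg.csd_n_legendre)
    lap = apply_csd(rec, op)

    # channel spectra, normalized to the N2 0-4 Hz baseline
    n2_spec = spectral.derivative_welch_psd(
        spectral.epoch_matrix(lap, hyp, "N2"), lap.fs, sources=lap.labels,
        stage="N2", night=night,
    )
    channel_spectra = {"N2": spectral.normalize_psd(n2_spec, n2_spec)}
    for stage in cfg.stages:
        if stage == "N2" or len(hyp.epochs_of(stage)) == 0:
            continue
        spec = spectral.derivative_welch_psd(
            spectral.epoch_matrix(lap, hyp, stage), lap.fs,
            sources=lap.labels, stage=stage, night=night,
        )
        channel_spectra[stage] = spectral.normalize_psd(spec, n2_spec)

    models = ged_peaks_for_stages(lap, hyp, cfg, night=night)
    peaks: dict[str, dict[str, float | None]] = {"slow": {}, "fast": {}}
    for stage, model in models.items():
        key = f"{stage}_night{night}"
        peaks["slow"][key] = (model.selected_slow.freq
                              if model.selected_slow else None)
        peaks["fast"][key] = (model.selected_fast.freq
                              if model.selected_fast else None)

    slow_band, fast_band, flags = assemble_subject_bands(peaks, subject, cfg)

    result = SubjectResult(
        subject=subject, night=night, laplacian=lap,
        channel_spectra=channel_spectra, ged_models=models, peaks=peaks,
        slow_band=slow_band, fast_band=fast_band, flags=flags,
    )

    for band, included in ((slow_band, flags.include_slow),
                           (fast_band, flags.include_fast)):
        if band is None or not included:
            continue
        for stage, spec in channel_spectra.items():
            result.sigma_maps[(band.klass, stage)] = topo_mod.sigma_power_map(
                spec, band
            )

    if detect:
        n2_slices = _stage_slices(hyp, lap.fs, "N2")
        stage_slices = {st: _stage_slices(hyp, lap.fs, st)
                        for st in cfg.stages if len(hyp.epochs_of(st))}
        for band, included in ((slow_band, flags.include_slow),
                               (fast_band, flags.include_fast)):
            if band is None or not included:
                continue
            evs = det_mod.detect_spindles(
                lap.data, lap.fs, lap.labels, band, n2_slices, stage_slices,
                subject=subject, night=night, order=cfg.detection_order,
            )
            result.events.extend(evs)
            for stage in stage_slices:
                minutes = hyp.minutes_of(stage)
                stage_evs = [e for e in evs if e.stage == stage]
                result.metrics[(band.klass, stage)] = det_mod.spindle_metrics(
                    stage_evs, minutes, lap.labels
                )
    return result


def subject_report(res: SubjectResult) -> dict:
    """JSON-ready per-subject summary (bands, flags, peaks, selections)."""
    return {
        "subject": res.subject,
        "night": res.night,
        "peaks": res.peaks,
        "slow_band": bands_mod.band_summary(res.slow_band),
        "fast_band": bands_mod.band_summary(res.fast_band),
        "include": {
            "slow": res.flags.include_slow,
            "fast": res.flags.include_fast,
            "topo": res.flags.include_topo,
            "reasons": res.flags.reasons,
        },
        "selections": {st: selection_summary(m)
                       for st, m in res.ged_models.items()},
        "n_events": len(res.events),
    }


def run_directory(data_dir: str | Path, out_dir: str | Path,
                  cfg: PipelineConfig | None = None) -> dict:
    """Process every subject found in ``data_dir`` and write artifacts.

    Expects ``montage.tsv`` plus, per subject S, ``S_night<k>.edf`` and
    ``S_night<k>_hypnogram.tsv`` (the layout `spindlesep simulate` writes).
    Returns the provenance dictionary that is also written to
    ``provenance.json``.
    """
    cfg = cfg or PipelineConfig()
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    for sub in ("spectra", "ged", "bands", "events", "topo"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)
    montage = eeg_io.read_montage(data_dir / "montage.tsv")

    runs = sorted(p.name[: -len(".edf")] for p in data_dir.glob("*_night*.edf"))
    if not runs:
        raise FileNotFoundError(f"no *_night*.edf recordings in {data_dir}")
    reports = {}
    for run in runs:
        subject, night_tag = run.rsplit("_night", 1)
        night = int(night_tag)
        rec = eeg_io.read_edf(data_dir / f"{run}.edf")
        hyp = eeg_io.read_hypnogram(data_dir / f"{run}_hypnogram.tsv")
        res = process_subject(rec, hyp, montage, subject, cfg, night=night)
        reports[run] = subject_report(res)

        eeg_io.write_json(reports[run], out_dir / "bands" / f"{run}.json")
        eeg_io.write_events(res.events, out_dir / "events" / f"{run}.tsv")
        for stage, spec in res.channel_spectra.items():
            eeg_io.write_table(
                spec.power.T, out_dir / "spectra" / f"{run}_{stage}.tsv",
                columns=spec.sources, index=list(spec.freqs),
                index_name="freq_hz",
            )
        for (klass, stage), mp in res.sigma_maps.items():
            eeg_io.write_table(
                np.asarray(mp)[:, None],
                out_dir / "topo" / f"{run}_{klass}_{stage}.tsv",
                columns=["sigma_power"], index=montage.labels,
                index_name="channel",
            )
        for stage, model in res.ged_models.items():
            eeg_io.write_json(selection_summary(model),
                              out_dir / "ged" / f"{run}_{stage}.json")

    provenance = {"config": cfg.to_dict(), "subject_runs": sorted(reports),
                  "reports": reports}
    eeg_io.write_json(provenance, out_dir / "provenance.json")
    return provenance
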