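"""Subject-specific 1.3 Hz sigma bands and inclusion rules.

Each subject's slow and fast sigma band is a 1.3 Hz window centered on the
arithmetic mean of that subject's selected component peak frequencies
across sleep stages and nights (missing stage/night entries are simply
omitted). Subjects whose N2 and N3 slow peaks disagree by more than 0.7 Hz
are excluded from slow-spindle analyses; subjects whose slow and fast
bands cannot be separated are excluded from all topographical analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

BAND_WIDTH = 1.3
HALF_WIDTH = BAND_WIDTH / 2.0
TRANSITION = 0.5
STAGE_DISCREPANCY_LIMIT = 0.7


@dataclass
class SigmaBand:
    subject: str
    klass: str  # "slow" | "fast"
    center: float
    provenance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (9.0 - HALF_WIDTH <= self.center <= 16.0 + HALF_WIDTH):
            raise ValueError(f"band center {self.center} Hz outside sigma range")

    @property
    def lo(self) -> float:
        return self.center - HALF_WIDTH

    @property
    def hi(self) -> float:
        return self.center + HALF_WIDTH

    def support(self, with_transitions: bool = False) -> tuple[float, float]:
        """Frequency support of the detection filter for this band."""
        pad = TRANSITION if with_transitions else 0.0
        return (self.lo - pad, self.hi + pad)


@dataclass
class InclusionFlags:
    include_slow: bool = True
    include_fast: bool = True
    include_topo: bool = True
    reasons: list[str] = field(default_factory=list)


def assemble_band(peaks: dict[str, float], subject: str, klass: str) -> SigmaBand:
    """Band from the available stage x night peaks, e.g. keys "N2_night1".

    The center is the plain mean of the provided peak frequencies;
    permutation of the peak list cannot change it.
    """
    vals = [v for v in peaks.values() if v is not None]
    if not vals:
        raise ValueError("need at least one contributing peak")
    center = math.fsum(sorted(vals)) / len(vals)  # order-independent mean
    return SigmaBand(subject=subject, klass=klass, center=center,
                     provenance={k: v for k, v in peaks.items() if v is not None})


def stage_means(peaks: dict[str, float]) -> dict[str, float]:
    """Night-averaged peak per stage from "stage_nightX" keyed peaks."""
    acc: dict[str, list[float]] = {}
    for key, v in peaks.items():
        if v is None:
            continue
        stage = key.split("_")[0]
        acc.setdefault(stage, []).append(v)
    return {st: sum(vs) / len(vs) for st, vs in acc.items()}


def bands_overlap(slow: SigmaBand, fast: SigmaBand,
                  with_transitions: bool = False) -> bool:
    lo_s, hi_s = slow.support(with_transitions)
    lo_f, hi_f = fast.support(with_transitions)
    return max(lo_s, lo_f) < min(hi_s, hi_f)


def apply_exclusions(slow_peaks: dict[str, float] | None,
                     fast_peaks: dict[str, float] | None,
                     slow_band: SigmaBand | None,
                     fast_band: SigmaBand | None,
                     overlap_with_transitions: bool = False) -> InclusionFlags:
    """Evaluate the subject-exclusion rules.

    * Slow analyses require night-averaged N2 and N3 slow peaks within
      0.7 Hz of each other (when both stages are available) and an
      assembled slow band.
    * Topographical analyses require both bands and non-overlapping slow
      and fast detection bands. The default overlap test uses the 1.3 Hz
      passbands themselves; ``overlap_with_transitions`` additionally
      counts the 0.5 Hz filter transition zones as overlap.
    """
    flags = InclusionFlags()
    if slow_band is None:
        flags.include_slow = False
        flags.reasons.append("no slow sigma peak isolated")
    elif slow_peaks:
        means = stage_means(slow_peaks)
        if "N2" in means and "N3" in means:
            d = abs(means["N2"] - means["N3"])
            if d > STAGE_DISCREPANCY_LIMIT + 1e-9:
                flags.include_slow = False
                flags.reasons.append(
                    f"stage discrepancy > 0.7 Hz (|N2-N3| = {d:.2f} Hz)"
                )
    if fast_band is None:
        flags.include_fast = False
        flags.reasons.append("no fast sigma peak isolated")
    if not (flags.include_slow and flags.include_fast):
        flags.include_topo = False
        if slow_band is None or fast_band is None:
            flags.reasons.append("topography excluded: missing band")
        else:
            flags.reasons.append("topography excluded: class exclusion")
    elif bands_overlap(slow_band, fast_band, overlap_with_transitions):
        flags.include_topo = False
        flags.reasons.append("slow and fast sigma filters overlap")
    return flags


def band_summary(band: SigmaBand | None) -> dict | None:
    if band is None:
        return None
    return {
        "subject": band.subject, "class": band.klass,
        "center_hz": band.center, "lo_hz": band.lo, "hi_hz": band.hi,
        "provenance": band.provenance,
    }
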