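"""Topographic maps and paired cluster-based permutation statistics.

Per-electrode maps (individualized-band sigma power, spindle density,
spindle amplitude) are compared between paired conditions with the
cluster-mass permutation test: per-electrode paired t values are
thresholded at the two-tailed clusteralpha=0.1 critical value, sign-
consistent suprathreshold electrodes are grouped into spatially connected
clusters under an angular-distance adjacency graph, and each cluster's
mass (summed t) is referred to a sign-flip permutation null of the
maximum same-sign cluster mass. Clusters are conventionally called significant at
p < 0.025 per tail (two-sided 0.05); all clusters are reported with their
p so the caller can threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy import stats as sst
from scipy.sparse.csgraph import connected_components

from .bands import SigmaBand
from .eeg_io import Montage
from .spectral import SpectrumSet


def sigma_power_map(normalized_spectra: SpectrumSet, band: SigmaBand
                    ) -> np.ndarray:
    """Per-electrode mean normalized power over the subject's 1.3 Hz band."""
    if normalized_spectra.normalization != "n2_delta":
        raise ValueError("sigma power maps require n2_delta-normalized spectra")
    mask = normalized_spectra.band_mask(band.lo, band.hi)
    if not mask.any():
        raise ValueError("band lies outside the spectrum's frequency grid")
    return normalized_spectra.power[:, mask].mean(axis=1)


def angular_distances(montage: Montage) -> np.ndarray:
    return np.arccos(np.clip(montage.xyz @ montage.xyz.T, -1.0, 1.0))


def electrode_adjacency(montage: Montage, max_angle: float | None = None,
                        target_degree: float = 7.0) -> np.ndarray:
    """Boolean adjacency: electrodes within ``max_angle`` radians.

    With ``max_angle=None`` the smallest angle giving mean degree >=
    ``target_degree`` is chosen (deterministic given the montage), keeping
    the graph in the 5-9 mean-degree regime cluster tests expect.
    """
    ang = angular_distances(montage)
    n = montage.n_channels
    if max_angle is None:
        off = ang[~np.eye(n, dtype=bool)]
        max_angle = float(np.quantile(off, min(1.0, target_degree / (n - 1))))
    adj = (ang <= max_angle) & ~np.eye(n, dtype=bool)
    adj = adj | adj.T
    if np.any(adj.sum(axis=1) == 0):
        warnings.warn("adjacency graph has isolated electrodes")
    return adj


@dataclass
class Cluster:
    electrodes: list[int]
    sign: int  # +1 / -1
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_values: np.ndarray
    t_critical: float
    n_permutations: int
    used_electrodes: np.ndarray = field(default=None)

    def significant(self, alpha_per_tail: float = 0.025) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha_per_tail]


def _clusters_from_t(t: np.ndarray, t_crit: float, adj: np.ndarray
                     ) -> list[tuple[list[int], int, float]]:
    out = []
    for sign in (1, -1):
        mask = (sign * t) > t_crit
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sparse.csr_matrix(sub),
                                              directed=False)
        for c in range(n_comp):
            members = idx[labels == c]
            out.append((list(map(int, members)), sign,
                        float(t[members].sum())))
    return out


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Per-electrode paired t over subjects; NaN-aware (pairwise deletion)."""
    n = np.sum(~np.isnan(diff), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nanmean(diff, axis=0)
        sd = np.nanstd(diff, axis=0, ddof=1)
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_permutation_paired(maps_a: np.ndarray, maps_b: np.ndarray,
                               adjacency: np.ndarray,
                               clusteralpha: float = 0.1,
                               n_permutations: int = 1000,
                               seed: int = 0,
                               min_subject_fraction: float = 0.8
                               ) -> ClusterResult:
    """Paired cluster-mass permutation test between conditions A and B.

    ``maps_a``/``maps_b`` are (subjects x electrodes); missing values (NaN,
    e.g. zero-spindle channels for amplitude maps) are excluded pairwise,
    and electrodes with fewer than ``min_subject_fraction`` contributing
    subjects are dropped from the test. The cluster-forming threshold is
    the two-tailed ``clusteralpha`` critical t (i.e. p < alpha/2 per tail);
    the null is built by randomly flipping each subject's A/B assignment
    and recording, per tail, the maximum cluster mass of that sign
    (positive clusters are referred to the max-positive-mass null,
    negative clusters to the max-negative-mass null), with the observed
    labeling included in the null ("+1" convention), so
    p >= 1/(n_permutations+1) and the test is bit-reproducible under a
    fixed seed.
    """
    A = np.asarray(maps_a, float)
    B = np.asarray(maps_b, float)
    if A.shape != B.shape:
        raise ValueError("paired maps must have identical (subjects x "
                         "electrodes) shape")
    n_subj, n_elec = A.shape
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    if adjacency.shape != (n_elec, n_elec):
        raise ValueError("adjacency does not match electrode count")
    diff = A - B
    valid = ~np.isnan(diff)
    keep = valid.mean(axis=0) >= min_subject_fraction
    diff = diff[:, keep]
    adj = adjacency[np.ix_(keep, keep)]

    n_eff = int(np.median(valid[:, keep].sum(axis=0))) if keep.any() else n_subj
    t_crit = float(sst.t.ppf(1.0 - clusteralpha / 2.0, df=max(n_eff - 1, 1)))

    t_obs = _paired_t(diff)
    obs = _clusters_from_t(t_obs, t_crit, adj)

    def tail_maxima(cl):
        pos = max((m for _, s, m in cl if s > 0), default=0.0)
        neg = max((-m for _, s, m in cl if s < 0), default=0.0)
        return pos, neg

    rng = np.random.default_rng(seed)
    null_pos = np.empty(n_permutations + 1)
    null_neg = np.empty(n_permutations + 1)
    null_pos[0], null_neg[0] = tail_maxima(obs)
    for p in range(n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n_subj)
        t_perm = _paired_t(diff * flips[:, None])
        perm = _clusters_from_t(t_perm, t_crit, adj)
        null_pos[p + 1], null_neg[p + 1] = tail_maxima(perm)

    clusters = []
    kept_idx = np.flatnonzero(keep)
    for members, sign, mass in obs:
        null = null_pos if sign > 0 else null_neg
        pval = float(np.mean(null >= abs(mass) - 1e-12))
        clusters.append(Cluster(
            electrodes=[int(kept_idx[m]) for m in members],
            sign=sign, mass=mass, p=pval,
        ))
    clusters.sort(key=lambda c: c.p)
    t_full = np.full(n_elec, np.nan)
    t_full[keep] = t_obs
    return ClusterResult(clusters=clusters, t_values=t_full, t_critical=t_crit,
                         n_permutations=n_permutations, used_electrodes=keep)


def cluster_report(result: ClusterResult, labels: list[str]) -> dict:
    return {
        "t_critical": result.t_critical,
        "n_permutations": result.n_permutations,
        "clusters": [
            {
                "electrodes": [labels[i] for i in c.electrodes],
                "sign": c.sign, "mass": c.mass, "p": c.p,
            }
            for c in result.clusters
        ],
    }
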