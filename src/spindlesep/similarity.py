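"""Within-subject similarity and subject-fingerprint classification.

Spectral (0-20 Hz bins) or topographic (per-electrode) profiles are
compared within subjects by Pearson correlation; the set of per-subject
R values is tested against zero with a one-sample t test, and the
proportion of subjects whose correlation survives Benjamini-Hochberg FDR
at 0.05 is reported. Complementarily, a k=1 nearest-neighbor classifier
under correlation distance (1 - R) asks whether a subject can be
recognized from their profile in the other condition; accuracy is
reported per direction with an exact one-sided binomial test against
chance 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sst
from sklearn.neighbors import KNeighborsClassifier
from statsmodels.stats.multitest import multipletests


def profile_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson R and two-sided p (t distribution, n-2 df) between two
    equal-length profiles."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("profiles must be equal-length 1-D vectors, n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance profile")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def group_r_ttest(rs) -> tuple[float, float]:
    """One-sample t test of the N correlation coefficients against zero."""
    rs = np.asarray(rs, float)
    t, p = sst.ttest_1samp(rs, 0.0)
    return float(t), float(p)


def knn_identify(train: np.ndarray, test: np.ndarray, k: int = 1
                 ) -> tuple[float, np.ndarray]:
    """Label each test profile as the training subject it correlates with
    most (k=1, correlation distance). Rows are subjects, in the same order
    in both conditions; ties go to the lowest subject index."""
    train = np.asarray(train, float)
    test = np.asarray(test, float)
    if train.shape != test.shape:
        raise ValueError("train and test must cover the same subjects/features")
    n = train.shape[0]
    clf = KNeighborsClassifier(n_neighbors=k, metric="correlation",
                               algorithm="brute")
    clf.fit(train, np.arange(n))
    pred = clf.predict(test)
    accuracy = float(np.mean(pred == np.arange(n)))
    return accuracy, pred


def binomial_significance(n_correct: int, n: int, chance: float | None = None
                          ) -> float:
    """One-sided exact binomial tail P(X >= n_correct) under chance accuracy
    (default 1/n)."""
    if not (0 <= n_correct <= n):
        raise ValueError("need 0 <= n_correct <= n")
    if chance is None:
        chance = 1.0 / n
    return float(sst.binom.sf(n_correct - 1, n, chance))


@dataclass
class SimilarityResult:
    """One row of a similarity table: a named paired comparison."""

    comparison: str
    n: int
    r_values: np.ndarray
    r_pvalues: np.ndarray
    group_t: float
    group_p: float
    pct_fdr_significant: float
    accuracy_ab: float
    accuracy_ba: float
    binom_p_ab: float
    binom_p_ba: float


def compare_profiles(profiles_a: np.ndarray, profiles_b: np.ndarray,
                     comparison: str = "", fdr_alpha: float = 0.05
                     ) -> SimilarityResult:
    """Full similarity analysis between two paired sets of profiles
    (subjects x features): per-subject Pearson R/p, group t test, FDR
    subject counts, and both-direction k=1 fingerprint classification."""
    A = np.asarray(profiles_a, float)
    B = np.asarray(profiles_b, float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("profile sets must be matching 2-D arrays")
    n = A.shape[0]
    rp = [profile_correlation(a, b) for a, b in zip(A, B)]
    rs = np.array([r for r, _ in rp])
    ps = np.array([p for _, p in rp])
    t, gp = group_r_ttest(rs)
    adj = fdr_adjust(ps)
    acc_ab, _ = knn_identify(A, B)
    acc_ba, _ = knn_identify(B, A)
    return SimilarityResult(
        comparison=comparison, n=n, r_values=rs, r_pvalues=ps,
        group_t=t, group_p=gp,
        pct_fdr_significant=100.0 * float(np.mean(adj < fdr_alpha)),
        accuracy_ab=acc_ab, accuracy_ba=acc_ba,
        binom_p_ab=binomial_significance(int(round(acc_ab * n)), n),
        binom_p_ba=binomial_significance(int(round(acc_ba * n)), n),
    )


def similarity_table(results: list[SimilarityResult]):
    """TSV-ready table mirroring the similarity summaries: mean +/- SD of R,
    % FDR-significant subjects, per-direction accuracy and binomial p."""
    import pandas as pd

    rows = []
    for r in results:
        rows.append({
            "comparison": r.comparison, "N": r.n,
            "mean_R": float(np.mean(r.r_values)),
            "sd_R": float(np.std(r.r_values, ddof=1)) if r.n > 1 else 0.0,
            "group_t": r.group_t, "group_p": r.group_p,
            "pct_fdr_significant": r.pct_fdr_significant,
            "accuracy_I_II": r.accuracy_ab, "binom_p_I_II": r.binom_p_ab,
            "accuracy_II_I": r.accuracy_ba, "binom_p_II_I": r.binom_p_ba,
        })
    return pd.DataFrame(rows)
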