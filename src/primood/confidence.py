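"""Confidence pooling and distributional summaries: the OOD read-out.

For each subject, the winning softmax probabilities of predictions whose
*predicted* class is motion-based (reach / transport / reposition) form a
probability cluster.  A classifier trained only on healthy movement should
assign high probabilities to in-distribution (healthy) clusters and lower
ones to out-of-distribution (impaired) clusters, so cluster location is a
continuous abnormality read-out.

Summaries per cluster: Gaussian fit (mean, SD), Cauchy maximum-likelihood
fit (location ~ median, scale; the reported "IQR" is 2 x scale, exact for a
Cauchy), first principal components of (mean, SD) and (location, IQR)
across subjects, and the 1-Wasserstein distance to the pooled healthy test
cluster.  Group inference uses a subject-level permutation test on mean
confidence, which respects within-subject correlation by collapsing each
subject to a single value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .schema import MOTION_BASED, PrimitiveClass

__all__ = [
    "ProbabilityCluster", "ConfidenceSummary", "pool_motion_probabilities",
    "gaussian_summary", "cauchy_summary", "cauchy_mle", "PC1Result",
    "pc1_scores", "wasserstein_1d", "spearman_with_impairment",
    "group_difference_test",
]

log = logging.getLogger(__name__)

_MOTION_NAMES = {p.value for p in MOTION_BASED}


@dataclass
class ProbabilityCluster:
    subject_id: str
    values: np.ndarray
    version_ids: list[str]

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0


@dataclass
class ConfidenceSummary:
    subject_id: str
    n: int
    mean: float
    sd: float
    cauchy_location: float
    cauchy_scale: float
    cauchy_iqr: float                  # 2 x scale (exact for a Cauchy)
    wasserstein_to_healthy: float


def pool_motion_probabilities(predictions: pd.DataFrame, subject_id: str) -> ProbabilityCluster:
    """Winning probabilities of motion-based *predicted* tokens for a subject.

    Predicted-class filtering is used (ground truth is unavailable at
    deployment).  An empty cluster is returned explicitly rather than
    raised, so callers can exclude-and-count.
    """
    rows = predictions[(predictions["subject_id"] == subject_id)
                       & predictions["predicted_label"].isin(_MOTION_NAMES)]
    return ProbabilityCluster(
        subject_id,
        rows["winning_probability"].to_numpy(dtype=float),
        sorted(rows["version_id"].unique().tolist()),
    )


def gaussian_summary(cluster: ProbabilityCluster) -> tuple[float, float]:
    v = cluster.values
    if v.size < 2:
        raise ValueError("need >= 2 values for a Gaussian summary")
    return float(v.mean()), float(v.std(ddof=1))


def cauchy_mle(values: np.ndarray, tol: float = 1e-8,
               max_iter: int = 200) -> tuple[float, float, bool]:
    """Damped-Newton Cauchy maximum likelihood; returns (loc, scale, converged).

    Initialized at (sample median, half-IQR).  If the Newton iteration
    fails to converge the initializer is returned with a logged warning.
    """
    x = np.asarray(values, dtype=float)
    med = float(np.median(x))
    q75, q25 = np.percentile(x, [75, 25])
    half_iqr = float(q75 - q25) / 2.0
    if half_iqr <= 0:
        # degenerate sample: Cauchy scale estimate collapses
        return med, half_iqr, True
    n = x.size

    def loglik(x0, g):
        u = x - x0
        return n * np.log(g) - np.sum(np.log(g * g + u * u))

    x0, g = med, half_iqr
    ll = loglik(x0, g)
    for _ in range(max_iter):
        u = x - x0
        D = g * g + u * u
        g1 = np.sum(2.0 * u / D)                      # dL/dx0
        g2 = n / g - np.sum(2.0 * g / D)              # dL/dgamma
        grad = np.array([g1, g2])
        if np.linalg.norm(grad) < tol:
            return float(x0), float(g), True
        h11 = np.sum(2.0 * (u * u - g * g) / (D * D))
        h22 = -n / (g * g) - np.sum(2.0 * (u * u - g * g) / (D * D))
        h12 = -4.0 * g * np.sum(u / (D * D))
        H = np.array([[h11, h12], [h12, h22]])
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = grad * 1e-3
        lam = 1.0
        for _ in range(40):
            nx0, ng = x0 + lam * step[0], g + lam * step[1]
            if ng > 0:
                nll = loglik(nx0, ng)
                if nll >= ll:
                    break
            lam *= 0.5
        else:
            break
        if abs(nx0 - x0) < tol and abs(ng - g) < tol:
            return float(nx0), float(ng), True
        x0, g, ll = nx0, ng, nll
    else:
        log.warning("Cauchy MLE did not converge; falling back to (median, IQR/2)")
        return med, half_iqr, False
    log.warning("Cauchy MLE line search stalled; falling back to (median, IQR/2)")
    return med, half_iqr, False


def cauchy_summary(cluster: ProbabilityCluster) -> tuple[float, float]:
    if cluster.values.size < 3:
        raise ValueError("need >= 3 values for a Cauchy summary")
    loc, scale, _ = cauchy_mle(cluster.values)
    return loc, scale


@dataclass
class PC1Result:
    scores: np.ndarray
    explained_ratio: float
    dropped_feature: str | None = None


def pc1_scores(locations, spreads) -> PC1Result:
    """Leading principal component of z-scored (location, spread) pairs.

    The sign is fixed so the loading on the location feature is <= 0:
    higher PC1 means lower confidence.  A zero-variance feature is dropped
    with a warning.
    """
    loc = np.asarray(locations, dtype=float)
    spr = np.asarray(spreads, dtype=float)
    if loc.size < 3:
        raise ValueError("need >= 3 subjects for PC1")
    sl, ss = loc.std(ddof=1), spr.std(ddof=1)
    if sl < 1e-12 and ss < 1e-12:
        raise ValueError("both features are constant")
    if sl < 1e-12 or ss < 1e-12:
        name = "location" if sl < 1e-12 else "spread"
        log.warning("PC1: zero-variance feature %s dropped", name)
        kept = spr if sl < 1e-12 else loc
        z = (kept - kept.mean()) / kept.std(ddof=1)
        sign = 1.0 if sl < 1e-12 else -1.0   # loading on location <= 0
        return PC1Result(sign * z, 1.0, dropped_feature=name)
    zl = (loc - loc.mean()) / sl
    zs = (spr - spr.mean()) / ss
    Z = np.column_stack([zl, zs])
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    if v[0] > 0:
        v = -v
    return PC1Result(Z @ v, float(evals[-1] / evals.sum()))


def wasserstein_1d(cluster_values, reference_values) -> float:
    """1-Wasserstein distance between two empirical distributions."""
    a = np.asarray(cluster_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty input")
    return float(stats.wasserstein_distance(a, b))


def spearman_with_impairment(summaries, scores) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) with its p-value."""
    s = np.asarray(summaries, dtype=float)
    y = np.asarray(scores, dtype=float)
    if s.size < 5:
        raise ValueError("need >= 5 subjects")
    if np.ptp(s) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for constant input")
    rho, p = stats.spearmanr(s, y)
    return float(rho), float(p)


def group_difference_test(healthy_subject_means, impaired_subject_means,
                          n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Subject-level permutation test of the group mean-confidence difference.

    Two-sided p = (1 + #{|perm diff| >= |observed|}) / (n_perm + 1).
    """
    a = np.asarray(healthy_subject_means, dtype=float)
    b = np.asarray(impaired_subject_means, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need >= 3 subjects per group")
    obs = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[: a.size].mean() - perm[a.size:].mean()
        if abs(d) >= abs(obs) - 1e-15:
            count += 1
    return float(obs), (1 + count) / (n_perm + 1)
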