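"""Group-level inference over subject-wise time series and scalars.

Covers the second-level procedures the single-subject analyses feed into:
sign-flip cluster-based permutation tests over time (family-wise error
control by maximal cluster mass), jackknife comparison of onset latencies
between conditions, BIC-approximated Bayes factors for evidence of absence,
anxiety median-split / correlation analyses with leave-one-out prediction
intervals, and Fisher z comparison of correlation coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# cluster-based permutation

@dataclass(frozen=True)
class Cluster:
    t_start: float
    t_end: float
    sign: int
    mass: float
    p_corrected: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    alpha: float
    threshold: float
    times: np.ndarray
    tvals: np.ndarray

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected <= self.alpha]


def _onesample_t(data: np.ndarray) -> np.ndarray:
    n = data.shape[0]
    m = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    return m / (sd / np.sqrt(n))


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of contiguous True runs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def _observed_clusters(tvals, thresh):
    out = []
    for sign in (1, -1):
        for a, b in _runs(sign * tvals > thresh):
            out.append((a, b, sign, float(tvals[a:b].sum())))
    out.sort(key=lambda c: c[0])
    return out


def _max_cluster_masses(T: np.ndarray, thresh: float) -> np.ndarray:
    """Max |cluster mass| per row, vectorized over permutations.

    Rows are separated by an inserted zero column so runs cannot straddle
    permutations; same-sign suprathreshold runs are summed with reduceat.
    """
    P, L = T.shape
    A = np.concatenate([T, np.zeros((P, 1))], axis=1).ravel()
    sup = np.abs(A) > thresh
    if not sup.any():
        return np.zeros(P)
    pos = A > thresh
    prev_sup = np.concatenate([[False], sup[:-1]])
    prev_pos = np.concatenate([[False], pos[:-1]])
    starts = sup & (~prev_sup | (pos != prev_pos))
    sidx = np.flatnonzero(starts)
    seg = np.add.reduceat(np.where(sup, A, 0.0), sidx)
    rows = sidx // (L + 1)
    out = np.zeros(P)
    np.maximum.at(out, rows, np.abs(seg))
    return out


def cluster_permutation(
    effect: np.ndarray,
    times: np.ndarray | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """One-sample cluster permutation test over time (sign-flip null).

    ``effect`` is subjects x time.  Per time point a one-sample t against
    zero is computed; contiguous runs beyond the two-sided critical value at
    ``alpha`` form clusters whose mass is the summed t.  The null is built by
    randomly sign-flipping subjects and recording the maximal |mass| per
    permutation; corrected p-values use the add-one permutation estimator
    (p in [1/(n_perm+1), 1]).
    """
    effect = np.asarray(effect, float)
    if effect.ndim != 2 or effect.shape[0] < 2:
        raise ValueError("effect must be subjects x time with >= 2 subjects")
    n, L = effect.shape
    if times is None:
        times = np.arange(L, dtype=float)
    if np.any(effect.std(axis=0, ddof=1) == 0):
        if np.allclose(effect, 0):
            return ClusterResult([], n_perm, alpha, np.inf, np.asarray(times),
                                 np.zeros(L))
        raise ValueError("degenerate (zero-variance) time points")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse corrected p-values")
    thresh = stats.t.ppf(1 - alpha / 2, df=n - 1)
    tvals = _onesample_t(effect)
    observed = _observed_clusters(tvals, thresh)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    M = signs @ effect / n
    sumsq = np.sum(effect**2, axis=0)  # invariant under sign flips
    var = (sumsq / n - M**2) * n / (n - 1)
    var = np.maximum(var, 1e-300)
    Tperm = M / np.sqrt(var / n)
    null_max = _max_cluster_masses(Tperm, thresh)
    clusters = []
    for a, b, sign, mass in observed:
        p = (np.sum(null_max >= abs(mass)) + 1) / (n_perm + 1)
        clusters.append(
            Cluster(float(times[a]), float(times[b - 1]), sign, mass, float(p))
        )
    return ClusterResult(clusters, n_perm, alpha, float(thresh),
                         np.asarray(times), tvals)


# ---------------------------------------------------------------------------
# onset latency

#: Minimum duration (s) of sustained significance defining an onset.
ONSET_MIN_DURATION = 0.02


def _resolve_n_consecutive(times, n_consecutive):
    if n_consecutive is not None:
        return n_consecutive
    dt = float(np.median(np.diff(times)))
    return max(3, int(round(ONSET_MIN_DURATION / dt)))


def encoding_onset(
    group_series: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
    n_consecutive: int | None = None,
    t_min: float = 0.0,
    sign: int = 0,
) -> float | None:
    """Onset = first time with sustained uncorrected significance.

    Significance is an uncorrected one-sample t across subjects at
    ``alpha`` (two-sided when ``sign`` is 0, else one-sided in ``sign``'s
    direction), from ``t_min`` onward; it must hold for ``n_consecutive``
    samples (default: 20 ms worth, at least 3).  The reported latency
    interpolates the |t| crossing of the critical value, so it varies
    continuously with the data.  NaN time points never count.  Returns None
    when no qualifying run exists.
    """
    g = np.asarray(group_series, float)
    n = g.shape[0]
    n_consecutive = _resolve_n_consecutive(times, n_consecutive)
    with np.errstate(invalid="ignore", divide="ignore"):
        tv = _onesample_t(g)
    if sign == 0:
        crit = stats.t.ppf(1 - alpha / 2, df=n - 1)
        sig = np.abs(tv) > crit
    else:
        crit = stats.t.ppf(1 - alpha, df=n - 1)
        sig = sign * tv > crit
    sig &= np.isfinite(tv) & (times >= t_min)
    for a, b in _runs(sig):
        if b - a >= n_consecutive:
            # continuous latency: interpolate |t| crossing the critical value
            # between the preceding sample and the run's first sample
            if a == 0 or not np.isfinite(tv[a - 1]):
                return float(times[a])
            s = np.sign(tv[a]) if sign == 0 else sign
            y0, y1 = s * tv[a - 1], s * tv[a]
            if y1 <= crit or y1 == y0:
                return float(times[a])
            frac = np.clip((crit - y0) / (y1 - y0), 0.0, 1.0)
            return float(times[a - 1] + frac * (times[a] - times[a - 1]))
    return None


@dataclass
class JackknifeOnsetResult:
    onset_a: float | None
    onset_b: float | None
    diff: float
    t: float
    p: float
    df: int
    undefined: bool = False


def jackknife_onset_diff(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    times: np.ndarray,
    alpha: float = 0.05,
    n_consecutive: int | None = None,
    t_min: float = 0.0,
    sign: int = 0,
) -> JackknifeOnsetResult:
    """Leave-one-subject-out jackknife test of an onset-latency difference.

    Onsets are re-estimated on each leave-one-out subsample; the jackknife
    variance of the onset difference carries the (n-1) correction factor and
    the t statistic has n-1 degrees of freedom.  If the onset is undefined in
    any subsample the result is flagged rather than raising.
    """
    A = np.asarray(cond_a, float)
    B = np.asarray(cond_b, float)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need matched subjects x time arrays with >= 3 subjects")
    n = A.shape[0]
    kw = dict(alpha=alpha, n_consecutive=n_consecutive, t_min=t_min, sign=sign)
    on_a = encoding_onset(A, times, **kw)
    on_b = encoding_onset(B, times, **kw)
    diffs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        oa = encoding_onset(A[keep], times, **kw)
        ob = encoding_onset(B[keep], times, **kw)
        if oa is None or ob is None:
            return JackknifeOnsetResult(on_a, on_b, np.nan, np.nan, np.nan,
                                        n - 1, undefined=True)
        diffs[i] = oa - ob
    dbar = diffs.mean()
    var_jack = (n - 1) / n * np.sum((diffs - dbar) ** 2)
    if var_jack == 0:
        t = 0.0 if dbar == 0 else np.inf * np.sign(dbar)
    else:
        t = dbar / np.sqrt(var_jack)
    p = 2 * stats.t.sf(abs(t), df=n - 1) if np.isfinite(t) else 0.0
    return JackknifeOnsetResult(on_a, on_b, float(dbar), float(t), float(p), n - 1)


# ---------------------------------------------------------------------------
# Bayes factors and correlations

@dataclass(frozen=True)
class NullBF:
    bf10: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def interpretation(self) -> str:
        if self.bf10 < 1 / 3:
            return "substantial evidence for the null"
        if self.bf10 > 3:
            return "substantial evidence for the effect"
        return "inconclusive"


def bic_bayes_null(effects: np.ndarray) -> NullBF:
    """BIC-approximated Bayes factor: effect (free mu) vs null (mu = 0).

    Both models take the per-subject effects as normal with free sigma; the
    BIC difference converts to a Bayes factor via exp(-dBIC/2).  bf10 < 1/3
    is substantial evidence of absence; bf10 > 3 of presence.
    """
    x = np.asarray(effects, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if x.std() == 0:
        raise ValueError("zero variance across subjects")
    s2_1 = x.var()  # ML variances
    s2_0 = np.mean(x**2)
    ll1 = -n / 2 * (np.log(2 * np.pi * s2_1) + 1)
    ll0 = -n / 2 * (np.log(2 * np.pi * s2_0) + 1)
    bic1 = 2 * np.log(n) - 2 * ll1
    bic0 = 1 * np.log(n) - 2 * ll0
    return NullBF(bf10=float(np.exp((bic0 - bic1) / 2)))


def compare_correlations(
    r_a: float,
    r_b: float,
    n_a: int,
    n_b: int,
    dependent: bool = False,
    r_cross: float | None = None,
) -> float:
    """Two-sided p for the difference between two Pearson correlations.

    Independent groups use the Fisher z test.  For dependent overlapping
    correlations (same sample, shared variable) provide the correlation
    ``r_cross`` between the two non-shared variables; Steiger's Z is used.
    """
    for r in (r_a, r_b):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    za, zb = np.arctanh(r_a), np.arctanh(r_b)
    if not dependent:
        if min(n_a, n_b) < 4:
            raise ValueError("need n >= 4 per group")
        se = np.sqrt(1 / (n_a - 3) + 1 / (n_b - 3))
        z = (za - zb) / se
    else:
        if r_cross is None:
            raise ValueError("dependent comparison needs r_cross")
        n = n_a
        rbar = (r_a + r_b) / 2
        # Steiger (1980) Z for overlapping dependent correlations
        psi = r_cross * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (
            1 - 2 * rbar**2 - r_cross**2
        )
        cov = psi / (1 - rbar**2) ** 2
        z = (za - zb) * np.sqrt((n - 3) / (2 - 2 * cov))
    return float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# anxiety analyses

@dataclass
class CorrelationReport:
    r: float
    df: int
    p: float
    loo_lower: np.ndarray
    loo_upper: np.ndarray
    outliers: list
    r_excluded: float | None
    p_excluded: float | None


@dataclass
class AnxietyResult:
    interaction_F: float
    interaction_p: float
    group_assignment: pd.Series
    correlation: CorrelationReport


def median_split(scores: pd.Series) -> pd.Series:
    """Low/high split of equal size; with odd n the median joins 'low'."""
    order = scores.sort_values(kind="stable").index
    n_low = (len(order) + 1) // 2
    out = pd.Series("high", index=scores.index)
    out.loc[order[:n_low]] = "low"
    return out


def loo_prediction_screen(x: np.ndarray, y: np.ndarray, level: float = 0.95):
    """Leave-one-out 95% prediction intervals for a group regression line.

    Subject n's interval comes from the line fitted without subject n; points
    outside their own cross-validated interval are flagged as outliers.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    lo = np.empty(n)
    hi = np.empty(n)
    tcrit_q = 1 - (1 - level) / 2
    for i in range(n):
        keep = np.arange(n) != i
        xi, yi = x[keep], y[keep]
        m = len(xi)
        slope, intercept = np.polyfit(xi, yi, 1)
        resid = yi - (slope * xi + intercept)
        s = np.sqrt(np.sum(resid**2) / (m - 2))
        sxx = np.sum((xi - xi.mean()) ** 2)
        se_pred = s * np.sqrt(1 + 1 / m + (x[i] - xi.mean()) ** 2 / sxx)
        tcrit = stats.t.ppf(tcrit_q, df=m - 2)
        pred = slope * x[i] + intercept
        lo[i], hi[i] = pred - tcrit * se_pred, pred + tcrit * se_pred
    outliers = np.flatnonzero((y < lo) | (y > hi))
    return lo, hi, outliers


def anxiety_analysis(
    gains: pd.DataFrame,
    anxiety: pd.DataFrame,
    score: str = "state_score",
) -> AnxietyResult:
    """Median-split interaction and anxiety-gain correlation with LOO screen.

    ``gains`` needs columns subject_id, threat_plus, threat_minus (one row
    per subject).  The 2 (anxiety group) x 2 (threat condition) mixed-design
    interaction F equals the squared two-sample t on the within-subject
    THREAT+ minus THREAT- difference between groups.  The Pearson correlation
    of anxiety with that difference is screened for outliers by leave-one-out
    95% prediction intervals, and re-computed after exclusion when any are
    flagged.
    """
    df = gains.merge(anxiety[["subject_id", score]], on="subject_id")
    if df["subject_id"].duplicated().any():
        raise ValueError("one gain row per subject required")
    diff = (df["threat_plus"] - df["threat_minus"]).to_numpy(float)
    anx = df[score].to_numpy(float)
    group = median_split(df[score])
    lo_mask = (group == "low").to_numpy()
    t, p_t = stats.ttest_ind(diff[~lo_mask], diff[lo_mask])
    n = len(df)
    r, p_r = stats.pearsonr(anx, diff)
    lo, hi, outliers = loo_prediction_screen(anx, diff)
    r_ex = p_ex = None
    if len(outliers):
        keep = np.ones(n, bool)
        keep[outliers] = False
        if keep.sum() >= 4:
            r_ex, p_ex = stats.pearsonr(anx[keep], diff[keep])
    report = CorrelationReport(
        r=float(r), df=n - 2, p=float(p_r),
        loo_lower=lo, loo_upper=hi,
        outliers=[df["subject_id"].iloc[i] for i in outliers],
        r_excluded=None if r_ex is None else float(r_ex),
        p_excluded=None if p_ex is None else float(p_ex),
    )
    return AnxietyResult(
        interaction_F=float(t**2),
        interaction_p=float(p_t),
        group_assignment=group.set_axis(df["subject_id"]),
        correlation=report,
    )
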