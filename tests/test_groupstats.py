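"""Cluster permutation, jackknife onsets, null Bayes factors, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from threatsense.groupstats import (
    anxiety_analysis,
    bic_bayes_null,
    cluster_permutation,
    compare_correlations,
    encoding_onset,
    jackknife_onset_diff,
    loo_prediction_screen,
    median_split,
)


# ---------------------------------------------------------------------------
# cluster permutation

def test_injected_effect_detected_and_localized():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((24, 300))
    X[:, 100:150] += 1.0
    res = cluster_permutation(X, n_perm=500, seed=1)
    sig = res.significant
    assert sig, "injected cluster not detected"
    assert any(c.t_start <= 149 and c.t_end >= 100 for c in sig)


def test_all_zero_data_gives_no_clusters():
    res = cluster_permutation(np.zeros((10, 50)), n_perm=200, seed=0)
    assert res.clusters == []


def test_cluster_p_bounds_and_sign():
    rng = np.random.default_rng(2)
    X = rng.standard_normal((16, 200)) - 0.8  # strong negative shift
    res = cluster_permutation(X, n_perm=300, seed=3)
    for c in res.clusters:
        assert 1 / 301 <= c.p_corrected <= 1.0
        assert np.sign(c.mass) == c.sign


def test_clusters_non_overlapping():
    rng = np.random.default_rng(3)
    res = cluster_permutation(rng.standard_normal((12, 400)), n_perm=200, seed=4)
    spans = sorted((c.t_start, c.t_end) for c in res.clusters)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert e1 < s2


def test_matches_mne_cluster_oracle():
    """Cluster masses and p-values agree with the mne implementation."""
    from mne.stats import permutation_cluster_1samp_test

    rng = np.random.default_rng(5)
    X = rng.standard_normal((15, 120))
    X[:, 40:70] += 0.9
    n = X.shape[0]
    thresh = stats.t.ppf(1 - 0.025, n - 1)
    res = cluster_permutation(X, n_perm=1000, seed=6)
    t_obs, clusters, pvals, _ = permutation_cluster_1samp_test(
        X, threshold=thresh, n_permutations=1000, tail=0, seed=7,
        out_type="mask", verbose="error",
    )
    masses_mine = sorted(round(abs(c.mass), 6) for c in res.clusters)
    masses_mne = sorted(round(abs(t_obs[m].sum()), 6) for m in clusters)
    assert masses_mine == masses_mne
    p_mine = min(c.p_corrected for c in res.clusters)
    assert p_mine == pytest.approx(min(pvals), abs=0.02)


def test_degenerate_variance_raises():
    X = np.ones((8, 30))
    with pytest.raises(ValueError, match="variance"):
        cluster_permutation(X, n_perm=200)


# ---------------------------------------------------------------------------
# onsets

def _ramp_curves(rng, onset, times, n=24, slope=2.0, noise=1.0):
    ramp = np.clip((times - onset) / 0.3, 0, None) * slope
    return ramp + noise * rng.standard_normal((n, len(times)))


def test_onset_estimator_near_truth():
    rng = np.random.default_rng(7)
    times = np.arange(-0.2, 1.0, 0.002)
    onsets = [
        encoding_onset(_ramp_curves(rng, 0.3, times, slope=4.0), times)
        for _ in range(10)
    ]
    assert all(o is not None for o in onsets)
    # detection lags truth (t must clear the critical value) but is stable
    assert 0.28 < np.mean(onsets) < 0.42


def test_jackknife_matches_hand_enumerated_four_subject_oracle():
    """t equals the explicit leave-one-out formula on a tiny example."""
    times = np.arange(-0.1, 1.0, 0.01)
    rng = np.random.default_rng(8)
    A = _ramp_curves(rng, 0.2, times, n=4, slope=8.0, noise=0.5)
    B = _ramp_curves(rng, 0.5, times, n=4, slope=8.0, noise=0.5)
    res = jackknife_onset_diff(A, B, times)
    assert not res.undefined
    # independent enumeration
    n = 4
    diffs = []
    for i in range(n):
        keep = [j for j in range(n) if j != i]
        oa = encoding_onset(A[keep], times)
        ob = encoding_onset(B[keep], times)
        diffs.append(oa - ob)
    diffs = np.asarray(diffs)
    dbar = diffs.mean()
    se = np.sqrt((n - 1) / n * np.sum((diffs - dbar) ** 2))
    t_oracle = dbar / se
    assert res.t == pytest.approx(t_oracle, rel=1e-12)
    assert res.p == pytest.approx(2 * stats.t.sf(abs(t_oracle), n - 1), rel=1e-12)


def test_jackknife_minimal_cohort_runs():
    times = np.arange(-0.1, 1.0, 0.01)
    rng = np.random.default_rng(9)
    A = _ramp_curves(rng, 0.2, times, n=3, slope=8.0, noise=0.3)
    B = _ramp_curves(rng, 0.6, times, n=3, slope=8.0, noise=0.3)
    res = jackknife_onset_diff(A, B, times)
    assert res.undefined or np.isfinite(res.t)


def test_jackknife_flags_undefined_onset():
    times = np.arange(0, 1.0, 0.01)
    rng = np.random.default_rng(10)
    A = _ramp_curves(rng, 0.2, times, n=6, slope=6.0, noise=0.5)
    B = rng.standard_normal((6, len(times)))  # no onset anywhere
    res = jackknife_onset_diff(A, B, times)
    assert res.undefined


# ---------------------------------------------------------------------------
# Bayes factors

def test_bf_overwhelming_effect():
    rng = np.random.default_rng(11)
    bf = bic_bayes_null(5 + 0.1 * rng.standard_normal(24))
    assert bf.bf10 > 3
    assert bf.interpretation == "substantial evidence for the effect"


def test_bf_reciprocal_consistency():
    rng = np.random.default_rng(12)
    bf = bic_bayes_null(rng.standard_normal(24))
    assert bf.bf10 * bf.bf01 == pytest.approx(1.0, rel=1e-12)


def test_bf_monotone_in_shift():
    rng = np.random.default_rng(13)
    base = rng.standard_normal(24)
    bfs = [bic_bayes_null(base + mu).bf10 for mu in (0.0, 0.4, 0.8, 1.6)]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))


def test_bf_null_calibration_median_below_one_third():
    rng = np.random.default_rng(14)
    bfs = [bic_bayes_null(rng.standard_normal(24)).bf10 for _ in range(200)]
    assert np.median(bfs) < 1 / 3


def test_bf_input_validation():
    with pytest.raises(ValueError):
        bic_bayes_null(np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        bic_bayes_null(np.full(10, 3.0))


# ---------------------------------------------------------------------------
# correlations

def test_compare_correlations_equal_gives_p_one():
    assert compare_correlations(0.4, 0.4, 20, 20) == pytest.approx(1.0)


def test_compare_correlations_reported_group_difference():
    """r = 0.66 vs r = -0.42 at n = 12 per group differs at p < 0.05."""
    p = compare_correlations(0.66, -0.42, 12, 12)
    assert p < 0.05
    # Fisher z arithmetic oracle
    z = (np.arctanh(0.66) - np.arctanh(-0.42)) / np.sqrt(1 / 9 + 1 / 9)
    assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)


def test_compare_correlations_symmetric():
    assert compare_correlations(0.2, 0.7, 15, 20) == pytest.approx(
        compare_correlations(0.7, 0.2, 20, 15)
    )


def test_compare_correlations_validates():
    with pytest.raises(ValueError):
        compare_correlations(1.0, 0.5, 10, 10)
    with pytest.raises(ValueError, match="r_cross"):
        compare_correlations(0.5, 0.3, 20, 20, dependent=True)


def test_compare_correlations_dependent_runs():
    p = compare_correlations(0.6, 0.2, 30, 30, dependent=True, r_cross=0.3)
    assert 0 < p < 1


# ---------------------------------------------------------------------------
# anxiety analyses

def _gain_frame(rng, n=24, coupling=0.8, noise=0.1):
    anx = rng.normal(30, 7, n)
    z = (anx - anx.mean()) / anx.std()
    diff = 0.5 + 0.2 * (coupling * z + np.sqrt(1 - coupling**2) * rng.standard_normal(n))
    gains = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "threat_plus": 1.0 + diff + noise * rng.standard_normal(n),
            "threat_minus": 1.0 + noise * rng.standard_normal(n),
        }
    )
    anx_df = pd.DataFrame(
        {"subject_id": gains["subject_id"], "state_score": anx, "trait_score": anx}
    )
    return gains, anx_df


def test_median_split_sizes():
    s = pd.Series([3.0, 1.0, 2.0, 5.0, 4.0])
    g = median_split(s)
    assert (g == "low").sum() == 3  # odd n: median joins low
    assert g[s.idxmin()] == "low" and g[s.idxmax()] == "high"


def test_anxiety_analysis_recovers_coupling():
    rng = np.random.default_rng(15)
    gains, anx = _gain_frame(rng, coupling=0.8)
    res = anxiety_analysis(gains, anx)
    assert res.correlation.r > 0.4
    assert res.interaction_p < 0.05
    assert res.correlation.df == 22


def test_anxiety_analysis_null_coupling():
    rng = np.random.default_rng(16)
    rs, ps = [], []
    for _ in range(10):
        gains, anx = _gain_frame(rng, coupling=0.0)
        res = anxiety_analysis(gains, anx)
        rs.append(res.correlation.r)
    assert abs(np.mean(rs)) < 0.25


def test_injected_outlier_flagged_by_loo_screen():
    rng = np.random.default_rng(17)
    gains, anx = _gain_frame(rng, coupling=0.9, noise=0.05)
    gains.loc[5, "threat_plus"] += 5.0  # gross outlier
    res = anxiety_analysis(gains, anx)
    assert "s5" in res.correlation.outliers
    assert res.correlation.r_excluded is not None


def test_interaction_matches_pingouin_mixed_anova():
    """2x2 mixed-design interaction F agrees with the pingouin oracle."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(18)
    gains, anx = _gain_frame(rng)
    res = anxiety_analysis(gains, anx)
    long = gains.melt(id_vars="subject_id", var_name="condition", value_name="gain")
    grp = res.group_assignment.rename("group")
    long = long.merge(grp, left_on="subject_id", right_index=True)
    aov = pingouin.mixed_anova(long, dv="gain", within="condition",
                               subject="subject_id", between="group")
    f_oracle = aov.loc[aov["Source"] == "Interaction", "F"].iloc[0]
    assert res.interaction_F == pytest.approx(f_oracle, rel=1e-6)
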