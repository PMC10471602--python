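import numpy as np
import pytest

import canalex as cx
from canalex.datamodel import MCMCSettings, ValidationError
from canalex.inference import (
    GroupPosterior,
    PosteriorSummary,
    cri_overlap,
    gibbs_linear_model,
    hpd_interval,
    posterior_mode,
    summarize_posterior,
)


def short_settings(seed=0, **kw):
    return MCMCSettings(iterations=1_300, thinning=1, burnin=300, seed=seed, **kw)


def test_retained_draw_bookkeeping():
    s = MCMCSettings(iterations=13_000, thinning=10, burnin=3_000)
    assert s.retained == 1_000
    draws = gibbs_linear_model(
        np.repeat([1.0, 2.0], 5), np.repeat(["a", "b"], 5), MCMCSettings(seed=1)
    )
    assert draws.means.shape == (1_000, 2)
    assert draws.sigma2.shape == (1_000,)


def test_settings_invariants():
    with pytest.raises(ValidationError):
        MCMCSettings(iterations=100, burnin=200)
    with pytest.raises(ValidationError):
        MCMCSettings(thinning=0)
    with pytest.raises(ValidationError):
        MCMCSettings(iterations=1_000, burnin=950, thinning=1)  # < 100 retained


def test_dominant_likelihood_single_group():
    rng = np.random.default_rng(0)
    y = 50.0 + rng.normal(0, 0.01, 500)
    draws = gibbs_linear_model(y, np.repeat("g", 500), short_settings(seed=2))
    mode = posterior_mode(draws.means[:, 0])
    assert mode == pytest.approx(50.0, abs=0.01)


def test_fixed_sigma_matches_conjugate_closed_form():
    """With sigma^2 pinned, the mean's posterior is Normal in closed form."""
    y = np.array([3.0, 5.0, 4.0, 6.0, 2.0])
    sigma2, c = 4.0, 100.0
    settings = MCMCSettings(iterations=13_000, thinning=10, burnin=3_000, seed=3,
                            coef_prior_variance=c)
    draws = gibbs_linear_model(y, np.repeat("g", 5), settings, fixed_sigma2=sigma2)
    post_var = 1.0 / (len(y) / sigma2 + 1.0 / c)
    post_mean = post_var * y.sum() / sigma2
    d = draws.means[:, 0]
    mc_se_mean = np.sqrt(post_var / d.size)
    assert abs(d.mean() - post_mean) < 3 * mc_se_mean
    # variance of iid normal draws: MC SE ~ var * sqrt(2/(n-1))
    assert abs(d.var(ddof=1) - post_var) < 3 * post_var * np.sqrt(2 / (d.size - 1))


def test_gibbs_seeded_determinism():
    y = np.random.default_rng(1).normal(10, 2, 40)
    g = np.repeat(["a", "b"], 20)
    d1 = gibbs_linear_model(y, g, short_settings(seed=7))
    d2 = gibbs_linear_model(y, g, short_settings(seed=7))
    assert np.array_equal(d1.means, d2.means)
    assert np.array_equal(d1.sigma2, d2.sigma2)


def test_posterior_modes_track_group_means_with_diffuse_prior():
    rng = np.random.default_rng(4)
    y = np.concatenate([rng.normal(30, 5, 60), rng.normal(70, 5, 60)])
    g = np.repeat(["a", "b"], 60)
    draws = gibbs_linear_model(y, g, short_settings(seed=5))
    for j, grp in enumerate(draws.group_names):
        sample_mean = y[g == grp].mean()
        post_sd = draws.means[:, j].std(ddof=1)
        assert abs(posterior_mode(draws.means[:, j]) - sample_mean) < 2 * post_sd


def test_weak_prior_robustness():
    """Widening the residual-variance prior barely moves the HPDs at n=50."""
    rng = np.random.default_rng(6)
    y = np.concatenate([rng.normal(40, 8, 50), rng.normal(55, 8, 50)])
    g = np.repeat(["a", "b"], 50)
    intervals = {}
    for V in (1.0, 100.0):
        draws = gibbs_linear_model(y, g, short_settings(seed=8, prior_V=V))
        intervals[V] = hpd_interval(draws.means[:, 0])
    lo1, hi1 = intervals[1.0]
    lo2, hi2 = intervals[100.0]
    width = hi1 - lo1
    assert abs(lo1 - lo2) < 0.05 * width and abs(hi1 - hi2) < 0.05 * width


# ---------- posterior mode ----------

def test_posterior_mode_point_mass():
    assert posterior_mode(np.full(200, 3.25)) == 3.25


def test_posterior_mode_normal_draws():
    """KDE mode of Normal(10,1) samples (n=10,000) concentrates near 10."""
    devs = [
        abs(posterior_mode(np.random.default_rng(s).normal(10, 1, 10_000)) - 10.0)
        for s in range(6)
    ]
    assert np.median(devs) < 0.1
    assert max(devs) < 0.3


def test_posterior_mode_bimodal_picks_a_center():
    rng = np.random.default_rng(10)
    d = np.concatenate([rng.normal(0, 0.5, 5_000), rng.normal(20, 0.5, 5_000)])
    mode = posterior_mode(d)
    assert min(abs(mode - 0), abs(mode - 20)) < 0.3


def test_posterior_mode_requires_draws():
    with pytest.raises(ValidationError):
        posterior_mode(np.ones(50))


# ---------- HPD ----------

def exhaustive_hpd(draws, mass):
    x = np.sort(draws)
    m = int(np.ceil(mass * len(x)))
    best = None
    for i in range(len(x) - m + 1):
        w = x[i + m - 1] - x[i]
        if best is None or w < best[0]:
            best = (w, x[i], x[i + m - 1])
    return best[1], best[2]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_hpd_matches_exhaustive_search(seed):
    d = np.random.default_rng(seed).lognormal(0, 1, 500)
    assert hpd_interval(d, 0.9) == pytest.approx(exhaustive_hpd(d, 0.9))


def test_hpd_full_range_at_mass_covering_all_draws():
    # 100 sorted draws at mass 0.995 -> ceil = 100 -> the full range
    d = np.sort(np.random.default_rng(3).normal(size=100))
    assert hpd_interval(d, 0.995) == (d[0], d[-1])


def test_hpd_symmetric_close_to_equal_tail():
    d = np.random.default_rng(4).normal(0, 1, 20_000)
    lo, hi = hpd_interval(d, 0.95)
    qlo, qhi = np.quantile(d, [0.025, 0.975])
    assert lo == pytest.approx(qlo, abs=0.1)
    assert hi == pytest.approx(qhi, abs=0.1)


def test_hpd_skewed_shorter_than_equal_tail():
    d = np.random.default_rng(5).lognormal(0, 1, 20_000)
    lo, hi = hpd_interval(d, 0.95)
    qlo, qhi = np.quantile(d, [0.025, 0.975])
    assert hi < qhi  # HPD shifts toward the mode on a right-skewed posterior
    assert (hi - lo) <= (qhi - qlo)


@pytest.mark.parametrize("seed", range(5))
def test_hpd_never_longer_than_equal_tail(seed):
    d = np.random.default_rng(100 + seed).gamma(2, 3, 1_000)
    lo, hi = hpd_interval(d, 0.95)
    qlo, qhi = np.quantile(d, [0.025, 0.975])
    assert (hi - lo) <= (qhi - qlo) + 1e-12


def test_hpd_rejects_bad_mass():
    with pytest.raises(ValidationError):
        hpd_interval(np.ones(200), 1.5)


# ---------- overlap ----------

def _summary(intervals):
    groups = [
        GroupPosterior(group=g, mode=(lo + hi) / 2, hpd_lower=lo, hpd_upper=hi,
                       n_draws=1000, lag1_autocorr=0.0, ess=1000.0)
        for g, (lo, hi) in intervals.items()
    ]
    return PosteriorSummary(cluster_id=1, groups=groups, sigma2_mode=1.0,
                            sigma2_hpd=(0.5, 2.0))


def test_cri_overlap_rules():
    s = _summary({"a": (0, 1), "b": (2, 3), "c": (1, 2), "d": (2.5, 4)})
    ov = cri_overlap(s)
    assert not ov.loc["a", "b"]          # disjoint
    assert ov.loc["b", "d"]              # overlapping
    assert ov.loc["a", "c"] and ov.loc["c", "b"]  # touching endpoints overlap
    assert (ov.to_numpy() == ov.to_numpy().T).all()
    assert all(ov.loc[g, g] for g in ov.index)


def test_summary_diagnostics_and_intervals():
    rng = np.random.default_rng(11)
    y = np.concatenate([rng.normal(30, 5, 40), rng.normal(60, 5, 40)])
    g = np.repeat(["a", "b"], 40)
    draws = gibbs_linear_model(y, g, MCMCSettings(seed=12))
    summary = summarize_posterior(draws, cluster_id="c1")
    for gp in summary.groups:
        assert gp.hpd_lower < gp.hpd_upper
        assert gp.n_draws == 1_000
        assert abs(gp.lag1_autocorr) < 0.1  # independence model mixes freely
    ov = cri_overlap(summary)
    assert not ov.loc["a", "b"]  # 30 vs 60 with n=40 are distinguishable
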