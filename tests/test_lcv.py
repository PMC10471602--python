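import numpy as np
import pandas as pd
import pytest

import canalex as cx
from canalex.datamodel import ValidationError
from canalex.lcv import GroupStats, LCVMatrix


def make_stats(means: dict, cvs: dict, gene_ids=None) -> GroupStats:
    """Build GroupStats directly from per-group mean/CV arrays."""
    groups = list(means)
    n_genes = len(next(iter(means.values())))
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    mean = pd.DataFrame({g: np.asarray(means[g], float) for g in groups}, index=gene_ids)
    cv = pd.DataFrame({g: np.asarray(cvs[g], float) for g in groups}, index=gene_ids)
    sd = cv * mean
    n = pd.DataFrame(9, index=gene_ids, columns=groups)
    return GroupStats(gene_ids, groups, n, mean, sd, cv)


def brute_force_lcv(means, cvs, gene_ids, window):
    """Independent enumerator: explicit window membership and tied-rank count."""
    order = sorted(range(len(means)), key=lambda i: (means[i], gene_ids[i]))
    n = len(order)
    w = min(window, n)
    out = {}
    for pos, gi in enumerate(order):
        start = min(max(pos - w // 2, 0), n - w)
        members = order[start:start + w]
        focal = cvs[gi]
        smaller = sum(1 for m in members if cvs[m] < focal)
        equal = sum(1 for m in members if cvs[m] == focal)
        rank = smaller + (equal + 1) / 2.0
        out[gene_ids[gi]] = 100.0 * (rank - 1.0) / (w - 1.0)
    return out


# ---------- size factors ----------

def _cm(mat):
    mat = np.asarray(mat)
    return cx.CountMatrix([f"g{i}" for i in range(mat.shape[0])],
                          [f"s{j}" for j in range(mat.shape[1])], mat)


def test_size_factors_identical_samples():
    counts = _cm([[10, 10], [20, 20], [5, 5]])
    assert np.allclose(cx.size_factors(counts), [1.0, 1.0])


def test_size_factors_doubled_sample():
    base = np.array([[10], [20], [40]])
    counts = _cm(np.hstack([base, 2 * base]))
    assert np.allclose(cx.size_factors(counts), [1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_ignore_all_zero_gene():
    base = np.array([[10, 20], [20, 40], [40, 80]])
    with_zero = np.vstack([base, [0, 0]])
    assert np.allclose(cx.size_factors(_cm(base)), cx.size_factors(_cm(with_zero)))


def test_size_factors_all_zero_matrix_errors():
    with pytest.raises(ValidationError):
        cx.size_factors(_cm(np.zeros((3, 2), dtype=int)))


def test_size_factors_fallback_without_reference_gene():
    # no gene is nonzero in every sample -> library-size fallback
    counts = _cm([[4, 0], [0, 8]])
    f = cx.size_factors(counts)
    assert np.allclose(f, [4 / 6, 8 / 6])


# ---------- normalize / group stats ----------

def test_normalize_definition_and_round_trip():
    counts = _cm([[10, 10], [4, 8]])
    norm = cx.normalize(counts, np.array([2.0, 1.0]))
    assert norm.values[0, 0] == 5.0
    assert np.allclose(norm.values * norm.size_factors[None, :], counts.counts)
    ident = cx.normalize(counts, np.ones(2))
    assert np.array_equal(ident.values, counts.counts)
    with pytest.raises(ValidationError):
        cx.normalize(counts, np.ones(3))


def _meta_one_group(sample_ids, cross=("PL", "PL")):
    return cx.SampleTable(pd.DataFrame([
        dict(sample_id=s, maternal_morph=cross[0], paternal_morph=cross[1],
             time_point=150, family_id="f1") for s in sample_ids
    ]))


def test_group_cv_closed_forms():
    counts = _cm([[5, 5, 5], [1, 2, 3]])
    meta = _meta_one_group(counts.sample_ids)
    stats = cx.group_cv(cx.normalize(counts, np.ones(3)), meta)
    grp = stats.group_names[0]
    assert stats.cv.loc["g0", grp] == 0.0
    assert stats.mean.loc["g1", grp] == pytest.approx(2.0)
    assert stats.sd.loc["g1", grp] == pytest.approx(1.0)
    assert stats.cv.loc["g1", grp] == pytest.approx(0.5)


def test_group_cv_replicate_order_invariant():
    rng = np.random.default_rng(0)
    mat = rng.integers(1, 100, size=(10, 6))
    meta = _meta_one_group([f"s{j}" for j in range(6)])
    a = cx.group_cv(cx.normalize(_cm(mat), np.ones(6)), meta)
    perm = rng.permutation(6)
    b = cx.group_cv(cx.normalize(_cm(mat[:, perm]), np.ones(6)), meta)
    assert np.allclose(a.cv.to_numpy(), b.cv.to_numpy())


def test_group_cv_zero_mean_flagged_undefined():
    counts = _cm([[0, 0, 0], [1, 2, 3]])
    meta = _meta_one_group(counts.sample_ids)
    stats = cx.group_cv(cx.normalize(counts, np.ones(3)), meta)
    assert np.isnan(stats.cv.iloc[0, 0])


def test_group_cv_requires_two_replicates():
    counts = _cm([[1], [2]])
    meta = _meta_one_group(counts.sample_ids)
    with pytest.raises(ValidationError):
        cx.group_cv(cx.NormalizedMatrix(counts.gene_ids, counts.sample_ids,
                                        counts.counts.astype(float), np.ones(1)), meta)


# ---------- LCV scores ----------

def test_lcv_matches_brute_force_20_genes_window_5():
    rng = np.random.default_rng(7)
    means = rng.uniform(1, 1000, 20)
    cvs = rng.uniform(0, 2, 20)
    stats = make_stats({"A": means}, {"A": cvs})
    result = cx.lcv_scores(stats, window_size=5)
    oracle = brute_force_lcv(list(means), list(cvs), stats.gene_ids, 5)
    for g in stats.gene_ids:
        assert result.scores.loc[g, "A"] == pytest.approx(oracle[g])


@pytest.mark.parametrize("seed,n_genes,window", [
    (0, 37, 2), (1, 100, 7), (2, 120, 20), (3, 50, 11), (4, 500, 20),
])
def test_lcv_oracle_equivalence_randomized(seed, n_genes, window):
    rng = np.random.default_rng(seed)
    means = rng.uniform(1, 1e4, n_genes)
    cvs = np.round(rng.uniform(0, 3, n_genes), 2)  # rounding forces ties
    stats = make_stats({"A": means}, {"A": cvs})
    result = cx.lcv_scores(stats, window_size=window)
    oracle = brute_force_lcv(list(means), list(cvs), stats.gene_ids, window)
    assert np.allclose(
        [result.scores.loc[g, "A"] for g in stats.gene_ids],
        [oracle[g] for g in stats.gene_ids],
    )


def test_lcv_endpoints():
    means = np.arange(1, 11, dtype=float)
    cvs = np.linspace(0.1, 1.0, 10)
    stats = make_stats({"A": means}, {"A": cvs})
    scores = cx.lcv_scores(stats, window_size=10).scores["A"]
    assert scores.iloc[np.argmin(cvs)] == 0.0
    assert scores.iloc[np.argmax(cvs)] == 100.0


def test_lcv_ties_share_mean_rank():
    means = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    cvs = np.array([0.5, 0.5, 0.1, 0.9, 0.5])
    stats = make_stats({"A": means}, {"A": cvs})
    scores = cx.lcv_scores(stats, window_size=5).scores["A"]
    assert scores.iloc[0] == scores.iloc[1] == scores.iloc[4]


def test_lcv_range_and_nan_propagation(small_lcv):
    stats, scores = small_lcv
    vals = scores.scores.to_numpy()
    defined = ~np.isnan(vals)
    assert (vals[defined] >= 0).all() and (vals[defined] <= 100).all()
    # genes flagged undefined in GroupStats are NA in the LCV matrix
    assert np.array_equal(np.isnan(stats.cv.to_numpy()), ~defined)


def test_lcv_scale_invariance():
    rng = np.random.default_rng(5)
    means = rng.uniform(1, 100, 30)
    cvs = rng.uniform(0.1, 1, 30)
    a = cx.lcv_scores(make_stats({"A": means}, {"A": cvs}), 7).scores
    # multiplying all normalized values by c scales mean and sd alike: CV fixed
    b = cx.lcv_scores(make_stats({"A": 3.7 * means}, {"A": cvs}), 7).scores
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_lcv_monotone_in_focal_cv():
    rng = np.random.default_rng(6)
    means = rng.uniform(1, 100, 25)
    cvs = rng.uniform(0.1, 1, 25)
    focal = 12
    prev = -1.0
    for focal_cv in np.linspace(0.0, 1.2, 13):
        cvs2 = cvs.copy()
        cvs2[focal] = focal_cv
        s = cx.lcv_scores(make_stats({"A": means}, {"A": cvs2}), 9).scores
        val = s.iloc[focal, 0]
        assert val >= prev
        prev = val


def test_lcv_window_shrinks_with_warning(caplog):
    means = np.arange(1.0, 6.0)
    cvs = np.array([0.5, 0.2, 0.9, 0.4, 0.7])
    stats = make_stats({"A": means}, {"A": cvs})
    with caplog.at_level("WARNING", logger="canalex"):
        scores = cx.lcv_scores(stats, window_size=10)
    assert "shrinking" in caplog.text
    assert scores.scores["A"].notna().all()


def test_lcv_planted_dispersion_raises_scores():
    """Genes with a 4x dispersion in some groups score higher there (n=9)."""
    cfg = cx.SimulationConfig(
        n_genes=400, seed=13, rho=4.0, mean_fractions={},
        var_fractions={"maternal": 0.15}, time_effect_fraction=0.0,
    )
    counts, meta, truth = cx.simulate_experiment(cfg)
    _, scores = cx.lcv_pipeline(counts, meta, window_size=100)
    planted = truth.genes(var_variant="maternal_SBhigh")
    sub = scores.scores.loc[planted]
    assert sub["SBxSB-200"].median() > sub["PLxPL-200"].median()
    assert sub["SBxPL-150"].median() > sub["PLxSB-150"].median()
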