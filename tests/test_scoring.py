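"""Rank-based signature scores, Z-ranks, pathway scores, pseudobulk Pearson."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tamscreen import scoring


def brute_force_ucell(values, genes, gene_set, r_max=1500):
    """Independent oracle: explicit rank table, no vectorized shortcuts."""
    order = {}
    # mid-ranks for ties, rank 1 = highest expression
    pairs = sorted(enumerate(values), key=lambda kv: -kv[1])
    i = 0
    ranks = [0.0] * len(values)
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][1] == pairs[i][1]:
            j += 1
        mid = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[pairs[k][0]] = mid
        i = j
    idx = {g: i for i, g in enumerate(genes)}
    rs = [min(ranks[idx[g]], r_max) for g in gene_set]
    n = len(gene_set)
    u = sum(rs) - n * (n + 1) / 2
    return max(0.0, 1.0 - u / (n * r_max))


def test_ucell_maximal_and_floor_scores():
    genes = [f"g{i}" for i in range(2000)]
    values = np.zeros(2000)
    values[:3] = [5.0, 4.0, 3.0]
    cell = pd.Series(values, index=genes)
    assert scoring.ucell_like_score(cell, ["g0", "g1", "g2"]) == pytest.approx(1.0)

    # all signature genes at the rank cap: score = (n+1) / (2 r_max)
    low = pd.Series(np.zeros(2000), index=genes)
    high = [f"g{i}" for i in range(1200)]
    low[high] = 10.0
    sig = ["g1800", "g1900", "g1999"]
    score = scoring.ucell_like_score(low, sig, r_max=1500)
    # the 800 zero-expression genes share mid-rank (1201+2000)/2 > 1500,
    # so every signature rank caps at exactly r_max
    assert score == pytest.approx(4 / 3000)


def test_ucell_rank_invariance_under_monotone_transform():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(300)]
    vals = rng.exponential(1.0, 300)
    cell = pd.Series(vals, index=genes)
    sig = ["g3", "g77", "g150", "g299"]
    a = scoring.ucell_like_score(cell, sig, r_max=200)
    b = scoring.ucell_like_score(np.log1p(cell), sig, genes=None, r_max=200) \
        if False else scoring.ucell_like_score(pd.Series(np.log1p(vals), index=genes), sig, r_max=200)
    assert a == pytest.approx(b)


def test_ucell_equals_bruteforce_on_random_draws():
    rng = np.random.default_rng(123)
    genes = [f"g{i}" for i in range(500)]
    for _ in range(200):
        vals = np.round(rng.exponential(1.0, 500) * 4) / 4  # force ties
        n_sig = int(rng.integers(1, 10))
        sig = list(rng.choice(genes, n_sig, replace=False))
        r_max = int(rng.choice([50, 200, 400]))
        ours = scoring.ucell_like_score(pd.Series(vals, index=genes), sig,
                                        r_max=r_max)
        oracle = brute_force_ucell(vals, genes, sig, r_max=r_max)
        assert ours == pytest.approx(oracle, abs=1e-12)


def test_ucell_rejects_bad_gene_sets():
    cell = pd.Series([1.0, 2.0], index=["a", "b"])
    with pytest.raises(ValueError, match="empty"):
        scoring.ucell_like_score(cell, [])
    with pytest.raises(ValueError, match="absent"):
        scoring.ucell_like_score(cell, ["zz"])


def test_vectorized_ucell_matches_scalar():
    rng = np.random.default_rng(5)
    X = rng.poisson(2.0, size=(40, 200)).astype(float)
    genes = [f"g{i}" for i in range(200)]
    sig = ["g5", "g10", "g42"]
    vec = scoring.ucell_scores(X, genes, sig, r_max=150)
    for i in range(40):
        assert vec[i] == pytest.approx(
            scoring.ucell_like_score(pd.Series(X[i], index=genes), sig,
                                     r_max=150)
        )


def test_top_marker_genes_rank_cluster_degs(small_normalized):
    norm, meta = small_normalized
    myeloid = meta["cell_type"].isin(["TAM_C1", "TAM_C3"]).to_numpy()
    degs = scoring.top_marker_genes(
        norm.values[np.flatnonzero(myeloid)], norm.genes,
        meta["cell_type"].to_numpy(object)[myeloid], n_top=3,
    )
    assert set(degs["TAM_C3"]) & {"Mrc1", "Pf4", "Msr1", "Il10"}
    assert set(degs["TAM_C1"]) & {"Il1b", "Rgs1", "Cxcl16"}


def test_score_rank_z_two_subclusters_antisymmetric():
    scores = pd.Series([1.0, 1.2, 3.0, 3.4])
    sub = pd.Series(["c1", "c1", "c2", "c2"])
    sample = pd.Series(["s"] * 4)
    z = scoring.score_rank_z(scores, sub, sample)
    assert z.loc["s", "c1"] == pytest.approx(-z.loc["s", "c2"])
    np.testing.assert_allclose(z.loc["s"].mean(), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.loc["s"].std(ddof=0), 1.0, atol=1e-12)

    # location invariance
    z2 = scoring.score_rank_z(scores + 100.0, sub, sample)
    pd.testing.assert_frame_equal(z, z2)


def test_score_rank_z_single_subcluster_flagged():
    with pytest.warns(UserWarning, match="single subcluster"):
        z = scoring.score_rank_z(pd.Series([1.0, 2.0]),
                                 pd.Series(["c1", "c1"]),
                                 pd.Series(["s", "s"]))
    assert z.isna().all().all()


def test_pathway_score_null_center_and_determinism(small_normalized):
    norm, _ = small_normalized
    rng = np.random.default_rng(1)
    random_set = list(rng.choice(np.asarray(norm.genes), 30, replace=False))
    s1 = scoring.pathway_score(norm.values, norm.genes, random_set, seed=3)
    s2 = scoring.pathway_score(norm.values, norm.genes, random_set, seed=3)
    np.testing.assert_array_equal(s1, s2)

    # gene sets drawn from the control pool score ~0 on average; the Monte
    # Carlo unit is the gene-set draw, not the cell
    set_means = []
    for trial in range(15):
        s = list(rng.choice(np.asarray(norm.genes), 30, replace=False))
        set_means.append(
            scoring.pathway_score(norm.values, norm.genes, s, seed=trial).mean()
        )
    set_means = np.asarray(set_means)
    se = set_means.std(ddof=1) / np.sqrt(len(set_means))
    assert abs(set_means.mean()) < 3 * se + 1e-3


def test_pathway_score_separates_planted_tam_states(small_normalized):
    norm, meta = small_normalized
    anti_inflammatory = ["Mrc1", "Pf4", "Msr1", "Il10"]
    s = scoring.pathway_score(norm.values, norm.genes, anti_inflammatory, seed=0)
    c3 = s[(meta["cell_type"] == "TAM_C3").to_numpy()]
    c1 = s[(meta["cell_type"] == "TAM_C1").to_numpy()]
    assert stats.mannwhitneyu(c3, c1, alternative="greater").pvalue < 0.01


def test_pseudobulk_correlation_rule():
    rng = np.random.default_rng(0)
    n = 40
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    xc = x - x.mean()
    zc = z - z.mean()
    zc = zc - zc.dot(xc) / xc.dot(xc) * xc    # centered and orthogonal to x
    xs = xc / xc.std()
    zs = zc / zc.std()
    profiles = pd.DataFrame({
        "self": xs,
        "strong": 0.9 * xs + np.sqrt(1 - 0.81) * zs,
        "weak": 0.1 * xs + np.sqrt(1 - 0.01) * zs,
        "flat": np.ones(n),
    })
    with pytest.warns(UserWarning, match="zero-variance"):
        r, p, sig = scoring.pseudobulk_correlation(profiles)
    assert r.loc["self", "self"] == pytest.approx(1.0)
    assert sig.loc["self", "self"]                  # trivially significant
    assert sig.loc["self", "strong"] and p.loc["self", "strong"] < 0.05
    assert not sig.loc["self", "weak"]
    assert not sig.loc["self", "flat"]

    # closed-form p: r ~ 0.3 at n = 40 -> t ~ 1.939, two-sided p ~ 0.060 > 0.05
    r_val = 0.3
    t_val = r_val * np.sqrt(38) / np.sqrt(1 - r_val**2)
    p_val = 2 * stats.t.sf(t_val, df=38)
    assert t_val == pytest.approx(1.939, abs=5e-3)
    assert p_val == pytest.approx(0.060, abs=2e-3)
    # the significance rule is strict: r exactly at the threshold fails
    y = r_val * xs + np.sqrt(1 - r_val**2) * zs
    prof2 = pd.DataFrame({"x": xs, "y": y})
    r2, p2, sig2 = scoring.pseudobulk_correlation(prof2)
    assert r2.loc["x", "y"] == pytest.approx(0.3, abs=1e-12)
    assert not sig2.loc["x", "y"]

    with pytest.raises(ValueError, match="4 samples"):
        scoring.pseudobulk_correlation(profiles.iloc[:3])


def test_pseudobulk_profile_means_by_sample(small_normalized):
    norm, meta = small_normalized
    mac = meta["cell_type"].isin(["TAM_C1", "TAM_C3"]).to_numpy()
    prof = scoring.pseudobulk_profile(norm.values, norm.genes,
                                      meta["sample"].to_numpy(object),
                                      subset_mask=mac)
    assert len(prof) == meta["sample"].nunique()
    s = prof.index[0]
    cells = (meta["sample"] == s).to_numpy() & mac
    expected = np.asarray(norm.values[np.flatnonzero(cells)].mean(axis=0)).ravel()
    np.testing.assert_allclose(prof.loc[s].to_numpy(), expected, rtol=1e-5)
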