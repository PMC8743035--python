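"""PCA, NMF, distances, heatmaps, likelihood fit, bootstrap flagging."""

import numpy as np
import pandas as pd
import pytest

import apespectra as ap
from apespectra import catalog
from apespectra.compartments import ContextContent
from apespectra.normalize import RescaledRates
from apespectra.stats import (
    FOLD_RANGE_THRESHOLD,
    bootstrap_enrichment_test,
    build_spectrum_matrix,
    cluster_signatures,
    dnm_fit_test,
    heatmap_correlation,
    log_odds_heatmap,
    match_signatures,
    pairwise_distance_distributions,
    run_nmf,
    run_pca,
)


def spec(values, ident="x", comp=""):
    return ap.SpectrumVector(np.asarray(values, dtype=float), 3, "count",
                             {"id": ident, "compartment": comp})


def rates(values, comp="c", ref="r"):
    v = np.asarray(values, dtype=float)
    return RescaledRates(ref, comp, v, v / v.sum())


# ---------------------------------------------------------------- matrix/PCA


def test_build_matrix_shapes_and_unit_guard():
    one = build_spectrum_matrix([spec(np.ones(96))])
    assert one.shape == (1, 96)
    rows = [spec(np.ones(96), f"s{i}", c) for i in range(3) for c in ("a", "b")]
    assert build_spectrum_matrix(rows).shape == (6, 96)
    freq = spec(np.ones(96)).frequencies()
    with pytest.raises(ValueError):
        build_spectrum_matrix([spec(np.ones(96)), freq])


def test_pca_properties():
    rng = np.random.default_rng(0)
    X = rng.random((12, 96))
    X[:, 5] = 0.7  # zero-variance column must be dropped
    mat = pd.DataFrame(X, columns=list(catalog.classes(3)))
    res = run_pca(mat)
    assert catalog.classes(3)[5] in res.dropped_columns
    assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(np.diff(res.variance_fractions) <= 1e-12)
    # orthonormal loadings
    L = res.loadings.to_numpy()
    np.testing.assert_allclose(L @ L.T, np.eye(L.shape[0]), atol=1e-8)
    # reconstruction of the centered/scaled matrix
    Xk = X[:, np.array([c not in res.dropped_columns for c in mat.columns])]
    Z = (Xk - Xk.mean(0)) / Xk.std(0, ddof=1)
    np.testing.assert_allclose(res.scores.to_numpy() @ L, Z, atol=1e-8)
    # sign convention: largest-|entry| of each loading positive
    for row in L:
        assert row[np.argmax(np.abs(row))] > 0
    # duplicated rows -> identical scores
    dup = pd.DataFrame(np.vstack([X[0], X[0], X[1], X[2]]))
    r2 = run_pca(dup)
    np.testing.assert_allclose(r2.scores.iloc[0], r2.scores.iloc[1], atol=1e-10)
    with pytest.raises(ValueError):
        run_pca(mat.iloc[:1])


# ---------------------------------------------------------------- NMF


def test_nmf_exact_low_rank_and_k1():
    rng = np.random.default_rng(1)
    W = rng.random((10, 2))
    H = rng.random((2, 96))
    X = pd.DataFrame(W @ H)
    res = run_nmf(X, 2, restarts=8, rng=np.random.default_rng(2))
    recon = res.exposures.to_numpy() @ res.signatures.to_numpy()
    rel_err = np.linalg.norm(recon - X.to_numpy()) / np.linalg.norm(X.to_numpy())
    assert rel_err < 1e-6
    np.testing.assert_allclose(res.signatures.sum(axis=1), 1.0, atol=1e-9)
    # K=1: the single signature is the normalized column mass
    r1 = run_nmf(X, 1, restarts=4, rng=np.random.default_rng(3))
    col = X.to_numpy().sum(axis=0)
    cos = (r1.signatures.to_numpy()[0] @ col) / (
        np.linalg.norm(r1.signatures.to_numpy()[0]) * np.linalg.norm(col)
    )
    assert cos > 0.9999
    with pytest.raises(ValueError):
        run_nmf(-X, 2)


def test_match_signatures_greedy():
    truth = np.eye(3, 96)
    inferred = pd.DataFrame(truth[[2, 0, 1]])
    pairs = match_signatures(inferred, truth)
    assert sorted((t, i) for t, i, _ in pairs) == [(0, 1), (1, 2), (2, 0)]
    assert all(c == pytest.approx(1.0) for _, _, c in pairs)


def test_cluster_signatures_trivial_cases():
    base = np.zeros(96)
    base[0] = 1.0
    s1 = ap.stats.SignatureSet(pd.DataFrame([base, base]), pd.DataFrame(np.ones((2, 2))), 0.0)
    out = cluster_signatures([s1], n_clusters=1)
    assert out["cluster"].nunique() == 1
    orth = np.eye(3, 96)
    s2 = ap.stats.SignatureSet(pd.DataFrame(orth), pd.DataFrame(np.ones((3, 3))), 0.0)
    out2 = cluster_signatures([s2], distance_threshold=0.5)
    assert out2["cluster"].nunique() == 3


# ---------------------------------------------------------------- distances


def test_distance_counts_and_trivial():
    v = np.zeros(96)
    v[0] = 5
    group_of = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(7)}
    spectra = [spec(v * (1 + 0.01 * i), f"s{i}") for i in range(7)]
    within, between = pairwise_distance_distributions(spectra, group_of)
    assert len(within["g1"]) == 6  # C(4,2)
    assert len(within["g2"]) == 3  # C(3,2)
    assert len(between[("g1", "g2")]) == 12  # 4x3
    # identical frequency spectra -> zero distance everywhere
    same = [spec(v, f"s{i}") for i in range(7)]
    w2, b2 = pairwise_distance_distributions(same, group_of)
    assert np.allclose(np.concatenate([w2["g1"], w2["g2"], b2[("g1", "g2")]]), 0)
    # single-member group: empty within list, no error
    w3, _ = pairwise_distance_distributions(spectra[:5], {**group_of, "s4": "solo"})
    assert len(w3["solo"]) == 0


# ---------------------------------------------------------------- heatmaps


def test_log_odds_heatmap_identity_antisymmetry_arithmetic():
    v = np.full(96, 1.0)
    v2 = v.copy()
    v2[0] = 2.0
    r1, r2 = rates(v2, "late"), rates(v, "early")
    h = log_odds_heatmap(r1, r2)
    hr = log_odds_heatmap(r2, r1)
    np.testing.assert_allclose(h.values, -hr.values)
    same = log_odds_heatmap(r1, r1)
    assert np.allclose(same.values, 0)
    # 0.2 vs 0.1 -> ln 2
    a = np.array([0.2, 0.1] + [0.7 / 94] * 94)
    b = np.array([0.1, 0.2] + [0.7 / 94] * 94)
    ha = log_odds_heatmap(rates(a), rates(b))
    assert ha.values[0] == pytest.approx(np.log(2))
    # zero in one compartment: masked
    z = v.copy()
    z[3] = 0
    hz = log_odds_heatmap(rates(z), rates(v))
    assert np.isnan(hz.values[3])


def test_heatmap_correlation_hand_example():
    v1 = np.full(96, np.nan)
    v2 = np.full(96, np.nan)
    v1[:3] = [1.0, 2.0, 4.0]
    v2[:3] = [2.0, 3.0, 7.0]
    h1 = ap.stats.LogOddsHeatmap(v1, ("a", "b"))
    h2 = ap.stats.LogOddsHeatmap(v2, ("a", "b"))
    r, p = heatmap_correlation(h1, h2)
    # closed-form Pearson on the three points
    x, y = v1[:3], v2[:3]
    expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    assert r == pytest.approx(expected)
    assert heatmap_correlation(h1, h1)[0] == pytest.approx(1.0)
    neg = ap.stats.LogOddsHeatmap(-v1, ("a", "b"))
    assert heatmap_correlation(h1, neg)[0] == pytest.approx(-1.0)
    v3 = np.full(96, np.nan)
    v3[:2] = 1.0
    with pytest.raises(ValueError):
        heatmap_correlation(h1, ap.stats.LogOddsHeatmap(v3, ("a", "b")))


# ---------------------------------------------------------------- DNM fit


def test_dnm_fit_identical_spectra_and_zero_class_invariance():
    p = np.arange(1.0, 97.0)
    s1 = spec(p, "sp1")
    s2 = spec(p * 3, "sp2")  # same frequencies
    obs = np.zeros(96)
    obs[10] = 40
    res = dnm_fit_test(obs, {"sp1": s1, "sp2": s2})
    assert res.fold_range == pytest.approx(1.0)
    assert not res.significant
    assert res.threshold == FOLD_RANGE_THRESHOLD == 20.0
    # adding a class with zero observed count leaves likelihoods unchanged
    q = p.copy()
    q[50] = 1e-12
    res2 = dnm_fit_test(obs, {"sp1": spec(q, "sp1"), "sp2": s2})
    assert res2.log_likelihoods["sp2"] == pytest.approx(res.log_likelihoods["sp2"])
    # zero probability on an observed class -> -inf, flagged by infinite fold
    z = p.copy()
    z[10] = 0
    res3 = dnm_fit_test(obs, {"sp1": spec(z, "sp1"), "sp2": s2})
    assert np.isinf(res3.fold_range) and res3.best_species == "sp2"
    with pytest.raises(ValueError):
        dnm_fit_test(obs, {"sp1": s1})


# ---------------------------------------------------------------- bootstrap


def test_bootstrap_enrichment_null_size_and_trivial_center():
    rng = np.random.default_rng(4)
    base = rng.integers(50, 150, size=96).astype(float)
    content = ContextContent(3, np.full(32, 1000), "bg")
    target = spec(base, "t", "bg")
    reps = [spec(rng.poisson(base).astype(float), f"r{i}") for i in range(100)]
    res = bootstrap_enrichment_test(
        target, spec(base, "b", "bg"), content, content, 5, reps,
        [content] * 100, rng, n_boot_ci=200,
    )
    assert len(res.null_values) == 100
    # target equals background: observed log odds exactly 0, inside null
    assert res.observed == pytest.approx(0.0)
    assert not res.outside_null
    assert res.ci_low <= 0 <= res.ci_high
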