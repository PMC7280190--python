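"""Community statistics: diversity, ordination, PERMANOVA, differential tests."""

import numpy as np
import pandas as pd
import pytest

from amf_otufree.abundance import AbundanceTable
from amf_otufree.stats import (
    DistanceMatrix,
    alpha_group_test,
    bh_adjust,
    bray_curtis,
    bray_curtis_matrix,
    lda_effect_size,
    observed_richness,
    pcoa,
    per_taxon_wilcoxon,
    permanova,
    shannon,
    simpson,
)

from _oracles import exact_rank_sum_two_sided_p


def _table(matrix, soils, times=None, taxa=None):
    matrix = np.asarray(matrix)
    samples = [f"S{i}" for i in range(matrix.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(matrix.shape[1])]
    counts = pd.DataFrame(matrix, index=samples, columns=taxa)
    meta = pd.DataFrame(
        {
            "soil": soils,
            "time": times or ["1S"] * len(samples),
            "replicate": list(range(1, len(samples) + 1)),
        },
        index=samples,
    )
    return AbundanceTable(counts, meta)


# -- alpha diversity ---------------------------------------------------------


def test_single_taxon_diversity():
    assert observed_richness([7]) == 1
    assert shannon([7]) == 0.0
    assert simpson([7]) == 0.0


def test_uniform_community_closed_forms():
    for k in (2, 5, 11):
        counts = [10] * k
        assert shannon(counts) == pytest.approx(np.log(k))
        assert simpson(counts) == pytest.approx(1 - 1 / k)
        assert observed_richness(counts) == k


def test_shannon_hand_computed_value():
    # counts [1,1,2]: H = -(2*0.25 ln 0.25 + 0.5 ln 0.5) = 1.0397
    assert shannon([1, 1, 2]) == pytest.approx(1.0397, abs=5e-5)


def test_diversity_inequalities_hold_on_random_communities(rng):
    for _ in range(50):
        counts = rng.integers(0, 100, size=rng.integers(2, 15))
        if counts.sum() == 0:
            continue
        s = observed_richness(counts)
        assert shannon(counts) <= np.log(s) + 1e-12
        assert simpson(counts) <= 1 - 1 / s + 1e-12


def test_diversity_rejects_all_zero():
    for fn in (observed_richness, shannon, simpson):
        with pytest.raises(ValueError):
            fn([0, 0])


def test_simpson_and_shannon_variants():
    assert simpson([5, 5], variant="inverse") == pytest.approx(2.0)
    assert shannon([5, 5], base=2) == pytest.approx(1.0)


def test_alpha_group_test_degenerate_and_separated(rng):
    identical = np.ones(8)
    groups = np.repeat(["a", "b"], 4)
    assert alpha_group_test(identical, groups) == (0.0, 1.0)
    sep = np.concatenate([rng.normal(0, 1, 5), rng.normal(10, 1, 5)])
    _, p = alpha_group_test(sep, np.repeat(["a", "b"], 5))
    assert p < 0.05
    _, p_anova = alpha_group_test(sep, np.repeat(["a", "b"], 5), method="anova")
    assert p_anova < 0.05
    with pytest.raises(ValueError):
        alpha_group_test(np.ones(4), ["a", "a", "a", "a"])
    with pytest.raises(ValueError):
        alpha_group_test(np.ones(4), ["a", "a", "a", "b"])


# -- beta diversity ----------------------------------------------------------


def test_bray_curtis_values_and_properties(rng):
    assert bray_curtis([2, 1], [2, 1]) == 0.0
    assert bray_curtis([5, 0], [0, 3]) == 1.0
    assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)
    x, y = rng.integers(0, 50, 20), rng.integers(0, 50, 20)
    assert bray_curtis(x, y) == bray_curtis(y, x)
    assert 0.0 <= bray_curtis(x, y) <= 1.0
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(np.array([[0, 1], [2, 0]]), ["a", "b"])
    with pytest.raises(ValueError):
        DistanceMatrix(np.array([[1.0]]), ["a"])


def test_pcoa_equilateral_triangle():
    D = np.ones((3, 3)) - np.eye(3)
    res = pcoa(DistanceMatrix(D, list("abc")))
    X = res.coordinates.to_numpy()
    d = [np.linalg.norm(X[i] - X[j]) for i, j in ((0, 1), (0, 2), (1, 2))]
    assert np.allclose(d, d[0])


def test_pcoa_recovers_euclidean_configuration(rng):
    pts = rng.normal(size=(6, 2))
    D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    res = pcoa(DistanceMatrix(D, [f"s{i}" for i in range(6)]))
    X = res.coordinates.to_numpy()[:, :2]
    D2 = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    assert np.allclose(D, D2, atol=1e-8)
    assert res.proportion_explained.sum() == pytest.approx(1.0)


def test_pcoa_duplicate_samples_coincide():
    table = _table([[10, 0, 5], [10, 0, 5], [0, 10, 5]], soils=["Bs", "Bs", "Rs"])
    res = pcoa(bray_curtis_matrix(table))
    X = res.coordinates.to_numpy()
    assert np.allclose(X[0], X[1], atol=1e-10)


def test_pcoa_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    rng = np.random.default_rng(4)
    counts = rng.integers(0, 60, size=(7, 12))
    table = _table(counts, soils=["Bs"] * 4 + ["Rs"] * 3)
    dm = bray_curtis_matrix(table)
    ours = pcoa(dm)
    theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(dm.data, dm.ids))
    n_pos = ours.coordinates.shape[1]
    ev_theirs = theirs.eigvals.to_numpy()[:n_pos]
    assert np.allclose(np.sort(ours.eigenvalues[:n_pos]), np.sort(ev_theirs), atol=1e-8)


def test_permanova_perfect_separation_and_identities(rng):
    a = rng.normal(0, 0.01, size=(5, 4)) + [10, 0, 0, 0]
    b = rng.normal(0, 0.01, size=(5, 4)) + [0, 10, 0, 0]
    X = np.abs(np.vstack([a, b]))
    table = _table(X, soils=["Bs"] * 5 + ["Rs"] * 5)
    dm = bray_curtis_matrix(table)
    res = permanova(dm, table.metadata["soil"].to_numpy(), n_perm=999, seed=3)
    # permutations recreating the same 5|5 partition (prob 2/252) tie with the
    # observed F and are counted by the ≥ rule, so the attainable minimum sits
    # just above 1/(1+n_perm)
    assert 1 / 1000 <= res.p_value < 0.03
    assert 0 <= res.r_squared <= 1
    res2 = permanova(dm, table.metadata["soil"].to_numpy(), n_perm=999, seed=3)
    assert res.f_statistic == res2.f_statistic and res.p_value == res2.p_value
    with pytest.raises(ValueError):
        permanova(dm, ["x"] * 10, n_perm=999)
    with pytest.raises(ValueError):
        permanova(dm, table.metadata["soil"].to_numpy(), n_perm=10)


def test_permanova_f_matches_skbio(rng):
    skbio = pytest.importorskip("skbio")
    counts = rng.integers(0, 80, size=(12, 15))
    labels = np.repeat(["a", "b", "c"], 4)
    table = _table(counts, soils=labels)
    dm = bray_curtis_matrix(table)
    ours = permanova(dm, labels, n_perm=99, seed=1)
    theirs = skbio.stats.distance.permanova(
        skbio.DistanceMatrix(dm.data, dm.ids), labels, permutations=99
    )
    assert ours.f_statistic == pytest.approx(float(theirs["test statistic"]), rel=1e-9)


# -- differential abundance --------------------------------------------------


def test_bh_adjustment_is_step_up():
    p = np.array([0.01, 0.04, 0.03, 0.5])
    adj = bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    assert (np.sort(adj) >= np.sort(p)).all()


def test_wilcoxon_identical_groups_p1_effect0():
    X = np.tile([5, 5, 5, 5, 5, 5], (3, 1)).T  # 6 samples, 3 taxa, all equal
    table = _table(X, soils=["Bs"] * 3 + ["Rs"] * 3)
    res = per_taxon_wilcoxon(table, "soil")
    assert all(r.p_raw == 1.0 and r.effect == 0.0 for r in res)


def test_wilcoxon_complete_separation_matches_enumeration():
    a, b = [0, 0, 0, 0, 0], [50, 60, 70, 80, 90]
    X = np.array(a + b)[:, None]
    table = _table(X, soils=["Bs"] * 5 + ["Rs"] * 5)
    res = per_taxon_wilcoxon(table, "soil")
    oracle_p = exact_rank_sum_two_sided_p(a, b)
    assert res[0].p_raw == pytest.approx(oracle_p)
    assert oracle_p == pytest.approx(2 / 252)
    assert res[0].effect == pytest.approx(np.log2(1 / 71))
    assert res[0].enriched == "Rs"


def test_wilcoxon_exact_p_agrees_with_enumeration_on_random_data(rng):
    for _ in range(5):
        a = rng.integers(0, 30, 5)
        b = rng.integers(0, 30, 5)
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        X = np.concatenate([a, b])[:, None]
        table = _table(X, soils=["Bs"] * 5 + ["Rs"] * 5)
        res = per_taxon_wilcoxon(table, "soil")
        # ties trigger scipy's untied exact distribution; compare only when untied
        if len(np.unique(np.concatenate([a, b]))) == 10:
            assert res[0].p_raw == pytest.approx(exact_rank_sum_two_sided_p(a, b))


def test_wilcoxon_requires_replicates():
    table = _table([[1], [2]], soils=["Bs", "Rs"])
    with pytest.raises(ValueError):
        per_taxon_wilcoxon(table, "soil")


def test_lefse_filters_flat_taxa_and_ranks_spiked_taxon_first(rng):
    # build the table directly on the relative-abundance scale (equal row
    # sums) so "flat" means flat after per-sample scaling too
    n = 20
    total = 1000.0
    X = np.zeros((n, 8))
    X[:, 0] = 100.0  # identical in every sample -> stage-1 filtered
    X[:10, 3] = 500.0  # spiked in Bs
    X[10:, 3] = 50.0
    rest = total - X[:, 0] - X[:, 3]
    fill = rng.dirichlet(np.ones(6), size=n) * rest[:, None]
    X[:, [1, 2, 4, 5, 6, 7]] = fill
    table = _table(np.rint(X), soils=["Bs"] * 10 + ["Rs"] * 10)
    res = lda_effect_size(table, "soil", seed=2)
    assert res, "spiked taxon should be reported"
    assert res[0].taxon == "t3"
    assert res[0].enriched == "Bs" and res[0].effect > 0
    assert all(r.taxon != "t0" for r in res)


def test_lefse_sign_tracks_enriched_class_in_simulation(rng):
    hits = 0
    runs = 20
    for run in range(runs):
        local = np.random.default_rng(300 + run)
        X = local.negative_binomial(5, 0.1, size=(20, 12)).astype(float) + 1
        enriched_class = "Bs" if run % 2 == 0 else "Rs"
        rows = slice(0, 10) if enriched_class == "Bs" else slice(10, 20)
        X[rows, 4] *= 6.0
        table = _table(X, soils=["Bs"] * 10 + ["Rs"] * 10)
        res = lda_effect_size(table, "soil", seed=run)
        found = {r.taxon: r for r in res}
        if "t4" in found and found["t4"].enriched == enriched_class:
            hits += 1
    assert hits >= int(0.8 * runs)


def test_lefse_requires_replicated_classes():
    table = _table([[1, 2], [3, 4]], soils=["Bs", "Rs"])
    with pytest.raises(ValueError):
        lda_effect_size(table, "soil")
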