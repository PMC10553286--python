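"""Tests of the gut-microbiota maturational markers."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import skbio

from eatrhythm.markers import (
    alpha_diversity,
    calinski_harabasz,
    enterotype,
    k_medoids,
    maturation_index,
    phylum_collapse,
    prediction_strength,
    unifrac_distance_matrix,
    weighted_unifrac,
)


def table(cols: dict, taxa=None) -> pd.DataFrame:
    taxa = taxa or [f"P|g{i}" for i in range(len(next(iter(cols.values()))))]
    return pd.DataFrame(cols, index=taxa)


# ---------------------------------------------------------------------------
# alpha diversity


def test_uniform_sample_closed_forms():
    res = alpha_diversity(table({"s": [10, 10, 10, 10]}))
    row = res.loc["s"]
    assert row.observed == 4
    assert row.shannon == pytest.approx(math.log(4), abs=1e-12)
    assert row.chao1 == pytest.approx(4.0)  # no singletons


def test_chao1_bias_corrected_with_singletons_no_doubletons():
    row = alpha_diversity(table({"s": [5, 1, 1]})).loc["s"]
    assert row.observed == 3
    # F1=2, F2=0: chao1 = 3 + 2*1/(2*1) = 4
    assert row.chao1 == pytest.approx(4.0)


def test_single_taxon_degenerate():
    row = alpha_diversity(table({"s": [42]}, taxa=["P|g"])).loc["s"]
    assert row.observed == 1 and row.shannon == pytest.approx(0.0)


def test_all_zero_sample_rejected():
    with pytest.raises(ValueError, match="all-zero"):
        alpha_diversity(table({"s": [0, 0]}))


def test_diversity_invariances(rng):
    counts = rng.integers(0, 50, size=12)
    counts[0] = 3
    t1 = table({"s": counts})
    perm = rng.permutation(12)
    t2 = pd.DataFrame({"s": counts[perm]}, index=[f"P|g{i}" for i in perm])
    r1, r2 = alpha_diversity(t1).loc["s"], alpha_diversity(t2).loc["s"]
    assert r1.shannon == pytest.approx(r2.shannon)
    assert r1.chao1 == pytest.approx(r2.chao1)
    # shannon invariant to rescaling of counts
    r3 = alpha_diversity(table({"s": counts * 10})).loc["s"]
    assert r3.shannon == pytest.approx(r1.shannon)
    # entropy bound and chao1 >= observed
    assert r1.shannon <= math.log(r1.observed) + 1e-12
    assert r1.chao1 >= r1.observed


# ---------------------------------------------------------------------------
# weighted UniFrac


def tree4():
    return skbio.TreeNode.read(["((a:1,b:2):1,(c:3,d:1):2);"])


def naive_weighted_unifrac(tree, pa, pb, taxa):
    """Brute-force branch enumeration of normalised weighted UniFrac."""
    pa = np.asarray(pa, float) / np.sum(pa)
    pb = np.asarray(pb, float) / np.sum(pb)
    frac = dict(zip(taxa, zip(pa, pb)))
    num = den = 0.0
    for node in tree.traverse(include_self=False):
        tips = [t.name for t in node.tips()] or [node.name]
        A = sum(frac[t][0] for t in tips if t in frac)
        B = sum(frac[t][1] for t in tips if t in frac)
        num += node.length * abs(A - B)
        den += node.length * (A + B)
    return num / den


def test_unifrac_identical_samples_is_zero():
    d = weighted_unifrac(tree4(), [5, 1, 2, 2], [5, 1, 2, 2], list("abcd"))
    assert d == pytest.approx(0.0, abs=1e-12)


def test_unifrac_disjoint_star_tree_is_one():
    # star metric written as a rooted topology with zero-length inner edges
    star = skbio.TreeNode.read(["((a:1,b:1):0.0,(c:1,d:1):0.0);"])
    d = weighted_unifrac(star, [3, 1, 0, 0], [0, 0, 2, 5], list("abcd"))
    assert d == pytest.approx(1.0, abs=1e-12)


def test_unifrac_matches_branch_enumeration_oracle():
    sa, sb = [2, 0, 1, 1], [0, 2, 0, 2]
    expected = naive_weighted_unifrac(tree4(), sa, sb, list("abcd"))
    assert weighted_unifrac(tree4(), sa, sb, list("abcd")) == pytest.approx(
        expected, abs=1e-10
    )


def test_unifrac_metric_properties(rng):
    counts = pd.DataFrame(
        rng.integers(0, 30, size=(4, 6)) + 1, index=list("abcd"),
        columns=[f"s{i}" for i in range(6)],
    )
    dm = unifrac_distance_matrix(counts, tree4()).data
    assert np.allclose(dm, dm.T)
    assert np.allclose(np.diag(dm), 0.0)
    for i, j, k in itertools.permutations(range(6), 3):
        assert dm[i, j] <= dm[i, k] + dm[k, j] + 1e-9


# ---------------------------------------------------------------------------
# clustering / enterotypes


def blob_distances(rng, n_per=6, sep=5.0):
    pts = np.concatenate(
        [rng.normal(0, 0.5, (n_per, 2)), rng.normal(sep, 0.5, (n_per, 2))]
    )
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    labels = np.repeat([0, 1], n_per)
    return d, labels


def test_kmedoids_recovers_separated_blobs(rng):
    d, truth = blob_distances(rng)
    _, labels = k_medoids(d, 2)
    same = (labels == truth).all() or (labels == 1 - truth).all()
    assert same


def test_ch_of_true_labels_is_optimal_over_all_bipartitions(rng):
    d, truth = blob_distances(rng, n_per=5)
    n = d.shape[0]
    best = -np.inf
    for bits in range(1, 2 ** (n - 1)):
        labels = np.array([(bits >> i) & 1 for i in range(n)])
        if labels.min() == labels.max():
            continue
        best = max(best, calinski_harabasz(d, labels))
    assert calinski_harabasz(d, truth) == pytest.approx(best)
    random_labels = rng.integers(0, 2, n)
    if random_labels.min() != random_labels.max():
        assert calinski_harabasz(d, truth) > calinski_harabasz(d, random_labels)


def test_equal_distances_are_non_separable():
    n = 8
    d = np.ones((n, n)) - np.eye(n)
    _, labels = k_medoids(d, 2)
    assert calinski_harabasz(d, labels) <= 1.0


def test_enterotype_labels_bifidobacterium_cluster_A(rng):
    d, truth = blob_distances(rng, n_per=6)
    ids = [f"s{i}" for i in range(12)]
    # first blob rich in Bifidobacterium
    bif = pd.Series(np.where(truth == 0, 0.6, 0.05) + rng.normal(0, 0.01, 12),
                    index=ids)
    res = enterotype(d, bif, sample_ids=ids, seed=0)
    assert (res.labels[truth == 0] == "A").all()
    assert (res.labels[truth == 1] == "B").all()
    assert res.separable
    assert res.prediction_strength > 0.8


def test_enterotype_invariant_to_sample_order(rng):
    d, truth = blob_distances(rng, n_per=5)
    ids = [f"s{i}" for i in range(10)]
    bif = pd.Series(np.where(truth == 0, 0.6, 0.05), index=ids)
    res = enterotype(d, bif, sample_ids=ids, seed=1)
    perm = rng.permutation(10)
    res_p = enterotype(d[np.ix_(perm, perm)], bif,
                       sample_ids=[ids[i] for i in perm], seed=1)
    for sid in ids:
        assert res.labels[sid] == res_p.labels[sid]


def test_asymmetric_matrix_rejected():
    d = np.array([[0, 1.0], [2.0, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        k_medoids(d, 1)


def test_prediction_strength_near_one_for_clean_blobs(rng):
    d, _ = blob_distances(rng, n_per=10)
    assert prediction_strength(d, 2, seed=3) > 0.9


# ---------------------------------------------------------------------------
# maturation index


def monotone_cohort(rng, n=150):
    """Taxa whose relative abundance moves linearly with age."""
    ages = rng.choice([3.0, 6.0, 12.0], size=n)
    cols = {}
    for i, age in enumerate(ages):
        up = age / 12.0
        base = np.array([up, up / 2, 1 - up, (1 - up) / 2, 0.5])
        base = np.clip(base + rng.normal(0, 0.05, 5), 0.01, None)
        cols[f"s{i}"] = rng.multinomial(5000, base / base.sum())
    counts = pd.DataFrame(cols, index=[f"P|g{j}" for j in range(5)])
    return counts, pd.Series(ages, index=counts.columns)


def test_maturation_index_learns_monotone_signal(rng):
    counts, ages = monotone_cohort(rng)
    res = maturation_index(counts, ages, n_trees=300, seed=0)
    rho = np.corrcoef(res.predicted_age, res.actual_age)[0, 1]
    assert rho > 0.8
    assert abs(res.maturation_index.mean()) < 0.5


def test_maturation_index_null_features_uninformative(rng):
    n = 150
    ages = pd.Series(rng.choice([3.0, 6.0, 12.0], size=n),
                     index=[f"s{i}" for i in range(n)])
    counts = pd.DataFrame(rng.integers(1, 100, size=(8, n)),
                          index=[f"P|g{j}" for j in range(8)],
                          columns=ages.index)
    res = maturation_index(counts, ages, n_trees=300, seed=0)
    rho = np.corrcoef(res.predicted_age, res.actual_age)[0, 1]
    assert abs(rho) < 0.25


def test_single_age_cohort_rejected(rng):
    counts = pd.DataFrame(rng.integers(1, 10, size=(3, 10)),
                          index=["P|a", "P|b", "P|c"],
                          columns=[f"s{i}" for i in range(10)])
    ages = pd.Series(3.0, index=counts.columns)
    with pytest.raises(ValueError, match="single age"):
        maturation_index(counts, ages)


# ---------------------------------------------------------------------------
# phylum collapse


def test_single_phylum_collapses_to_one():
    counts = table({"s": [3, 7]}, taxa=["Firmicutes|Blautia", "Firmicutes|Dorea"])
    rel = phylum_collapse(counts)
    assert rel.loc["s", "Firmicutes"] == pytest.approx(1.0)


def test_two_phyla_proportions():
    counts = table({"s": [30, 70]},
                   taxa=["Firmicutes|Blautia", "Bacteroidetes|Bacteroides"])
    rel = phylum_collapse(counts)
    assert rel.loc["s", "Firmicutes"] == pytest.approx(0.3)
    assert rel.loc["s", "Bacteroidetes"] == pytest.approx(0.7)
    assert rel.loc["s"].sum() == pytest.approx(1.0, abs=1e-9)


def test_unannotated_taxa_routed_to_other_with_warning():
    counts = table({"s": [5, 5]}, taxa=["Firmicutes|Blautia", "mystery"])
    with pytest.warns(UserWarning, match="other"):
        rel = phylum_collapse(counts)
    assert rel.loc["s", "other"] == pytest.approx(0.5)


def test_collapse_matches_simulator_phylum_mix():
    from eatrhythm.synthetic import (
        CohortConfig, simulate_diaries, simulate_microbiota, TAXA,
    )

    cfg = CohortConfig(n_subjects=150, seed=17)
    _, truth = simulate_diaries(cfg)
    counts, meta = simulate_microbiota(truth, cfg)
    rel = phylum_collapse(counts)
    # per-sample phylum means agree with the pooled count composition
    pooled = counts.sum(axis=1)
    phyla = pd.Index([t.split("|")[0] for t in counts.index])
    expected = pooled.groupby(
        np.where(phyla.isin(rel.columns[:-1]), phyla, "other")
    ).sum() / pooled.sum()
    mean_rel = rel.mean()
    for phylum in expected.index:
        assert mean_rel[phylum] == pytest.approx(expected[phylum], abs=0.05)
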