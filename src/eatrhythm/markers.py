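"""Maturational markers of the infant gut microbiota.

Three candidate mediators are computed from a taxa x samples count table:

* **alpha diversity** — Observed species (richness), Shannon entropy
  (natural log) and the bias-corrected Chao1 richness estimator;
* **bacterial maturation index** — a random-forest regression of
  chronological age on genus-level relative abundances; the index is the
  out-of-bag predicted age minus the actual age, so positive values mean
  a community more mature than expected for the infant's age;
* **enterotype** — a two-cluster partition (deterministic k-medoids,
  PAM BUILD+SWAP) of the weighted-UniFrac distance matrix, scored with
  the Calinski-Harabasz index and Tibshirani-Walther prediction
  strength, labelled A (Bifidobacterium-rich) or B (Bacteroides-rich).

Phylum-level relative abundances (Firmicutes, Bacteroidetes,
Actinobacteria, Proteobacteria, other) are also provided as exploratory
mediators.  Weighted UniFrac itself is delegated to scikit-bio
(normalised form: sum over branches of length x |A - B| divided by the
sum of length x (A + B)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio
from skbio.diversity import beta_diversity
from skbio.diversity.beta import weighted_unifrac as _skbio_weighted_unifrac
from sklearn.ensemble import RandomForestRegressor

from .io import check_tree_tips

__all__ = [
    "alpha_diversity",
    "weighted_unifrac",
    "unifrac_distance_matrix",
    "k_medoids",
    "calinski_harabasz",
    "prediction_strength",
    "enterotype",
    "EnterotypeAssignment",
    "maturation_index",
    "phylum_collapse",
    "marker_table",
    "CANONICAL_PHYLA",
]

CANONICAL_PHYLA = ["Firmicutes", "Bacteroidetes", "Actinobacteria", "Proteobacteria"]


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_diversity(counts: pd.DataFrame) -> pd.DataFrame:
    """Observed species, Shannon (nats) and bias-corrected Chao1 per sample.

    ``counts`` is taxa x samples.  Chao1 uses the bias-corrected form
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` (F1 singletons, F2
    doubletons), which stays defined when no doubletons are present.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("negative counts")
    totals = values.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[totals == 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    observed = (values > 0).sum(axis=0)
    p = values / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=0)
    f1 = (values == 1).sum(axis=0)
    f2 = (values == 2).sum(axis=0)
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return pd.DataFrame(
        dict(observed=observed, shannon=shannon, chao1=chao1),
        index=counts.columns,
    )


# ---------------------------------------------------------------------------
# weighted UniFrac


def weighted_unifrac(
    tree: skbio.TreeNode,
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    taxa: list[str],
) -> float:
    """Normalised weighted UniFrac distance between two samples, in [0, 1]."""
    check_tree_tips(tree, [t for t, c in zip(taxa, np.asarray(sample_a) + np.asarray(sample_b)) if c > 0])
    return float(
        _skbio_weighted_unifrac(sample_a, sample_b, taxa=taxa, tree=tree, normalized=True)
    )


def unifrac_distance_matrix(
    counts: pd.DataFrame, tree: skbio.TreeNode
) -> skbio.DistanceMatrix:
    """All-pairs normalised weighted UniFrac for a taxa x samples table."""
    check_tree_tips(tree, counts.index[counts.sum(axis=1) > 0].tolist())
    return beta_diversity(
        "weighted_unifrac",
        counts.T.to_numpy(),
        ids=counts.columns.tolist(),
        taxa=counts.index.tolist(),
        tree=tree,
        normalized=True,
    )


# ---------------------------------------------------------------------------
# clustering around a distance matrix


def k_medoids(dist: np.ndarray, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PAM (BUILD + SWAP) on a precomputed distance matrix.

    Returns ``(medoid_indices, labels)``.  BUILD greedily seeds medoids
    (ties towards the smaller index); SWAP applies the best improving
    medoid/non-medoid exchange until no swap lowers total cost, so the
    result does not depend on any random state.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if k >= n:
        raise ValueError("need more samples than clusters")

    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))

    def cost(meds: list[int]) -> float:
        return float(dist[:, meds].min(axis=1).sum())

    best = cost(medoids)
    improved = True
    while improved:
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best - 1e-12:
                    best, medoids, improved = c, trial, True
    medoids_arr = np.array(sorted(medoids))
    labels = np.argmin(dist[:, medoids_arr], axis=1)
    return medoids_arr, labels


def calinski_harabasz(dist: np.ndarray, labels: np.ndarray) -> float:
    """Distance-based Calinski-Harabasz (pseudo-F) index.

    Uses the identity that a cluster's within sum of squares equals the
    sum of squared pairwise distances divided by the cluster size, so no
    coordinates are needed.  Returns 0 for a structureless partition
    (zero between-cluster dispersion).
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = dist.shape[0]
    ks = np.unique(labels)
    k = ks.size
    if k < 2 or k >= n:
        raise ValueError("need 2 <= k < n clusters")
    sq = dist**2
    total = sq.sum() / (2.0 * n)
    within = 0.0
    for lab in ks:
        idx = np.flatnonzero(labels == lab)
        within += sq[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    between = max(total - within, 0.0)
    if within <= 1e-12:
        return float("inf") if between > 1e-12 else 0.0
    return float((between / (k - 1)) / (within / (n - k)))


def prediction_strength(dist: np.ndarray, k: int = 2, seed: int = 0) -> float:
    """Two-fold co-membership prediction strength of a k-clustering.

    The samples are split into two seeded folds.  Each fold is clustered
    on its own; the other fold's medoids then classify it by nearest
    medoid.  For every test cluster, the fraction of its sample pairs
    that the train-based rule keeps together is computed; the prediction
    strength is the worst cluster's fraction, averaged over the two fold
    directions.  1 = perfectly reproducible clustering, ~0.5 = chance
    for k=2.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if n < 2 * (k + 1):
        raise ValueError("too few samples for a two-fold split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [perm[: n // 2], perm[n // 2 :]]

    def one_direction(train: np.ndarray, test: np.ndarray) -> float:
        train_medoids, _ = k_medoids(dist[np.ix_(train, train)], k)
        assigned = np.argmin(dist[np.ix_(test, train[train_medoids])], axis=1)
        _, test_labels = k_medoids(dist[np.ix_(test, test)], k)
        worst = 1.0
        for lab in np.unique(test_labels):
            members = np.flatnonzero(test_labels == lab)
            if members.size < 2:
                continue
            same = assigned[members][:, None] == assigned[members][None, :]
            n_pairs = members.size * (members.size - 1) / 2
            agree = (np.triu(same, 1).sum()) / n_pairs
            worst = min(worst, float(agree))
        return worst

    return 0.5 * (one_direction(folds[0], folds[1]) + one_direction(folds[1], folds[0]))


@dataclass
class EnterotypeAssignment:
    """Two-cluster enterotype partition of a cohort of stool samples."""

    labels: pd.Series  # 'A' (Bifidobacterium-rich) or 'B' (Bacteroides-rich)
    ch_index: float
    prediction_strength: float
    separable: bool
    medoid_samples: list[str] = field(default_factory=list)


def enterotype(
    distances: skbio.DistanceMatrix | np.ndarray,
    bifidobacterium_abundance: pd.Series,
    sample_ids: list[str] | None = None,
    seed: int = 0,
) -> EnterotypeAssignment:
    """Cluster samples into the two canonical infant enterotypes.

    ``distances`` is the weighted-UniFrac matrix; the cluster whose
    members carry the higher mean Bifidobacterium relative abundance is
    labelled A, the other B.  A near-zero Calinski-Harabasz index marks
    the partition as non-separable (prediction strength then hovers at
    chance level).
    """
    if isinstance(distances, skbio.DistanceMatrix):
        ids = list(distances.ids)
        dist = distances.data
    else:
        dist = np.asarray(distances, dtype=float)
        if sample_ids is None:
            raise ValueError("sample_ids required with a bare array")
        ids = list(sample_ids)
    if dist.shape[0] < 4:
        raise ValueError("need at least 4 samples to enterotype")
    medoids, labels01 = k_medoids(dist, k=2)
    if len(np.unique(labels01)) < 2:
        raise ValueError("degenerate two-cluster solution")
    ch = calinski_harabasz(dist, labels01)
    ps = prediction_strength(dist, k=2, seed=seed)
    bif = bifidobacterium_abundance.reindex(ids).to_numpy(dtype=float)
    mean0 = bif[labels01 == 0].mean()
    mean1 = bif[labels01 == 1].mean()
    name_of = {0: "A", 1: "B"} if mean0 >= mean1 else {0: "B", 1: "A"}
    labels = pd.Series([name_of[int(l)] for l in labels01], index=ids, name="enterotype")
    return EnterotypeAssignment(
        labels=labels,
        ch_index=ch,
        prediction_strength=ps,
        separable=ch > 1.0,
        medoid_samples=[ids[m] for m in medoids],
    )


# ---------------------------------------------------------------------------
# maturation index


def maturation_index(
    counts: pd.DataFrame,
    ages: pd.Series,
    n_trees: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Microbiota-for-age index from an out-of-bag random forest.

    Regresses chronological age (months) on genus-level relative
    abundances.  Predictions for the training samples are out-of-bag, so
    the index — predicted minus actual age — is not inflated by
    memorisation; its mean over the training distribution is ~0 by
    construction.
    """
    ages = ages.reindex(counts.columns)
    if ages.isna().any():
        raise ValueError("every sample needs an age")
    if ages.nunique() < 2:
        raise ValueError("cohort spans a single age; nothing to learn")
    genus = counts.copy()
    genus.index = [t.split("|")[-1] for t in counts.index]
    genus = genus.groupby(level=0).sum()
    rel = genus / genus.sum(axis=0)
    X = rel.T.to_numpy()
    y = ages.to_numpy(dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny cohorts: some samples never OOB
        forest.fit(X, y)
    predicted = forest.oob_prediction_
    return pd.DataFrame(
        dict(
            actual_age=y,
            predicted_age=predicted,
            maturation_index=predicted - y,
        ),
        index=counts.columns,
    )


# ---------------------------------------------------------------------------
# phylum collapse


def phylum_collapse(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance of the four canonical phyla + other.

    Taxon labels are expected as ``Phylum|Genus``; anything without a
    recognised phylum annotation is routed to ``other`` with a warning.
    Rows sum to 1.
    """
    phylum = []
    unannotated = []
    for label in counts.index:
        p = label.split("|")[0] if "|" in label else ""
        if p in CANONICAL_PHYLA:
            phylum.append(p)
        else:
            if p == "":
                unannotated.append(label)
            phylum.append("other")
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} taxa without phylum annotation routed to 'other'"
        )
    grouped = counts.groupby(pd.Index(phylum, name="phylum")).sum()
    grouped = grouped.reindex(CANONICAL_PHYLA + ["other"], fill_value=0)
    rel = (grouped / grouped.sum(axis=0)).T
    rel.index.name = "sample_id"
    return rel


# ---------------------------------------------------------------------------
# one-stop marker table


def marker_table(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    tree: skbio.TreeNode,
    seed: int = 0,
    n_trees: int = 500,
) -> pd.DataFrame:
    """Join all markers into one per-sample table keyed by sample_id.

    Columns: observed, shannon, chao1, maturation_index, enterotype
    (0 = A, 1 = B) and the five phylum relative abundances.
    """
    meta = metadata.set_index("sample_id")
    alpha = alpha_diversity(counts)
    phyla = phylum_collapse(counts)
    dist = unifrac_distance_matrix(counts, tree)
    bif_rows = [t for t in counts.index if t.endswith("|Bifidobacterium")]
    bif = counts.loc[bif_rows].sum(axis=0) / counts.sum(axis=0)
    ent = enterotype(dist, bif, seed=seed)
    mat = maturation_index(counts, meta["age"], n_trees=n_trees, seed=seed)
    out = alpha.join(mat[["maturation_index"]]).join(phyla)
    out["enterotype"] = (ent.labels.reindex(out.index) == "B").astype(int)
    out["subject_id"] = meta["subject_id"]
    out["age"] = meta["age"]
    out.index.name = "sample_id"
    return out
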