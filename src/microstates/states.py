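"""Discrete community-state discovery and body-site representation.

Samples are clustered on their Bray-Curtis dissimilarities: k-means in
the full PCoA embedding (all positive-eigenvalue axes) by default, with
PAM (k-medoids on the dissimilarity matrix itself) as an alternative.
Cluster quality is judged by the mean silhouette computed on the original
dissimilarities, with the Calinski-Harabasz criterion (computed on the
embedding, which it requires) as tie-breaker for choosing k.  Clusters
are named after their dominant ASV's genus when the in-cluster mean
relative abundance of one ASV reaches a dominance threshold (e.g. "SC"
for a Staphylococcus-dominated state); otherwise they get an
intermediate/mixed "IC"-style label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from ._rng import substream
from .diversity import pcoa
from .tables import CountTable, extract_genus

__all__ = ["StateAssignment", "SiteRepresentation", "select_k", "assign_states",
           "site_representation", "label_agreement"]

#: minimum in-cluster mean relative abundance for naming a cluster after
#: its top ASV; clusters below it get an intermediate ("IC") label
DOMINANCE_THRESHOLD = 0.4


@dataclass
class StateAssignment:
    labels: pd.Series                 # sample -> state name
    silhouette: pd.Series             # per-sample silhouette on the BC matrix
    mean_silhouette: float
    calinski_harabasz: float
    k: int
    dominant_asv: dict[str, str | None]   # state -> dominant ASV (None if mixed)
    state_mean_abundance: pd.DataFrame | None = None


def _embed(d: DistanceMatrix) -> np.ndarray:
    coords = pcoa(d).coordinates.to_numpy()
    if coords.shape[1] == 0:
        raise ValueError("degenerate distance matrix: no positive PCoA axis")
    return coords


def _kmeans_labels(coords: np.ndarray, k: int, seed: int, n_init: int) -> np.ndarray:
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        random_state=int(substream(seed, "kmeans", k).integers(0, 2**31 - 1)),
    )
    return km.fit_predict(coords)


def _pam_labels(D: np.ndarray, k: int, seed: int, n_init: int) -> np.ndarray:
    """Basic PAM: random medoid init + greedy swap, best of n_init restarts."""
    n = D.shape[0]
    rng = substream(seed, "pam", k)
    best_cost, best_labels = np.inf, None
    for _ in range(max(1, n_init // 10)):
        medoids = rng.choice(n, size=k, replace=False)
        for _ in range(100):
            labels = D[:, medoids].argmin(axis=1)
            new_medoids = medoids.copy()
            for j in range(k):
                members = np.where(labels == j)[0]
                if members.size == 0:
                    new_medoids[j] = rng.integers(n)
                    continue
                within = D[np.ix_(members, members)].sum(axis=1)
                new_medoids[j] = members[within.argmin()]
            if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
                break
            medoids = new_medoids
        labels = D[:, medoids].argmin(axis=1)
        cost = D[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def _name_clusters(
    raw_labels: np.ndarray,
    table: CountTable | None,
    sample_ids: list[str],
    dominance_threshold: float,
) -> tuple[dict[int, str], dict[str, str | None], pd.DataFrame | None]:
    """Deterministic names: genus initial + 'C' for dominated clusters, 'IC'
    style for mixed ones; ties broken by cluster size then ASV id."""
    k = len(np.unique(raw_labels))
    if table is None:
        names = {c: f"S{c + 1}" for c in range(k)}
        return names, {v: None for v in names.values()}, None
    rel = table.relative_abundance().loc[sample_ids]
    mean_ab = rel.groupby(pd.Series(raw_labels, index=sample_ids)).mean()
    names: dict[int, str] = {}
    dominant: dict[str, str | None] = {}
    used: set[str] = set()
    for c in sorted(mean_ab.index):
        top_asv = mean_ab.loc[c].idxmax()
        top_mean = float(mean_ab.loc[c, top_asv])
        if top_mean >= dominance_threshold:
            genus = extract_genus(table.taxonomy[top_asv])
            base = (genus[0].upper() if genus and genus != "unclassified" else "X") + "C"
            dom = top_asv
        else:
            base, dom = "IC", None
        name = base
        suffix = 2
        while name in used:
            name = f"{base}{suffix}"
            suffix += 1
        used.add(name)
        names[c] = name
        dominant[name] = dom
    mean_ab.index = [names[c] for c in mean_ab.index]
    return names, dominant, mean_ab


def assign_states(
    d: DistanceMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 100,
    table: CountTable | None = None,
    method: str = "kmeans",
    dominance_threshold: float = DOMINANCE_THRESHOLD,
) -> StateAssignment:
    """Partition samples into ``k`` community states.

    Silhouettes are always computed on the original dissimilarity matrix;
    Calinski-Harabasz on the PCoA embedding.  Passing the count table
    enables dominance-based state naming.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(d.ids)
    D = np.asarray(d.data, dtype=float)
    coords = _embed(d)
    if method == "kmeans":
        raw = _kmeans_labels(coords, k, seed, n_init)
    elif method == "pam":
        raw = _pam_labels(D, k, seed, n_init)
    else:
        raise ValueError(f"unknown method {method!r}")
    if len(np.unique(raw)) < k:
        raise RuntimeError(f"clustering produced fewer than {k} non-empty clusters")
    sil = silhouette_samples(D, raw, metric="precomputed")
    ch = calinski_harabasz_score(coords, raw)
    names, dominant, mean_ab = _name_clusters(raw, table, ids, dominance_threshold)
    labels = pd.Series([names[c] for c in raw], index=ids, name="state")
    return StateAssignment(
        labels=labels,
        silhouette=pd.Series(sil, index=ids, name="silhouette"),
        mean_silhouette=float(sil.mean()),
        calinski_harabasz=float(ch),
        k=k,
        dominant_asv=dominant,
        state_mean_abundance=mean_ab,
    )


def select_k(
    d: DistanceMatrix,
    k_range=range(2, 9),
    seed: int = 0,
    n_init: int = 100,
    table: CountTable | None = None,
    method: str = "kmeans",
) -> tuple[int, pd.DataFrame]:
    """Choose k by mean-silhouette maximisation, Calinski-Harabasz tie-break.

    Returns the chosen k and the per-k score table.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("need at least 3 samples to choose k")
    if np.all(np.asarray(d.data) == 0):
        raise ValueError("all distances are zero; clustering is degenerate")
    rows = []
    for k in k_range:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, n-1]")
        a = assign_states(d, k, seed=seed, n_init=n_init, table=table, method=method)
        rows.append(
            {"k": k, "mean_silhouette": a.mean_silhouette,
             "calinski_harabasz": a.calinski_harabasz}
        )
    scores = pd.DataFrame(rows).set_index("k")
    best = scores.sort_values(
        ["mean_silhouette", "calinski_harabasz"], ascending=False
    ).index[0]
    return int(best), scores


def label_agreement(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Best-matching accuracy between two labelings of the same samples.

    Cluster names are arbitrary, so agreement is the maximum fraction of
    samples on which the labelings coincide over all one-to-one
    relabelings (Hungarian assignment on the confusion matrix).
    """
    from scipy.optimize import linear_sum_assignment

    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("labelings share no samples")
    confusion = pd.crosstab(labels_a.loc[common], labels_b.loc[common])
    cost = -confusion.to_numpy()
    rows, cols = linear_sum_assignment(cost)
    matched = -cost[rows, cols].sum()
    return float(matched / len(common))


@dataclass
class SiteRepresentation:
    """Per-state percentage distribution across body sites."""

    percentages: pd.DataFrame   # state x site, rows sum to 100
    deviation: pd.DataFrame     # percentage - 100/|sites|
    counts: pd.DataFrame


def site_representation(assignment: StateAssignment, meta: pd.DataFrame) -> SiteRepresentation:
    """How each community state distributes over body sites.

    Percentages are per state (rows sum to 100); deviation is against the
    uniform expectation of 100/|sites| per site.
    """
    meta_idx = meta.set_index("sample_id")
    sites = sorted(meta_idx["body_site"].unique())
    df = pd.DataFrame(
        {"state": assignment.labels, "body_site": meta_idx.loc[assignment.labels.index, "body_site"]}
    )
    counts = pd.crosstab(df["state"], df["body_site"]).reindex(columns=sites, fill_value=0)
    percentages = counts.div(counts.sum(axis=1), axis=0) * 100.0
    deviation = percentages - 100.0 / len(sites)
    return SiteRepresentation(percentages=percentages, deviation=deviation, counts=counts)
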