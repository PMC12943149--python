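"""Internal cluster-validity indices and Borda-count consensus over K.

All five indices are computed in DTW distance space, with medoids
standing in for centroids where the original (Euclidean) definition is
centroid-based:

* silhouette: mean of (b - a)/max(a, b); singletons contribute 0
* Dunn: min single-linkage inter-cluster distance / max cluster diameter
* Davies-Bouldin: mean over clusters of max_j (S_i + S_j) / M_ij with
  S = mean member-to-medoid distance, M = medoid-medoid distance
* modified Davies-Bouldin (DB*): max numerator over min denominator
* pseudo Calinski-Harabasz: [B/(K-1)] / [W/(n-K)] with squared
  member-to-medoid (W) and medoid-to-global-medoid (B) distances

Consensus: each index ranks the candidate Ks (1 = best, average ranks
on ties, undefined values take the worst rank); the K with the lowest
rank sum wins, ties broken toward the smaller K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from tdp.cluster import ClusterSolution, compute_medoids
from tdp.dtw import DistanceMatrix

INDEX_NAMES = ("silhouette", "dunn", "davies_bouldin", "modified_db", "calinski_harabasz")
#: True if larger values indicate a better clustering
HIGHER_BETTER = {"silhouette": True, "dunn": True, "davies_bouldin": False,
                 "modified_db": False, "calinski_harabasz": True}


@dataclass
class ValidityScores:
    K: int
    silhouette: float
    dunn: float
    davies_bouldin: float
    modified_db: float
    calinski_harabasz: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


def validity_indices(dist: DistanceMatrix, solution: ClusterSolution | np.ndarray) -> ValidityScores:
    """All five indices for one candidate clustering."""
    labels = solution.labels if isinstance(solution, ClusterSolution) else np.asarray(solution)
    D = dist.values
    n = D.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("validity indices need at least 2 non-empty clusters")
    members = {c: np.flatnonzero(labels == c) for c in uniq}

    # silhouette
    sil = np.zeros(n)
    for idx in range(n):
        c = labels[idx]
        own = members[c]
        if own.size <= 1:
            sil[idx] = 0.0
            continue
        a = D[idx, own].sum() / (own.size - 1)
        b = min(D[idx, members[o]].mean() for o in uniq if o != c)
        sil[idx] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    silhouette = float(sil.mean())

    # Dunn
    diameters = [D[np.ix_(m, m)].max() for m in members.values()]
    max_diam = max(diameters)
    if max_diam <= 0:
        raise ValueError("Dunn index undefined: all points identical")
    min_sep = min(D[np.ix_(members[a], members[b])].min()
                  for i, a in enumerate(uniq) for b in uniq[i + 1:])
    dunn = float(min_sep / max_diam)

    # medoid-based DB, DB*, pseudo-CH
    medoids = compute_medoids(dist, labels)
    S = np.array([D[members[c], medoids[i]].mean() for i, c in enumerate(uniq)])
    M = D[np.ix_(medoids, medoids)]
    db_terms, dbstar_terms = [], []
    for i in range(k):
        others = [j for j in range(k) if j != i]
        ratios = [(S[i] + S[j]) / M[i, j] if M[i, j] > 0 else math.inf for j in others]
        db_terms.append(max(ratios))
        num = max(S[i] + S[j] for j in others)
        den = min(M[i, j] for j in others)
        dbstar_terms.append(num / den if den > 0 else math.inf)
    db = float(np.mean(db_terms))
    dbstar = float(np.mean(dbstar_terms))

    W = sum(float((D[members[c], medoids[i]] ** 2).sum()) for i, c in enumerate(uniq))
    gmedoid = int(D.sum(axis=1).argmin())
    B = sum(members[c].size * float(D[medoids[i], gmedoid] ** 2) for i, c in enumerate(uniq))
    if W <= 0:
        ch = math.inf if B > 0 else math.nan
    else:
        ch = float((B / (k - 1)) / (W / (n - k)))

    K = solution.K if isinstance(solution, ClusterSolution) else k
    return ValidityScores(K=K, silhouette=silhouette, dunn=dunn,
                          davies_bouldin=db, modified_db=dbstar, calinski_harabasz=ch)


@dataclass
class ConsensusTable:
    table: pd.DataFrame  # index K; columns: index values, per-index ranks, aggregate
    selected_K: int

    def to_json(self) -> dict:
        return {"selected_K": int(self.selected_K),
                "aggregate": self.table["aggregate"].to_dict()}


def borda_consensus(scores: list[ValidityScores]) -> ConsensusTable:
    """Aggregate index rankings over candidate Ks by Borda count."""
    if len(scores) < 2:
        raise ValueError("need at least 2 candidate solutions")
    ks = [s.K for s in scores]
    if len(set(ks)) != len(ks):
        raise ValueError("duplicate candidate K")
    values = pd.DataFrame({name: [getattr(s, name) for s in scores] for name in INDEX_NAMES},
                          index=pd.Index(ks, name="K"))
    ranks = {}
    for name in INDEX_NAMES:
        v = values[name].to_numpy(dtype=float)
        key = -v if HIGHER_BETTER[name] else v.copy()
        key[np.isnan(v)] = np.inf  # undefined -> worst possible rank
        ranks[f"rank_{name}"] = rankdata(key, method="average")
    table = values.copy()
    for col, r in ranks.items():
        table[col] = r
    table["aggregate"] = np.sum(list(ranks.values()), axis=0)
    best = table["aggregate"].min()
    selected = min(k for k in ks if table.loc[k, "aggregate"] == best)
    return ConsensusTable(table=table, selected_K=int(selected))
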