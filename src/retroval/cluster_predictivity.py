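"""k-means clustering of project compounds and the cluster verdict.

A cluster is *predictive* when it contains at least one alpha compound and
strictly more gamma than beta compounds: the late-stage active chemistry
was already present at project start. It is *unpredictive* when alpha is
present but beta outnumbers gamma; everything else (no alpha, or a tie) is
*indeterminate*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .activity_scorer import feature_matrix
from .chem_io import MoleculeRecord

DEFAULT_K = 10


@dataclass(frozen=True)
class ClusterPredictivity:
    cluster_id: int
    n_alpha: int
    n_beta: int
    n_gamma: int
    verdict: str
    centroid_member_id: str
    top_active_id: str


def kmeans_clusters(
    labelled_dataset,
    k: int = DEFAULT_K,
    seed: int = 0,
    features: np.ndarray | None = None,
) -> np.ndarray:
    """Cluster compounds on ECFP6 bits with seeded k-means++.

    Returns integer labels 0..k-1 aligned with the dataset records.
    """
    n = len(labelled_dataset)
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    X = (
        features
        if features is not None
        else feature_matrix(
            [r.smiles_canonical for r in labelled_dataset.records]
        )
    )
    if np.allclose(X, X[0]):
        raise ValueError("degenerate feature matrix: all compounds identical")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(X)


def region_counts(
    cluster_labels: Sequence[int], region_labels: Sequence[str]
) -> dict[int, tuple[int, int, int]]:
    """Per-cluster (n_alpha, n_beta, n_gamma); region 'none' is not tallied."""
    if len(cluster_labels) != len(region_labels):
        raise ValueError("labels must be aligned")
    counts: dict[int, list[int]] = {}
    for cl, rg in zip(cluster_labels, region_labels):
        c = counts.setdefault(int(cl), [0, 0, 0])
        if rg == "alpha":
            c[0] += 1
        elif rg == "beta":
            c[1] += 1
        elif rg == "gamma":
            c[2] += 1
    return {k: tuple(v) for k, v in sorted(counts.items())}


def classify_cluster(n_alpha: int, n_beta: int, n_gamma: int) -> str:
    """Predictive / unpredictive / indeterminate verdict for one cluster."""
    if min(n_alpha, n_beta, n_gamma) < 0:
        raise ValueError("counts must be non-negative")
    if n_alpha > 0 and n_gamma > n_beta:
        return "predictive"
    if n_alpha > 0 and n_gamma < n_beta:
        return "unpredictive"
    return "indeterminate"


def representatives(
    members: Sequence[MoleculeRecord], features: np.ndarray
) -> tuple[MoleculeRecord, MoleculeRecord]:
    """(nearest-to-mean member, highest-pXC50 member) of a cluster.

    Ties go to the smallest source_row.
    """
    if len(members) == 0:
        raise ValueError("empty cluster")
    mean = features.mean(axis=0)
    dists = np.linalg.norm(features - mean, axis=1)
    centroid_i = min(
        range(len(members)), key=lambda i: (dists[i], members[i].source_row)
    )
    top_i = min(
        range(len(members)),
        key=lambda i: (-members[i].pxc50, members[i].source_row),
    )
    return members[centroid_i], members[top_i]


def analyze_clusters(
    labelled_dataset,
    k: int = DEFAULT_K,
    seed: int = 0,
    features: np.ndarray | None = None,
) -> list[ClusterPredictivity]:
    """Full cluster-predictivity table for a labelled dataset."""
    if features is None:
        features = feature_matrix(
            [r.smiles_canonical for r in labelled_dataset.records]
        )
    labels = kmeans_clusters(labelled_dataset, k=k, seed=seed, features=features)
    counts = region_counts(labels, labelled_dataset.region)
    results = []
    for cid in range(k):
        na, nb, ng = counts.get(cid, (0, 0, 0))
        mask = labels == cid
        members = [r for r, m in zip(labelled_dataset.records, mask) if m]
        cm, ta = representatives(members, features[mask])
        results.append(
            ClusterPredictivity(
                cluster_id=cid,
                n_alpha=na,
                n_beta=nb,
                n_gamma=ng,
                verdict=classify_cluster(na, nb, ng),
                centroid_member_id=cm.id,
                top_active_id=ta.id,
            )
        )
    return results


def predictivity_table(results: Sequence[ClusterPredictivity]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_alpha": r.n_alpha,
                "n_beta": r.n_beta,
                "n_gamma": r.n_gamma,
                "verdict": r.verdict,
                "centroid_member_id": r.centroid_member_id,
                "top_active_id": r.top_active_id,
            }
            for r in results
        ]
    )


def predictivity_summary(results: Sequence[ClusterPredictivity]) -> dict:
    verdicts = [r.verdict for r in results]
    return {
        "n_predictive": verdicts.count("predictive"),
        "n_unpredictive": verdicts.count("unpredictive"),
        "n_indeterminate": verdicts.count("indeterminate"),
    }
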