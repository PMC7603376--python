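"""Cluster-number selection, k-means subtyping and survival-ordered labels.

The cluster count is chosen by the mean silhouette coefficient over a
candidate range (Calinski-Harabasz breaks ties; the elbow/distortion curve
is reported for inspection only, since it requires human judgment). Cluster
labels are then re-ordered by Kaplan-Meier median survival so that higher
label = longer survival; with two clusters this makes subtype 1 the
longer-surviving group by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .io_preprocess import ClinicalTable
from .feature_selection import IntegrationMatrix
from .survival_stats import km_median


@dataclass
class KSelectionReport:
    k_values: list[int]
    distortion: dict[int, float]  # within-cluster sum of squares (inertia)
    calinski_harabasz: dict[int, float]
    silhouette: dict[int, float]
    chosen_k: int

    def to_json_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "distortion": self.distortion,
            "calinski_harabasz": self.calinski_harabasz,
            "silhouette": self.silhouette,
            "chosen_k": self.chosen_k,
        }


@dataclass
class SubtypeAssignment:
    """Survival-ordered subtype per sample.

    With K = 2, subtype 1 is the longer-surviving group (KM median; mean
    observed time breaks ties). ``provenance`` records whether labels come
    from clustering the common cohort or from a classifier's prediction.
    """

    labels: pd.Series  # index: sample ids, values: int subtype
    provenance: str = "clustered"  # or "predicted"
    probabilities: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("clustered", "predicted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def vector(self, sample_ids=None) -> np.ndarray:
        if sample_ids is None:
            return self.labels.to_numpy(dtype=int)
        return self.labels.loc[list(sample_ids)].to_numpy(dtype=int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def counts(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.labels.value_counts().items()}

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"subtype": self.labels, "provenance": self.provenance}
        )
        df.to_csv(path, sep="\t", index_label="sample_id")


def fit_kmeans(matrix: IntegrationMatrix, k: int, seed: int = 0):
    """Seeded k-means (k-means++ init, 10 restarts, best inertia kept)."""
    n = matrix.shape[0]
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    labels = km.fit_predict(matrix.values.to_numpy(dtype=float))
    return labels, km.cluster_centers_, float(km.inertia_)


def k_selection(
    matrix: IntegrationMatrix, k_range=range(2, 11), seed: int = 0
) -> KSelectionReport:
    """Score every candidate K and choose by silhouette (CH breaks ties)."""
    ks = sorted(k_range)
    if ks[0] < 2:
        raise ValueError("silhouette is undefined at K = 1; k_range must start at 2")
    x = matrix.values.to_numpy(dtype=float)
    if x.shape[0] <= ks[-1]:
        raise ValueError("need more samples than the largest candidate K")
    dist, ch, sil = {}, {}, {}
    for k in ks:
        labels, _, inertia = fit_kmeans(matrix, k, seed=seed)
        dist[k] = inertia
        ch[k] = float(calinski_harabasz_score(x, labels))
        sil[k] = float(silhouette_score(x, labels))
    chosen = max(ks, key=lambda k: (sil[k], ch[k]))
    return KSelectionReport(
        k_values=ks, distortion=dist, calinski_harabasz=ch, silhouette=sil,
        chosen_k=chosen,
    )


def order_labels_by_survival(
    labels, sample_ids, clinical: ClinicalTable
) -> SubtypeAssignment:
    """Relabel clusters by ascending survival: subtype K-1 survives longest.

    Ordering is by KM median survival (undefined medians count as infinite);
    ties break by mean observed time. For K = 2 this realizes the contract
    that subtype 1 is the longer-surviving group.
    """
    labels = np.asarray(labels, dtype=int)
    sample_ids = list(sample_ids)
    clin = clinical.subset(sample_ids)
    times = clin.data["time_days"].to_numpy(dtype=float)
    events = clin.data["event"].to_numpy(dtype=int)
    uniq = np.unique(labels)
    keys = []
    for u in uniq:
        m = labels == u
        keys.append((km_median(times[m], events[m]), float(times[m].mean()), u))
    ranked = sorted(keys)  # ascending survival
    remap = {int(old): new for new, (_, _, old) in enumerate(ranked)}
    new_labels = np.array([remap[int(l)] for l in labels])
    return SubtypeAssignment(
        labels=pd.Series(new_labels, index=pd.Index(sample_ids, name="sample_id")),
        provenance="clustered",
    )


def tsne_embed(
    matrix: IntegrationMatrix, seed: int = 0, perplexity: float = 30.0
) -> np.ndarray:
    """2-D t-SNE embedding for visualization only (nothing downstream uses it)."""
    n = matrix.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs n > 3 * perplexity ({n} samples, perplexity {perplexity})"
        )
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(matrix.values.to_numpy(dtype=float))
    return np.asarray(emb)
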