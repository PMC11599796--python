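"""Behavioral-state discovery on pooled pose features.

K-means over the seven z-scored features partitions frames into recurring
two-animal configurations ("behavioral states"); a 2-D UMAP embedding is
provided for plotting only and never influences labels. Downstream
statistics quantify how states distribute over recordings and how they
are enriched in dyads of a given rank difference:

    enrichment(i, j) = n_ij / n_i. − n_.j / N

i.e., the share of rank-difference-``i`` frames falling in cluster ``j``
minus the cluster's overall share of frames. Rows sum to zero by
construction; positive values mean over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from domsuite.errors import ValidationError
from domsuite.pose_features import FeatureMatrix


@dataclass
class StateModel:
    """A fitted k-means state model in z-scored feature space."""

    k: int
    centroids: np.ndarray
    seed: int
    inertia: float

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        x = features.data.to_numpy()
        d = np.linalg.norm(x[:, None, :] - self.centroids[None, :, :], axis=2)
        return d.argmin(axis=1)


@dataclass
class StateAssignment:
    """Cluster labels with provenance and per-recording rank metadata.

    ``table`` columns: recording, frame, cluster, and (where rank metadata
    was supplied) rank_a, rank_b, rank_diff.
    """

    table: pd.DataFrame
    k: int


def fit_states(
    features: FeatureMatrix, k: int = 8, seed: int = 0, n_init: int = 10
) -> tuple[StateModel, np.ndarray]:
    """Fit k-means (k-means++ init, ``n_init`` restarts, fixed seed).

    Returns the model and the per-row labels. Deterministic for a fixed
    seed; cluster label order carries no meaning across seeds, so
    cross-run comparisons should use label-invariant scores.
    """
    n = len(features)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available rows")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    labels = km.fit_predict(features.data.to_numpy())
    model = StateModel(k=k, centroids=km.cluster_centers_, seed=seed, inertia=float(km.inertia_))
    return model, labels


def embed_2d(features: FeatureMatrix, seed: int = 42, **umap_kwargs) -> np.ndarray:
    """UMAP projection to 2-D for visualization only.

    Default parameters except the fixed ``random_state``. Cluster
    assignments never depend on this embedding.
    """
    if len(features) < 3:
        raise ValidationError("need at least 3 rows to embed")
    import umap  # deferred: numba compilation is slow at import

    reducer = umap.UMAP(n_components=2, random_state=seed, **umap_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return reducer.fit_transform(features.data.to_numpy())


def make_assignment(
    features: FeatureMatrix,
    labels: np.ndarray,
    rank_meta: pd.DataFrame | None = None,
) -> StateAssignment:
    """Join labels with provenance and optional per-recording rank metadata.

    ``rank_meta`` columns: recording, rank_a, rank_b (each animal's 1–4
    cage rank in the recording's dyad). Recordings absent from the
    metadata keep NaN rank columns and are excluded from enrichment.
    """
    table = features.provenance.copy()
    table["cluster"] = np.asarray(labels, dtype=int)
    if rank_meta is not None:
        meta = rank_meta.copy()
        meta["rank_diff"] = (meta["rank_a"] - meta["rank_b"]).abs()
        table = table.merge(meta, on="recording", how="left")
    return StateAssignment(table=table, k=int(table["cluster"].max()) + 1)


@dataclass
class EnrichmentTable:
    """Rank-difference × cluster percent-enrichment with audit marginals."""

    enrichment: pd.DataFrame  # index: rank_diff, columns: cluster
    counts: pd.DataFrame  # n_ij
    row_totals: pd.Series  # n_i.
    col_totals: pd.Series  # n_.j
    total: int  # N


def percent_enriched(assign: StateAssignment) -> EnrichmentTable:
    """Enrichment of each rank-difference stratum in each cluster.

    Frames without rank metadata are excluded. A stratum present in the
    metadata but with zero frames would be undefined; none can arise from
    the contingency construction (absent strata are simply not rows).
    """
    t = assign.table.dropna(subset=["rank_diff"]) if "rank_diff" in assign.table else None
    if t is None or t.empty:
        raise ValidationError("no frames carry rank metadata")
    counts = (
        t.assign(rank_diff=t["rank_diff"].astype(int))
        .groupby(["rank_diff", "cluster"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(assign.k), fill_value=0)
    )
    row_totals = counts.sum(axis=1)
    col_totals = counts.sum(axis=0)
    total = int(col_totals.sum())
    enrich = counts.div(row_totals, axis=0) - col_totals / total
    return EnrichmentTable(
        enrichment=enrich,
        counts=counts,
        row_totals=row_totals,
        col_totals=col_totals,
        total=total,
    )


def cluster_distribution(assign: StateAssignment) -> pd.DataFrame:
    """Per-recording fraction of frames in each cluster (rows sum to 1)."""
    counts = (
        assign.table.groupby(["recording", "cluster"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=range(assign.k), fill_value=0)
    )
    totals = counts.sum(axis=1)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"recordings with no labeled frames excluded: {empty}")
        counts = counts.drop(index=empty)
        totals = totals.drop(index=empty)
    return counts.div(totals, axis=0)


def sample_cluster_frames(
    assign: StateAssignment, n: int = 600, seed: int = 0
) -> dict[int, list[tuple[str, int]]]:
    """Uniformly sample up to ``n`` (recording, frame) pairs per cluster.

    Mirrors the construction of cluster exemplar videos: a human
    annotator watches the sampled frames to name each state. Sampling is
    without replacement and reproducible for a fixed seed; clusters with
    fewer than ``n`` frames return all of them.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: dict[int, list[tuple[str, int]]] = {}
    for c in range(assign.k):
        rows = assign.table[assign.table["cluster"] == c]
        if rows.empty:
            warnings.warn(f"cluster {c} is empty")
            out[c] = []
            continue
        take = min(n, len(rows))
        chosen = rows.iloc[rng.choice(len(rows), size=take, replace=False)]
        out[c] = list(zip(chosen["recording"], chosen["frame"].astype(int)))
    return out
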