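"""Variable-feature selection and hierarchical sample clustering.

The heatmap-style structure check: rank features by median absolute
deviation (MAD) across samples, keep the top N (500 by default), z-score
each selected feature, and cluster the samples hierarchically.  Distance
defaults to correlation with average linkage, the usual pairing for
expression heatmaps; both are configurable.  MAD ranking is deterministic
— ties break lexicographically on feature ID.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .data_model import DataError, ExpressionMatrix, log


def top_mad_features(m: ExpressionMatrix, n: int = 500) -> list[str]:
    """Top-n features by MAD = median(|x - median(x)|) across samples.

    Constant features have MAD 0 and rank last; ``n`` larger than the
    feature count returns every feature.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if m.data.isna().to_numpy().any():
        raise DataError("top_mad_features requires a complete-case matrix")
    med = m.data.median(axis=1)
    mad = (m.data.sub(med, axis=0)).abs().median(axis=1)
    ranked = mad.sort_index().sort_values(ascending=False, kind="stable")
    return ranked.index[: min(n, len(ranked))].tolist()


@dataclasses.dataclass
class ClusterResult:
    selected_features: list[str]
    linkage: np.ndarray          # scipy linkage matrix over samples
    sample_order: list[str]      # dendrogram leaf order
    cut_labels: dict[str, int]   # sample -> cluster id at the chosen k


def hierarchical_cluster(
    m: ExpressionMatrix,
    features: list[str],
    distance: str = "correlation",
    linkage: str = "average",
    k: int = 2,
) -> ClusterResult:
    """Cluster samples on the z-scored selected-feature submatrix.

    Zero-variance features are uninformative under either metric (and
    undefined under correlation) and are excluded with a warning.
    """
    if distance not in ("euclidean", "correlation"):
        raise DataError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete", "ward"):
        raise DataError(f"unknown linkage {linkage!r}")
    if m.n_samples < 2:
        raise DataError("need >= 2 samples to cluster")
    sub = m.data.loc[features]
    sd = sub.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        log.warning("excluding %d zero-variance feature(s) from clustering",
                    int(flat.sum()))
        sub = sub.loc[~flat]
        sd = sd[~flat]
    if sub.empty:
        raise DataError("no informative features left to cluster on")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    obs = z.to_numpy().T  # samples x features
    dist = pdist(obs, metric=distance)
    Z = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(Z)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    sample_ids = m.sample_ids
    return ClusterResult(
        selected_features=sub.index.tolist(),
        linkage=Z,
        sample_order=[sample_ids[i] for i in order],
        cut_labels={s: int(c) for s, c in zip(sample_ids, labels)},
    )


def write_cluster_result(res: ClusterResult, prefix) -> None:
    pd.Series(res.selected_features, name="feature_id").to_csv(
        f"{prefix}_features.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        res.linkage, columns=["left", "right", "height", "size"]
    ).to_csv(f"{prefix}_linkage.tsv", sep="\t", index=False)
    pd.Series(res.cut_labels, name="cluster").rename_axis("sample_id").to_csv(
        f"{prefix}_clusters.tsv", sep="\t"
    )
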