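"""Correlation-threshold (canopy-style) clustering and a k-means assist.

Contigs from one genome share an abundance profile across samples, so a
seed contig and every contig whose profile correlates with it above a
threshold form a candidate bin.  The clustering is a deterministic
single-pass canopy:

1. order unassigned contigs by the seed policy (default: descending mean
   abundance, ties by contig id);
2. take the first as seed; the candidate set is the seed plus every
   unassigned contig whose correlation with the *seed profile* reaches
   the threshold (membership is pinned to the seed, no centroid
   re-estimation);
3. commit the candidate set as a bin if it reaches the minimal cluster
   size, otherwise spend the seed (it stays eligible as a member of
   later bins);
4. repeat until no fresh seed remains; leftovers are ``unbinned``.

At least five variables are required — a profile over fewer samples gives
correlations too unstable to threshold.  Non-abundance variables (GC,
k-mer frequencies) may extend the profile; they are z-scored first so one
scale cannot dominate, while abundance columns enter raw (Pearson is
location/scale-free per pair).

k-means (scikit-learn, k-means++ initialisation, fixed seed) is provided
to enlarge or narrow selections during refinement, not as a primary
binner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .exceptions import BinrefError
from .features import FeatureMatrix
from .io import UNBINNED

#: Correlation clustering requires at least this many variables.
MIN_VARIABLES = 5


@dataclass
class ClusteringParams:
    """Parameters of correlation-threshold clustering.

    correlation_threshold
        Minimum correlation with the seed profile for membership,
        in (-1, 1].
    min_cluster_size
        Minimum candidate-set size (seed included) for a bin to commit.
    flavor
        "pearson" (default) or "spearman".
    seed_order
        "abundance" (descending mean profile value, ties by id) or "id".
    """

    correlation_threshold: float = 0.9
    min_cluster_size: int = 5
    flavor: str = "pearson"
    seed_order: str = "abundance"

    def __post_init__(self) -> None:
        if not (-1 < self.correlation_threshold <= 1):
            raise BinrefError("correlation_threshold must be in (-1, 1]")
        if self.min_cluster_size < 1:
            raise BinrefError("min_cluster_size must be >= 1")
        if self.flavor not in ("pearson", "spearman"):
            raise BinrefError(f"unknown correlation flavor: {self.flavor!r}")
        if self.seed_order not in ("abundance", "id"):
            raise BinrefError(f"unknown seed_order policy: {self.seed_order!r}")


def _profile_matrix(features: FeatureMatrix | pd.DataFrame) -> pd.DataFrame:
    """Profiles for correlation: abundance raw, other kinds z-scored."""
    if isinstance(features, pd.DataFrame):
        return features.astype(float)
    data = features.data.astype(float)
    out = {}
    for col in data.columns:
        vals = data[col]
        if features.kinds[col] == "abundance":
            out[col] = vals
        else:
            sd = vals.std(ddof=0)
            out[col] = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
    return pd.DataFrame(out, index=data.index)


def _seed_correlations(profiles: np.ndarray, seed_row: int) -> np.ndarray:
    """Pearson correlation of every row with one seed row.

    Rows with zero variance (constant profiles) get correlation 0 — they
    can only self-bin at min_cluster_size 1.
    """
    centered = profiles - profiles.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    seed = centered[seed_row]
    seed_norm = norms[seed_row]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (centered @ seed) / (norms * seed_norm)
    corr[~np.isfinite(corr)] = 0.0
    if seed_norm == 0:
        corr[:] = 0.0
    return corr


def correlation_cluster(
    features: FeatureMatrix | pd.DataFrame,
    params: ClusteringParams | None = None,
) -> pd.Series:
    """Single-pass seed clustering of contig profiles.

    Returns a contig-id-indexed label Series (``bin1``, ``bin2``, ... in
    commit order; leftovers ``unbinned``), suitable for
    :meth:`BinAssignmentTable.add_column`.  The result is a partition —
    no contig belongs to two bins — and is invariant to input row order.
    """
    params = params or ClusteringParams()
    profiles = _profile_matrix(features)
    n, p = profiles.shape
    if p < MIN_VARIABLES:
        raise BinrefError(
            f"correlation clustering requires at least {MIN_VARIABLES} "
            f"variables, got {p}"
        )
    if n < 1:
        raise BinrefError("no contigs to cluster")

    if params.seed_order == "abundance":
        order_key = pd.DataFrame(
            {"mean": -profiles.mean(axis=1), "id": profiles.index}
        )
        ordered_ids = list(order_key.sort_values(["mean", "id"])["id"])
    else:
        ordered_ids = sorted(profiles.index)
    profiles = profiles.loc[ordered_ids]
    X = profiles.to_numpy()
    if params.flavor == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    if (X.std(axis=1) == 0).any():
        warnings.warn(
            "constant contig profile(s): correlation defined as 0; such "
            "contigs can only self-bin at min_cluster_size 1",
            stacklevel=2,
        )

    labels = pd.Series(UNBINNED, index=pd.Index(ordered_ids), dtype=object)
    unassigned = np.ones(n, dtype=bool)
    seed_spent = np.zeros(n, dtype=bool)
    bin_no = 0
    while True:
        fresh = np.flatnonzero(unassigned & ~seed_spent)
        if fresh.size == 0:
            break
        seed = fresh[0]
        corr = _seed_correlations(X, seed)
        candidates = unassigned & (corr >= params.correlation_threshold)
        candidates[seed] = True
        if candidates.sum() >= params.min_cluster_size:
            bin_no += 1
            labels.iloc[np.flatnonzero(candidates)] = f"bin{bin_no}"
            unassigned &= ~candidates
        else:
            seed_spent[seed] = True
    if isinstance(features, FeatureMatrix):
        original_index = features.data.index
    else:
        original_index = features.index
    return labels.reindex(original_index)


def kmeans_cluster(
    features: FeatureMatrix | pd.DataFrame | Sequence[Sequence[float]],
    k: int,
    random_seed: int = 0,
) -> pd.Series:
    """k-means labels for a feature slice, reproducible for a fixed seed.

    Labels are renumbered by descending cluster size (``k1`` largest) with
    ties broken by first occurrence, so identical inputs and seed give
    identical label strings.
    """
    if isinstance(features, FeatureMatrix):
        data = features.data
    elif isinstance(features, pd.DataFrame):
        data = features
    else:
        data = pd.DataFrame(np.asarray(features, dtype=float))
    n = data.shape[0]
    if not 1 <= k <= n:
        raise BinrefError(f"k must be in 1..{n}, got {k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=random_seed)
    raw = km.fit_predict(data.to_numpy(dtype=float))
    sizes = np.bincount(raw, minlength=k)
    first_seen = np.full(k, n, dtype=int)
    for pos, lab in enumerate(raw):
        if first_seen[lab] == n:
            first_seen[lab] = pos
    rank = sorted(range(k), key=lambda lab: (-sizes[lab], first_seen[lab]))
    rename = {lab: f"k{i + 1}" for i, lab in enumerate(rank)}
    return pd.Series([rename[lab] for lab in raw], index=data.index, dtype=object)
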