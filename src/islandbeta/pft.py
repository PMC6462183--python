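"""Plant functional type classification by k-means on standardized traits.

Species are clustered on eight morpho-functional traits (maximal height,
leaf area, specific leaf area, leaf thickness, leaf dry-matter content,
chlorophyll content, twig dry-matter content, wood density).  Because
the traits span incommensurable units, each is z-scored before
clustering.  The number of types defaults to 4; cluster labels are
relabelled 1..k by descending cluster size (ties broken by the
lexicographically smallest member id) so that output labels are stable
and comparable across runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score


def standardize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score each trait column (population std, so a 2-row table maps to +/-1)."""
    if table.isna().any().any():
        raise ValueError("trait table contains missing cells")
    std = table.std(ddof=0)
    dead = std.index[std == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance trait(s): {dead}")
    return (table - table.mean()) / std


def _relabel_by_size(labels: np.ndarray, index: pd.Index, k: int) -> pd.Series:
    order = sorted(
        range(k),
        key=lambda c: (-(labels == c).sum(), min(index[labels == c])),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([remap[c] for c in labels], index=index, name="pft")


def kmeans_partition(
    table: pd.DataFrame,
    k: int = 4,
    n_init: int = 10,
    seed: int | None = None,
) -> pd.Series:
    """Best-of-n_init k-means partition of (already standardized) traits.

    Returns a species -> type assignment with labels 1..k ordered by
    descending cluster size.
    """
    if k > len(table):
        raise ValueError("k cannot exceed the number of species")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(table.to_numpy(dtype=float))
    if len(np.unique(labels)) < k:
        raise ValueError("k-means converged with an empty cluster")
    return _relabel_by_size(labels, table.index, k)


def classification_report(assignment: pd.Series, table: pd.DataFrame) -> pd.DataFrame:
    """Per-type member counts and trait centroids in original units."""
    missing = table.index.difference(assignment.index)
    if len(missing):
        raise ValueError(f"species without assignment: {list(missing)}")
    rep = table.groupby(assignment.loc[table.index]).mean()
    rep.insert(0, "n_species", table.groupby(assignment.loc[table.index]).size())
    rep.index.name = "pft"
    return rep


def silhouette(table: pd.DataFrame, assignment: pd.Series) -> float:
    """Mean silhouette width of the partition on standardized traits.

    Internal-consistency diagnostic for the chosen k (an external
    ordination check is out of scope here).
    """
    return float(
        silhouette_score(table.to_numpy(dtype=float), assignment.loc[table.index].to_numpy())
    )
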