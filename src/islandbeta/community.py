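"""Core data model for fragmented-island community analysis.

The central object is the community matrix: a pandas DataFrame of
non-negative integer abundances with islands as rows and species as
columns.  Presence is defined as count > 0; all dissimilarity metrics
downstream are presence/absence based, so the counts matter only for
richness and for the abundance weights of the null model.

Island attributes (area in ha, distance to nearest island DNI and
distance to mainland DM, both in m) live in a second DataFrame indexed
by island id.  The three binary island classifications (large/small,
isolated/clumped, far/near) are derived from fixed thresholds, with
boundary values falling in the <= class.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ATTRIBUTE_COLUMNS = ("area_ha", "dni_m", "dm_m")
GROUP_COLUMNS = ("size_class", "clumping_class", "distance_class")

#: grouping column -> (class if attribute > threshold, class if <= threshold)
GROUP_CLASSES = {
    "size_class": ("large", "small"),
    "clumping_class": ("isolated", "clumped"),
    "distance_class": ("far", "near"),
}


def _check_labels(labels, kind: str) -> None:
    dup = pd.Index(labels)[pd.Index(labels).duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate {kind} labels: {list(dup)}")


def validate_community(matrix: pd.DataFrame) -> pd.DataFrame:
    """Validate a community matrix: unique labels, non-negative integer cells."""
    _check_labels(matrix.index, "island")
    _check_labels(matrix.columns, "species")
    values = matrix.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValueError("community matrix has non-numeric cells")
    if values.size:
        bad = np.argwhere(~np.isfinite(values) | (values < 0) | (values != np.round(values)))
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"invalid abundance {values[i, j]!r} at island "
                f"{matrix.index[i]!r}, species {matrix.columns[j]!r} "
                "(cells must be non-negative integers)"
            )
    out = matrix.astype(np.int64)
    out.index.name = "island_id"
    return out


def read_community(path) -> pd.DataFrame:
    """Read an islands x species abundance CSV (first column = island ids)."""
    raw = pd.read_csv(path, index_col=0)
    return validate_community(raw)


def write_community(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="island_id")


def read_attributes(path) -> pd.DataFrame:
    attrs = pd.read_csv(path, index_col=0)
    missing = [c for c in ATTRIBUTE_COLUMNS if c not in attrs.columns]
    if missing:
        raise ValueError(f"attribute table missing columns: {missing}")
    _check_labels(attrs.index, "island")
    if (attrs["area_ha"] <= 0).any():
        raise ValueError("island areas must be positive")
    if (attrs[["dni_m", "dm_m"]] < 0).to_numpy().any():
        raise ValueError("distances must be non-negative")
    attrs.index.name = "island_id"
    return attrs[list(ATTRIBUTE_COLUMNS)]


def richness(matrix: pd.DataFrame) -> pd.Series:
    """Per-island species richness (alpha-diversity): number of species with count > 0."""
    return (matrix > 0).sum(axis=1).rename("richness")


def classify_islands(
    attrs: pd.DataFrame,
    area_cut_ha: float = 1.0,
    dni_cut_m: float = 50.0,
    dm_cut_m: float = 2000.0,
) -> pd.DataFrame:
    """Binary island groups from the three attribute thresholds.

    Strictly greater than the cut goes to large / isolated / far; equality
    falls in the small / clumped / near class.
    """
    for name, cut in (("area", area_cut_ha), ("dni", dni_cut_m), ("dm", dm_cut_m)):
        if cut <= 0:
            raise ValueError(f"{name} threshold must be positive, got {cut}")
    groups = pd.DataFrame(index=attrs.index)
    groups["size_class"] = np.where(attrs["area_ha"] > area_cut_ha, "large", "small")
    groups["clumping_class"] = np.where(attrs["dni_m"] > dni_cut_m, "isolated", "clumped")
    groups["distance_class"] = np.where(attrs["dm_m"] > dm_cut_m, "far", "near")
    return groups


def subset_by_pft(matrix: pd.DataFrame, assignment: pd.Series, pft) -> pd.DataFrame:
    """Restrict the community matrix to the species of one functional type.

    Islands are retained even when they hold no species of the type; empty
    islands make some pairwise metrics undefined and are handled downstream.
    """
    unassigned = matrix.columns.difference(assignment.index)
    if len(unassigned):
        raise ValueError(f"species without PFT assignment: {list(unassigned)}")
    if pft not in set(assignment.values):
        raise ValueError(f"unknown PFT label {pft!r}")
    members = assignment.index[assignment == pft]
    return matrix.loc[:, matrix.columns.intersection(members)]


def island_pairs(island_ids) -> list[tuple]:
    """All unordered island pairs with a < b in sorted label order."""
    return list(itertools.combinations(sorted(island_ids), 2))


def build_pair_table(
    matrix: pd.DataFrame,
    attrs: pd.DataFrame,
    beta_j: pd.DataFrame,
    beta_rc: pd.DataFrame,
    reduction: str = "difference",
) -> pd.DataFrame:
    """One row per unordered island pair: responses and pair-level predictors.

    Predictors reduce the two islands' attributes to a single number per
    pair.  The default is the absolute between-island difference (area on
    the log10 scale first); ``reduction="mean"`` uses the pair mean instead.
    """
    if reduction not in ("difference", "mean"):
        raise ValueError(f"unknown reduction {reduction!r}")
    ids = sorted(matrix.index)
    for name, other in (("attributes", attrs.index), ("beta_j", beta_j.index), ("beta_rc", beta_rc.index)):
        if set(other) != set(ids):
            raise ValueError(f"island ids of {name} do not match the community matrix")
    s = richness(matrix)
    log_area = np.log10(attrs["area_ha"])
    rows = []
    for a, b in itertools.combinations(ids, 2):
        if reduction == "difference":
            pa = abs(log_area[a] - log_area[b])
            pn = abs(attrs.at[a, "dni_m"] - attrs.at[b, "dni_m"])
            pm = abs(attrs.at[a, "dm_m"] - attrs.at[b, "dm_m"])
        else:
            pa = (log_area[a] + log_area[b]) / 2.0
            pn = (attrs.at[a, "dni_m"] + attrs.at[b, "dni_m"]) / 2.0
            pm = (attrs.at[a, "dm_m"] + attrs.at[b, "dm_m"]) / 2.0
        rows.append(
            {
                "island_a": a,
                "island_b": b,
                "delta_richness": abs(int(s[a]) - int(s[b])),
                "beta_j": beta_j.at[a, b],
                "beta_rc": beta_rc.at[a, b],
                "pred_area": pa,
                "pred_dni": pn,
                "pred_dm": pm,
            }
        )
    return pd.DataFrame(rows)


def pair_classes(pairs: pd.DataFrame, groups: pd.DataFrame, column: str) -> pd.Series:
    """Class label per pair; NaN when the two islands straddle classes."""
    ga = groups.loc[pairs["island_a"], column].to_numpy()
    gb = groups.loc[pairs["island_b"], column].to_numpy()
    return pd.Series(np.where(ga == gb, ga, None), index=pairs.index, name=column)


def group_summary(values: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Mean and t-based 95% confidence interval per class.

    ``values`` and ``classes`` are aligned; NaN classes (e.g. pairs that
    straddle two classes) and NaN values are excluded.  Classes with fewer
    than two values are flagged and get no interval.
    """
    df = pd.DataFrame({"value": values, "cls": classes}).dropna()
    out = []
    for cls, sub in df.groupby("cls", sort=True):
        v = sub["value"].to_numpy(dtype=float)
        row = {"class": cls, "n": len(v), "mean": v.mean(), "ci_low": np.nan, "ci_high": np.nan, "ci_omitted": True}
        if len(v) >= 2:
            sem = v.std(ddof=1) / np.sqrt(len(v))
            half = stats.t.ppf(0.975, len(v) - 1) * sem
            row.update(ci_low=v.mean() - half, ci_high=v.mean() + half, ci_omitted=False)
        else:
            logger.warning("class %r has %d value(s); confidence interval omitted", cls, len(v))
        out.append(row)
    return pd.DataFrame(out).set_index("class")
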