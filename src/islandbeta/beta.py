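"""Pairwise beta-diversity: Jaccard dissimilarity and the Raup-Crick metric.

Jaccard dissimilarity (beta_J) confounds two components: differences in
richness between islands and richness-independent species replacement.
The Raup-Crick metric (beta_RC) isolates the second component with a
null model that holds each island's richness fixed at its observed value
and draws species from the regional pool with probability proportional
to their observed abundance (an abundance-weighted richness-fixed
randomization).  Writing SS_obs for the observed number of shared
species of a pair and SS_null for a null draw,

    beta_RC = 2 * [ P(SS_null > SS_obs) + 0.5 * P(SS_null = SS_obs) ] - 1

so beta_RC lies in [-1, 1]: values near -1 mean the pair shares more
species than expected by chance (shared deterministic filters), values
near +1 mean fewer than chance (divergent filtering or dispersal
limitation), and values near 0 indicate stochastic assembly.

The Monte-Carlo estimator draws null assemblages by sequential weighted
sampling without replacement, implemented with exponential sort keys
(Efraimidis-Spirakis): species i receives key E_i / w_i with E_i ~
Exp(1), and the S smallest keys form the sample.  ``raup_crick_exact``
enumerates the same distribution exactly on pools of at most 10 species
and serves as an independent oracle.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd

from .community import group_summary, pair_classes

WEIGHT_MODES = ("abundance", "occurrence_frequency")


@dataclasses.dataclass(frozen=True)
class NullModelConfig:
    """Settings of the richness-fixed null model.

    n_reps : number of null draws per island (default 1,000).
    weight_mode : "abundance" weights species by their total count across
        the matrix; "occurrence_frequency" by the number of islands
        occupied (the classical r1 weighting).
    tie_weight : weight given to null draws that tie the observed shared
        count; 0.5 is standard Raup-Crick practice.
    """

    n_reps: int = 1000
    weight_mode: str = "abundance"
    seed: int | None = None
    tie_weight: float = 0.5

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.weight_mode not in WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {WEIGHT_MODES}")
        if not 0.0 <= self.tie_weight <= 1.0:
            raise ValueError("tie_weight must lie in [0, 1]")


def jaccard(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarity 1 - |intersection| / |union| on presence sets.

    Pairs whose union of presences is empty are undefined (NaN), as is the
    diagonal.
    """
    pres = (matrix.to_numpy() > 0).astype(np.int64)
    inter = (pres @ pres.T).astype(float)
    s = pres.sum(axis=1)
    union = s[:, None] + s[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.divide(inter, union, out=np.full_like(inter, np.nan), where=union > 0)
    np.fill_diagonal(d, np.nan)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _pool_weights(matrix: pd.DataFrame, weight_mode: str) -> pd.Series:
    counts = matrix.to_numpy()
    present = counts.sum(axis=0) > 0
    if weight_mode == "abundance":
        w = counts.sum(axis=0).astype(float)
    else:
        w = (counts > 0).sum(axis=0).astype(float)
    return pd.Series(w[present], index=matrix.columns[present])


def raup_crick(
    matrix: pd.DataFrame,
    cfg: NullModelConfig | None = None,
    *,
    pool_weights: pd.Series | None = None,
    chunk: int = 200,
) -> pd.DataFrame:
    """Monte-Carlo Raup-Crick dissimilarity for every island pair.

    The species pool is every species with a positive total count in
    ``matrix``; null richness per island equals observed richness.  All
    pairs share the per-replicate null assemblages, which leaves every
    pair's marginal null distribution unchanged and makes the matrix
    symmetric by construction.  Islands with zero species yield NaN.

    ``pool_weights`` overrides the within-matrix weights with externally
    supplied sampling weights (indexed by species id); species of the
    matrix missing from it are excluded from the pool.
    """
    cfg = cfg or NullModelConfig()
    if pool_weights is not None:
        keep = matrix.columns.intersection(pool_weights.index)
        weights = pool_weights.loc[keep].astype(float)
        if (weights <= 0).any():
            raise ValueError("pool weights must be strictly positive")
    else:
        weights = _pool_weights(matrix, cfg.weight_mode)
    pool = matrix[weights.index]
    pres = (pool.to_numpy() > 0).astype(np.int64)
    n_islands, pool_size = pres.shape
    s_obs = pres.sum(axis=1)
    ss_obs = pres @ pres.T

    rng = np.random.default_rng(cfg.seed)
    w = weights.to_numpy(dtype=float)
    gt = np.zeros((n_islands, n_islands), dtype=np.int64)
    eq = np.zeros((n_islands, n_islands), dtype=np.int64)
    take = np.arange(pool_size)[None, None, :] < s_obs[None, :, None]
    done = 0
    while done < cfg.n_reps:
        reps = min(chunk, cfg.n_reps - done)
        # exponential sort keys: smallest S_i keys = weighted sample w/o replacement
        keys = rng.exponential(size=(reps, n_islands, pool_size)) / w[None, None, :]
        order = np.argsort(keys, axis=2)
        null = np.zeros((reps, n_islands, pool_size), dtype=bool)
        np.put_along_axis(null, order, np.broadcast_to(take, order.shape), axis=2)
        nf = null.astype(np.float64)
        ss_null = np.rint(np.einsum("rik,rjk->rij", nf, nf)).astype(np.int64)
        gt += (ss_null > ss_obs[None]).sum(axis=0)
        eq += (ss_null == ss_obs[None]).sum(axis=0)
        done += reps

    rc = 2.0 * ((gt + cfg.tie_weight * eq) / cfg.n_reps) - 1.0
    rc[s_obs == 0, :] = np.nan
    rc[:, s_obs == 0] = np.nan
    np.fill_diagonal(rc, np.nan)
    return pd.DataFrame(rc, index=matrix.index, columns=matrix.index)


def _subset_distribution(weights: np.ndarray, s: int) -> dict[frozenset, float]:
    """P(drawing each size-s subset) under sequential weighted sampling w/o replacement."""
    n = len(weights)
    total = float(weights.sum())
    out: dict[frozenset, float] = {}
    for subset in itertools.combinations(range(n), s):
        p = 0.0
        for perm in itertools.permutations(subset):
            q = 1.0
            rem = total
            for i in perm:
                q *= weights[i] / rem
                rem -= weights[i]
            p += q
        out[frozenset(subset)] = p
    return out


def null_shared_distribution(pool_weights, s_a: int, s_b: int) -> np.ndarray:
    """Exact pmf of the null shared-species count for two independent draws.

    Enumeration is factorial in the pool size, so pools are capped at 10
    species.  Index k of the returned array is P(SS_null = k).
    """
    w = np.asarray(pool_weights, dtype=float)
    if len(w) > 10:
        raise ValueError("exact enumeration supports pools of at most 10 species")
    if np.any(w <= 0):
        raise ValueError("pool weights must be strictly positive")
    for s in (s_a, s_b):
        if not 0 < s <= len(w):
            raise ValueError("richness must lie in [1, pool size]")
    da = _subset_distribution(w, s_a)
    db = _subset_distribution(w, s_b)
    pmf = np.zeros(min(s_a, s_b) + 1)
    for sub_a, pa in da.items():
        for sub_b, pb in db.items():
            pmf[len(sub_a & sub_b)] += pa * pb
    return pmf


def raup_crick_exact(
    pool_weights, s_a: int, s_b: int, ss_obs: int, tie_weight: float = 0.5
) -> float:
    """Exact Raup-Crick value by full enumeration (test oracle, pool <= 10)."""
    pmf = null_shared_distribution(pool_weights, s_a, s_b)
    if not 0 <= ss_obs <= min(s_a, s_b):
        raise ValueError("observed shared count out of range")
    p_gt = float(pmf[ss_obs + 1 :].sum())
    p_eq = float(pmf[ss_obs])
    return 2.0 * (p_gt + tie_weight * p_eq) - 1.0


def pairwise_to_long(pairwise: pd.DataFrame, value_name: str = "value") -> pd.DataFrame:
    """Square symmetric matrix -> long form with one row per unordered pair."""
    ids = sorted(pairwise.index)
    rows = [
        {"island_a": a, "island_b": b, value_name: pairwise.at[a, b]}
        for a, b in itertools.combinations(ids, 2)
    ]
    return pd.DataFrame(rows)


def beta_summary(pairwise: pd.DataFrame, groups: pd.DataFrame, column: str) -> pd.DataFrame:
    """Per-class mean and 95% CI of a pairwise metric.

    A pair belongs to a class only when both islands share it; straddling
    pairs are excluded.
    """
    long = pairwise_to_long(pairwise)
    classes = pair_classes(long, groups, column)
    return group_summary(long["value"], classes)
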