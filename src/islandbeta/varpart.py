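"""Variation partitioning of beta_J between richness variation and turnover.

With one response variable per pair (beta_J), redundancy analysis
degenerates to multiple linear regression, so the partition is computed
from three coefficients of determination:

    a = R2(x1, x2) - R2(x2)      unique to richness variation |dS|
    c = R2(x1, x2) - R2(x1)      unique to spatial turnover beta_RC
    b = R2(x1) + R2(x2) - R2(x1, x2)   shared
    d = 1 - R2(x1, x2)           residual

Raw fractions sum to 100% by construction.  Adjusted fractions use the
Ezekiel correction 1 - (1 - R2) * (n - 1) / (n - p - 1) and may be
negative; they are reported as computed.  Pairwise observations are not
independent; as in the GLM stage this is ignored by design and noted in
the output metadata.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from . import beta as _beta
from .community import pair_classes, richness, subset_by_pft

logger = logging.getLogger(__name__)

MIN_PAIRS = 10


@dataclasses.dataclass
class VarpartResult:
    """Variance fractions (percent) for one stratum of island pairs."""

    stratum: str
    n_pairs: int
    raw: dict[str, float]       # keys a, b, c, d
    adjusted: dict[str, float]

    def as_row(self) -> dict:
        row = {"stratum": self.stratum, "n_pairs": self.n_pairs}
        row.update({f"raw_{k}": v for k, v in self.raw.items()})
        row.update({f"adj_{k}": v for k, v in self.adjusted.items()})
        return row


def _r2(y: np.ndarray, predictors: list[np.ndarray]) -> float:
    X = np.column_stack([np.ones(len(y)), *predictors])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - rss / tss if tss else 0.0


def _ezekiel(r2: float, n: int, p: int) -> float:
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def varpart2(response, x1, x2, stratum: str = "all") -> VarpartResult:
    """Two-set variation partitioning of a pairwise response.

    ``x1`` is the richness-variation predictor, ``x2`` the turnover
    predictor.  Rows with any NaN are removed pairwise-complete.
    """
    df = pd.DataFrame({"y": np.asarray(response, dtype=float),
                       "x1": np.asarray(x1, dtype=float),
                       "x2": np.asarray(x2, dtype=float)}).dropna()
    n = len(df)
    if n < MIN_PAIRS:
        raise ValueError(f"need at least {MIN_PAIRS} complete pairs, have {n}")
    for name in ("x1", "x2"):
        if df[name].nunique() == 1:
            warnings.warn(f"predictor {name} is constant; its unique fraction is 0", stacklevel=2)
    y = df["y"].to_numpy()
    r_both = _r2(y, [df["x1"].to_numpy(), df["x2"].to_numpy()])
    r_1 = _r2(y, [df["x1"].to_numpy()])
    r_2 = _r2(y, [df["x2"].to_numpy()])

    def fractions(rb: float, r1: float, r2: float) -> dict[str, float]:
        return {
            "a": 100.0 * (rb - r2),
            "b": 100.0 * (r1 + r2 - rb),
            "c": 100.0 * (rb - r1),
            "d": 100.0 * (1.0 - rb),
        }

    raw = fractions(r_both, r_1, r_2)
    adj = fractions(_ezekiel(r_both, n, 2), _ezekiel(r_1, n, 1), _ezekiel(r_2, n, 1))
    return VarpartResult(stratum=stratum, n_pairs=n, raw=raw, adjusted=adj)


def varpart_pairs(pairs: pd.DataFrame, stratum: str = "all") -> VarpartResult:
    """Partition beta_J on (delta_richness, beta_rc) for a pair table."""
    return varpart2(pairs["beta_j"], pairs["delta_richness"], pairs["beta_rc"], stratum)


def pft_pair_table(
    matrix: pd.DataFrame,
    attrs: pd.DataFrame,
    assignment: pd.Series,
    pft,
    null_cfg: _beta.NullModelConfig | None = None,
) -> pd.DataFrame:
    """Pair table recomputed on one functional type's species subset.

    beta_RC is re-pooled within the type (null weights from the subset
    matrix); islands holding no species of the type make their pairs
    undefined, which downstream stages drop.
    """
    from .community import build_pair_table  # local import to avoid cycle at module load

    sub = subset_by_pft(matrix, assignment, pft)
    empty = int((richness(sub) == 0).sum())
    if empty:
        logger.info("PFT %r: %d island(s) empty; their pairs are undefined", pft, empty)
    bj = _beta.jaccard(sub)
    brc = _beta.raup_crick(sub, null_cfg)
    return build_pair_table(sub, attrs, bj, brc)


def varpart_by_stratum(
    pairs: pd.DataFrame,
    groups: pd.DataFrame,
    matrix: pd.DataFrame,
    attrs: pd.DataFrame,
    assignment: pd.Series | None = None,
    null_cfg: _beta.NullModelConfig | None = None,
) -> list[VarpartResult]:
    """Partitions for the whole system, each island-group class, and each PFT.

    Group strata use only within-class pairs.  Strata with fewer than 10
    defined pairs are skipped with a log entry.
    """
    results = []
    results.append(varpart_pairs(pairs, "all"))
    for column in groups.columns:
        classes = pair_classes(pairs, groups, column)
        for cls in sorted(groups[column].unique()):
            sub = pairs[classes == cls]
            try:
                results.append(varpart_pairs(sub, f"{column}:{cls}"))
            except ValueError as exc:
                logger.warning("stratum %s:%s skipped: %s", column, cls, exc)
    if assignment is not None:
        for pft in sorted(set(assignment.values)):
            try:
                ptab = pft_pair_table(matrix, attrs, assignment, pft, null_cfg)
                results.append(varpart_pairs(ptab, f"pft:{pft}"))
            except ValueError as exc:
                logger.warning("stratum pft:%s skipped: %s", pft, exc)
    return results
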