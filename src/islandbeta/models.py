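"""Gaussian GLMs of pairwise diversity responses on island-pair attributes.

Each response (richness variation |dS|, Jaccard dissimilarity beta_J, or
Raup-Crick beta_RC) is modelled on three pair-level predictors — the
between-island contrast in log10 area, in distance to nearest island,
and in distance to mainland — their three two-way products and the
three-way product.  A Gaussian family with identity link makes the fit
ordinary least squares; results are reported GLM-style (estimate, SE,
Wald p, AIC, deviance explained).

Model selection is backward stepwise on AIC from the full model.  By
default the candidate moves respect marginality (an interaction can only
be dropped before its constituent main effects); ``hierarchy=False``
allows any term to be dropped, which can retain an interaction without
its main effects.

Pairwise observations are not independent (each island enters n-1
pairs).  The default Wald p-values ignore this, matching common
practice; ``mantel_pvalues`` offers an island-label permutation test for
honest inference.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

MAIN_EFFECTS = ("pred_area", "pred_dni", "pred_dm")

#: a model term is a sorted tuple of main-effect names; len > 1 => product term
Term = tuple[str, ...]

RESPONSES = ("delta_richness", "beta_rc", "beta_j")


def candidate_terms() -> list[Term]:
    """The 7 candidate terms: 3 main effects, 3 two-way and 1 three-way product."""
    terms: list[Term] = []
    for r in (1, 2, 3):
        terms.extend(tuple(c) for c in itertools.combinations(MAIN_EFFECTS, r))
    return terms


def term_label(term: Term) -> str:
    return " x ".join(t.removeprefix("pred_") for t in term)


def _column(pairs: pd.DataFrame, term: Term) -> np.ndarray:
    col = np.ones(len(pairs))
    for t in term:
        col = col * pairs[t].to_numpy(dtype=float)
    return col


def design_matrix(pairs: pd.DataFrame, terms: list[Term]) -> np.ndarray:
    cols = [np.ones(len(pairs))] + [_column(pairs, t) for t in terms]
    return np.column_stack(cols)


@dataclasses.dataclass
class GLMResult:
    """Fitted Gaussian GLM: one row per retained term plus the intercept."""

    response: str
    terms: list[Term]
    params: pd.Series        # estimates, index = ["intercept"] + term labels
    bse: pd.Series
    pvalues: pd.Series
    aic: float
    null_deviance: float     # total sum of squares
    resid_deviance: float    # residual sum of squares
    n_obs: int
    n_dropped: int           # rows lost to undefined responses

    @property
    def deviance_explained_pct(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return 100.0 * (1.0 - self.resid_deviance / self.null_deviance)


def _prepare(pairs: pd.DataFrame, response: str) -> tuple[pd.DataFrame, int]:
    needed = [response, *MAIN_EFFECTS]
    kept = pairs.dropna(subset=needed)
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("dropped %d pair(s) with undefined %s", dropped, response)
    return kept, dropped


def fit_gaussian_glm(pairs: pd.DataFrame, response: str, terms: list[Term] | None = None) -> GLMResult:
    """OLS fit (Gaussian family, identity link) of a pairwise response.

    ``terms=None`` fits the full 7-term candidate model; ``terms=[]`` the
    intercept-only model.
    """
    if terms is None:
        terms = candidate_terms()
    terms = [tuple(t) for t in terms]
    kept, dropped = _prepare(pairs, response)
    if len(kept) < 10:
        raise ValueError(f"need at least 10 defined pairs, have {len(kept)}")
    X = design_matrix(kept, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        for j, t in enumerate(terms, start=1):
            sub = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(term_label(t))
        raise ValueError(f"rank-deficient design; collinear term(s): {bad}")
    y = kept[response].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    names = ["intercept"] + [term_label(t) for t in terms]
    return GLMResult(
        response=response,
        terms=list(terms),
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        pvalues=pd.Series(fit.pvalues, index=names),
        aic=float(fit.aic),
        null_deviance=float(((y - y.mean()) ** 2).sum()),
        resid_deviance=float(fit.ssr),
        n_obs=len(kept),
        n_dropped=dropped,
    )


def _removable(terms: list[Term], hierarchy: bool) -> list[Term]:
    if not hierarchy:
        return list(terms)
    return [t for t in terms if not any(set(t) < set(u) for u in terms)]


def hierarchical_submodels(terms: list[Term] | None = None) -> list[tuple[Term, ...]]:
    """Every subset of the candidate terms that respects marginality."""
    terms = terms or candidate_terms()
    out = []
    for r in range(len(terms) + 1):
        for sub in itertools.combinations(terms, r):
            present = set(sub)
            if all(all(tuple(c) in present for k in range(1, len(t)) for c in itertools.combinations(t, k)) for t in sub):
                out.append(sub)
    return out


def backward_stepwise(
    pairs: pd.DataFrame,
    response: str,
    hierarchy: bool = True,
    start_terms: list[Term] | None = None,
) -> GLMResult:
    """Backward AIC selection from the full model.

    At each step the removable term whose deletion gives the lowest AIC
    is dropped, as long as some deletion lowers the AIC; AIC ties are
    broken by dropping the highest-order term, then lexicographically.
    """
    current = list(start_terms) if start_terms is not None else candidate_terms()
    best = fit_gaussian_glm(pairs, response, current)
    while current:
        moves = []
        for t in _removable(current, hierarchy):
            trial = [u for u in current if u != t]
            res = fit_gaussian_glm(pairs, response, trial)
            moves.append((res.aic, -len(t), term_label(t), t, res))
        moves.sort(key=lambda m: m[:3])
        if moves and moves[0][0] < best.aic:
            _, _, _, t, best = moves[0]
            current = [u for u in current if u != t]
        else:
            break
    return best


def deviance_by_term(result: GLMResult, pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-term percentage of the null deviance explained.

    Sequential shares add terms main-effects-first (then two-way, then
    three-way products, each in canonical order); each share is the drop
    in residual deviance when the term enters, as a percentage of the
    null deviance, so shares telescope to the model's total.  Drop-one
    shares (deviance increase when the term alone is removed) are
    reported alongside.
    """
    kept, _ = _prepare(pairs, result.response)
    y = kept[result.response].to_numpy(dtype=float)
    tss = float(((y - y.mean()) ** 2).sum())

    def rss(terms: list[Term]) -> float:
        X = design_matrix(kept, terms)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    ordered = sorted(result.terms, key=lambda t: (len(t), t))
    rows = []
    prev = rss([])
    for i, t in enumerate(ordered):
        cur = rss(ordered[: i + 1])
        seq = 100.0 * (prev - cur) / tss if tss else 0.0
        drop = 100.0 * (rss([u for u in result.terms if u != t]) - result.resid_deviance) / tss if tss else 0.0
        rows.append({"term": term_label(t), "sequential_pct": seq, "drop_one_pct": drop})
        prev = cur
    frame = pd.DataFrame(rows, columns=["term", "sequential_pct", "drop_one_pct"])
    return frame.set_index("term")


def mantel_pvalues(
    pairs: pd.DataFrame,
    result: GLMResult,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.Series:
    """Island-label permutation p-values for the retained coefficients.

    Island identities are permuted and pair responses re-mapped, which
    preserves the dependence structure of pairwise observations that the
    naive Wald test ignores.  Two-sided p with the observed statistic
    included in the reference set.
    """
    kept, _ = _prepare(pairs, result.response)
    islands = sorted(set(kept["island_a"]) | set(kept["island_b"]))
    lookup = {
        frozenset((a, b)): v
        for a, b, v in zip(kept["island_a"], kept["island_b"], kept[result.response])
    }
    X = design_matrix(kept, result.terms)
    XtX_inv_Xt = np.linalg.pinv(X)
    obs = np.abs(XtX_inv_Xt @ kept[result.response].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    exceed = np.ones_like(obs)  # count the observed permutation
    n_used = 1
    for _ in range(n_perm):
        perm = dict(zip(islands, rng.permutation(islands)))
        y_perm = np.array(
            [lookup[frozenset((perm[a], perm[b]))] for a, b in zip(kept["island_a"], kept["island_b"])]
        )
        stat = np.abs(XtX_inv_Xt @ y_perm)
        exceed += stat >= obs
        n_used += 1
    names = ["intercept"] + [term_label(t) for t in result.terms]
    return pd.Series(exceed / n_used, index=names, name="perm_p")
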