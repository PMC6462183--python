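"""Synthetic island metacommunities with known assembly processes.

The generator emulates a fragmented land-bridge island system: a set of
islands with log-uniform areas and two isolation axes (distance to the
nearest island, distance to mainland), a regional species pool with a
skewed species-abundance distribution, and island communities whose
richness follows a deterministic species-area rule S(A) = round(c * A^z)
while composition is assembled under one of four regimes:

``stochastic``
    species drawn purely in proportion to regional abundance — by design
    the same process as the Raup-Crick null model, so beta_RC is
    calibrated to 0 on these landscapes;
``shared_filter``
    every island applies the same Gaussian niche filter centred at 0.5,
    pushing communities to share more species than chance (beta_RC < 0);
``divergent_filter``
    each island filters around its own environment value (a function of
    log area plus noise), pushing composition apart (beta_RC > 0);
``dispersal_limited``
    species randomly fail to reach an island with probability
    (1 - exp(-decay_rate * DM)) scaled up with rarity, creating
    island-specific absences and divergent composition (beta_RC > 0).

Richness is deterministic given area so that the alpha channel (richness
variation) and the turnover channel can be manipulated independently —
the point of the downstream decomposition.  Abundances feed only the
null-model weights, never the presence/absence dissimilarity metrics
themselves, and are allocated so that each species' total count across
the landscape is proportional to its regional weight.  This keeps the
stochastic mode exactly equal to the abundance-weighted null model
(whose pool weights are the observed totals): a per-island multinomial
of a fixed total would amplify the abundance skew through the number of
occupied islands and systematically de-calibrate beta_RC.

A matching trait generator produces an 8-trait table with k latent
clusters a configurable number of standard deviations apart, used to
validate functional-type recovery.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

ASSEMBLY_MODES = ("stochastic", "shared_filter", "divergent_filter", "dispersal_limited")
SAD_SHAPES = ("lognormal", "logseries")

TRAIT_COLUMNS = (
    "max_height",
    "leaf_area",
    "specific_leaf_area",
    "leaf_thickness",
    "leaf_dry_matter",
    "chlorophyll",
    "twig_dry_matter",
    "wood_density",
)


def island_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"i{k:0{width}d}" for k in range(1, n + 1)]


def species_labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"sp{k:0{width}d}" for k in range(1, n + 1)]


@dataclasses.dataclass(frozen=True)
class SpeciesPool:
    """Regional pool: one weight and one niche position per species.

    Weights are relative regional abundances (sorted descending); niche
    positions in [0, 1] are used only by the filtering regimes.
    """

    species_ids: tuple
    regional_abundance: np.ndarray
    niche_position: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.regional_abundance, dtype=float)
        p = np.asarray(self.niche_position, dtype=float)
        if len(self.species_ids) != len(w) or len(w) != len(p):
            raise ValueError("pool fields must have equal length")
        if not np.all(w > 0) or not np.isfinite(w.sum()):
            raise ValueError("regional abundances must be strictly positive and finite")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("niche positions must lie in [0, 1]")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)


@dataclasses.dataclass
class AssemblyConfig:
    """Knobs of the synthetic assembly process.

    sar_c, sar_z : species-area rule S(A) = round(sar_c * A^sar_z), A in ha.
    sad_shape, sad_param : regional abundance distribution (lognormal
        sigma, or log-series parameter in (0, 1)).
    filter_strength : Gaussian niche-kernel precision for the two
        filtering regimes (dimensionless; 0 disables filtering).
    decay_rate : per-metre thinning rate of rare species with distance to
        mainland (dispersal_limited regime only).
    total_individuals : mean individuals per island; the landscape-wide
        total n_islands * total_individuals is split over species in
        proportion to their regional weights.
    """

    mode: str = "stochastic"
    n_islands: int = 29
    n_species: int = 76
    sar_c: float = 25.0
    sar_z: float = 0.25
    sad_shape: str = "lognormal"
    sad_param: float = 1.5
    filter_strength: float = 30.0
    decay_rate: float = 5e-4
    total_individuals: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ASSEMBLY_MODES:
            raise ValueError(f"mode must be one of {ASSEMBLY_MODES}, got {self.mode!r}")
        if self.sad_shape not in SAD_SHAPES:
            raise ValueError(f"sad_shape must be one of {SAD_SHAPES}")
        if self.n_islands < 2 or self.n_species < 2:
            raise ValueError("need at least 2 islands and 2 species")
        if self.sar_c <= 0 or not 0 < self.sar_z < 1:
            raise ValueError("sar_c must be positive and sar_z in (0, 1)")
        if self.filter_strength < 0 or self.decay_rate < 0:
            raise ValueError("filter_strength and decay_rate must be non-negative")


def _check_interval(name: str, interval, positive: bool) -> tuple[float, float]:
    try:
        lo, hi = float(interval[0]), float(interval[1])
    except (TypeError, ValueError, IndexError) as exc:
        raise ValueError(f"{name} must be a (low, high) pair") from exc
    if lo > hi:
        raise ValueError(f"{name} is not ordered: ({lo}, {hi})")
    if positive and lo <= 0:
        raise ValueError(f"{name} must be strictly positive")
    if not positive and lo < 0:
        raise ValueError(f"{name} must be non-negative")
    return lo, hi


def generate_island_attributes(
    n_islands: int = 29,
    area_range_ha=(0.25, 50.0),
    dni_range_m=(5.0, 80.0),
    dm_range_m=(500.0, 4000.0),
    seed: int | None = None,
) -> pd.DataFrame:
    """Island attribute table: log-uniform areas, uniform independent distances."""
    if n_islands < 2:
        raise ValueError("n_islands must be >= 2")
    a_lo, a_hi = _check_interval("area_range_ha", area_range_ha, positive=True)
    n_lo, n_hi = _check_interval("dni_range_m", dni_range_m, positive=False)
    m_lo, m_hi = _check_interval("dm_range_m", dm_range_m, positive=False)
    rng = np.random.default_rng(seed)
    attrs = pd.DataFrame(
        {
            "area_ha": np.exp(rng.uniform(np.log(a_lo), np.log(a_hi), n_islands)),
            "dni_m": rng.uniform(n_lo, n_hi, n_islands),
            "dm_m": rng.uniform(m_lo, m_hi, n_islands),
        },
        index=pd.Index(island_labels(n_islands), name="island_id"),
    )
    return attrs


def generate_species_pool(
    n_species: int = 76,
    sad_shape: str = "lognormal",
    sad_param: float = 1.5,
    seed: int | None = None,
) -> SpeciesPool:
    """Regional pool with a lognormal or log-series abundance distribution."""
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if sad_shape not in SAD_SHAPES:
        raise ValueError(f"unknown sad_shape {sad_shape!r}")
    rng = np.random.default_rng(seed)
    if sad_shape == "lognormal":
        if sad_param < 0:
            raise ValueError("lognormal sigma must be non-negative")
        weights = rng.lognormal(mean=0.0, sigma=sad_param, size=n_species)
    else:
        if not 0 < sad_param < 1:
            raise ValueError("log-series parameter must lie in (0, 1)")
        weights = stats.logser.rvs(sad_param, size=n_species, random_state=rng).astype(float)
    weights = np.sort(weights)[::-1]
    niche = rng.uniform(0.0, 1.0, n_species)
    return SpeciesPool(tuple(species_labels(n_species)), weights, niche)


def sar_richness(area_ha, sar_c: float, sar_z: float, n_species: int) -> np.ndarray:
    """Deterministic species-area richness, rounded and clipped to [1, pool size]."""
    s = np.rint(sar_c * np.asarray(area_ha, dtype=float) ** sar_z)
    return np.clip(s, 1, n_species).astype(int)


def _log_selection_weights(pool: SpeciesPool, attrs: pd.DataFrame, cfg: AssemblyConfig, rng) -> np.ndarray:
    """Log selection weight per (island, species); -inf marks excluded species."""
    n_i = len(attrs)
    logw = np.log(pool.regional_abundance)[None, :].repeat(n_i, axis=0)
    if cfg.mode == "stochastic":
        return logw
    if cfg.mode == "shared_filter":
        return logw - cfg.filter_strength * (pool.niche_position[None, :] - 0.5) ** 2
    if cfg.mode == "divergent_filter":
        la = np.log10(attrs["area_ha"].to_numpy())
        sd = la.std()
        z = (la - la.mean()) / sd if sd > 0 else np.zeros_like(la)
        env = 1.0 / (1.0 + np.exp(-(z + rng.normal(0.0, 0.5, n_i))))
        return logw - cfg.filter_strength * (pool.niche_position[None, :] - env[:, None]) ** 2
    # dispersal_limited: species randomly fail to reach far islands, the
    # rarer the species the more likely.  Thinning must also touch common
    # species: island-specific absences of high-weight species are what
    # drives compositions apart relative to the richness-fixed null --
    # excluding only rare species would make islands converge on the same
    # common set and invert the sign of beta_RC.
    rarity = pd.Series(pool.regional_abundance).rank(ascending=False, pct=True).to_numpy()
    p_far = 1.0 - np.exp(-cfg.decay_rate * attrs["dm_m"].to_numpy())
    p_drop = p_far[:, None] * (0.3 + 0.7 * rarity[None, :])
    dropped = rng.random((n_i, pool.n_species)) < p_drop
    out = logw.copy()
    out[dropped] = -np.inf
    return out


def assemble_communities(pool: SpeciesPool, attrs: pd.DataFrame, cfg: AssemblyConfig) -> pd.DataFrame:
    """Assemble one community per island under the configured regime.

    Richness follows the species-area rule exactly; species are drawn
    without replacement with probability proportional to regional
    abundance times the regime factor.  Counts are then allocated
    species by species: each species' landscape total is proportional to
    its regional weight, split over its occupied islands (one individual
    guaranteed per occurrence), so observed totals reproduce the
    regional abundance distribution.
    """
    if pool.n_species == 0:
        raise ValueError("species pool is empty")
    rng = np.random.default_rng(cfg.seed)
    s_target = sar_richness(attrs["area_ha"], cfg.sar_c, cfg.sar_z, pool.n_species)
    if s_target.min() < 1:
        raise ValueError("target richness fell to zero after clipping")
    logw = _log_selection_weights(pool, attrs, cfg, rng)
    presence = np.zeros((len(attrs), pool.n_species), dtype=bool)
    order_by_weight = np.argsort(-pool.regional_abundance, kind="stable")
    for i in range(len(attrs)):
        lw = logw[i]
        available = np.isfinite(lw)
        if available.sum() < s_target[i]:
            # re-admit excluded species in descending regional weight until feasible
            lw = lw.copy()
            for j in order_by_weight:
                if not available[j]:
                    available[j] = True
                    lw[j] = np.log(pool.regional_abundance[j])
                    if available.sum() >= s_target[i]:
                        break
        # exponential sort keys on the log scale: robust to extreme filter strengths
        keys = np.where(available, np.log(rng.exponential(size=pool.n_species)) - lw, np.inf)
        presence[i, np.argsort(keys, kind="stable")[: s_target[i]]] = True

    grand_total = cfg.total_individuals * len(attrs)
    share = pool.regional_abundance / pool.regional_abundance.sum()
    counts = np.zeros((len(attrs), pool.n_species), dtype=np.int64)
    for j in range(pool.n_species):
        occupied = np.flatnonzero(presence[:, j])
        if not len(occupied):
            continue
        total_j = max(int(round(grand_total * share[j])), len(occupied))
        alloc = rng.multinomial(total_j - len(occupied), np.full(len(occupied), 1.0 / len(occupied)))
        counts[occupied, j] = 1 + alloc
    return pd.DataFrame(counts, index=attrs.index, columns=list(pool.species_ids))


def generate_traits(
    n_species: int = 76,
    k_clusters: int = 4,
    separation: float = 6.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Species x 8-trait table with k latent clusters, plus the latent labels.

    Cluster centroids are placed so the smallest centroid-to-centroid
    distance equals ``separation`` within-cluster standard deviations;
    separation 0 collapses every centroid to the origin (no signal).
    Between-centroid variance is balanced across the eight traits so that
    per-trait z-scoring (which clustering applies) rescales all traits by
    the same factor and the stated separation survives standardization.
    """
    if k_clusters < 1 or k_clusters > n_species:
        raise ValueError("need 1 <= k_clusters <= n_species")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    labels = np.arange(n_species) % k_clusters
    rng.shuffle(labels)
    centroids = rng.normal(size=(k_clusters, len(TRAIT_COLUMNS)))
    if k_clusters > 1 and separation > 0:
        centroids -= centroids.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(centroids, axis=0, keepdims=True)
        norms[norms == 0] = 1.0
        centroids /= norms  # equal centroid spread on every trait
        d = np.sqrt(((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1))
        d_min = d[np.triu_indices(k_clusters, 1)].min()
        centroids = centroids * (separation / d_min) if d_min > 0 else centroids * 0.0
    else:
        centroids = centroids * 0.0
    traits = centroids[labels] + rng.normal(size=(n_species, len(TRAIT_COLUMNS)))
    ids = pd.Index(species_labels(n_species), name="species_id")
    table = pd.DataFrame(traits, index=ids, columns=list(TRAIT_COLUMNS))
    latent = pd.Series(labels + 1, index=ids, name="latent_pft")
    return table, latent
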