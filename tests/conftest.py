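import numpy as np
import pandas as pd
import pytest

from islandbeta import (
    AssemblyConfig,
    NullModelConfig,
    assemble_communities,
    generate_island_attributes,
    generate_species_pool,
)
from islandbeta.beta import jaccard, raup_crick
from islandbeta.community import build_pair_table


@pytest.fixture
def tiny_matrix():
    """4 islands x 4 equal-abundance species; pairs cover SS_obs = 0, 1, 2."""
    return pd.DataFrame(
        [[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1], [1, 0, 0, 1]],
        index=pd.Index(list("ABCD"), name="island_id"),
        columns=["s1", "s2", "s3", "s4"],
    )


@pytest.fixture
def twin_matrix():
    """Two identical pairs of islands; equal species totals, SS_obs in {0, 2}."""
    return pd.DataFrame(
        [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
        index=pd.Index(list("ABCD"), name="island_id"),
        columns=["s1", "s2", "s3", "s4"],
    )


def make_landscape(seed, mode="stochastic", n_islands=29, rc_reps=1000, **kw):
    """One synthetic landscape: (matrix, attrs, pool) under derived sub-seeds."""
    attrs = generate_island_attributes(n_islands, seed=seed, **{
        k: kw.pop(k) for k in ("area_range_ha", "dni_range_m", "dm_range_m") if k in kw
    })
    cfg = AssemblyConfig(mode=mode, n_islands=n_islands, seed=seed + 1, **kw)
    pool = generate_species_pool(cfg.n_species, cfg.sad_shape, cfg.sad_param, seed=seed + 2)
    matrix = assemble_communities(pool, attrs, cfg)
    return matrix, attrs, pool


def landscape_pair_table(seed, mode="stochastic", n_islands=29, rc_reps=1000, **kw):
    matrix, attrs, _ = make_landscape(seed, mode=mode, n_islands=n_islands, **kw)
    bj = jaccard(matrix)
    brc = raup_crick(matrix, NullModelConfig(n_reps=rc_reps, seed=seed + 3))
    return build_pair_table(matrix, attrs, bj, brc)


@pytest.fixture(scope="session")
def default_landscape():
    """A 29-island stochastic landscape shared across read-only tests."""
    return make_landscape(seed=20240)
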