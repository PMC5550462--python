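import itertools
import math

import numpy as np
import pandas as pd
import pytest

from estuarsens.grids import GridSpec
from estuarsens.synthetic import WorldConfig, generate_world


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths they check)


def brute_buffer_cells(spec: GridSpec, center, radius_km, mask=None):
    """Explicit double-loop enumeration of buffer∩mask cell indices."""
    x, y = center
    out = []
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            cx = spec.origin[0] + (j + 0.5) * spec.cell_size_km
            cy = spec.origin[1] + (i + 0.5) * spec.cell_size_km
            if (cx - x) ** 2 + (cy - y) ** 2 <= radius_km**2:
                if mask is None or mask[i][j]:
                    out.append((i, j))
    return out


def brute_buffer_mean(field, spec, center, radius_km, mask=None):
    cells = brute_buffer_cells(spec, center, radius_km, mask)
    if not cells:
        return float("nan"), 0
    return math.fsum(field[i][j] for i, j in cells) / len(cells), len(cells)


def brute_coverage(pa, spec, center, radius_km, mask, labels):
    """(percent, km2, total_km2) by explicit enumeration."""
    cells = brute_buffer_cells(spec, center, radius_km, mask)
    if not cells:
        return float("nan"), float("nan"), 0.0
    prot = sum(1 for i, j in cells if pa[i][j] in labels)
    area = spec.cell_size_km**2
    return 100.0 * prot / len(cells), prot * area, len(cells) * area


def ols_r2(y, cols):
    """R² by direct least squares on an explicit column list (+ intercept)."""
    y = np.asarray(y, float)
    M = np.column_stack([np.ones(len(y))] + [np.asarray(c, float) for c in cols])
    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    rss = float(((y - M @ beta) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - rss / tss


def lmg_by_permutations(y, group_cols: dict):
    """LMG shares by explicit averaging over all g! entry orderings."""
    names = list(group_cols)
    shares = dict.fromkeys(names, 0.0)
    perms = list(itertools.permutations(names))
    for perm in perms:
        cols = []
        r2_prev = 0.0
        for name in perm:
            cols = cols + list(group_cols[name])
            r2 = ols_r2(y, cols)
            shares[name] += r2 - r2_prev
            r2_prev = r2
    return {k: v / len(perms) for k, v in shares.items()}


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_world():
    cfg = WorldConfig(
        n_estuaries=25,
        n_samples=45,
        n_species=300,
        grid=GridSpec(60, 60, 10.0),
        seed=11,
    )
    return generate_world(cfg)


@pytest.fixture()
def species_table():
    return pd.DataFrame(
        {
            "taxon_id": [f"t{i}" for i in range(10)],
            "guild": ["marine"] * 4 + ["resident"] * 3 + ["freshwater"] * 2 + ["diadromous"],
            "vulnerability_score": [5, 10, 20, 25, 35, 45, 65, 75, 90, np.nan],
            "doubling_time_yr": [1.0, 1.2, 1.3, 2.0, 3.0, 5.0, 15.0, 1.0, np.nan, 2.0],
            "max_length_cm": [10, 12, 20, 55, 120, 30, 80, 99, 101, 14],
        }
    )
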