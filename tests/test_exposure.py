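"""Percentile radii, masked buffer means, composites and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_buffer_mean
from estuarsens.exposure import (
    DEFAULT_SCHEMES,
    ESTUARY_SCHEME,
    FRESHWATER_SCHEME,
    MARINE_SCHEME,
    PressureGrids,
    RadiusScheme,
    assign_radius,
    buffer_mean,
    composite_pressures,
    exposure_record,
    normalize_pressures,
    percentile_breaks,
    scheme_breaks,
)
from estuarsens.grids import ECO_LAND_FRESH, ECO_MARINE_SHELF, GridSpec


def test_percentile_breaks_uniform_grid():
    breaks = percentile_breaks(np.arange(1, 101), (25, 50, 75, 90, 95, 100))
    assert np.allclose(breaks, [25.75, 50.5, 75.25, 90.1, 95.05, 100])


def test_percentile_breaks_edges():
    assert np.allclose(percentile_breaks([7, 7, 7], (25, 100)), [7, 7])
    assert percentile_breaks([1, 5], (100,)) == [5]
    with pytest.raises(ValueError):
        percentile_breaks([1.0], (100,))


def test_assign_radius_ladder():
    breaks = percentile_breaks(np.arange(1, 101), MARINE_SCHEME.probs)
    assert assign_radius(3.0, MARINE_SCHEME, breaks) == 20.0
    assert assign_radius(100.0, MARINE_SCHEME, breaks) == 980.0
    assert assign_radius(0.0, MARINE_SCHEME, breaks) == 20.0
    # above every break -> top radius
    assert assign_radius(1e9, MARINE_SCHEME, breaks) == 980.0
    with pytest.raises(ValueError):
        assign_radius(-1.0, MARINE_SCHEME, breaks)


@given(st.floats(0, 200), st.floats(0, 200))
@settings(max_examples=100, deadline=None)
def test_assign_radius_monotone(v1, v2):
    breaks = percentile_breaks(np.arange(1, 101), MARINE_SCHEME.probs)
    lo, hi = sorted((v1, v2))
    assert assign_radius(lo, MARINE_SCHEME, breaks) <= assign_radius(
        hi, MARINE_SCHEME, breaks
    )


def test_radius_scheme_validation():
    with pytest.raises(ValueError):
        RadiusScheme("d", (1.0, 2.0), probs=(50.0, 90.0))  # last prob != 100
    with pytest.raises(ValueError):
        RadiusScheme("d", (2.0, 1.0), probs=(50.0, 100.0))  # radii not ascending


def test_buffer_mean_constant_field():
    spec = GridSpec(20, 20, 5.0)
    field = np.full(spec.shape, 3.7)
    mean, n = buffer_mean(field, spec, (50.0, 50.0), 20.0)
    assert mean == pytest.approx(3.7)
    assert n > 0


def test_buffer_mean_seam():
    # left half 0, right half 1, center on the seam: brute enumeration oracle
    spec = GridSpec(10, 10, 1.0)
    field = np.zeros(spec.shape)
    field[:, 5:] = 1.0
    expected, n_exp = brute_buffer_mean(field, spec, (5.0, 5.0), 3.0)
    got, n = buffer_mean(field, spec, (5.0, 5.0), 3.0)
    assert got == expected
    assert n == n_exp
    assert got == pytest.approx(0.5, abs=0.2)


def test_buffer_mean_oracle_random_grids():
    rng = np.random.default_rng(42)
    for _ in range(10):
        spec = GridSpec(
            int(rng.integers(5, 15)), int(rng.integers(5, 15)), float(rng.uniform(1, 5))
        )
        field = rng.random(spec.shape)
        mask = rng.random(spec.shape) < 0.7
        w, h = spec.extent_km
        center = (float(rng.uniform(0, w)), float(rng.uniform(0, h)))
        radius = float(rng.uniform(1, max(w, h)))
        expected, n_exp = brute_buffer_mean(field, spec, center, radius, mask)
        got, n = buffer_mean(field, spec, center, radius, mask)
        assert n == n_exp
        if n_exp:
            assert got == expected  # exact: same sums in the same order class
        else:
            assert np.isnan(got)


def test_buffer_mean_guards():
    spec = GridSpec(5, 5, 1.0)
    field = np.ones(spec.shape)
    with pytest.raises(ValueError):
        buffer_mean(field, spec, (99.0, 1.0), 2.0)
    mean, n = buffer_mean(field, spec, (2.5, 2.5), 1.0, np.zeros(spec.shape, bool))
    assert np.isnan(mean) and n == 0


def _grids_uniform(spec, a, b, c):
    eco = np.full(spec.shape, ECO_LAND_FRESH, dtype=np.int64)
    eco[: spec.n_rows // 2] = ECO_MARINE_SHELF
    return PressureGrids(
        np.full(spec.shape, float(a)),
        np.full(spec.shape, float(b)),
        np.full(spec.shape, float(c)),
        eco,
        spec,
    )


def _estuary(spec, **over):
    base = {
        "estuary_id": "e0",
        "x_km": spec.extent_km[0] / 2 + spec.cell_size_km / 2,
        "y_km": spec.n_rows // 2 * spec.cell_size_km,
        "shelf_width_km": 10.0,
        "estuary_area_km2": 5.0,
        "basin_area_km2": 100.0,
    }
    base.update(over)
    return pd.Series(base)


def test_exposure_record_uniform_fields():
    # cell size small enough that even the 1 km estuary radius is non-empty
    spec = GridSpec(100, 100, 1.5)
    grids = _grids_uniform(spec, 1.5, 2.5, 3.5)
    est = _estuary(spec)
    table = pd.DataFrame([_estuary(spec), _estuary(spec, shelf_width_km=50.0)])
    breaks = scheme_breaks(table)
    rec = exposure_record(est, grids, breaks)
    assert rec["H_marine"] == pytest.approx(1.5)
    assert rec["H_estuary"] == pytest.approx(2.5)
    assert rec["H_freshwater"] == pytest.approx(3.5)


def test_scheme_independence():
    # basin_area spanning a percentile break changes only the freshwater radius
    spec = GridSpec(30, 30, 5.0)
    table = pd.DataFrame(
        [_estuary(spec, basin_area_km2=v) for v in (1, 10, 100, 1000, 5000)]
    )
    breaks = scheme_breaks(table)
    grids = _grids_uniform(spec, 1, 1, 1)
    r1 = exposure_record(table.iloc[0], grids, breaks)
    r2 = exposure_record(table.iloc[4], grids, breaks)
    assert r1["radius_freshwater_km"] < r2["radius_freshwater_km"]
    assert r1["radius_marine_km"] == r2["radius_marine_km"]
    assert r1["radius_estuary_km"] == r2["radius_estuary_km"]


def test_composites_hand_checked():
    rec = {"H_marine": 0.9, "H_estuary": 0.3, "H_freshwater": 0.6}
    guilds = {
        "p_marine": 0.5,
        "p_resident": 0.25,
        "p_freshwater": 0.125,
        "p_diadromous": 0.125,
    }
    out = composite_pressures(rec, guilds)
    assert out["H_mean"] == pytest.approx(0.6)
    # independent dot-product oracle: 0.45 + 0.075 + 0.075 + 0.075
    expected = np.dot([0.5, 0.25, 0.125, 0.125], [0.9, 0.3, 0.6, 0.6])
    assert out["H_weighted_mean"] == pytest.approx(expected)
    assert out["H_weighted_mean"] == pytest.approx(0.675)


def test_composites_fixed_point_and_degenerate():
    guilds = {"p_marine": 1.0, "p_resident": 0.0, "p_freshwater": 0.0, "p_diadromous": 0.0}
    rec = {"H_marine": 0.9, "H_estuary": 0.3, "H_freshwater": 0.6}
    assert composite_pressures(rec, guilds)["H_weighted_mean"] == pytest.approx(0.9)
    equal = {"H_marine": 0.4, "H_estuary": 0.4, "H_freshwater": 0.4}
    g2 = {"p_marine": 0.3, "p_resident": 0.3, "p_freshwater": 0.2, "p_diadromous": 0.2}
    out = composite_pressures(equal, g2)
    assert out["H_mean"] == pytest.approx(0.4)
    assert out["H_weighted_mean"] == pytest.approx(0.4)


def test_composites_missing_component_flagged():
    rec = {"H_marine": float("nan"), "H_estuary": 0.3, "H_freshwater": 0.6}
    g = {"p_marine": 0.25, "p_resident": 0.25, "p_freshwater": 0.25, "p_diadromous": 0.25}
    out = composite_pressures(rec, g)
    assert np.isnan(out["H_mean"]) and np.isnan(out["H_weighted_mean"])
    assert out["composite_flag"] == "missing-component"


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=50, deadline=None)
def test_weighted_mean_convexity(seed):
    rng = np.random.default_rng(seed)
    h = rng.uniform(0, 10, 3)
    w = rng.dirichlet(np.ones(4))
    rec = dict(zip(("H_marine", "H_estuary", "H_freshwater"), h))
    g = dict(zip(("p_marine", "p_resident", "p_freshwater", "p_diadromous"), w))
    out = composite_pressures(rec, g)
    vals = [*h, out["H_mean"]]
    assert min(vals) - 1e-12 <= out["H_weighted_mean"] <= max(vals) + 1e-12


def test_normalize_pressures():
    df = pd.DataFrame({"H_marine": [0.0, 1.0, 3.0]})
    out = normalize_pressures(df, ["H_marine"])
    expected = np.array([0.0, np.log(2) / np.log(4), 1.0])
    assert np.allclose(out["H_marine_norm"], expected)
    # endpoints for (0, e-1)
    df2 = pd.DataFrame({"H_marine": [0.0, np.e - 1]})
    out2 = normalize_pressures(df2, ["H_marine"])
    assert np.allclose(out2["H_marine_norm"], [0.0, 1.0])


def test_normalize_order_preserving_and_duplication_invariant():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"H_marine": rng.uniform(0, 50, 30)})
    out = normalize_pressures(df, ["H_marine"])
    assert out["H_marine_norm"].between(0, 1).all()
    order = np.argsort(df["H_marine"].to_numpy())
    assert (np.diff(out["H_marine_norm"].to_numpy()[order]) >= 0).all()
    doubled = normalize_pressures(pd.concat([df, df], ignore_index=True), ["H_marine"])
    assert np.allclose(doubled["H_marine_norm"][:30], out["H_marine_norm"])


def test_normalize_constant_column_errors():
    with pytest.raises(ValueError, match="H_marine"):
        normalize_pressures(pd.DataFrame({"H_marine": [2.0, 2.0]}), ["H_marine"])
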