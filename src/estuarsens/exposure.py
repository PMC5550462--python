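"""Human-pressure exposure around estuary mouths.

Exposure per ecosystem is the mean of a gridded pressure field over the cells
whose centers fall within an influence radius of the estuary mouth and that
belong to the ecosystem considered:

* ``H_marine``  — cumulative marine human-impact field, masked to the
  continental shelf (marine cells shallower than 200 m);
* ``H_estuary`` — human population density, unmasked (land and water in and
  around the estuary);
* ``H_freshwater`` — incident-threat index to river biodiversity, masked to
  land/freshwater cells.

The influence radius is not fixed: each ecosystem has a ladder of radii tied
to percentile bins of its size driver across the whole estuary table
(continental shelf width, estuary area, drainage-basin area respectively), so
that larger ecosystems are integrated over larger neighbourhoods.

Composites: ``H_mean`` is the arithmetic mean of the three ecosystem
pressures; ``H_weighted_mean`` weights them by the assemblage's guild
percentages, with the diadromous weight applied to ``H_mean`` (diadromous
fish use all three ecosystems). All pressure variables are log(x+1)
transformed and min-max scaled to [0, 1] across the table before analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ECO_LAND_FRESH, ECO_MARINE_SHELF, GridSpec

logger = logging.getLogger(__name__)

DEFAULT_PROBS = (25.0, 50.0, 75.0, 90.0, 95.0, 100.0)


@dataclass(frozen=True)
class RadiusScheme:
    """Percentile-binned influence-radius ladder for one ecosystem driver."""

    driver: str
    radii_km: tuple[float, ...]
    probs: tuple[float, ...] = DEFAULT_PROBS

    def __post_init__(self) -> None:
        if len(self.probs) != len(self.radii_km):
            raise ValueError("probs and radii_km must have matching lengths")
        if list(self.probs) != sorted(set(self.probs)) or self.probs[-1] != 100.0:
            raise ValueError("probs must be strictly ascending and end at 100")
        if list(self.radii_km) != sorted(set(self.radii_km)):
            raise ValueError("radii_km must be strictly ascending")


MARINE_SCHEME = RadiusScheme("shelf_width_km", (20.0, 40.0, 125.0, 440.0, 600.0, 980.0))
ESTUARY_SCHEME = RadiusScheme("estuary_area_km2", (1.0, 5.0, 10.0, 30.0, 40.0, 265.0))
FRESHWATER_SCHEME = RadiusScheme(
    "basin_area_km2", (15.0, 35.0, 85.0, 270.0, 315.0, 1345.0)
)
DEFAULT_SCHEMES = {
    "marine": MARINE_SCHEME,
    "estuary": ESTUARY_SCHEME,
    "freshwater": FRESHWATER_SCHEME,
}


@dataclass
class PressureGrids:
    """The three pressure fields plus the ecosystem-class layer."""

    marine_impact: np.ndarray
    population_density: np.ndarray
    freshwater_threat: np.ndarray
    ecosystem_class: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        for name in ("marine_impact", "population_density", "freshwater_threat"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
            if np.nanmin(arr) < 0:
                raise ValueError(f"{name} has negative values")
        if self.ecosystem_class.shape != self.grid.shape:
            raise ValueError("ecosystem_class shape mismatch")


def percentile_breaks(values, probs=DEFAULT_PROBS) -> np.ndarray:
    """Empirical quantiles (linear interpolation) of the driver values."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("need at least 2 finite driver values for percentile breaks")
    return np.percentile(values, list(probs))


def assign_radius(value: float, scheme: RadiusScheme, breaks) -> float:
    """Radius (km) of the first percentile bin whose break covers ``value``.

    Ties go to the smaller radius; values above every break (possible only
    for values outside the table the breaks were computed from) get the
    top radius. Monotone non-decreasing in ``value``.
    """
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"driver value must be finite and >= 0, got {value}")
    breaks = np.asarray(breaks, dtype=float)
    for b, r in zip(breaks, scheme.radii_km):
        if value <= b:
            return r
    return scheme.radii_km[-1]


def buffer_mean(
    field: np.ndarray,
    spec: GridSpec,
    center: tuple[float, float],
    radius_km: float,
    mask: np.ndarray | None = None,
) -> tuple[float, int]:
    """Mean of ``field`` over cells with center within ``radius_km`` of
    ``center`` that pass ``mask``; returns (mean, n_cells).

    Membership is by cell-center Euclidean distance, inclusive of the radius.
    An empty buffer-mask intersection returns (nan, 0) with a warning.
    """
    x, y = center
    if not spec.contains(x, y):
        raise ValueError(f"center {center} outside grid bounds")
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    sel = spec.distance_from(x, y) <= radius_km
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    n = int(sel.sum())
    if n == 0:
        logger.warning("empty buffer: center=%s radius=%.1f km", center, radius_km)
        return float("nan"), 0
    # exactly rounded sum: result is independent of summation order
    return math.fsum(np.asarray(field, dtype=float)[sel]) / n, n


def scheme_breaks(
    estuaries: pd.DataFrame, schemes: dict[str, RadiusScheme] | None = None
) -> dict[str, np.ndarray]:
    """Percentile breaks per ecosystem scheme, over the full estuary table."""
    schemes = schemes or DEFAULT_SCHEMES
    return {
        name: percentile_breaks(estuaries[s.driver], s.probs)
        for name, s in schemes.items()
    }


def exposure_record(
    estuary: pd.Series,
    grids: PressureGrids,
    breaks: dict[str, np.ndarray],
    schemes: dict[str, RadiusScheme] | None = None,
) -> dict:
    """Raw masked buffer means of the three pressure fields for one estuary."""
    schemes = schemes or DEFAULT_SCHEMES
    center = (float(estuary["x_km"]), float(estuary["y_km"]))
    eco = grids.ecosystem_class
    plan = {
        "marine": (grids.marine_impact, eco == ECO_MARINE_SHELF),
        "estuary": (grids.population_density, None),
        "freshwater": (grids.freshwater_threat, eco == ECO_LAND_FRESH),
    }
    rec: dict = {"estuary_id": estuary["estuary_id"]}
    for name, (fld, mask) in plan.items():
        scheme = schemes[name]
        radius = assign_radius(float(estuary[scheme.driver]), scheme, breaks[name])
        mean, n = buffer_mean(fld, grids.grid, center, radius, mask)
        rec[f"H_{name}"] = mean
        rec[f"radius_{name}_km"] = radius
        rec[f"n_cells_{name}"] = n
    return rec


def composite_pressures(record: dict, guilds: dict[str, float]) -> dict:
    """Add H_mean and H_weighted_mean to a raw exposure record.

    H_mean averages the three ecosystem pressures. H_weighted_mean weights
    H_marine, H_estuary and H_freshwater by the marine, resident and
    freshwater guild fractions, and H_mean by the diadromous fraction; the
    denominator is the explicit sum of weights (1 up to rounding).
    """
    rec = dict(record)
    h = [rec.get("H_marine"), rec.get("H_estuary"), rec.get("H_freshwater")]
    if any(v is None or not np.isfinite(v) for v in h):
        rec["H_mean"] = float("nan")
        rec["H_weighted_mean"] = float("nan")
        rec["composite_flag"] = "missing-component"
        return rec
    h_mean = float(np.mean(h))
    w = [
        guilds["p_marine"],
        guilds["p_resident"],
        guilds["p_freshwater"],
        guilds["p_diadromous"],
    ]
    vals = [h[0], h[1], h[2], h_mean]
    rec["H_mean"] = h_mean
    rec["H_weighted_mean"] = float(np.dot(w, vals) / np.sum(w))
    rec["composite_flag"] = ""
    return rec


PRESSURE_COLUMNS = ("H_marine", "H_estuary", "H_freshwater", "H_mean", "H_weighted_mean")


def normalize_pressures(table: pd.DataFrame, columns=PRESSURE_COLUMNS) -> pd.DataFrame:
    """log(x+1)-transform then min-max scale each pressure column to [0, 1].

    Appends ``<col>_norm`` columns; the table minimum maps to 0 and the
    maximum to 1. A constant column has no range and raises ValueError.
    """
    out = table.copy()
    for col in columns:
        x = np.log1p(out[col].astype(float))
        lo, hi = np.nanmin(x), np.nanmax(x)
        if not np.isfinite(lo) or hi == lo:
            raise ValueError(f"pressure variable {col!r} has zero range")
        out[f"{col}_norm"] = (x - lo) / (hi - lo)
    return out


def exposure_table(
    estuaries: pd.DataFrame,
    grids: PressureGrids,
    guilds: pd.DataFrame,
    schemes: dict[str, RadiusScheme] | None = None,
) -> pd.DataFrame:
    """Per-sample exposure table: raw H, composites and normalized columns.

    Buffer means are computed once per estuary; composites are per sample
    because the guild weights are a property of the assemblage.
    """
    breaks = scheme_breaks(estuaries, schemes)
    raw = {
        row["estuary_id"]: exposure_record(row, grids, breaks, schemes)
        for _, row in estuaries.iterrows()
    }
    rows = []
    for _, g in guilds.iterrows():
        rec = composite_pressures(raw[g["estuary_id"]], g)
        rec["sample_id"] = g["sample_id"]
        rows.append(rec)
    table = pd.DataFrame(rows)
    front = ["sample_id", "estuary_id"]
    table = table[front + [c for c in table.columns if c not in front]]
    return normalize_pressures(table)
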