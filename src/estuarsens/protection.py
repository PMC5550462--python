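"""Protected-area coverage within the influence radii used for exposure.

Coverage is quantified under two selections — all protected areas
(``PA_all``) versus only IUCN management categories I-IV (``PA_I_IV``, the
regimes that restrict extractive activities) — and three ecosystem variants:

* marine: marine radius, continental-shelf cells only;
* estuary: estuary radius, no ecosystem mask;
* freshwater: freshwater radius, all non-marine (land/freshwater) cells.

Coverage is reported both as a percentage of the eligible (mask-passing)
area within the radius and in km².
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exposure import RadiusScheme, assign_radius, scheme_breaks
from .grids import ECO_LAND_FRESH, ECO_MARINE_SHELF, PA_OTHER, PA_STRICT, GridSpec

logger = logging.getLogger(__name__)

SELECTIONS = {"all": (PA_STRICT, PA_OTHER), "I-IV": (PA_STRICT,)}


def coverage_in_buffer(
    pa: np.ndarray,
    spec: GridSpec,
    center: tuple[float, float],
    radius_km: float,
    mask: np.ndarray | None = None,
    selection: str = "all",
) -> tuple[float, float, float]:
    """Protected coverage in a buffer: (percent, protected km², eligible km²).

    ``percent`` is protected-cell area over eligible-cell area within the
    radius (cells whose centers are within ``radius_km`` and pass ``mask``).
    An empty buffer-mask intersection returns (nan, nan, 0.0) with a warning.
    """
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}")
    x, y = center
    if not spec.contains(x, y):
        raise ValueError(f"center {center} outside grid bounds")
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    sel = spec.distance_from(x, y) <= radius_km
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    n_eligible = int(sel.sum())
    if n_eligible == 0:
        logger.warning(
            "empty protection buffer: center=%s radius=%.1f km", center, radius_km
        )
        return float("nan"), float("nan"), 0.0
    labels = np.asarray(pa)[sel]
    n_protected = int(np.isin(labels, SELECTIONS[selection]).sum())
    area = spec.cell_area_km2
    return (
        100.0 * n_protected / n_eligible,
        n_protected * area,
        n_eligible * area,
    )


def protection_record(
    estuary: pd.Series,
    pa: np.ndarray,
    ecosystem_class: np.ndarray,
    spec: GridSpec,
    breaks: dict[str, np.ndarray],
    schemes: dict[str, RadiusScheme] | None = None,
) -> dict:
    """All six coverage figures (2 selections x 3 variants) for one estuary."""
    from .exposure import DEFAULT_SCHEMES

    schemes = schemes or DEFAULT_SCHEMES
    center = (float(estuary["x_km"]), float(estuary["y_km"]))
    masks = {
        "marine": ecosystem_class == ECO_MARINE_SHELF,
        "estuary": None,
        "freshwater": ecosystem_class == ECO_LAND_FRESH,
    }
    rec: dict = {"estuary_id": estuary["estuary_id"]}
    for variant, mask in masks.items():
        scheme = schemes[variant]
        radius = assign_radius(float(estuary[scheme.driver]), scheme, breaks[variant])
        rec[f"radius_{variant}_km"] = radius
        for sel_name, tag in (("all", "all"), ("I-IV", "I_IV")):
            pct, km2, total = coverage_in_buffer(
                pa, spec, center, radius, mask, sel_name
            )
            rec[f"PA_{tag}_{variant}_pct"] = pct
            rec[f"PA_{tag}_{variant}_km2"] = km2
        rec[f"A_{variant}_km2"] = total
    return rec


def protection_table(
    estuaries: pd.DataFrame,
    pa: np.ndarray,
    ecosystem_class: np.ndarray,
    spec: GridSpec,
    schemes: dict[str, RadiusScheme] | None = None,
) -> pd.DataFrame:
    """Protection records for every estuary, radii shared with exposure."""
    breaks = scheme_breaks(estuaries, schemes)
    rows = [
        protection_record(row, pa, ecosystem_class, spec, breaks, schemes)
        for _, row in estuaries.iterrows()
    ]
    return pd.DataFrame(rows)


#: normalized protection columns used in correlation analyses
PROTECTION_PCT_COLUMNS = (
    "PA_all_marine_pct",
    "PA_all_estuary_pct",
    "PA_all_freshwater_pct",
    "PA_I_IV_marine_pct",
    "PA_I_IV_estuary_pct",
    "PA_I_IV_freshwater_pct",
)
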