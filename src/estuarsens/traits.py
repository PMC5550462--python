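"""Trait categorization and per-sample trait profiles.

Fish sensitivity is summarized by three species-level traits:

* **vulnerability** — intrinsic extinction vulnerability to fishing, an
  aggregate 0-100% score built from life-history and ecological parameters;
* **resilience** — productivity, indexed by the minimum population doubling
  time in years (short doubling time = high resilience);
* **maximum body size** — maximum recorded length in cm.

Each trait is binned into ordered categories, and a sample's *relative taxa
richness* for a category is the proportion of the sample's taxa that fall in
it. Published bin edges are ambiguous where ranges touch ("0-30%", "30-40%";
"1.4-4.4 yr", "4.5-14 yr"); the conventions fixed here are left-closed /
right-open interiors, with the final bin closed, and the resilience gap
(4.4, 4.5) resolved so Medium = [1.4, 4.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

GUILDS = ("marine", "resident", "freshwater", "diadromous")

VULNERABILITY_CATEGORIES = (
    "Low",
    "Low-Moderate",
    "Moderate-High",
    "High-Very High",
    "Very High",
)
#: right edges of the vulnerability bins; bins are [0,30), [30,40), [40,60),
#: [60,70), [70,100]
VULNERABILITY_EDGES = (30.0, 40.0, 60.0, 70.0, 100.0)

RESILIENCE_CATEGORIES = ("High", "Medium", "Low", "Very Low")
#: doubling-time (years) bins: (0,1.4) High, [1.4,4.5) Medium, [4.5,14] Low,
#: (14, inf) Very Low
RESILIENCE_EDGES = (1.4, 4.5, 14.0)

SIZE_CATEGORIES = ("Small", "Medium", "Large", "Very Large")
#: max-length (cm) bins: (0,15) Small, [15,50) Medium, [50,100] Large,
#: (100, inf) Very Large
SIZE_EDGES = (15.0, 50.0, 100.0)

#: short column keys used in tabular outputs, per trait
PROFILE_COLUMNS: dict[str, tuple[str, ...]] = {
    "vulnerability": ("vuln_L", "vuln_LM", "vuln_MH", "vuln_HVH", "vuln_VH"),
    "resilience": ("resil_H", "resil_M", "resil_L", "resil_VL"),
    "size": ("size_S", "size_M", "size_L", "size_VL"),
}
#: the nine modelled responses (vulnerability and resilience categories)
RESPONSE_COLUMNS = PROFILE_COLUMNS["vulnerability"] + PROFILE_COLUMNS["resilience"]

GUILD_COLUMNS = ("p_marine", "p_resident", "p_freshwater", "p_diadromous")


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def categorize_vulnerability(score: float | None) -> str | None:
    """Bin a 0-100% vulnerability score into its five-level category.

    Bins are left-closed, right-open, the last closed at 100. Missing input
    (None/NaN) returns None; out-of-range scores raise ValueError.
    """
    if _is_missing(score):
        return None
    if not 0.0 <= score <= 100.0:
        raise ValueError(f"vulnerability score {score} outside [0, 100]")
    for cat, edge in zip(VULNERABILITY_CATEGORIES, VULNERABILITY_EDGES):
        if score < edge:
            return cat
    return VULNERABILITY_CATEGORIES[-1]  # score == 100


def categorize_resilience(doubling_time: float | None) -> str | None:
    """Bin a minimum population doubling time (years) into resilience.

    <1.4 High; [1.4, 4.5) Medium; [4.5, 14] Low; >14 Very Low. Missing input
    returns None; non-positive times raise ValueError.
    """
    if _is_missing(doubling_time):
        return None
    if doubling_time <= 0:
        raise ValueError(f"doubling time must be positive, got {doubling_time}")
    if doubling_time < RESILIENCE_EDGES[0]:
        return "High"
    if doubling_time < RESILIENCE_EDGES[1]:
        return "Medium"
    if doubling_time <= RESILIENCE_EDGES[2]:
        return "Low"
    return "Very Low"


def categorize_size(max_length_cm: float | None) -> str | None:
    """Bin maximum body length (cm): <15 Small, [15,50) Medium, [50,100]
    Large, >100 Very Large. Missing input returns None."""
    if _is_missing(max_length_cm):
        return None
    if max_length_cm <= 0:
        raise ValueError(f"max length must be positive, got {max_length_cm}")
    if max_length_cm < SIZE_EDGES[0]:
        return "Small"
    if max_length_cm < SIZE_EDGES[1]:
        return "Medium"
    if max_length_cm <= SIZE_EDGES[2]:
        return "Large"
    return "Very Large"


_CATEGORIZERS = {
    "vulnerability": (categorize_vulnerability, "vulnerability_score"),
    "resilience": (categorize_resilience, "doubling_time_yr"),
    "size": (categorize_size, "max_length_cm"),
}


def categorize_species(species: pd.DataFrame) -> pd.DataFrame:
    """Add a ``<trait>_cat`` column per trait to a species table.

    Expects columns ``vulnerability_score``, ``doubling_time_yr``,
    ``max_length_cm``; missing values propagate to missing categories.
    """
    out = species.copy()
    for trait, (fn, col) in _CATEGORIZERS.items():
        out[f"{trait}_cat"] = out[col].map(fn)
    return out


@dataclass(frozen=True)
class TraitProfile:
    """Relative taxa richness per trait category for one sample."""

    sample_id: str
    proportions: Mapping[str, float]  # keyed by PROFILE_COLUMNS entries
    n_taxa_total: int
    n_taxa_with_trait: Mapping[str, int]  # keyed by trait name


def relative_taxa_richness(
    taxa: Iterable[str],
    species: pd.DataFrame,
    denominator_mode: str = "total",
    sample_id: str = "",
) -> TraitProfile:
    """Compute relative taxa richness per trait category for one sample.

    ``taxa`` is the set of taxon ids observed in the sample; ``species`` is
    the trait table indexed (or keyed by column ``taxon_id``). Taxa with a
    missing trait value count in no category of that trait. The denominator
    is the total observed richness (mode ``"total"``, the literal published
    definition) or only taxa with a known value for that trait
    (mode ``"known-only"``, in which proportions sum to exactly 1).
    """
    if denominator_mode not in ("total", "known-only"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    taxa = list(taxa)
    if not taxa:
        raise ValueError("sample has no taxa")
    if len(set(taxa)) != len(taxa):
        taxa = sorted(set(taxa))
    table = species.set_index("taxon_id") if "taxon_id" in species.columns else species
    missing_ids = set(taxa) - set(table.index)
    if missing_ids:
        raise KeyError(f"taxa absent from species table: {sorted(missing_ids)[:5]}")
    sub = table.loc[taxa]
    if not {"vulnerability_cat", "resilience_cat", "size_cat"} <= set(sub.columns):
        sub = categorize_species(sub.reset_index()).set_index("taxon_id")

    n_total = len(taxa)
    props: dict[str, float] = {}
    n_known: dict[str, int] = {}
    for trait, cats in (
        ("vulnerability", VULNERABILITY_CATEGORIES),
        ("resilience", RESILIENCE_CATEGORIES),
        ("size", SIZE_CATEGORIES),
    ):
        col = sub[f"{trait}_cat"]
        counts = col.value_counts()
        known = int(col.notna().sum())
        n_known[trait] = known
        denom = n_total if denominator_mode == "total" else known
        for cat, key in zip(cats, PROFILE_COLUMNS[trait]):
            c = int(counts.get(cat, 0))
            props[key] = c / denom if denom > 0 else float("nan")
    return TraitProfile(sample_id, props, n_total, n_known)


def guild_percentages(taxa: Iterable[str], species: pd.DataFrame) -> dict[str, float]:
    """Fraction of a sample's taxa per guild of origin; fractions sum to 1."""
    taxa = sorted(set(taxa))
    if not taxa:
        raise ValueError("sample has no taxa")
    table = species.set_index("taxon_id") if "taxon_id" in species.columns else species
    missing_ids = set(taxa) - set(table.index)
    if missing_ids:
        raise KeyError(f"taxa absent from species table: {sorted(missing_ids)[:5]}")
    guilds = table.loc[taxa, "guild"]
    counts = guilds.value_counts()
    n = len(taxa)
    return {
        col: float(counts.get(guild, 0)) / n for guild, col in zip(GUILDS, GUILD_COLUMNS)
    }


def profile_samples(
    occurrences: pd.DataFrame,
    species: pd.DataFrame,
    samples: pd.DataFrame,
    denominator_mode: str = "total",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile every sample in a long-format occurrence table.

    ``occurrences`` has columns (sample_id, estuary_id, taxon_id); ``samples``
    has (sample_id, estuary_id, sampled_area_m2). Returns
    (trait_profiles, guilds) DataFrames, one row per sample.
    """
    sp = categorize_species(species)
    profile_rows = []
    guild_rows = []
    grouped = occurrences.groupby("sample_id", sort=True)["taxon_id"]
    meta = samples.set_index("sample_id")
    for sample_id, taxa in grouped:
        prof = relative_taxa_richness(taxa, sp, denominator_mode, sample_id=sample_id)
        row = {
            "sample_id": sample_id,
            "estuary_id": meta.loc[sample_id, "estuary_id"],
            **prof.proportions,
            "n_taxa_total": prof.n_taxa_total,
        }
        for trait in ("vulnerability", "resilience", "size"):
            row[f"n_known_{trait}"] = prof.n_taxa_with_trait[trait]
        profile_rows.append(row)
        guild_rows.append(
            {
                "sample_id": sample_id,
                "estuary_id": meta.loc[sample_id, "estuary_id"],
                **guild_percentages(taxa, sp),
            }
        )
    missing_samples = set(meta.index) - set(grouped.groups)
    if missing_samples:
        raise ValueError(
            f"samples without occurrences: {sorted(missing_samples)[:5]}"
        )
    return pd.DataFrame(profile_rows), pd.DataFrame(guild_rows)
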