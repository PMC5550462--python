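"""Seeded synthetic worlds: estuaries, species pools, assemblages and grids.

The generator emulates the structure of a compiled global estuarine-fish
database together with the gridded layers needed for exposure and protection
accounting, with *known* trait-environment structure so that every downstream
stage (profiling, buffer statistics, correlation and model inference) can be
validated against planted truth.

A world consists of:

* an estuary table on a synthetic equal-area plane whose lower part is ocean
  (continental shelf near the coast, deep ocean beyond) and upper part is
  land; every estuary mouth sits on the shelf/land interface;
* a species pool whose vulnerability, resilience and size traits are drawn
  from a Gaussian copula so that category frequencies match configurable
  marginal targets (defaults follow the observed global means: vulnerability
  40/22/23/6/4%, resilience 32/50/8/2%) while traits covary positively in
  rank (bigger fish are more vulnerable and slower-doubling);
* assemblage samples in which each pool species enters independently with a
  logit-linear inclusion probability: a guild baseline (marine-guild odds
  rise with connectivity), optional planted trait-category x environment
  effects, and an effort term;
* spatially autocorrelated pressure fields (moving-average smoothed noise)
  and a patchy protected-area layer with a stated IUCN I-IV mix.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter
from scipy.special import expit, ndtr

from .grids import (
    ECO_LAND_FRESH,
    ECO_MARINE_DEEP,
    ECO_MARINE_SHELF,
    PA_NONE,
    PA_OTHER,
    PA_STRICT,
    GridSpec,
    write_ascii_grid,
)
from .traits import GUILDS, PROFILE_COLUMNS, categorize_species

# Observed global mean relative richness per category (fractions), used as
# the default calibration targets for the species pool.
DEFAULT_VULN_MARGINALS = (0.40, 0.22, 0.23, 0.06, 0.04)
DEFAULT_RESIL_MARGINALS = (0.32, 0.50, 0.08, 0.02)

# Score/time supports of the trait bins (see traits module for conventions).
_VULN_SUPPORTS = ((0.0, 30.0), (30.0, 40.0), (40.0, 60.0), (60.0, 70.0), (70.0, 100.0))
_RESIL_SUPPORTS = ((0.3, 1.4), (1.4, 4.5), (4.5, 14.0), (14.0, 40.0))

# Latent rank correlations: vulnerability-resilience(time), vulnerability-size,
# time-size. Directions are biological (large fish: higher vulnerability,
# longer doubling time); magnitudes are a modelling choice.
_LATENT_CORR = np.array([[1.0, 0.5, 0.6], [0.5, 1.0, 0.5], [0.6, 0.5, 1.0]])

CONTINENTS = (
    "North America",
    "South America",
    "Europe",
    "Africa",
    "Asia",
    "Oceania",
)
REALMS = tuple(f"realm_{i}" for i in range(1, 10))


@dataclass(frozen=True)
class PlantedEffect:
    """A known trait-category x environment effect on the inclusion logit.

    ``category`` is a profile column key (e.g. ``vuln_L``), ``driver`` an
    estuary column (e.g. ``sst``), ``beta`` the logit slope per driver unit
    (drivers are centered on their table mean before entering the logit).
    """

    category: str
    driver: str
    beta: float


@dataclass
class WorldConfig:
    """Full configuration of a synthetic world; defaults are the reference
    study conditions used throughout the test-bed."""

    n_estuaries: int = 150
    n_samples: int = 200
    n_species: int = 800
    grid: GridSpec = field(default_factory=lambda: GridSpec(200, 200, 10.0))
    guild_mix: tuple[float, float, float, float] = (0.50, 0.25, 0.15, 0.10)
    vuln_marginals: tuple[float, ...] = DEFAULT_VULN_MARGINALS
    resil_marginals: tuple[float, ...] = DEFAULT_RESIL_MARGINALS
    #: None derives per-trait missing fractions from the marginals' deficit
    #: from 1 (the published category means fall short of 100% by exactly
    #: the missing-trait share)
    missing_rate: float | None = None
    planted_effects: tuple[PlantedEffect, ...] = ()
    pressure_mean: float = 3.0
    pressure_sd: float = 1.0
    pressure_corr_range: int = 5
    pa_coverage: float = 0.12
    pa_strict_fraction: float = 0.3
    effort_range: tuple[float, float] = (1e3, 1e5)
    alpha_guild: dict[str, float] = field(
        default_factory=lambda: {
            "marine": -1.8,
            "resident": -1.6,
            "freshwater": -2.2,
            "diadromous": -2.4,
        }
    )
    #: connectivity bonus on the marine-guild logit per unit of (tidal-2)
    #: and (type-1.5)
    connectivity_tidal: float = 0.25
    connectivity_type: float = 0.5
    gamma_effort: float = 0.3
    shelf_band_km: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.guild_mix) - 1.0) > 1e-9:
            raise ValueError("guild_mix must sum to 1")
        if not 0.0 <= self.pa_coverage <= 1.0:
            raise ValueError("pa_coverage must be in [0, 1]")
        if not 0.0 <= self.pa_strict_fraction <= 1.0:
            raise ValueError("pa_strict_fraction must be in [0, 1]")
        if self.n_estuaries < 2:
            raise ValueError("need at least 2 estuaries (percentile breaks)")
        if self.n_samples < self.n_estuaries:
            raise ValueError("need at least one sample per estuary")
        if self.missing_rate is not None and not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = dataclasses.asdict(self.grid)
        d["planted_effects"] = [dataclasses.asdict(e) for e in self.planted_effects]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "WorldConfig":
        d = dict(d)
        if "grid" in d and isinstance(d["grid"], dict):
            g = dict(d["grid"])
            if "origin" in g:
                g["origin"] = tuple(g["origin"])
            d["grid"] = GridSpec(**g)
        if "planted_effects" in d:
            d["planted_effects"] = tuple(
                e if isinstance(e, PlantedEffect) else PlantedEffect(**e)
                for e in d["planted_effects"]
            )
        for key in ("guild_mix", "vuln_marginals", "resil_marginals", "effort_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class World:
    """A generated world plus the truth needed to score recovery."""

    config: WorldConfig
    estuaries: pd.DataFrame
    species: pd.DataFrame
    samples: pd.DataFrame
    occurrences: pd.DataFrame
    marine_impact: np.ndarray
    population_density: np.ndarray
    freshwater_threat: np.ndarray
    ecosystem_class: np.ndarray
    pa_class: np.ndarray
    driver_means: dict[str, float]
    truth: dict

    def pressure_grids(self):
        from .exposure import PressureGrids

        return PressureGrids(
            self.marine_impact,
            self.population_density,
            self.freshwater_threat,
            self.ecosystem_class,
            self.config.grid,
        )

    def write(self, out_dir: str | Path) -> list[str]:
        """Write all world files (CSV tables, ASCII rasters, truth.json)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in (
            ("estuaries", self.estuaries),
            ("species", self.species),
            ("samples", self.samples),
            ("occurrences", self.occurrences),
        ):
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path.name)
        rasters = {
            "marine_impact": self.marine_impact,
            "population_density": self.population_density,
            "freshwater_threat": self.freshwater_threat,
            "ecosystem_class": self.ecosystem_class,
            "pa_class": self.pa_class,
        }
        for name, arr in rasters.items():
            path = out / f"{name}.asc"
            write_ascii_grid(path, arr, self.config.grid)
            written.append(path.name)
        path = out / "truth.json"
        path.write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        written.append(path.name)
        return written


def _inverse_piecewise_uniform(u: np.ndarray, probs, supports) -> np.ndarray:
    """Inverse CDF of a mixture of uniforms over ``supports`` with bin
    probabilities ``probs``; exact and monotone in ``u``."""
    probs = np.asarray(probs, dtype=float)
    if probs.sum() <= 0 or (probs < 0).any():
        raise ValueError("bin targets must be non-negative and sum > 0")
    probs = probs / probs.sum()
    cum = np.concatenate([[0.0], np.cumsum(probs)])
    cum[-1] = 1.0
    idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(probs) - 1)
    # guard bins with zero probability reached only at exact boundary values
    while (probs[idx] == 0).any():
        idx[probs[idx] == 0] -= 1
    lo = np.array([s[0] for s in supports])[idx]
    hi = np.array([s[1] for s in supports])[idx]
    frac = (u - cum[idx]) / probs[idx]
    return lo + np.clip(frac, 0.0, 1.0) * (hi - lo)


def generate_species_pool(
    n_species: int,
    guild_mix=None,
    vuln_marginals=DEFAULT_VULN_MARGINALS,
    resil_marginals=DEFAULT_RESIL_MARGINALS,
    missing_rate: float | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a species pool with calibrated trait-category frequencies.

    Traits come from a Gaussian copula: vulnerability score and doubling time
    are inverse-CDF transforms of correlated latent normals through
    piecewise-uniform bin mixtures (so known-trait bin frequencies are exact
    multinomial draws of the renormalized targets), and maximum length is
    lognormal on the third latent.

    Missing values are blanked completely at random. With
    ``missing_rate=None`` the per-trait missing fraction is the deficit of
    the raw targets from 1 (published category means fall short of 100% by
    the missing-trait share), so that whole-pool category frequencies —
    missing taxa counted in the denominator — reproduce the raw targets.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    guild_mix = guild_mix if guild_mix is not None else (0.50, 0.25, 0.15, 0.10)
    if missing_rate is None:
        miss = {
            "vulnerability_score": max(0.0, 1.0 - float(np.sum(vuln_marginals))),
            "doubling_time_yr": max(0.0, 1.0 - float(np.sum(resil_marginals))),
            "max_length_cm": 0.05,
        }
    else:
        miss = {
            "vulnerability_score": missing_rate,
            "doubling_time_yr": missing_rate,
            "max_length_cm": missing_rate,
        }
    z = rng.standard_normal((n_species, 3)) @ np.linalg.cholesky(_LATENT_CORR).T
    u = ndtr(z)
    vuln = _inverse_piecewise_uniform(u[:, 0], vuln_marginals, _VULN_SUPPORTS)
    doubling = _inverse_piecewise_uniform(u[:, 1], resil_marginals, _RESIL_SUPPORTS)
    length = np.exp(np.log(25.0) + 0.8 * z[:, 2])
    guild = rng.choice(GUILDS, size=n_species, p=np.asarray(guild_mix))
    df = pd.DataFrame(
        {
            "taxon_id": [f"t{i:05d}" for i in range(n_species)],
            "guild": guild,
            "vulnerability_score": vuln,
            "doubling_time_yr": doubling,
            "max_length_cm": np.round(length, 1),
        }
    )
    for col, rate in miss.items():
        if rate > 0:
            blank = rng.random(n_species) < rate
            df.loc[blank, col] = np.nan
    return df


def generate_environment(
    n_estuaries: int, grid: GridSpec, shelf_band_km: float, rng: np.random.Generator
) -> pd.DataFrame:
    """Estuary table: coastline positions plus environmental features."""
    width, height = grid.extent_km
    coast_row = int(0.55 * grid.n_rows)
    y_coast = grid.origin[1] + coast_row * grid.cell_size_km
    x = grid.origin[0] + width * (0.05 + 0.9 * rng.random(n_estuaries))
    lat = rng.uniform(-62.0, 62.0, n_estuaries)
    sst = np.clip(28.5 - 0.37 * np.abs(lat) + rng.normal(0, 1.2, n_estuaries), -1.5, 31)
    ter_npp = np.clip(
        1000.0 * np.exp(-((np.abs(lat) / 40.0) ** 2))
        + rng.normal(0, 120.0, n_estuaries),
        10.0,
        None,
    )
    mar_chl = np.exp(rng.normal(np.log(0.8), 0.6, n_estuaries))
    shelf_width = np.exp(rng.normal(np.log(40.0), 1.0, n_estuaries))
    estuary_area = np.exp(rng.normal(np.log(50.0), 1.5, n_estuaries))
    basin_area = np.exp(rng.normal(np.log(5000.0), 2.0, n_estuaries))
    mouth_width = 0.2 * np.sqrt(estuary_area) * np.exp(rng.normal(0, 0.4, n_estuaries))
    tidal = rng.choice([1, 2, 3], size=n_estuaries, p=(0.45, 0.35, 0.20))
    etype = rng.choice([1, 2], size=n_estuaries, p=(0.30, 0.70))
    salinity = rng.choice([1, 2, 3], size=n_estuaries, p=(0.80, 0.15, 0.05))
    # biogeography follows longitudinal bands of the synthetic plane
    xs = (x - grid.origin[0]) / width
    continent = np.array(CONTINENTS)[
        np.minimum((xs * len(CONTINENTS)).astype(int), len(CONTINENTS) - 1)
    ]
    realm = np.array(REALMS)[
        np.minimum((xs * len(REALMS)).astype(int), len(REALMS) - 1)
    ]
    return pd.DataFrame(
        {
            "estuary_id": [f"e{i:04d}" for i in range(n_estuaries)],
            "x_km": x,
            "y_km": np.full(n_estuaries, y_coast),
            "latitude": lat,
            "sst": sst,
            "ter_npp": ter_npp,
            "mar_chl": mar_chl,
            "shelf_width_km": shelf_width,
            "estuary_area_km2": estuary_area,
            "basin_area_km2": basin_area,
            "mouth_width_km": mouth_width,
            "tidal_regime": tidal,
            "estuary_type": etype,
            "salinity_type": salinity,
            "continent": continent,
            "realm": realm,
        }
    )


def ecosystem_class_layer(grid: GridSpec, shelf_band_km: float) -> np.ndarray:
    """Coastline-band ecosystem classes: land above the coast row, shelf
    within ``shelf_band_km`` below it, deep ocean beyond."""
    coast_row = int(0.55 * grid.n_rows)
    rows = np.arange(grid.n_rows)
    depth_km = (coast_row - rows - 0.5) * grid.cell_size_km  # distance below coast
    classes = np.full(grid.n_rows, ECO_LAND_FRESH, dtype=np.int64)
    classes[(depth_km > 0) & (depth_km <= shelf_band_km)] = ECO_MARINE_SHELF
    classes[depth_km > shelf_band_km] = ECO_MARINE_DEEP
    return np.repeat(classes[:, None], grid.n_cols, axis=1)


def _smoothed_field(
    grid: GridSpec, mean: float, sd: float, corr_range: int, rng: np.random.Generator
) -> np.ndarray:
    if sd < 0:
        raise ValueError("pressure sd must be >= 0")
    if corr_range < 0:
        raise ValueError("correlation range must be >= 0")
    if sd == 0:
        return np.full(grid.shape, float(mean))
    noise = rng.standard_normal(grid.shape)
    if corr_range > 0:
        noise = uniform_filter(noise, size=2 * corr_range + 1, mode="reflect")
    noise = (noise - noise.mean()) / noise.std()
    return np.clip(mean + sd * noise, 0.0, None)


def generate_pressure_grids(
    grid: GridSpec,
    mean: float = 3.0,
    sd: float = 1.0,
    corr_range: int = 5,
    shelf_band_km: float = 150.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
):
    """Three autocorrelated non-negative pressure fields + ecosystem classes."""
    from .exposure import PressureGrids

    rng = rng if rng is not None else np.random.default_rng(seed)
    fields = [_smoothed_field(grid, mean, sd, corr_range, rng) for _ in range(3)]
    eco = ecosystem_class_layer(grid, shelf_band_km)
    return PressureGrids(fields[0], fields[1], fields[2], eco, grid)


def generate_protected_areas(
    grid: GridSpec,
    coverage: float,
    strict_fraction: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    mean_patch_cells: int | None = None,
) -> np.ndarray:
    """Patchy protected-area layer via seeded random patch growth.

    Exactly ``round(coverage * n_cells)`` cells are protected; among them
    exactly ``round(strict_fraction * n_protected)`` carry the IUCN I-IV
    label, assigned patch-by-patch with a per-cell top-up.
    """
    if not 0.0 <= coverage <= 1.0 or not 0.0 <= strict_fraction <= 1.0:
        raise ValueError("coverage and strict_fraction must be in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_rows, n_cols = grid.shape
    n_cells = n_rows * n_cols
    target = int(round(coverage * n_cells))
    pa = np.zeros(grid.shape, dtype=np.int64)
    if target == 0:
        return pa
    mean_patch = mean_patch_cells or max(4, target // 25)
    patches: list[list[tuple[int, int]]] = []
    remaining = target
    protected = np.zeros(grid.shape, dtype=bool)
    while remaining > 0:
        free = np.flatnonzero(~protected.ravel())
        start = free[rng.integers(len(free))]
        size = min(remaining, max(1, int(rng.geometric(1.0 / mean_patch))))
        patch: list[tuple[int, int]] = []
        frontier = [(start // n_cols, start % n_cols)]
        while frontier and len(patch) < size:
            k = rng.integers(len(frontier))
            r, c = frontier.pop(k)
            if protected[r, c]:
                continue
            protected[r, c] = True
            patch.append((r, c))
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols and not protected[rr, cc]:
                    frontier.append((rr, cc))
        patches.append(patch)
        remaining -= len(patch)
    pa[protected] = PA_OTHER
    n_strict = int(round(strict_fraction * target))
    order = rng.permutation(len(patches))
    assigned = 0
    for pi in order:
        if assigned >= n_strict:
            break
        patch = patches[pi]
        take = min(len(patch), n_strict - assigned)
        for r, c in patch[:take]:
            pa[r, c] = PA_STRICT
        assigned += take
    return pa


def _category_indicator(species_cat: pd.DataFrame, key: str) -> np.ndarray:
    """0/1 indicator of membership in a profile-column category (missing
    trait values count as non-members)."""
    for trait, keys in PROFILE_COLUMNS.items():
        if key in keys:
            from .traits import (
                RESILIENCE_CATEGORIES,
                SIZE_CATEGORIES,
                VULNERABILITY_CATEGORIES,
            )

            cats = {
                "vulnerability": VULNERABILITY_CATEGORIES,
                "resilience": RESILIENCE_CATEGORIES,
                "size": SIZE_CATEGORIES,
            }[trait]
            cat = cats[keys.index(key)]
            return (species_cat[f"{trait}_cat"] == cat).to_numpy(dtype=float)
    raise KeyError(f"unknown trait-category key {key!r}")


def inclusion_probabilities(
    estuary: pd.Series,
    species_cat: pd.DataFrame,
    planted_effects,
    effort: float,
    driver_means: dict[str, float],
    alpha_guild: dict[str, float],
    connectivity_tidal: float = 0.25,
    connectivity_type: float = 0.5,
    gamma_effort: float = 0.3,
    effort_ref: float = 1e4,
) -> np.ndarray:
    """Per-species inclusion probability for one sample (the model truth)."""
    eta = np.array([alpha_guild[g] for g in species_cat["guild"]], dtype=float)
    is_marine = (species_cat["guild"] == "marine").to_numpy(dtype=float)
    eta += is_marine * (
        connectivity_tidal * (float(estuary["tidal_regime"]) - 2.0)
        + connectivity_type * (float(estuary["estuary_type"]) - 1.5)
    )
    for eff in planted_effects:
        ind = _category_indicator(species_cat, eff.category)
        centered = float(estuary[eff.driver]) - driver_means.get(
            eff.driver, 0.0
        )
        eta += eff.beta * centered * ind
    eta += gamma_effort * (np.log(effort) - np.log(effort_ref))
    return expit(eta)


def assemble_sample(
    estuary: pd.Series,
    pool: pd.DataFrame,
    planted_effects,
    effort: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    driver_means: dict[str, float] | None = None,
    **kwargs,
) -> list[str]:
    """Draw one assemblage: the taxa included in one estuary survey.

    Each pool species enters independently with a logit-linear probability;
    see :func:`inclusion_probabilities`. Returns the included taxon ids
    (never empty: if no species is drawn, one is included at random).
    """
    if len(pool) == 0:
        raise ValueError("species pool is empty")
    if effort <= 0:
        raise ValueError("effort must be positive")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cat = pool if "vulnerability_cat" in pool.columns else categorize_species(pool)
    alpha = kwargs.pop("alpha_guild", None) or {g: -1.8 for g in GUILDS}
    p = inclusion_probabilities(
        estuary, cat, planted_effects, effort, driver_means or {}, alpha, **kwargs
    )
    include = rng.random(len(pool)) < p
    if not include.any():
        include[rng.integers(len(pool))] = True
    return list(pool.loc[include, "taxon_id"])


def generate_world(config: WorldConfig) -> World:
    """Generate a full world from one config; deterministic in the seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_env, rng_sp, rng_pr, rng_pa, rng_sam = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    estuaries = generate_environment(
        config.n_estuaries, config.grid, config.shelf_band_km, rng_env
    )
    species = generate_species_pool(
        config.n_species,
        config.guild_mix,
        config.vuln_marginals,
        config.resil_marginals,
        config.missing_rate,
        rng=rng_sp,
    )
    grids = generate_pressure_grids(
        config.grid,
        config.pressure_mean,
        config.pressure_sd,
        config.pressure_corr_range,
        config.shelf_band_km,
        rng=rng_pr,
    )
    pa = generate_protected_areas(
        config.grid, config.pa_coverage, config.pa_strict_fraction, rng=rng_pa
    )
    driver_means = {
        c: float(estuaries[c].mean())
        for c in estuaries.columns
        if estuaries[c].dtype.kind in "fi"
    }
    species_cat = categorize_species(species)
    # every estuary gets one sample; the remainder are assigned at random
    est_idx = np.concatenate(
        [
            np.arange(config.n_estuaries),
            rng_sam.integers(0, config.n_estuaries, config.n_samples - config.n_estuaries),
        ]
    )
    lo, hi = config.effort_range
    efforts = np.exp(rng_sam.uniform(np.log(lo), np.log(hi), config.n_samples))
    sample_rows = []
    occ_rows = []
    for i, (ei, effort) in enumerate(zip(est_idx, efforts)):
        estuary = estuaries.iloc[ei]
        sample_id = f"s{i:04d}"
        taxa = assemble_sample(
            estuary,
            species_cat,
            config.planted_effects,
            effort,
            rng=rng_sam,
            driver_means=driver_means,
            alpha_guild=config.alpha_guild,
            connectivity_tidal=config.connectivity_tidal,
            connectivity_type=config.connectivity_type,
            gamma_effort=config.gamma_effort,
            effort_ref=float(np.sqrt(lo * hi)),
        )
        sample_rows.append(
            {
                "sample_id": sample_id,
                "estuary_id": estuary["estuary_id"],
                "sampled_area_m2": effort,
            }
        )
        occ_rows.extend(
            {
                "sample_id": sample_id,
                "estuary_id": estuary["estuary_id"],
                "taxon_id": t,
            }
            for t in taxa
        )
    truth = {
        "seed": config.seed,
        "planted_effects": [dataclasses.asdict(e) for e in config.planted_effects],
        "driver_means": driver_means,
        "gamma_effort": config.gamma_effort,
    }
    return World(
        config=config,
        estuaries=estuaries,
        species=species,
        samples=pd.DataFrame(sample_rows),
        occurrences=pd.DataFrame(occ_rows),
        marine_impact=grids.marine_impact,
        population_density=grids.population_density,
        freshwater_threat=grids.freshwater_threat,
        ecosystem_class=grids.ecosystem_class,
        pa_class=pa,
        driver_means=driver_means,
        truth=truth,
    )
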