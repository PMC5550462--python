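"""End-to-end orchestration: simulate -> profile -> exposure -> protection ->
correlate -> model -> report, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import PRESSURE_COLUMNS, PressureGrids, exposure_table
from .grids import read_ascii_grid
from .inference import (
    build_analysis_table,
    pearson_matrix,
    trait_environment_models,
    trait_pressure_correlations,
)
from .protection import PROTECTION_PCT_COLUMNS, protection_table
from .synthetic import WorldConfig, generate_world
from .traits import PROFILE_COLUMNS, RESPONSE_COLUMNS, profile_samples

logger = logging.getLogger(__name__)

STAGES = ("simulate", "profile", "exposure", "protection", "correlate", "model")

INPUT_TABLES = ("estuaries.csv", "species.csv", "samples.csv", "occurrences.csv")
INPUT_RASTERS = (
    "marine_impact.asc",
    "population_density.asc",
    "freshwater_threat.asc",
    "ecosystem_class.asc",
    "pa_class.asc",
)


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; round-trips through YAML."""

    input_dir: str = "."
    output_dir: str = "out"
    simulate: bool = True
    world: WorldConfig = field(default_factory=WorldConfig)
    denominator_mode: str = "total"
    alpha: float = 0.05
    criterion: str = "aicc"
    importance_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.world, dict):
            self.world = WorldConfig.from_dict(self.world)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"] = self.world.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(stage, f"missing input file: {path}")
    return path


def load_inputs(input_dir: str | Path) -> dict:
    """Load the input tables and rasters a non-simulated run consumes."""
    d = Path(input_dir)
    data = {
        name.split(".")[0]: pd.read_csv(_require(d / name, "load"))
        for name in INPUT_TABLES
    }
    spec = None
    for name in INPUT_RASTERS:
        arr, gspec = read_ascii_grid(_require(d / name, "load"))
        data[name.split(".")[0]] = arr
        spec = gspec
    data["grid"] = spec
    truth_path = d / "truth.json"
    data["truth"] = json.loads(truth_path.read_text()) if truth_path.exists() else None
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns the manifest dict.

    Every output CSV, the report and the manifest land in
    ``config.output_dir``; the manifest records per-stage row counts and the
    config hash so identical config+seed runs are identical byte-for-byte.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": [],
        "warnings": [],
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    if config.simulate:
        wc = dataclasses.replace(config.world, seed=config.seed)
        world = generate_world(wc)
        written = world.write(out / "world")
        manifest["outputs"] += [f"world/{w}" for w in written]
        estuaries, species = world.estuaries, world.species
        samples, occurrences = world.samples, world.occurrences
        grids = world.pressure_grids()
        pa, eco, gspec = world.pa_class, world.ecosystem_class, wc.grid
        truth = world.truth
        record(
            "simulate",
            n_estuaries=len(estuaries),
            n_species=len(species),
            n_samples=len(samples),
            n_occurrences=len(occurrences),
        )
    else:
        data = load_inputs(config.input_dir)
        estuaries, species = data["estuaries"], data["species"]
        samples, occurrences = data["samples"], data["occurrences"]
        gspec = data["grid"]
        grids = PressureGrids(
            data["marine_impact"].astype(float),
            data["population_density"].astype(float),
            data["freshwater_threat"].astype(float),
            data["ecosystem_class"],
            gspec,
        )
        pa, eco = data["pa_class"], data["ecosystem_class"]
        truth = data["truth"]
        record("simulate", skipped=True)

    def save(name: str, df: pd.DataFrame) -> None:
        df.to_csv(out / name, index=False, float_format="%.10g")
        manifest["outputs"].append(name)

    try:
        profiles, guilds = profile_samples(
            occurrences, species, samples, config.denominator_mode
        )
        save("trait_profiles.csv", profiles)
        save("guilds.csv", guilds)
        record("profile", n_samples=len(profiles))
    except Exception as exc:  # noqa: BLE001
        raise StageError("profile", str(exc)) from exc

    try:
        exposure = exposure_table(estuaries, grids, guilds)
        save("exposure.csv", exposure)
        record("exposure", n_rows=len(exposure))
    except Exception as exc:  # noqa: BLE001
        raise StageError("exposure", str(exc)) from exc

    try:
        protection = protection_table(estuaries, pa, eco, gspec)
        save("protection.csv", protection)
        record("protection", n_rows=len(protection))
    except Exception as exc:  # noqa: BLE001
        raise StageError("protection", str(exc)) from exc

    try:
        env_cols = [
            "latitude",
            "sst",
            "ter_npp",
            "mar_chl",
            "shelf_width_km",
            "estuary_area_km2",
            "basin_area_km2",
            "mouth_width_km",
        ]
        merged = (
            exposure.merge(estuaries, on="estuary_id")
            .merge(protection, on="estuary_id", suffixes=("", "_prot"))
        )
        norm_cols = [f"{c}_norm" for c in PRESSURE_COLUMNS]
        pa_cols = [c for c in PROTECTION_PCT_COLUMNS if c in merged.columns]
        corr = pearson_matrix(
            merged,
            rows=[c for c in env_cols if c in merged.columns] + norm_cols + pa_cols,
            alpha=config.alpha,
        )
        save("correlations.csv", corr.formatted().reset_index(names="variable"))
        tp = trait_pressure_correlations(profiles, exposure, protection, config.alpha)
        save("trait_pressure_correlations.csv", tp.formatted().reset_index(names="trait"))
        record("correlate", n_vars=len(corr.r))
    except Exception as exc:  # noqa: BLE001
        raise StageError("correlate", str(exc)) from exc

    try:
        analysis = build_analysis_table(profiles, estuaries, samples)
        models = trait_environment_models(analysis, criterion=config.criterion)
        save("model_table.csv", models.table)
        save("model_summary.csv", models.summary)
        save("model_important.csv", models.important(config.importance_threshold))
        record("model", n_rows=len(models.table), n_samples=len(analysis))
    except Exception as exc:  # noqa: BLE001
        raise StageError("model", str(exc)) from exc

    report = make_report(
        profiles, corr, tp, models, truth, threshold=config.importance_threshold
    )
    (out / "report.txt").write_text(report)
    manifest["outputs"].append("report.txt")

    manifest["outputs"].append("manifest.json")
    manifest_path = out / "manifest.json"
    tmp = manifest_path.with_suffix(".tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    tmp.replace(manifest_path)
    return manifest


def make_report(
    profiles: pd.DataFrame,
    correlations,
    trait_corr,
    models,
    truth: dict | None = None,
    threshold: float = 0.5,
) -> str:
    """Human-readable summary: trait-frequency table, correlation matrices,
    model battery, and (when truth is available) a recovery scorecard."""
    lines: list[str] = []
    lines.append("Trait-category relative taxa richness (%, mean and SD across samples)")
    for trait, cols in PROFILE_COLUMNS.items():
        for col in cols:
            m = 100 * profiles[col].mean()
            s = 100 * profiles[col].std()
            lines.append(f"  {col:10s} mean {m:5.1f}  sd {s:5.1f}")
    lines.append("")
    lines.append("Environment / pressure / protection Pearson correlations (ns-masked)")
    lines.append(correlations.formatted().to_string())
    lines.append("")
    lines.append("Trait vs pressure/protection Pearson correlations (ns-masked)")
    lines.append(trait_corr.formatted().to_string())
    lines.append("")
    lines.append("Model summaries (per response and variant)")
    lines.append(models.summary.round(3).to_string(index=False))
    lines.append("")
    lines.append(f"Predictors with linear-model importance I > {threshold}")
    imp = models.important(threshold)
    lines.append(
        imp[["response", "variant", "predictor", "C", "lmg_pct", "I_lm", "I_mm"]]
        .round(3)
        .to_string(index=False)
    )
    if truth and truth.get("planted_effects"):
        lines.append("")
        lines.append("Planted-effect recovery scorecard")
        t = models.table
        for eff in truth["planted_effects"]:
            cat, drv, beta = eff["category"], eff["driver"], eff["beta"]
            sub = t[(t["response"] == cat) & (t["predictor"] == drv)]
            for _, row in sub.iterrows():
                sign_ok = np.sign(row["C"]) == np.sign(beta) if beta != 0 else True
                lines.append(
                    f"  {cat} ~ {drv} (beta={beta:+.3g}) [{row['variant']}]: "
                    f"C={row['C']:+.4f} sign_ok={bool(sign_ok)} "
                    f"I_lm={row['I_lm']:.2f} I_mm={row['I_mm']:.2f}"
                )
    return "\n".join(lines) + "\n"
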