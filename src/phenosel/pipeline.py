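"""End-to-end runner: config to selection tables, report and manifest.

A run either simulates a dataset (synthetic mode) or loads census, shoot
and fruit CSVs (real mode), estimates per-plant traits and fitness,
applies the completeness filter, and fits every model family for every
year under both standardization schemes, with BCa bootstrap intervals.
Identical config and seed give byte-identical output CSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bootstrap import BootstrapConfig
from .fitness import PredationModel, attach_fitness
from .phenology import estimate_plant_seasons
from .report import render_table1, selection_tables_frame
from .selection import (
    MODEL_FAMILIES,
    SCHEMES,
    compare_direct_vs_total,
    fit_selection_model,
    pearson_correlation,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = ["run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

_SIM_FIELDS = {f.name for f in fields(SimulationConfig)}
_CSV_KEYS = ("census_csv", "fruits_csv", "shoots_csv")


def load_config(path) -> dict:
    """Read a plain-text ``key: value`` (YAML-compatible) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} did not parse to a key:value mapping")
    return cfg


def _stable_seed(base_seed: int, *parts) -> int:
    digest = hashlib.sha256("|".join(str(p) for p in (base_seed, *parts)).encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _load_inputs(cfg: dict) -> dict[str, pd.DataFrame]:
    synthetic = cfg.get("synthetic")
    csv_keys_present = [k for k in _CSV_KEYS if k in cfg]
    if synthetic is not None and csv_keys_present:
        raise ValueError(
            "config mixes synthetic mode with CSV inputs "
            f"({csv_keys_present}); choose one"
        )
    if synthetic is not None:
        unknown = set(synthetic) - _SIM_FIELDS
        if unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
        for key in ("year_labels", "leaflet_count_range"):
            if key in synthetic and isinstance(synthetic[key], list):
                synthetic[key] = tuple(synthetic[key])
        sim_cfg = SimulationConfig(**synthetic)
        tables = simulate_dataset(sim_cfg)
        tables["simulation_config"] = sim_cfg
        return tables
    if not csv_keys_present:
        raise ValueError("config must contain either a 'synthetic' section or CSV inputs")
    tables = {}
    for key, name in zip(_CSV_KEYS, ("census", "fruits", "shoots")):
        if key not in cfg:
            if key == "shoots_csv":
                tables["shoots"] = None
                continue
            raise ValueError(f"missing required input {key!r} in config")
        path = Path(cfg[key])
        if not path.exists():
            raise FileNotFoundError(f"input file not found: {path} (config key {key!r})")
        tables[name] = pd.read_csv(path)
    return tables


def _completeness_filter(seasons: pd.DataFrame) -> pd.DataFrame:
    """Keep plant-seasons with complete trait, size and fitness records."""
    ok = (
        seasons["leaf_out_day"].notna()
        & seasons["first_flowering_day"].notna()
        & seasons["aboveground_volume"].notna()
        & (seasons["aboveground_volume"] > 0)
        & seasons["fitness_intact_seeds"].notna()
    )
    return seasons[ok].reset_index(drop=True)


def run_pipeline(config, outdir) -> Path:
    """Run the full analysis described by ``config`` into ``outdir``.

    ``config`` is a dict or a path to a key:value config file.  Recognized
    keys: ``synthetic`` (SimulationConfig fields) or
    ``census_csv``/``fruits_csv``/``shoots_csv``; plus ``schemes``,
    ``n_replicates``, ``confidence_level``, ``seed``, ``include_size``,
    ``double_interaction``, ``predation_rate_constant``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    schemes = tuple(config.get("schemes", SCHEMES))
    bad = [s for s in schemes if s not in SCHEMES]
    if bad:
        raise ValueError(f"unknown scheme(s) {bad}; choose from {SCHEMES}")
    n_replicates = int(config.get("n_replicates", 10_000))
    level = float(config.get("confidence_level", 0.95))
    base_seed = int(config.get("seed", 0))
    include_size = bool(config.get("include_size", True))
    double_interaction = bool(config.get("double_interaction", False))
    rate_constant = float(config.get("predation_rate_constant", PredationModel().rate_constant))

    run_warnings: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        tables = _load_inputs(config)
        seasons = estimate_plant_seasons(tables["census"], tables.get("shoots"))
        seasons = attach_fitness(
            seasons, tables["fruits"], PredationModel(rate_constant=rate_constant)
        )
        analysis = _completeness_filter(seasons)
        if len(analysis) == 0:
            raise ValueError("no complete plant-season records after filtering")

        seasons.to_csv(out / "plant_seasons_all.csv", index=False)
        analysis.to_csv(out / "plant_seasons.csv", index=False)

        years = list(pd.unique(analysis["year"]))

        selection_tables = []
        comparisons = []
        for scheme in schemes:
            for year in years:
                fits = {}
                for family in MODEL_FAMILIES:
                    boot = BootstrapConfig(
                        n_replicates=n_replicates,
                        confidence_level=level,
                        rng_seed=_stable_seed(base_seed, scheme, year, family),
                    )
                    fits[family] = fit_selection_model(
                        analysis,
                        family,
                        year=year,
                        scheme=scheme,
                        include_size=include_size,
                        bootstrap=boot,
                        double_interaction=double_interaction,
                    )
                selection_tables.extend(fits.values())
                for family, term in (
                    ("total_leafout", "leaf_out_day"),
                    ("total_ffd", "first_flowering_day"),
                ):
                    cmp_result = compare_direct_vs_total(
                        fits["direct_linear"], fits[family], term=term
                    )
                    comparisons.append(
                        {
                            "scheme": scheme,
                            "year": year,
                            "term": term,
                            "direct_estimate": cmp_result.direct_estimate,
                            "total_bca_lower": cmp_result.total_interval[0],
                            "total_bca_upper": cmp_result.total_interval[1],
                            "differs": cmp_result.differs,
                            "interpretation": cmp_result.interpretation,
                        }
                    )

        long_frame = selection_tables_frame(selection_tables)
        long_frame.to_csv(out / "selection_tables.csv", index=False)
        pd.DataFrame(comparisons).to_csv(out / "comparisons.csv", index=False)

        corr_rows = []
        for year in years:
            sub = analysis[analysis["year"] == year]
            ct = pearson_correlation(sub["leaf_out_day"], sub["first_flowering_day"])
            corr_rows.append(
                {"year": year, "n": len(sub), "r": ct.r, "t": ct.t, "df": ct.df, "p": ct.p}
            )
        pd.DataFrame(corr_rows).to_csv(out / "correlations.csv", index=False)

        for scheme in schemes:
            scheme_tables = [t for t in selection_tables if t.scheme == scheme]
            frame, text = render_table1(scheme_tables)
            frame.to_csv(out / f"table1_{scheme}.csv", index=False)
            (out / f"table1_{scheme}.txt").write_text(text + "\n")

        plot = analysis[
            [
                "individual_id",
                "year",
                "leaf_out_day",
                "first_flowering_day",
                "development_time",
                "fitness_intact_seeds",
            ]
        ].copy()
        plot.to_csv(out / "plot_data.csv", index=False)

        run_warnings.extend(str(c.message) for c in caught)
        for table in selection_tables:
            run_warnings.extend(table.warnings)

    config_for_digest = {k: v for k, v in config.items()}
    digest = hashlib.sha256(
        json.dumps(config_for_digest, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "phenosel_version": __version__,
        "config_digest": digest,
        "seed": base_seed,
        "n_replicates": n_replicates,
        "confidence_level": level,
        "schemes": list(schemes),
        "include_size": include_size,
        "double_interaction": double_interaction,
        "predation_rate_constant": rate_constant,
        "n_per_year": {str(y): int((analysis["year"] == y).sum()) for y in years},
        "warnings": sorted(set(run_warnings)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    for w in manifest["warnings"]:
        logger.warning(w)
    return out
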