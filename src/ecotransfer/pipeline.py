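"""Pipeline orchestration: simulate-or-load, corrections, summaries,
relative-distribution comparison, robust correlation, concentration ratios,
and threshold screening, written as seed-stamped CSVs plus a manifest.

Every output CSV starts with a ``# seed=<seed>`` comment line; two runs with
equal configuration produce byte-identical files (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    CohortDataset,
    DEFAULT_NUCLIDES,
    default_transfer_config,
    read_cohort,
    read_soil,
    write_cohort,
)
from .permutation import paired_signflip_test
from .robustcorr import RobustCorrelation
from .screening import screen_thresholds
from .simulate import SimulationParams, generate_cohort
from .summaries import relative_to_muscle, spearman_matrix, summary_table
from .transfer import cr_frame, cr_table

__all__ = ["RunConfig", "run_pipeline", "compare_relative_distributions"]

logger = logging.getLogger(__name__)

ALL_STAGES = ("cohort", "summaries", "relative", "spearman", "robustcorr", "cr", "screen")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    When ``animals_csv``/``measurements_csv`` are unset a synthetic cohort is
    generated with ``n_animals`` and ``seed``; ``soil_csv`` defaults to the
    packaged synthetic soil-reference table.
    """

    out_dir: str | Path = "ecotransfer_run"
    seed: int = 0
    n_animals: int = 10
    animals_csv: str | None = None
    measurements_csv: str | None = None
    soil_csv: str | None = None
    censoring: str = "drop"
    n_chains: int = 4
    n_draws: int = 1000
    n_tune: int = 500
    n_permutations: int = 10_000
    analogue_pairs: dict = field(default_factory=lambda: {"Cs137": "Cs", "Pb210": "Pb"})
    spearman_analytes: tuple = ("Cs137", "Cd", "Pb")
    cr_analytes: tuple = ("Cs137", "Pb210", "Cd", "Pb")
    stages: tuple = ALL_STAGES


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def compare_relative_distributions(
    dataset: CohortDataset,
    radionuclide: str,
    stable: str,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Paired sign-flip comparison of two analytes' relative-to-muscle
    distributions, one test per non-muscle tissue.

    The paired difference for each animal is (percent of muscle for the
    radionuclide) minus (percent of muscle for the stable analogue); the
    reported statistic is the mean difference (Delta-mean) with its two-sided
    sign-flip p-value.
    """
    rel_rad = relative_to_muscle(dataset, radionuclide)
    rel_stable = relative_to_muscle(dataset, stable)
    rows = []
    for tissue in sorted(set(rel_rad) & set(rel_stable) - {"muscle"}):
        a = dict(zip(rel_rad[tissue].animal_ids, rel_rad[tissue].per_animal_percent))
        b = dict(zip(rel_stable[tissue].animal_ids, rel_stable[tissue].per_animal_percent))
        common = sorted(set(a) & set(b))
        if len(common) < 2:
            continue
        diffs = [a[i] - b[i] for i in common]
        res = paired_signflip_test(diffs, n_permutations=n_permutations, seed=seed)
        rows.append(
            {
                "tissue": tissue,
                "n": len(common),
                "delta_mean": res.statistic_observed,
                "p_value": res.p_value,
                "method": res.method,
                "n_permutations_used": res.n_permutations_used,
            }
        )
    return pd.DataFrame(
        rows, columns=["tissue", "n", "delta_mean", "p_value", "method", "n_permutations_used"]
    )


def _load_or_simulate(config: RunConfig) -> CohortDataset:
    if config.animals_csv and config.measurements_csv:
        ds = read_cohort(config.animals_csv, config.measurements_csv)
        logger.info("loaded cohort: %d animals, %d measurements", len(ds.animals), len(ds.measurements))
        return ds
    ds = generate_cohort(SimulationParams(n_animals=config.n_animals, seed=config.seed))
    logger.info("simulated cohort: %d animals, %d measurements", len(ds.animals), len(ds.measurements))
    return ds


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages and return the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    stage = "cohort"
    try:
        dataset = _load_or_simulate(config)
        if "cohort" in config.stages:
            write_cohort(dataset, out / "animals.csv", out / "measurements.csv")

        if "summaries" in config.stages:
            stage = "summaries"
            df = summary_table(dataset, policy=config.censoring)
            _write_csv(df, out / "summary.csv", seed)
            logger.info("summaries: %d cells", len(df))

        if "relative" in config.stages:
            stage = "relative"
            frames = []
            for rad, stable in config.analogue_pairs.items():
                try:
                    cmp_df = compare_relative_distributions(
                        dataset, rad, stable, config.n_permutations, seed
                    )
                except Exception as exc:  # pair absent from this dataset
                    logger.warning("relative comparison %s vs %s skipped: %s", rad, stable, exc)
                    continue
                cmp_df.insert(0, "stable", stable)
                cmp_df.insert(0, "radionuclide", rad)
                frames.append(cmp_df)
            if frames:
                _write_csv(pd.concat(frames, ignore_index=True), out / "relative_tests.csv", seed)

        if "spearman" in config.stages:
            stage = "spearman"
            for analyte in config.spearman_analytes:
                mat = spearman_matrix(dataset, analyte)
                if mat.empty:
                    continue
                _write_csv(mat.reset_index(names="tissue"), out / f"spearman_{analyte}.csv", seed)

        if "robustcorr" in config.stages:
            stage = "robustcorr"
            rows = []
            mdf = dataset.measurements_frame()
            for rad, stable in config.analogue_pairs.items():
                wide_r = mdf[(mdf["analyte"] == rad) & (~mdf["censored"])].pivot_table(
                    index="animal_id", columns="tissue", values="value"
                )
                wide_s = mdf[(mdf["analyte"] == stable) & (~mdf["censored"])].pivot_table(
                    index="animal_id", columns="tissue", values="value"
                )
                for tissue in sorted(set(wide_r.columns) & set(wide_s.columns)):
                    pair = pd.concat(
                        [wide_r[tissue], wide_s[tissue]], axis=1, keys=["r", "s"]
                    ).dropna()
                    if len(pair) < 3:
                        continue
                    est = RobustCorrelation(
                        n_chains=config.n_chains,
                        n_draws=config.n_draws,
                        n_tune=config.n_tune,
                        seed=seed,
                    ).fit(pair["r"].to_numpy(), pair["s"].to_numpy())
                    rows.append(
                        {
                            "radionuclide": rad,
                            "stable": stable,
                            "tissue": tissue,
                            "n": len(pair),
                            "rho_mean": est.rho_mean_,
                            "hdi_low": est.hdi_low_,
                            "hdi_high": est.hdi_high_,
                            "rhat_max": est.rhat_max_,
                            "ess_min": est.ess_min_,
                        }
                    )
            _write_csv(pd.DataFrame(rows), out / "robust_correlation.csv", seed)

        if "cr" in config.stages:
            stage = "cr"
            soil_path = config.soil_csv
            if soil_path is None:
                soil_path = importlib.resources.files("ecotransfer.data") / (
                    "synthetic_soil_reference.csv"
                )
            elif not Path(soil_path).exists():
                raise FileNotFoundError(f"soil table not found: {soil_path}")
            soil = read_soil(soil_path)
            results = cr_table(
                dataset, config.cr_analytes, default_transfer_config(), soil, DEFAULT_NUCLIDES
            )
            _write_csv(cr_frame(results), out / "cr_table.csv", seed)

        if "screen" in config.stages:
            stage = "screen"
            _write_csv(screen_thresholds(dataset), out / "screening.csv", seed)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "ecotransfer",
        "version": __version__,
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "out_dir"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
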