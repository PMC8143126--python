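"""End-to-end pipeline runner: simulate -> estimate -> compare -> model.

:func:`run_pipeline` executes every stage into a run directory and writes a
manifest recording the configuration hash, the master seed, the derived
per-stage seeds, and a checksum for every output file. The same configuration
and seed always reproduce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import albedo, albedo_stats, slopes, synthetic, thermal
from .config import DEFAULT_PROVENANCE, PipelineConfig

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "estimate_albedo",
    "compare_albedo",
    "assemble",
    "fit_models",
    "compare_slopes",
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Derive one deterministic sub-seed per stage from the master seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s & 0x7FFFFFFF) for name, s in zip(STAGES, state)}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory.

    Stage order: simulate (winter scenes + thermal tables), estimate-albedo,
    compare-albedo, assemble, fit-models for both responses, compare-slopes.
    Any stage failure aborts with the stage name and cause.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    gray_weights = albedo.LUMINANCE_WEIGHTS if config.gray_rule == "luminance" else None
    outputs: dict[str, list[str]] = {stage: [] for stage in STAGES}

    def record(stage: str, path: Path) -> None:
        outputs[stage].append(path.name)

    current = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        images, mask_sets = [], []
        for i in range(config.n_replicate_images):
            spec = synthetic.SceneSpec(
                noise_sd=config.image_noise_sd, seed=seeds["simulate"] + i
            )
            image, masks, truth = synthetic.generate_winter_image(spec)
            images.append(image)
            mask_sets.append(masks)
            albedo.write_image(out / f"scene_{i}.png", image)
            albedo.write_mask_set(
                out / f"scene_{i}_labels.png", out / f"scene_{i}_labels.yaml", masks
            )
            synthetic.write_truth(out / f"scene_{i}_truth.txt", truth)
            for name in (f"scene_{i}.png", f"scene_{i}_labels.png",
                         f"scene_{i}_labels.yaml", f"scene_{i}_truth.txt"):
                record("simulate", out / name)
        model_params = synthetic.ThermalGenParams(
            n=config.n_observations, mode="model",
            noise_sd=config.noise_sd, seed=seeds["simulate"],
        )
        obs, cov, truth = synthetic.generate_thermal_observations(model_params)
        _write_csv(obs, out / "observations.csv")
        _write_csv(cov, out / "covariates.csv")
        synthetic.write_truth(out / "thermal_truth.txt", truth)
        slope_params = synthetic.ThermalGenParams(
            n=config.n_observations, mode="slope",
            noise_sd=config.slope_noise_sd, seed=seeds["simulate"] + 1,
        )
        slope_obs, slope_cov, slope_truth = synthetic.generate_thermal_observations(
            slope_params
        )
        _write_csv(slope_obs, out / "slope_observations.csv")
        synthetic.write_truth(out / "slope_truth.txt", slope_truth)
        for name in ("observations.csv", "covariates.csv", "thermal_truth.txt",
                     "slope_observations.csv", "slope_truth.txt"):
            record("simulate", out / name)

        # --- estimate-albedo ----------------------------------------------
        current = "estimate_albedo"
        estimator = albedo.SnowReferencedAlbedo(
            snow_ref=config.snow_ref, gray_weights=gray_weights
        ).fit(images, mask_sets)
        estimates = albedo.estimates_to_frame(estimator.estimates_)
        _write_csv(estimates, out / "albedo_estimates.csv")
        _write_csv(estimator.replicate_summary_, out / "albedo_replicates.csv")
        record("estimate_albedo", out / "albedo_estimates.csv")
        record("estimate_albedo", out / "albedo_replicates.csv")

        # --- compare-albedo -----------------------------------------------
        current = "compare_albedo"
        cows = estimates[estimates["label"] != "snow"]
        report = albedo_stats.compare_albedo_groups(cows, alpha=config.alpha)
        _write_csv(report.contrasts, out / "albedo_contrasts.csv")
        letters = pd.DataFrame(
            {"color": list(report.letters), "letter": list(report.letters.values())}
        )
        _write_csv(letters, out / "albedo_letters.csv")
        record("compare_albedo", out / "albedo_contrasts.csv")
        record("compare_albedo", out / "albedo_letters.csv")

        # --- assemble -----------------------------------------------------
        current = "assemble"
        merged = thermal.assemble_dataset(obs, cov)
        slope_merged = thermal.assemble_dataset(slope_obs, slope_cov)
        _write_csv(merged, out / "merged.csv")
        record("assemble", out / "merged.csv")

        # --- fit-models (both responses) ----------------------------------
        current = "fit_models"
        for response in ("temp_cow", "delta_t"):
            selector = thermal.StagedAICcSelector(
                response=response,
                weather_candidates=config.weather_candidates,
                radiation_candidates=config.radiation_candidates,
                correlation_threshold=config.correlation_threshold,
                drop_preference=config.drop_preference,
            ).fit(merged)
            ledger = pd.concat(
                [
                    step.table.assign(step=step.name)
                    for step in selector.report_.steps
                ],
                ignore_index=True,
            )
            _write_csv(ledger, out / f"selection_{response}.csv")
            coef = selector.final_fit_.conf_int.copy()
            coef.insert(0, "estimate", selector.final_fit_.params)
            coef = coef.reset_index(names="term")
            coef["informative"] = coef["term"].map(
                lambda t: selector.ci_flags_.get(t, pd.NA)
            )
            _write_csv(coef, out / f"coefficients_{response}.csv")
            _write_csv(
                selector.pruning_report_, out / f"pruning_{response}.csv"
            )
            for name in (f"selection_{response}.csv", f"coefficients_{response}.csv",
                         f"pruning_{response}.csv"):
                record("fit_models", out / name)

        # --- compare-slopes -----------------------------------------------
        current = "compare_slopes"
        analyzer = slopes.ColorSlopeAnalyzer().fit(slope_merged)
        fit_rows = pd.DataFrame(
            [
                {
                    "color": f.color,
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "slope_se": f.slope_se,
                    "r_squared": f.r_squared,
                    "p_value": f.p_value,
                    "n": f.n,
                }
                for f in analyzer.fits_.values()
            ]
        )
        _write_csv(fit_rows, out / "slope_fits.csv")
        _write_csv(analyzer.report_.pairwise, out / "slope_pairwise.csv")
        tests = pd.DataFrame(
            {
                "test": ["ancova_interaction", "levene", "kruskal_wallis"],
                "statistic": [
                    analyzer.report_.interaction_f,
                    analyzer.report_.levene_stat,
                    analyzer.report_.kruskal_h,
                ],
                "p_value": [
                    analyzer.report_.interaction_p,
                    analyzer.report_.levene_p,
                    analyzer.report_.kruskal_p,
                ],
            }
        )
        _write_csv(tests, out / "slope_tests.csv")
        for name in ("slope_fits.csv", "slope_pairwise.csv", "slope_tests.csv"):
            record("compare_slopes", out / name)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    # --- manifest ---------------------------------------------------------
    config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [
            {
                "name": stage,
                "outputs": {
                    name: _sha256(out / name) for name in outputs[stage]
                },
            }
            for stage in STAGES
        ],
        "default_provenance": DEFAULT_PROVENANCE,
    }
    (out / "config.yaml").write_text(config_yaml)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
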