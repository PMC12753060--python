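"""End-to-end orchestration: simulate -> exclude -> analyze -> fit -> compare.

Every stage draws its seed deterministically from the master seed via a
fixed counter scheme, the full configuration is serialized into the run
manifest (with a content hash stamped on every output), and stage timings
plus warning counters are logged to both the console and a run log file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import fitting, psychometrics, synthetic_data
from .observers import ModelTag, ObserverParams

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger("priorcfc")

_STAGES = ("calibrate", "design", "simulate", "fit", "recover")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: master seed combined with the stage's fixed counter."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % (2**31)
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative run configuration (see docs for the schema)."""

    seed: int = 1
    model: str = "wppce"
    sigma_p: float = 30.0
    sigma_l: float = 15.0
    w: float = 1.0
    alpha: float = 0.34
    sigma_n: float = 0.1
    sigma_t: float = 0.05
    repetitions: int = 24
    use_asa: bool = True
    model_set: tuple[str, ...] = ("bayes", "dist", "dp", "pce", "wppce", "ec")
    n_sim: int = 10_000
    run_recovery: bool = False
    recovery_datasets: int = 5
    recovery_repetitions: int = 8
    recovery_n_sim: int = 2000
    out_dir: str = "run"

    def observer_params(self) -> ObserverParams:
        return ObserverParams(
            sigma_p=self.sigma_p,
            sigma_l=self.sigma_l,
            w=self.w,
            alpha=self.alpha,
            sigma_n=self.sigma_n,
            sigma_t=self.sigma_t,
        )

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_json(path: Path, payload: dict, config_hash: str) -> None:
    payload = {"config_hash": config_hash, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = config.digest()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    warnings_counter: dict[str, int] = {}
    timings: dict[str, float] = {}

    try:
        params = config.observer_params()
        model = ModelTag(config.model)

        t0 = time.perf_counter()
        if config.use_asa:
            rng = np.random.default_rng(stage_seed(config.seed, "calibrate"))
            settings, fits, staircases = synthetic_data.calibrate_settings(
                model, params, rng
            )
            warnings_counter["clipped_staircases"] = sum(
                r.clipped for runs in staircases.values() for r in runs
            )
        else:
            settings = synthetic_data.ideal_stimulus_levels(model, params)
        timings["calibrate"] = time.perf_counter() - t0
        logger.info("calibrated 8 stimulus levels (%.2fs)", timings["calibrate"])

        t0 = time.perf_counter()
        design_rng = np.random.default_rng(stage_seed(config.seed, "design"))
        design = synthetic_data.build_trial_design(
            settings, config.repetitions, design_rng
        )
        trials = synthetic_data.simulate_dataset(
            design, model, params, stage_seed(config.seed, "simulate")
        )
        levels = synthetic_data.selected_levels_table(settings)
        synthetic_data.write_dataset(
            trials,
            out / "trials.csv",
            manifest={
                "config": dataclasses.asdict(config),
                "config_hash": config_hash,
                "n_trials": len(trials),
            },
            manifest_path=out / "manifest.json",
        )
        levels.to_csv(out / "selected_levels.csv", index=False, float_format="%.10g")
        timings["simulate"] = time.perf_counter() - t0
        logger.info("simulated %d trials (%.2fs)", len(trials), timings["simulate"])

        t0 = time.perf_counter()
        kept, report = psychometrics.apply_exclusions(trials, levels)
        _write_json(
            out / "exclusions.json",
            {
                "n_input": report.n_input,
                "n_slow_rt": report.n_slow_rt,
                "n_fast_rt": report.n_fast_rt,
                "n_bias_check": report.n_bias_check,
                "n_kept": report.n_kept,
                "flagged_settings": list(report.flagged_settings),
            },
            config_hash,
        )
        decisions = fitting.decisions_from_trials(kept)
        bias_fit = psychometrics.fit_symmetric_bias(decisions)
        cb = psychometrics.nonparametric_confidence_bias(kept)
        _write_json(
            out / "analysis.json",
            {
                "mu_bias": bias_fit.mu_bias,
                "sigma_bias": bias_fit.sigma_bias,
                "mu_nobias": bias_fit.mu_nobias,
                "sigma_nobias": bias_fit.sigma_nobias,
                "confidence_bias_pse": cb.mu_cb,
                "confidence_bias_sigma": cb.sigma_cb,
                "p_bias_at_matched_rates": cb.p_bias_at_zero,
            },
            config_hash,
        )
        timings["analyze"] = time.perf_counter() - t0
        logger.info("analysis done (%.2fs)", timings["analyze"])

        t0 = time.perf_counter()
        fit_seed = stage_seed(config.seed, "fit")
        results = fitting.fit_all_models(
            kept, config.model_set, n_sim=config.n_sim, seed=fit_seed
        )
        table, winner = fitting.compare_models(results)
        table.to_csv(out / "fits.csv", index=False, float_format="%.10g")
        _write_json(
            out / "comparison.json",
            {
                "winner": winner,
                "aic": {r.model_tag.value: r.aic for r in results},
                "fitted_parameters": {
                    r.model_tag.value: dataclasses.asdict(r.params) for r in results
                },
            },
            config_hash,
        )
        timings["fit"] = time.perf_counter() - t0
        logger.info("model comparison winner: %s (%.2fs)", winner, timings["fit"])

        if config.run_recovery:
            t0 = time.perf_counter()
            gen_params = {ModelTag(m): params for m in config.model_set}
            rec = fitting.model_recovery(
                config.model_set,
                gen_params,
                n_datasets=config.recovery_datasets,
                repetitions=config.recovery_repetitions,
                seed=stage_seed(config.seed, "recover"),
                n_sim=config.recovery_n_sim,
            )
            rec.confusion.to_csv(out / "recovery_confusion.csv")
            rec.mean_delta_aic.to_csv(
                out / "recovery_delta_aic.csv", float_format="%.6g"
            )
            timings["recover"] = time.perf_counter() - t0
            logger.info("recovery done (%.2fs)", timings["recover"])

        _write_json(
            out / "report.json",
            {"timings_s": timings, "warnings": warnings_counter},
            config_hash,
        )
    except Exception as exc:  # persist partial outputs with the failing stage
        _write_json(
            out / "report.json",
            {"error": str(exc), "timings_s": timings, "warnings": warnings_counter},
            config_hash,
        )
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
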