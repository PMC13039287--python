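"""End-to-end estimation pipeline: TAC -> NLS -> MCMC -> report.

Configuration is a flat dictionary (typically loaded from YAML).  Recognised
keys, all optional unless noted:

- ``input``: path to a TAC CSV, **or** ``scenario`` settings for a synthetic
  run: ``kf``, ``count_scale``, ``schedule`` ("ex_vivo" | "in_vivo" |
  "reduced"), plus the global ``seed``;
- ``fix_b`` (bool): pin the baseline B at zero (the simulation-study
  convention);
- ``bound_factor`` (default 5), ``chains`` (3), ``iters`` (10000),
  ``burn_in`` (1000), ``thin`` (1), ``prior_width`` (ln(5)/2),
  ``count_scale`` (from metadata when absent);
- ``seed`` (default 0).

The report is a plain JSON-serializable dict carrying estimates in mV,
R-hat values, diagnostics and provenance (seed, package version, config
hash).  A stage failure marks the report failed at that stage instead of
raising.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time

from . import __version__
from .fitting import default_initial_vector, fit_nls
from .io import TimeActivityCurve, read_tac
from .mcmc import DEFAULT_PRIOR_WIDTH, adaptive_metropolis, posterior_summary
from .simulate import (
    SimulationScenario,
    ex_vivo_times,
    generate_tac,
    in_vivo_frames,
    simulation_study_truth,
    scaled_times,
)

__all__ = ["run_pipeline", "load_config", "config_hash"]

logger = logging.getLogger("nernstfit")

_SCHEDULES = {
    "ex_vivo": lambda: dict(times=ex_vivo_times()),
    "in_vivo": lambda: dict(frames=in_vivo_frames()),
    "reduced": lambda: dict(times=scaled_times()),
}


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a canonical JSON rendering of the config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _obtain_tac(config: dict) -> TimeActivityCurve:
    if "input" in config:
        return read_tac(config["input"], normalize=True)
    if "scenario" not in config:
        raise ValueError("config must name an 'input' TAC or a 'scenario'")
    scen_cfg = dict(config["scenario"])
    schedule = scen_cfg.pop("schedule", "reduced")
    if schedule not in _SCHEDULES:
        raise ValueError(f"unknown schedule {schedule!r}")
    kf = float(scen_cfg.pop("kf", 2.0))
    scenario = SimulationScenario(
        truth=simulation_study_truth(kf=kf),
        count_scale=float(scen_cfg.pop("count_scale", 1e4)),
        seed=int(config.get("seed", 0)),
        **_SCHEDULES[schedule](),
    )
    if scen_cfg:
        raise ValueError(f"unknown scenario keys: {sorted(scen_cfg)}")
    return generate_tac(scenario)


def run_pipeline(config: dict) -> dict:
    """Execute NLS then MCMC on a configured input and return a report dict."""
    report: dict = {
        "status": "ok",
        "stages": {},
        "provenance": {
            "seed": int(config.get("seed", 0)),
            "version": __version__,
            "config_sha256": config_hash(config),
        },
    }
    stage = "load"
    try:
        t0 = time.perf_counter()
        logger.info("stage load: obtaining TAC")
        tac = _obtain_tac(config)
        report["stages"]["load"] = {
            "n_points": len(tac),
            "seconds": round(time.perf_counter() - t0, 3),
        }

        stage = "nls"
        t0 = time.perf_counter()
        logger.info("stage nls: least-squares fit")
        fixed = {"B": 0.0} if config.get("fix_b", False) else None
        fit = fit_nls(
            tac,
            init=default_initial_vector(),
            bound_factor=float(config.get("bound_factor", 5.0)),
            fixed=fixed,
        )
        report["stages"]["nls"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "converged": fit.converged,
            "degenerate": fit.degenerate,
            "cost": fit.cost,
            "estimates": fit.params,
            "cv": fit.cv,
        }

        stage = "mcmc"
        t0 = time.perf_counter()
        logger.info("stage mcmc: adaptive Metropolis sampling")
        chains = adaptive_metropolis(
            tac,
            fit,
            n_iter=int(config.get("iters", 10_000)),
            n_chains=int(config.get("chains", 3)),
            burn_in=int(config.get("burn_in", 1_000)),
            thin=int(config.get("thin", 1)),
            seed=int(config.get("seed", 0)),
            count_scale=config.get("count_scale"),
            prior_width=float(config.get("prior_width", DEFAULT_PRIOR_WIDTH)),
        )
        summary = posterior_summary(chains)
        report["stages"]["mcmc"] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "n_draws": summary.n_draws,
            "acceptance_rates": list(summary.acceptance_rates),
        }
        report["estimates_mv"] = {
            "Em": summary.mean["Em"],
            "dPsi_m": summary.mean["dPsi_m"],
        }
        report["posterior"] = {
            "mean": summary.mean,
            "median": summary.median,
            "sd": summary.sd,
            "map": summary.map,
        }
        report["rhat"] = summary.rhat
    except Exception as exc:  # noqa: BLE001 - report, don't crash the pipeline
        logger.exception("pipeline failed at stage %s", stage)
        report["status"] = "failed"
        report["failed_stage"] = stage
        report["error"] = f"{type(exc).__name__}: {exc}"
    return report
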