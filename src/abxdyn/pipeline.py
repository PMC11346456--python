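"""Full analysis pipeline: intervals -> half-life -> discovery -> dynamics.

Driven by a flat config dictionary with sections mirroring the module
names (``input`` or ``simulate``, ``intervals``, ``resistance``,
``discovery``, ``dynamics``, ``output``); every stage option has a
default, so a minimal config only names an input CSV or a simulation
block. The JSON report carries full provenance (input or simulation
config, seeds, software version, timestamp) so every number in it can be
recomputed from the report alone.
"""

from __future__ import annotations

import copy
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from . import __version__
from .discovery import DiscoveryParams, YearlyCounts, fit_discovery
from .dynamics import fit_resistance_detection, undetected_curve
from .errors import AbxdynError, PipelineError
from .resistance import fit_exponential_binned_poisson, fit_exponential_mle, half_life_ci
from .simulate import SimulationConfig, simulate_timelines
from .timeline import compute_intervals, read_timelines

logger = logging.getLogger("abxdyn")

SCHEMA_VERSION = "1"

DEFAULTS: dict[str, dict[str, Any]] = {
    "input": {"path": None},
    "simulate": None,  # set to a dict to simulate instead of reading a CSV
    "intervals": {"observation_year": None},
    "resistance": {
        "include_censored": False,  # panel-B default: histogram of realised times
        "binned": False,
        "bin_width": 5.0,
        "ci_level": 0.95,
        "n_boot": 1000,
        "seed": 0,
    },
    "discovery": {"k_max": 200, "t_lag_max": 60, "t0": None, "n_max": 50.0},
    "dynamics": {
        "mode": "per_class_hazard",
        "rate_convention": "half_life",
        "half_life": None,  # None -> fit from yearly first-resistance counts
    },
    "output": {"report": None, "curves": None},
}

SIMULATE_DEFAULTS: dict[str, Any] = {
    "k": 30, "n": 1.5, "t_lag": 28, "t0": 1900, "half_life": 15.0,
    "use_delay_mean": 8.0, "horizon_year": 2020, "observation_year": None,
    "seed": 0,
}


def merge_config(config: dict | None) -> dict:
    """Overlay a user config onto the defaults, section by section."""
    merged = copy.deepcopy(DEFAULTS)
    for section, values in (config or {}).items():
        if section not in merged:
            raise ValueError(f"unknown config section {section!r}")
        if values is None:
            continue
        if merged[section] is None:
            merged[section] = copy.deepcopy(SIMULATE_DEFAULTS) if section == "simulate" else {}
        for key, val in values.items():
            base = SIMULATE_DEFAULTS if section == "simulate" else DEFAULTS[section]
            if key not in base:
                raise ValueError(f"unknown config key {section}.{key}")
            merged[section][key] = val
    return merged


@dataclass
class PipelineReport:
    """Machine-readable summary of one pipeline run."""

    resistance_fit: dict
    discovery_fit: dict
    detection_fit: dict | None
    dynamics: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "resistance_fit": self.resistance_fit,
            "discovery_fit": self.discovery_fit,
            "detection_fit": self.detection_fit,
            "dynamics": self.dynamics,
            "provenance": self.provenance,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: dict | None = None) -> PipelineReport:
    """Execute intervals -> resistance fit (+CI) -> discovery fit ->
    dynamics curves; write the JSON report and tidy curves CSV if output
    paths are configured. Partial outputs are removed on failure."""
    cfg = merge_config(config)
    written: list[Path] = []
    try:
        with _stage("input"):
            if cfg["simulate"] is not None:
                s = cfg["simulate"]
                sim = SimulationConfig(
                    dparams=DiscoveryParams(k=int(s["k"]), n=float(s["n"]),
                                            t_lag=float(s["t_lag"]), t0=int(s["t0"])),
                    half_life=float(s["half_life"]),
                    use_delay_mean=float(s["use_delay_mean"]),
                    horizon_year=int(s["horizon_year"]),
                    observation_year=s["observation_year"],
                    seed=int(s["seed"]),
                )
                table = simulate_timelines(sim)
                source: dict[str, Any] = {"simulate": dict(s)}
                logger.info("simulated %d classes (seed %d)", len(table), sim.seed)
            else:
                path = cfg["input"]["path"]
                if path is None:
                    raise ValueError("config must set input.path or a simulate block")
                table = read_timelines(path)
                source = {"input_path": str(path)}
                logger.info("read %d classes from %s", len(table), path)

        with _stage("intervals"):
            obs = cfg["intervals"]["observation_year"]
            intervals = compute_intervals(table, observation_year=obs)
            logger.info("intervals: %d events, %d censored, observation year %d",
                        intervals.n_events, intervals.n_censored, intervals.observation_year)

        with _stage("resistance"):
            r = cfg["resistance"]
            if r["binned"]:
                rfit = fit_exponential_binned_poisson(intervals, bin_width=float(r["bin_width"]))
            else:
                rfit = fit_exponential_mle(intervals, include_censored=bool(r["include_censored"]))
            rfit.ci_half_life = half_life_ci(
                intervals, level=float(r["ci_level"]), n_boot=int(r["n_boot"]),
                seed=int(r["seed"]), include_censored=bool(r["include_censored"]),
            )
            logger.info("resistance half-life %.2f y (CI %.1f-%.1f)", rfit.half_life,
                        *rfit.ci_half_life)

        with _stage("discovery"):
            dcfg = cfg["discovery"]
            # the origin year anchors the lag; when simulating it is known,
            # otherwise it defaults to the first observed discovery year.
            t0 = dcfg["t0"]
            if t0 is None and cfg["simulate"] is not None:
                t0 = int(cfg["simulate"]["t0"])
            first_disc = int(table.discovery_years.min())
            window_start = first_disc if t0 is None else min(int(t0), first_disc)
            dcounts = YearlyCounts.from_years(
                table.discovery_years, start_year=window_start,
                end_year=intervals.observation_year)
            dfit = fit_discovery(dcounts, k_max=int(dcfg["k_max"]),
                                 t_lag_max=dcfg["t_lag_max"], t0=t0,
                                 n_max=float(dcfg["n_max"]))
            logger.info("discovery fit: k=%d n=%.3f/y t_lag=%.0f y (t0=%d)",
                        dfit.params.k, dfit.params.n, dfit.params.t_lag, dfit.params.t0)

        with _stage("dynamics"):
            dyn = cfg["dynamics"]
            detection_dict = None
            if dyn["half_life"] is not None:
                half_life = float(dyn["half_life"])
            else:
                rcounts = YearlyCounts.from_years(
                    table.resistance_years, start_year=dfit.params.t0,
                    end_year=intervals.observation_year)
                det = fit_resistance_detection(
                    rcounts, dfit, mode=dyn["mode"],
                    rate_convention=dyn["rate_convention"])
                detection_dict = det.to_dict()
                half_life = det.half_life
                logger.info("detection-side half-life %.2f y (%s)", half_life, dyn["mode"])
            years = list(range(dfit.params.t0, intervals.observation_year + 1))
            curve = undetected_curve(dfit.params, half_life, years, mode=dyn["mode"],
                                     rate_convention=dyn["rate_convention"])

        with _stage("output"):
            curves_path = cfg["output"]["curves"]
            if curves_path is not None:
                curve.to_frame().to_csv(curves_path, index=False)
                written.append(Path(curves_path))
            report = PipelineReport(
                resistance_fit=rfit.to_dict(),
                discovery_fit=dfit.to_dict(),
                detection_fit=detection_dict,
                dynamics={
                    "mode": dyn["mode"],
                    "half_life_used": half_life,
                    "curves_path": None if curves_path is None else str(curves_path),
                    "peak_undetected": float(curve.expected_undetected.max()),
                    "peak_undetected_year": int(
                        curve.years[int(curve.expected_undetected.argmax())]),
                },
                provenance={
                    "source": source,
                    "observation_year": intervals.observation_year,
                    "bootstrap_seed": int(cfg["resistance"]["seed"]),
                    "config": cfg,
                    "version": __version__,
                    "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
                },
            )
            report_path = cfg["output"]["report"]
            if report_path is not None:
                Path(report_path).write_text(report.to_json() + "\n", encoding="utf-8")
                written.append(Path(report_path))
        return report
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
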