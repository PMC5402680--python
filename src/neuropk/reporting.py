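"""Deterministic serialization of simulation results and run reports.

All numeric output is formatted to 9 significant digits so that re-running
an identical configuration reproduces byte-identical CSV and JSON files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .errors import NeuropkError
from .kinetics import CompartmentModel, SimulationResult

log = logging.getLogger("neuropk")

CSV_HEADER = "time_min,serum_ng_ml,excreted_ng,influx_ng,index"
_FMT = "%.9g"


def _sig9(value):
    """Round floats (recursively through containers) to 9 significant digits."""
    if isinstance(value, float):
        return float(_FMT % value)
    if isinstance(value, dict):
        return {k: _sig9(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_sig9(v) for v in value]
    return value


def timeseries_csv(result: SimulationResult) -> str:
    """The run's time series as CSV text with the canonical header."""
    lines = [CSV_HEADER]
    for row in zip(
        result.times, result.serum_conc, result.excreted_mass, result.influx_mass, result.index
    ):
        lines.append(",".join(_FMT % v for v in row))
    return "\n".join(lines) + "\n"


def run_report(
    result: SimulationResult, model: CompartmentModel, config_echo: dict | None = None
) -> dict:
    """JSON-serializable run report: resolved model echo plus diagnostics."""
    from .scenarios import _resolved_parameters

    report = {
        "model": _resolved_parameters(model),
        "steady_state": {
            "concentration_ng_ml": result.steady_state_conc,
            "time_min": result.steady_state_time,
        },
        "final": {
            "time_min": float(result.times[-1]),
            "serum_ng_ml": float(result.serum_conc[-1]),
            "excreted_ng": float(result.excreted_mass[-1]),
            "influx_ng": float(result.influx_mass[-1]),
        },
    }
    if config_echo is not None:
        report["config"] = config_echo
    return _sig9(report)


def write_outputs(
    result: SimulationResult,
    report: dict,
    outdir: str | Path,
    basename: str = "run",
) -> dict[str, Path]:
    """Write the time-series CSV, the report JSON, and a log line; returns
    the file set. Identical inputs yield byte-identical CSV/JSON."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / f"{basename}_timeseries.csv"
        json_path = outdir / f"{basename}_report.json"
        log_path = outdir / f"{basename}.log"
        csv_path.write_text(timeseries_csv(result))
        json_path.write_text(json.dumps(_sig9(report), indent=2, sort_keys=True) + "\n")
        log_path.write_text(
            f"wrote {csv_path.name} ({result.times.size} rows) and {json_path.name}\n"
        )
    except OSError as exc:
        raise NeuropkError(f"cannot write outputs to {outdir}: {exc}") from exc
    log.info("outputs written to %s", outdir)
    return {"csv": csv_path, "json": json_path, "log": log_path}


def write_scenario_report(report, outdir: str | Path) -> Path:
    """Serialize a ScenarioReport to JSON in ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{report.scenario_name}.json"
    path.write_text(json.dumps(_sig9(report.to_dict()), indent=2, sort_keys=True) + "\n")
    return path
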