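"""Joining model predictions against benchtop gas-exchange measurements.

Measured CO2 removal and oxygenation rates come in as a simple CSV
(columns flow_ml_min, vco2_obs_ml_min, vo2_obs_ml_min; either
observation column may be blank).  Flows are matched exactly against
simulated flows -- no interpolation -- and unsigned percent errors are
reported per flow and variant, with a max-error summary row per variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import percent_error

__all__ = ["ExperimentRecord", "read_experiment_csv", "compare_to_experiment"]


@dataclass(frozen=True)
class ExperimentRecord:
    """One benchtop operating point: flow plus measured exchange rates."""

    flow: float
    vco2_obs: float | None = None
    vo2_obs: float | None = None

    def __post_init__(self) -> None:
        if self.flow <= 0:
            raise ValueError(f"flow must be positive, got {self.flow}")
        if self.vco2_obs is None and self.vo2_obs is None:
            raise ValueError(
                f"experiment record at flow {self.flow} has no observations"
            )


def read_experiment_csv(path: str | Path) -> list[ExperimentRecord]:
    """Parse the experiment CSV into records."""
    df = pd.read_csv(path)
    required = {"flow_ml_min"}
    if not required <= set(df.columns):
        raise ValueError(f"experiment CSV must contain columns {sorted(required)}")
    records = []
    for _, row in df.iterrows():
        def opt(col: str) -> float | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return float(row[col])

        records.append(
            ExperimentRecord(
                flow=float(row["flow_ml_min"]),
                vco2_obs=opt("vco2_obs_ml_min"),
                vo2_obs=opt("vo2_obs_ml_min"),
            )
        )
    return records


def compare_to_experiment(
    results: pd.DataFrame, experiment: list[ExperimentRecord]
) -> pd.DataFrame:
    """Percent errors of predictions vs. measurements, flow-matched exactly.

    ``results`` is a results table (as from ``results_table``) with one
    row per (flow, variant).  Each experimental flow must appear among
    the simulated flows of every variant present; the returned frame has
    one row per (variant, flow) plus a ``max`` summary row per variant.
    """
    if not experiment:
        raise ValueError("no experiment records supplied")
    rows = []
    for variant, sub in results.groupby("variant", sort=False):
        sim_by_flow = {float(r.flow_ml_min): r for r in sub.itertuples()}
        errs_co2, errs_o2 = [], []
        for rec in experiment:
            if rec.flow not in sim_by_flow:
                raise ValueError(
                    f"no simulated flow matches experimental flow {rec.flow} mL/min "
                    f"for variant {variant!r} (simulated: {sorted(sim_by_flow)})"
                )
            sim = sim_by_flow[rec.flow]
            err_co2 = err_o2 = None
            if rec.vco2_obs is not None:
                err_co2 = percent_error(sim.vco2_flux_ml_min, rec.vco2_obs)
                errs_co2.append(err_co2)
            if rec.vo2_obs is not None:
                err_o2 = percent_error(sim.vo2_ml_min, rec.vo2_obs)
                errs_o2.append(err_o2)
            rows.append(
                {
                    "variant": variant,
                    "flow_ml_min": rec.flow,
                    "vco2_pred_ml_min": sim.vco2_flux_ml_min,
                    "vco2_obs_ml_min": rec.vco2_obs,
                    "vco2_pct_error": err_co2,
                    "vo2_pred_ml_min": sim.vo2_ml_min,
                    "vo2_obs_ml_min": rec.vo2_obs,
                    "vo2_pct_error": err_o2,
                }
            )
        rows.append(
            {
                "variant": variant,
                "flow_ml_min": "max",
                "vco2_pred_ml_min": None,
                "vco2_obs_ml_min": None,
                "vco2_pct_error": max(errs_co2) if errs_co2 else None,
                "vo2_pred_ml_min": None,
                "vo2_obs_ml_min": None,
                "vo2_pct_error": max(errs_o2) if errs_o2 else None,
            }
        )
    return pd.DataFrame(rows)
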