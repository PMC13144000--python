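"""End-to-end analysis runner and deterministic result serialization.

``run_full_analysis`` drives the whole pipeline for one scenario: the
calibration table, risk thresholds, replicator dynamics and phase-line data
at the scenario's own risk level, subsidy analysis per table row, an
optional parameter sweep, and the cohort burden estimate.  Everything in a
report is reproducible from the echoed configuration alone; data files are
byte-identical across runs, with the timestamp segregated into a separate
metadata entry.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .burden import BurdenEstimate, burden_report
from .calibration import (
    RiskThresholds,
    ScenarioTable,
    build_scenario_table,
    derive_quantities,
    risk_thresholds,
)
from .config import ScenarioConfig
from .game import (
    EquilibriumReport,
    PayoffParameters,
    Trajectory,
    find_equilibria,
    integrate_replicator,
    phase_portrait,
)
from .policy import SubsidyAnalysis, SweepResult, analyze_subsidy, sweep_parameter

__all__ = ["RunReport", "run_full_analysis", "write_report"]

logger = logging.getLogger("sungame")


@dataclass(frozen=True)
class RunReport:
    """Everything one scenario run produces."""

    config: dict
    table: ScenarioTable
    thresholds: RiskThresholds
    game_params: PayoffParameters
    equilibrium: EquilibriumReport
    trajectory: Trajectory
    phase: np.ndarray
    subsidies: tuple[SubsidyAnalysis, ...]
    sweep: Optional[SweepResult]
    burden: Optional[BurdenEstimate]
    version: str
    timestamp: str


def run_full_analysis(config: ScenarioConfig) -> RunReport:
    """Run calibration, dynamics, policy and burden analyses for one scenario."""
    if len(config.risks) == 0:
        raise ValueError("at least one risk level is required")

    logger.info("[calibrate] building scenario table for %d risks", len(config.risks))
    table = build_scenario_table(config.economic, config.risks)
    thresholds = risk_thresholds(config.economic)

    d = derive_quantities(config.economic)
    params = PayoffParameters(
        benefit=d.b_private,
        cost=d.c_lifetime,
        externality=d.e_external,
        subsidy=config.policy.subsidy,
    )
    logger.info(
        "[dynamics] selection coefficient B - C + s = %.2f AUD",
        params.selection_coefficient,
    )
    g = params.payoff_difference()
    equilibrium = find_equilibria(g)
    times = np.linspace(0.0, config.dynamics.horizon, config.dynamics.n_points)
    trajectory = integrate_replicator(g, config.dynamics.x0, times)
    phase = phase_portrait(g, config.dynamics.n_points)

    logger.info("[policy] subsidy analysis per table row")
    subsidies = tuple(
        analyze_subsidy(row.private_benefit_aud, row.external_benefit_aud, row.lifetime_cost_aud)
        for row in table.frame.itertuples()
    )

    sweep = None
    if config.policy.sweep is not None:
        sw = config.policy.sweep
        grid = np.linspace(sw.start, sw.stop, sw.n)
        logger.info("[sweep] %s over [%g, %g] (%d points)", sw.parameter, sw.start, sw.stop, sw.n)
        sweep = sweep_parameter(config.economic, sw.parameter, grid)

    burden = None
    if config.cohort is not None:
        logger.info("[burden] cohort product and currency conversion")
        burden = burden_report(config.cohort, rate=config.conversion_rate)

    return RunReport(
        config=config.model_dump(exclude_none=True),
        table=table,
        thresholds=thresholds,
        game_params=params,
        equilibrium=equilibrium,
        trajectory=trajectory,
        phase=phase,
        subsidies=subsidies,
        sweep=sweep,
        burden=burden,
        version=__version__,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def _report_payload(report: RunReport) -> dict:
    return {
        "config": report.config,
        "table": json.loads(report.table.frame.to_json(orient="records")),
        "thresholds": {
            "p_social": report.thresholds.p_social,
            "p_private": report.thresholds.p_private,
            "p_social_reachable": report.thresholds.p_social_reachable,
            "p_private_reachable": report.thresholds.p_private_reachable,
        },
        "equilibrium": {
            "regime": report.equilibrium.regime,
            "continuum": report.equilibrium.continuum,
            "equilibria": [
                {"x": eq.x, "stability": eq.stability}
                for eq in report.equilibrium.equilibria
            ],
        },
        "subsidies": [
            {
                "s_star": s.s_star,
                "pre_regime": s.pre_regime.value,
                "post_regime": s.post_regime.value,
                "flipped": s.flipped,
            }
            for s in report.subsidies
        ],
        "sweep": None
        if report.sweep is None
        else {
            "parameter": report.sweep.parameter,
            "boundaries": [
                {"comparison": b.comparison, "value": b.value}
                for b in report.sweep.boundaries
            ],
        },
        "burden": None if report.burden is None else report.burden.to_dict(),
    }


def write_report(report: RunReport, outdir: str | Path, fmt: str = "csv") -> list[Path]:
    """Write all data products to ``outdir``; returns the paths written.

    Data files are deterministic; the run timestamp and version go to
    ``run_meta.json`` only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(df: pd.DataFrame, stem: str) -> None:
        if fmt == "json":
            p = outdir / f"{stem}.json"
            p.write_text(df.to_json(orient="records", indent=2))
        else:
            p = outdir / f"{stem}.csv"
            df.to_csv(p, index=False)
        written.append(p)

    _write_df(report.table.frame, "table")
    _write_df(report.trajectory.to_frame(), "trajectory")
    _write_df(pd.DataFrame(report.phase, columns=["x", "xdot"]), "phase")
    if report.sweep is not None:
        _write_df(report.sweep.frame, "sweep")

    p = outdir / "report.json"
    p.write_text(json.dumps(_report_payload(report), indent=2))
    written.append(p)

    meta = outdir / "run_meta.json"
    meta.write_text(
        json.dumps({"version": report.version, "timestamp": report.timestamp}, indent=2)
    )
    written.append(meta)
    return written
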