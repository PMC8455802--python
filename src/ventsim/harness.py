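"""Functional-test harness: the 96-condition test-lung benchmark matrix.

The benchmark crosses the four test-lung resistance levels (5, 20, 50,
200 mbar/(L·s)) and four compliance levels (10, 15, 20, 30 mL/mbar)
with the guidance-document tidal-volume bounds (50, 750 mL) and rate
levels (6, 20, 35 bpm) — 4·4·2·3 = 96 conditions.  Each condition is
run as a steady-state closed-loop simulation (six breaths, first
dropped) and summarized by maximum and mean inspiratory flow, delivered
V_T and its percentage error.  Guidance pass/fail thresholds are user
configuration, not code: the shipping default is empty (metrics-only
report).

The canonical sweep runs in volume-control mode with PEEP 0 and FiO2
0.21, since neither was independently specified during functional
testing; a pressure-mode sweep (PIP chosen quasi-statically as
V_T/C + PEEP) is available via ``mode="pressure"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .controller import Mode, VentSettings
from .engine import Scenario, breath_metrics, simulate
from .lung import LungParams
from .units import ConfigurationError

__all__ = [
    "RESISTANCE_LEVELS",
    "COMPLIANCE_LEVELS",
    "VT_LEVELS",
    "RR_LEVELS",
    "TestCondition",
    "build_aarc_matrix",
    "run_matrix",
    "check_guidance",
    "RESULT_COLUMNS",
]

RESISTANCE_LEVELS = (5.0, 20.0, 50.0, 200.0)   # mbar/(L·s)
COMPLIANCE_LEVELS = (10.0, 15.0, 20.0, 30.0)   # mL/mbar
VT_LEVELS = (50.0, 750.0)                      # mL, guidance min/max
RR_LEVELS = (6.0, 20.0, 35.0)                  # bpm, guidance levels

RESULT_COLUMNS = [
    "resistance",
    "compliance",
    "vt_target",
    "rr",
    "max_insp_flow_slpm",
    "mean_insp_flow_slpm",
    "delivered_vt_ml",
    "vt_error_pct",
    "over_inflated",
    "status",
]


@dataclass(frozen=True)
class TestCondition:
    """One cell of the benchmark matrix."""

    __test__ = False  # not a pytest collection target

    resistance: float
    compliance: float
    vt_target: float
    rr: float


def build_aarc_matrix() -> list[TestCondition]:
    """The canonical 96-condition matrix, in lexicographic order
    (resistance, then compliance, then V_T, then RR).  Pure and
    order-stable."""
    return [
        TestCondition(r, c, vt, rr)
        for r, c, vt, rr in itertools.product(
            RESISTANCE_LEVELS, COMPLIANCE_LEVELS, VT_LEVELS, RR_LEVELS
        )
    ]


def _condition_scenario(
    cond: TestCondition, base: Scenario, mode: str, n_breaths: int
) -> Scenario:
    duration = n_breaths * 60.0 / cond.rr
    if mode == "volume":
        # PIP acts only as a safety flag in volume mode; keep it valid even
        # for a deliberately depressurized base scenario
        pip = base.drive_pressure if base.drive_pressure > 0 else base.settings.pip
        settings = replace(
            base.settings,
            mode=Mode.VOLUME,
            vt_setpoint=cond.vt_target,
            rr=cond.rr,
            pip=pip,
            peep=0.0,
        )
    elif mode == "pressure":
        settings = replace(
            base.settings,
            mode=Mode.PRESSURE,
            vt_setpoint=None,
            rr=cond.rr,
            pip=cond.vt_target / cond.compliance,  # quasi-static PIP for the target V_T
            peep=0.0,
        )
    else:
        raise ConfigurationError(f"mode must be 'volume' or 'pressure', got {mode!r}")
    return replace(
        base,
        settings=settings,
        lung=LungParams(resistance=cond.resistance, compliance=cond.compliance),
        duration=duration,
    )


def run_matrix(
    matrix: Sequence[TestCondition] | None = None,
    base_scenario: Scenario | None = None,
    mode: str = "volume",
    n_breaths: int = 6,
    seed: int = 0,
) -> pd.DataFrame:
    """Run every condition and return one result row per matrix entry.

    Conditions are independent: results do not depend on execution
    order.  A condition that cannot deliver its target (e.g. the
    expiratory time constant exceeds the cycle at 200 mbar/(L·s) and
    35 bpm) is still reported, with its shortfall visible in
    ``vt_error_pct``; a condition that fails outright is recorded as an
    error row, never aborting the sweep.
    """
    if mode not in ("volume", "pressure"):
        raise ConfigurationError(f"mode must be 'volume' or 'pressure', got {mode!r}")
    if matrix is None:
        matrix = build_aarc_matrix()
    if base_scenario is None:
        base_scenario = Scenario(
            settings=VentSettings(mode=Mode.VOLUME, vt_setpoint=500.0, pip=100.0, rr=20.0),
            lung=LungParams(resistance=5.0, compliance=20.0),
            duration=60.0,
        )
    if n_breaths < 2:
        raise ConfigurationError("n_breaths must be at least 2 (first breath is dropped)")
    rows = []
    for cond in matrix:
        row: dict = {
            "resistance": cond.resistance,
            "compliance": cond.compliance,
            "vt_target": cond.vt_target,
            "rr": cond.rr,
        }
        try:
            scen = _condition_scenario(cond, base_scenario, mode, n_breaths)
            scen = replace(scen, seed=seed)
            record = simulate(scen)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                metrics = breath_metrics(record)
            steady = metrics[metrics["breath_index"] > 0]
            if steady.empty:
                raise RuntimeError("no steady-state breath completed")
            delivered = float(steady["delivered_vt_ml"].mean())
            row.update(
                max_insp_flow_slpm=float(steady["max_insp_flow_slpm"].max()),
                mean_insp_flow_slpm=float(steady["mean_insp_flow_slpm"].mean()),
                delivered_vt_ml=delivered,
                vt_error_pct=100.0 * abs(delivered - cond.vt_target) / cond.vt_target,
                over_inflated=bool(steady["over_inflated"].any()),
                status="ok",
            )
        except Exception as exc:  # keep the sweep alive; report the failure
            row.update(
                max_insp_flow_slpm=np.nan,
                mean_insp_flow_slpm=np.nan,
                delivered_vt_ml=np.nan,
                vt_error_pct=np.nan,
                over_inflated=False,
                status=f"error: {exc}",
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def check_guidance(
    results: pd.DataFrame,
    thresholds: Mapping[str, Mapping[str, float]] | None = None,
) -> dict:
    """Evaluate sweep results against user-supplied guidance thresholds.

    ``thresholds`` maps a result column to ``{"min": x}`` and/or
    ``{"max": y}`` bounds, e.g. ``{"vt_error_pct": {"max": 10}}``.  With
    no thresholds the report is metrics-only ("not evaluated").
    Returns a dict with the annotated per-condition table and overall
    counts.
    """
    table = results.copy()
    if not thresholds:
        table["guidance_status"] = "not evaluated"
        return {
            "per_condition": table,
            "n_pass": 0,
            "n_fail": 0,
            "n_not_evaluated": len(table),
            "overall_pass": None,
        }
    passed = pd.Series(True, index=table.index)
    for metric, bounds in thresholds.items():
        if metric not in table.columns:
            raise ConfigurationError(f"unknown metric in thresholds: {metric!r}")
        if not isinstance(bounds, Mapping) or not set(bounds) <= {"min", "max"}:
            raise ConfigurationError(
                f"threshold bounds for {metric!r} must be a mapping with 'min'/'max' keys"
            )
        values = table[metric]
        ok = values.notna()
        if "min" in bounds:
            ok &= values >= bounds["min"]
        if "max" in bounds:
            ok &= values <= bounds["max"]
        table[f"{metric}_pass"] = ok
        passed &= ok
    passed &= table["status"] == "ok"
    table["guidance_status"] = np.where(passed, "pass", "fail")
    n_pass = int(passed.sum())
    return {
        "per_condition": table,
        "n_pass": n_pass,
        "n_fail": len(table) - n_pass,
        "n_not_evaluated": 0,
        "overall_pass": bool(passed.all()),
    }
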