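"""Pre/post comparison protocol and report generation.

A comparison between two geometries is run as six simulations: the pre-op
model once under the reference forcing (yielding the self-consistent
reference triple ``(Q0, dp0, P0)``), twice more under the other two
forcings as a consistency check, and the post-op model three times, once per
forcing target taken from the triple.  The report mirrors the usual
global-quantities table: per forcing, pre and post values of throat
pressure, flow rate, power and resistance, with percent changes.

``report_from_globals`` performs only the table arithmetic from externally
supplied ``(Q, dp)`` pairs, with no simulation; it is the report-only mode
used to post-process published global values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping

import pandas as pd

from .forcing import (
    ForcingMode,
    ForcingSpec,
    GlobalQuantities,
    percent_change,
)

__all__ = [
    "ReferenceTriple",
    "ForcingRow",
    "ComparisonReport",
    "report_from_globals",
    "run_comparison",
    "resistance_reduction_overestimate",
    "overestimate_from_reductions",
    "to_liters_per_minute",
]

_QUANTS = ("Q", "dp", "P", "R")


def to_liters_per_minute(Q: float) -> float:
    """Convert a flow rate from m^3/s to l/min."""
    return Q * 6.0e4


@dataclass(frozen=True)
class ReferenceTriple:
    """Self-consistent reference operating point ``(Q0, dp0, P0)``."""

    Q0: float
    dp0: float
    P0: float

    def __post_init__(self) -> None:
        if min(self.Q0, self.dp0, self.P0) <= 0.0:
            raise ValueError(f"reference triple must be positive: {self}")
        if abs(self.P0 - self.Q0 * self.dp0) > 1e-8 * abs(self.P0):
            raise ValueError(
                f"inconsistent reference triple: P0={self.P0!r} vs Q0*dp0={self.Q0 * self.dp0!r}"
            )

    @classmethod
    def from_Q_dp(cls, Q0: float, dp0: float) -> "ReferenceTriple":
        return cls(Q0=Q0, dp0=dp0, P0=Q0 * dp0)

    def target_for(self, mode: ForcingMode) -> ForcingSpec:
        mode = ForcingMode.coerce(mode)
        value = {
            ForcingMode.CFR: self.Q0,
            ForcingMode.CPG: self.dp0,
            ForcingMode.CPI: self.P0,
        }[mode]
        return ForcingSpec(mode, value)


@dataclass(frozen=True)
class ForcingRow:
    """Pre/post global quantities and percent changes under one forcing."""

    mode: ForcingMode
    pre: GlobalQuantities
    post: GlobalQuantities
    pct: dict = field(default_factory=dict)  # keys Q, dp, P, R

    @classmethod
    def build(
        cls, mode: ForcingMode, pre: GlobalQuantities, post: GlobalQuantities
    ) -> "ForcingRow":
        pct = {
            "Q": percent_change(pre.Q_mean, post.Q_mean),
            "dp": percent_change(pre.dp_mean, post.dp_mean),
            "P": percent_change(pre.P_mean, post.P_mean),
            "R": percent_change(pre.R, post.R),
        }
        return cls(mode=ForcingMode.coerce(mode), pre=pre, post=post, pct=pct)


@dataclass
class ComparisonReport:
    """Global-quantities table for a pre/post comparison, one row per forcing."""

    rows: dict[ForcingMode, ForcingRow]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mode, row in self.rows.items():
            enforced = {
                ForcingMode.CFR: "Q",
                ForcingMode.CPG: "dp",
                ForcingMode.CPI: "P",
            }[mode]
            if abs(row.pct[enforced]) > 1e-6:
                raise ValueError(
                    f"{mode.value}: enforced quantity {enforced} changed by "
                    f"{row.pct[enforced]:g}% between pre and post"
                )
            # P = Q*dp must tie the three percent changes together
            implied = 100.0 * (
                (1.0 + row.pct["Q"] / 100.0) * (1.0 + row.pct["dp"] / 100.0) - 1.0
            )
            if abs(implied - row.pct["P"]) > 0.1:
                raise ValueError(
                    f"{mode.value}: power change {row.pct['P']:.3f}% inconsistent "
                    f"with flow/pressure changes (implied {implied:.3f}%)"
                )

    def row(self, mode: "ForcingMode | str") -> ForcingRow:
        return self.rows[ForcingMode.coerce(mode)]

    # -- export ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        records = []
        for mode, row in self.rows.items():
            for stage, gq in (("pre", row.pre), ("post", row.post)):
                records.append(
                    {
                        "forcing": mode.value,
                        "stage": stage,
                        "Q": gq.Q_mean,
                        "dp": gq.dp_mean,
                        "P": gq.P_mean,
                        "R": gq.R,
                    }
                )
            records.append(
                {"forcing": mode.value, "stage": "pct_change", **row.pct}
            )
        return pd.DataFrame.from_records(records)

    def to_dict(self) -> dict:
        return {
            "rows": {
                mode.value: {
                    "pre": row.pre.to_dict(),
                    "post": row.post.to_dict(),
                    "pct_change": row.pct,
                }
                for mode, row in self.rows.items()
            },
            "metadata": self.metadata,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def render_text(self) -> str:
        """Plain-text table: forcings as column groups, quantities as rows.

        Values are rounded only here, at presentation time: pressure in Pa to
        one decimal (printed negative, as throat pressure), flow in 1e-4
        m^3/s and power in mW to two decimals, resistance in 1e4 Pa s/m^3 to
        two decimals, percent changes to one decimal.
        """
        modes = list(self.rows)
        header = ["quantity"] + [
            f"{m.value} {stage}" for m in modes for stage in ("pre", "post", "%d")
        ]
        lines = ["  ".join(f"{h:>12}" for h in header)]

        def fmt(x: float, nd: int) -> str:
            return f"{x:>12.{nd}f}"

        specs = [
            ("p_th [Pa]", lambda g: -g.dp_mean, 1, "dp"),
            ("Q [1e-4 m3/s]", lambda g: g.Q_mean * 1e4, 2, "Q"),
            ("P [mW]", lambda g: g.P_mean * 1e3, 2, "P"),
            ("R [1e4 Pa.s/m3]", lambda g: g.R * 1e-4, 2, "R"),
        ]
        for name, get, nd, key in specs:
            cells = [f"{name:>12}"]
            for m in modes:
                row = self.rows[m]
                cells.append(fmt(get(row.pre), nd))
                cells.append(fmt(get(row.post), nd))
                cells.append(fmt(row.pct[key], 1))
            lines.append("  ".join(cells))
        return "\n".join(lines)


def report_from_globals(
    pre: tuple[float, float],
    post_per_forcing: Mapping["ForcingMode | str", tuple[float, float]],
    metadata: dict | None = None,
) -> ComparisonReport:
    """Report-only mode: table arithmetic from ``(Q, dp)`` pairs, no simulation.

    ``pre`` is the shared pre-op pair; ``post_per_forcing`` maps each forcing
    mode to its post-op pair.  Power and resistance are derived per cell as
    ``P = Q dp`` and ``R = dp / Q``.
    """
    Q_pre, dp_pre = pre
    if Q_pre <= 0.0 or dp_pre <= 0.0:
        raise ValueError("pre-op flow rate and pressure drop must be positive")
    pre_gq = GlobalQuantities.from_Q_dp(Q_pre, dp_pre)
    rows: dict[ForcingMode, ForcingRow] = {}
    for mode, (Q_post, dp_post) in post_per_forcing.items():
        if Q_post <= 0.0 or dp_post <= 0.0:
            raise ValueError("post-op flow rate and pressure drop must be positive")
        mode = ForcingMode.coerce(mode)
        rows[mode] = ForcingRow.build(mode, pre_gq, GlobalQuantities.from_Q_dp(Q_post, dp_post))
    return ComparisonReport(rows=rows, metadata=dict(metadata or {}))


Runner = Callable[[object, ForcingSpec], GlobalQuantities]


def _lumped_runner(model, forcing: ForcingSpec) -> GlobalQuantities:
    from .lumped import solve_steady

    return solve_steady(model, forcing)


def _duct_runner(model, forcing: ForcingSpec) -> GlobalQuantities:
    from .duct import run_case

    geom, cfg = model
    gq, _, _ = run_case(geom, forcing, cfg)
    return gq


_RUNNERS: dict[str, Runner] = {"lumped": _lumped_runner, "duct": _duct_runner}


def run_comparison(
    pre_model,
    post_model,
    reference_forcing: ForcingSpec,
    backend: str = "lumped",
    runner: Runner | None = None,
    consistency_rtol: float | None = None,
    metadata: dict | None = None,
) -> ComparisonReport:
    """Run the full six-simulation pre/post comparison protocol.

    1. Pre-op under ``reference_forcing`` defines the reference triple.
    2. Pre-op under the other two forcings must reproduce the triple to
       within ``consistency_rtol`` (single-geometry forcing equivalence).
    3. Post-op under each of the three targets fills the table.

    ``backend`` selects the bundled runner (``"lumped"`` models are
    :class:`~noseflow.lumped.AirwayNetwork`; ``"duct"`` models are
    ``(DuctGeometry, SolverConfig)`` pairs); a custom ``runner`` callable
    overrides it.
    """
    if runner is None:
        try:
            runner = _RUNNERS[backend]
        except KeyError:
            raise ValueError(f"unknown backend {backend!r}; expected 'lumped' or 'duct'")
    if consistency_rtol is None:
        consistency_rtol = 1e-8 if backend == "lumped" else 2e-2

    ref_gq = runner(pre_model, reference_forcing)
    triple = ReferenceTriple(Q0=ref_gq.Q_mean, dp0=ref_gq.dp_mean, P0=ref_gq.P_mean)

    pre_by_mode: dict[ForcingMode, GlobalQuantities] = {reference_forcing.mode: ref_gq}
    for mode in ForcingMode:
        if mode is reference_forcing.mode:
            continue
        gq = runner(pre_model, triple.target_for(mode))
        for name, got, want in (
            ("Q", gq.Q_mean, triple.Q0),
            ("dp", gq.dp_mean, triple.dp0),
            ("P", gq.P_mean, triple.P0),
        ):
            if abs(got - want) > consistency_rtol * abs(want):
                raise RuntimeError(
                    f"pre-op consistency check failed: {mode.value} gives "
                    f"{name}={got:g}, reference forcing gave {want:g} "
                    f"(rtol {consistency_rtol:g})"
                )
        pre_by_mode[mode] = gq

    rows = {}
    for mode in ForcingMode:
        post_gq = runner(post_model, triple.target_for(mode))
        rows[mode] = ForcingRow.build(mode, pre_by_mode[mode], post_gq)

    meta = {
        "backend": backend,
        "reference_forcing": {
            "mode": reference_forcing.mode.value,
            "target": reference_forcing.target,
        },
        "reference_triple": {"Q0": triple.Q0, "dp0": triple.dp0, "P0": triple.P0},
    }
    meta.update(metadata or {})
    return ComparisonReport(rows=rows, metadata=meta)


def resistance_reduction_overestimate(report: ComparisonReport) -> float:
    """Relative overestimation (%) of the resistance reduction, CFR vs CPG.

    ``100 * (|%dR_CFR| - |%dR_CPG|) / |%dR_CPG|``; requires both reductions
    to be actual reductions (negative percent changes).
    """
    try:
        cfr = report.row(ForcingMode.CFR).pct["R"]
        cpg = report.row(ForcingMode.CPG).pct["R"]
    except KeyError as exc:
        raise ValueError("report must contain both CFR and CPG rows") from exc
    if cfr >= 0.0 or cpg >= 0.0:
        raise ValueError(
            f"both resistance changes must be reductions, got CFR {cfr:g}%, CPG {cpg:g}%"
        )
    return overestimate_from_reductions(abs(cfr), abs(cpg))


def overestimate_from_reductions(reduction_cfr: float, reduction_cpg: float) -> float:
    """Same ratio from two already-extracted reduction magnitudes (%)."""
    if reduction_cfr <= 0.0 or reduction_cpg <= 0.0:
        raise ValueError("reduction magnitudes must be positive percentages")
    return 100.0 * (reduction_cfr - reduction_cpg) / reduction_cpg
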