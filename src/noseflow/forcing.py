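"""Global flow quantities and the three flow-forcing controllers.

A run through an airway (or any duct-like flow model) is characterised by
three global quantities: the volumetric flow rate ``Q``, the throat pressure
``p_th`` (relative to an ambient reference ``p = 0``, negative during
inspiration) and the mechanical power ``P = -Q * p_th`` driving the flow.
A comparison between two geometries must hold exactly one of these constant:

* CFR — constant flow rate ``Q = Q0``;
* CPG — constant pressure gradient, i.e. constant drop ``dp0 = -p_th``;
* CPI — constant power input ``P = P0``.

This module defines the shared value types, the sign conventions, and the
small amount of controller arithmetic (notably the one-step-lagged CPI
throat-pressure update) that every backend uses.  Everything here is
independent of any particular flow model.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ForcingMode",
    "ForcingSpec",
    "FlowState",
    "GlobalQuantities",
    "ControllerError",
    "DEFAULT_Q_FLOOR",
    "compute_power",
    "cpi_throat_pressure",
    "nasal_resistance",
    "percent_change",
    "time_average",
]

#: Below this flow rate (m^3/s) the CPI controller refuses to run: the
#: pressure update is singular at rest, so CPI needs a warm start.
DEFAULT_Q_FLOOR = 1e-6


class ControllerError(RuntimeError):
    """Raised when a forcing controller cannot produce a valid update."""


class ForcingMode(str, enum.Enum):
    """Which global quantity is held constant across a comparison."""

    CFR = "CFR"  # constant flow rate
    CPG = "CPG"  # constant pressure gradient (ambient-to-throat drop)
    CPI = "CPI"  # constant power input

    @classmethod
    def coerce(cls, value: "ForcingMode | str") -> "ForcingMode":
        if isinstance(value, cls):
            return value
        return cls(str(value).upper())


@dataclass(frozen=True)
class ForcingSpec:
    """One active global constraint: a mode and its positive target value.

    ``target`` is ``Q0`` in m^3/s for CFR, the positive pressure drop
    ``dp0`` in Pa for CPG, and ``P0`` in W for CPI.
    """

    mode: ForcingMode
    target: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", ForcingMode.coerce(self.mode))
        if not (self.target > 0.0) or not math.isfinite(self.target):
            raise ValueError(
                f"forcing target must be a positive finite number, got {self.target!r}"
            )


def compute_power(Q: float, p_th: float) -> float:
    """Mechanical power input ``P = -Q * p_th`` (W).

    Positive when the flow is driven inward (``Q > 0``) by suction at the
    throat (``p_th < 0``).
    """
    return -Q * p_th


def cpi_throat_pressure(
    P0: float, Q_prev: float, q_floor: float = DEFAULT_Q_FLOOR
) -> float:
    """One-step-lagged CPI controller: throat pressure enforcing power ``P0``.

    Returns ``-P0 / Q_prev`` where ``Q_prev`` is the flow rate at the
    previous time step.  Singular at rest, hence the flow-rate floor.

    Raises
    ------
    ControllerError
        If ``Q_prev <= q_floor``: the controller cannot start from
        (near-)stagnant flow and needs a warm start.
    """
    if not P0 > 0.0:
        raise ValueError(f"CPI power target must be positive, got {P0!r}")
    if not q_floor > 0.0:
        raise ValueError(f"q_floor must be positive, got {q_floor!r}")
    if Q_prev <= q_floor:
        raise ControllerError(
            f"CPI controller needs Q_prev > {q_floor:g} m^3/s to avoid the "
            f"singular update at stagnation; got Q_prev = {Q_prev:g}"
        )
    return -P0 / Q_prev


def nasal_resistance(dp: float, Q: float) -> float:
    """Resistance ``R = dp / Q`` (Pa s/m^3) from a positive drop and flow."""
    if Q <= 0.0:
        raise ValueError(f"flow rate must be positive to define a resistance, got {Q!r}")
    if dp < 0.0:
        raise ValueError(f"pressure drop must be non-negative, got {dp!r}")
    return dp / Q


def percent_change(pre: float, post: float) -> float:
    """Signed percent change ``100 * (post - pre) / |pre|``."""
    if pre == 0.0:
        raise ValueError("percent change is undefined for a zero reference value")
    return 100.0 * (post - pre) / abs(pre)


def time_average(
    t: "np.ndarray | list[float]",
    y: "np.ndarray | list[float]",
    discard_fraction: float = 0.3,
) -> float:
    """Time-weighted mean of a sampled signal after discarding a transient.

    The first ``discard_fraction`` of the total time span is dropped, then
    the mean is computed with trapezoidal weighting (the samples produced by
    CFL-limited stepping are not uniform).

    Raises
    ------
    ValueError
        If the retained window is empty or the inputs are inconsistent.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError(f"discard_fraction must be in [0, 1), got {discard_fraction!r}")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape or t.size == 0:
        raise ValueError("t and y must be equal-length non-empty 1-D arrays")
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be non-decreasing")
    t_cut = t[0] + discard_fraction * (t[-1] - t[0])
    keep = t >= t_cut
    if not np.any(keep):
        raise ValueError("retained averaging window is empty")
    tk, yk = t[keep], y[keep]
    span = tk[-1] - tk[0]
    if span == 0.0:
        return float(yk[-1])
    return float(np.trapezoid(yk, tk) / span)


@dataclass
class FlowState:
    """Instantaneous global state of a run.

    ``P`` is derived from ``Q`` and ``p_th`` when omitted; when given
    explicitly it must close on ``-Q * p_th`` to round-off.
    """

    t: float
    Q: float
    p_th: float
    P: float | None = None

    def __post_init__(self) -> None:
        expected = compute_power(self.Q, self.p_th)
        if self.P is None:
            self.P = expected
        elif abs(self.P - expected) > 1e-12 * max(1.0, abs(self.P)):
            raise ValueError(
                f"inconsistent FlowState: P={self.P!r} but -Q*p_th={expected!r}"
            )


@dataclass(frozen=True)
class GlobalQuantities:
    """Time-averaged global outcome of one run (all positive magnitudes)."""

    Q_mean: float  # m^3/s
    dp_mean: float  # Pa, positive ambient-to-throat drop
    P_mean: float  # W
    R: float = field(default=float("nan"))  # Pa s/m^3

    def __post_init__(self) -> None:
        if math.isnan(self.R):
            object.__setattr__(self, "R", nasal_resistance(self.dp_mean, self.Q_mean))

    @classmethod
    def from_Q_dp(cls, Q: float, dp: float) -> "GlobalQuantities":
        """Build the full set from a (flow rate, pressure drop) pair."""
        return cls(Q_mean=Q, dp_mean=dp, P_mean=Q * dp)

    def to_dict(self) -> dict:
        return {
            "Q_mean": self.Q_mean,
            "dp_mean": self.dp_mean,
            "P_mean": self.P_mean,
            "R": self.R,
            "units": {
                "Q_mean": "m3/s",
                "dp_mean": "Pa",
                "P_mean": "W",
                "R": "Pa.s/m3",
            },
        }
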