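"""Quasi-steady lumped-parameter airway models.

The airway is reduced to three segments with linear-plus-quadratic
pressure-flow laws ``dp(Q) = a Q + b Q^2``: two nasal branches in parallel
(left/right passage) in series with a common pharyngeal segment.  Because
every law is strictly increasing for positive flow, the steady state under
each forcing is a bracketed root of a monotone map, so this backend provides
fast, analytically checkable answers against which the time-dependent duct
solver can be validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .forcing import (
    DEFAULT_Q_FLOOR,
    ForcingMode,
    ForcingSpec,
    GlobalQuantities,
)

__all__ = [
    "SegmentLaw",
    "AirwayNetwork",
    "CalibrationSpec",
    "dp_of_Q",
    "calibrate",
    "apply_virtual_surgery",
    "solve_steady",
    "lateral_resistances",
    "cpi_relaxed_iteration",
]

_BRENTQ_KW = dict(xtol=1e-300, rtol=8.9e-16, maxiter=200)


@dataclass(frozen=True)
class SegmentLaw:
    """Pressure-flow law ``dp(Q) = a Q + b Q^2`` of one airway segment.

    ``a`` (Pa s/m^3) and ``b`` (Pa s^2/m^6) are non-negative; a segment used
    as a parallel branch must have ``a + b > 0``.
    """

    a: float
    b: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.a < 0.0 or self.b < 0.0:
            raise ValueError(f"segment coefficients must be non-negative: {self}")

    @property
    def is_zero(self) -> bool:
        return self.a == 0.0 and self.b == 0.0

    def dp(self, Q: float) -> float:
        """Pressure drop across the segment at flow ``Q``."""
        return self.a * Q + self.b * Q * Q

    def scaled(self, factor: float) -> "SegmentLaw":
        return replace(self, a=self.a * factor, b=self.b * factor)


@dataclass(frozen=True)
class AirwayNetwork:
    """Two parallel nasal branches in series with a common segment.

    The common (pharyngeal) segment may have zero resistance; both branches
    must not, otherwise the parallel split is indeterminate.
    """

    left: SegmentLaw
    right: SegmentLaw
    common: SegmentLaw

    def __post_init__(self) -> None:
        for name, seg in (("left", self.left), ("right", self.right)):
            if seg.is_zero:
                raise ValueError(f"{name} branch must have nonzero resistance")

    @classmethod
    def single_segment(cls, a: float, b: float, label: str = "single") -> "AirwayNetwork":
        """Degenerate network equivalent to one segment with law ``aQ + bQ^2``.

        Realised as identical twin branches (each ``2a``, ``4b``) and a
        zero-resistance common segment; at equal split the parallel pair
        reproduces the single-segment law exactly.
        """
        twin = SegmentLaw(2.0 * a, 4.0 * b, label=label)
        return cls(left=twin, right=twin, common=SegmentLaw(0.0, 0.0, label="none"))

    def to_dict(self) -> dict:
        return {
            side: {"a": seg.a, "b": seg.b, "label": seg.label}
            for side, seg in (("left", self.left), ("right", self.right), ("common", self.common))
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AirwayNetwork":
        segs = {}
        for side in ("left", "right", "common"):
            block = d[side]
            segs[side] = SegmentLaw(
                a=float(block["a"]), b=float(block["b"]), label=str(block.get("label", ""))
            )
        return cls(**segs)


@dataclass(frozen=True)
class CalibrationSpec:
    """Reference operating point and shape parameters for model construction.

    ``blend`` splits the reference drop of every segment between a linear
    part (fraction ``blend``) and a quadratic part; ``split`` is the fraction
    of the reference flow carried by the left branch; ``common_fraction`` is
    the share of the reference drop assigned to the common segment.
    """

    Q0: float
    dp0: float
    blend: float = 0.5
    split: float = 0.5
    common_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not self.Q0 > 0.0 or not self.dp0 > 0.0:
            raise ValueError("reference flow rate and pressure drop must be positive")
        if not 0.0 <= self.blend <= 1.0:
            raise ValueError(f"blend must be in [0, 1], got {self.blend!r}")
        if not 0.0 < self.split < 1.0:
            raise ValueError(f"split must be in (0, 1), got {self.split!r}")
        if not 0.0 <= self.common_fraction < 1.0:
            raise ValueError(
                f"common_fraction must be in [0, 1), got {self.common_fraction!r}"
            )


def _blended_law(dp_ref: float, q_ref: float, blend: float, label: str) -> SegmentLaw:
    # a*q_ref + b*q_ref^2 == dp_ref with the linear part carrying `blend` of it
    return SegmentLaw(
        a=blend * dp_ref / q_ref,
        b=(1.0 - blend) * dp_ref / (q_ref * q_ref),
        label=label,
    )


def calibrate(spec: CalibrationSpec) -> AirwayNetwork:
    """Build a network whose total drop at ``Q0`` equals ``dp0`` exactly.

    The common segment takes ``common_fraction * dp0`` at ``Q0``; the two
    branches each take the remaining drop at their reference branch flows
    ``split * Q0`` and ``(1 - split) * Q0``, which makes the equal-drop
    parallel equilibrium at ``Q0`` hold by construction.
    """
    dp_common = spec.common_fraction * spec.dp0
    dp_branch = spec.dp0 - dp_common
    if dp_common > 0.0:
        common = _blended_law(dp_common, spec.Q0, spec.blend, "pharynx")
    else:
        common = SegmentLaw(0.0, 0.0, label="pharynx")
    left = _blended_law(dp_branch, spec.split * spec.Q0, spec.blend, "left")
    right = _blended_law(dp_branch, (1.0 - spec.split) * spec.Q0, spec.blend, "right")
    return AirwayNetwork(left=left, right=right, common=common)


def branch_split(model: AirwayNetwork, Q: float) -> float:
    """Left-branch flow at equilibrium: equal branch drops, flows sum to Q."""
    if Q < 0.0:
        raise ValueError(f"flow rate must be non-negative, got {Q!r}")
    if Q == 0.0:
        return 0.0

    def f(q: float) -> float:
        return model.left.dp(q) - model.right.dp(Q - q)

    f0, f1 = f(0.0), f(Q)
    if f0 == 0.0:
        return 0.0
    if f1 == 0.0:
        return Q
    if f0 > 0.0 or f1 < 0.0:  # unreachable for strictly increasing branch laws
        raise RuntimeError(f"branch split not bracketed on [0, {Q!r}]")
    return float(brentq(f, 0.0, Q, **_BRENTQ_KW))


def dp_of_Q(model: AirwayNetwork, Q: float) -> float:
    """Total ambient-to-throat pressure drop at flow rate ``Q``."""
    if Q == 0.0:
        return 0.0
    q_left = branch_split(model, Q)
    return model.common.dp(Q) + model.left.dp(q_left)


def apply_virtual_surgery(
    model: AirwayNetwork, side: str, factor: float
) -> AirwayNetwork:
    """Scale the coefficients of one branch (or both) by ``factor`` in (0, 1].

    ``side`` is ``"left"``, ``"right"`` or ``"both"``; the common segment is
    never touched, mirroring a unilateral operation that leaves the
    contralateral passage and the pharynx unchanged.
    """
    if not 0.0 < factor <= 1.0:
        raise ValueError(f"surgery factor must be in (0, 1], got {factor!r}")
    if side not in ("left", "right", "both"):
        raise ValueError(f"side must be 'left', 'right' or 'both', got {side!r}")
    left = model.left.scaled(factor) if side in ("left", "both") else model.left
    right = model.right.scaled(factor) if side in ("right", "both") else model.right
    return replace(model, left=left, right=right)


def _bracket_Q(residual, q_floor: float) -> tuple[float, float]:
    """Grow an upper bound geometrically until the monotone residual changes sign."""
    lo = 0.0
    hi = max(q_floor, 1e-8)
    for _ in range(200):
        if residual(hi) >= 0.0:
            return lo, hi
        lo, hi = hi, hi * 2.0
    raise RuntimeError(f"failed to bracket the steady state; last bracket [{lo!r}, {hi!r}]")


def solve_steady(
    model: AirwayNetwork,
    forcing: ForcingSpec,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> GlobalQuantities:
    """Steady state of the network under one forcing.

    CFR evaluates the law directly; CPG and CPI are bracketed root-finds on
    the strictly increasing maps ``Q -> dp(Q)`` and ``Q -> Q dp(Q)``.
    """
    if forcing.mode is ForcingMode.CFR:
        Q = forcing.target
    elif forcing.mode is ForcingMode.CPG:
        Q = _solve_monotone(lambda q: dp_of_Q(model, q) - forcing.target, q_floor)
    else:  # CPI
        Q = _solve_monotone(lambda q: q * dp_of_Q(model, q) - forcing.target, q_floor)
    dp = dp_of_Q(model, Q)
    return GlobalQuantities(Q_mean=Q, dp_mean=dp, P_mean=Q * dp)


def _solve_monotone(residual, q_floor: float) -> float:
    lo, hi = _bracket_Q(residual, q_floor)
    if residual(hi) == 0.0:
        return hi
    return float(brentq(residual, lo, hi, **_BRENTQ_KW))


def lateral_resistances(
    model: AirwayNetwork, state: GlobalQuantities
) -> tuple[float, float]:
    """Per-side resistances ``dp_branch / Q_branch`` at the converged split."""
    q_left = branch_split(model, state.Q_mean)
    q_right = state.Q_mean - q_left
    if q_left <= 0.0 or q_right <= 0.0:
        raise ValueError(
            f"lateral resistance undefined: branch flows ({q_left!r}, {q_right!r})"
        )
    dp_branch = model.left.dp(q_left)
    return dp_branch / q_left, dp_branch / q_right


def cpi_relaxed_iteration(
    model: AirwayNetwork,
    P0: float,
    relaxation: float = 0.5,
    tol: float = 1e-12,
    max_iter: int = 500,
    p_start: float | None = None,
    q_floor: float = DEFAULT_Q_FLOOR,
) -> tuple[GlobalQuantities, int]:
    """Under-relaxed fixed-point CPI iteration mimicking the time-stepping controller.

    Iterates ``p <- (1 - w) p + w (-P0 / Q(p))`` where ``Q(p)`` is the CPG
    steady flow at drop ``|p|``.  The raw map (``w = 1``) is neutrally stable
    on a linear model (it 2-cycles), so under-relaxation is required; the
    fixed point satisfies ``Q * (-p) = P0`` and must agree with the direct
    root-find of :func:`solve_steady`.

    Returns the converged global quantities and the iteration count.
    """
    if not 0.0 < relaxation <= 1.0:
        raise ValueError(f"relaxation must be in (0, 1], got {relaxation!r}")
    if p_start is None:
        # seed from a pure-resistance estimate at unit-ish flow scale
        q_seed = max(q_floor * 10.0, 1e-5)
        p_start = -max(dp_of_Q(model, q_seed), P0 / q_seed)
    p = -abs(p_start)
    n_done = 0
    for n_done in range(1, max_iter + 1):
        Q = solve_steady(model, ForcingSpec(ForcingMode.CPG, -p), q_floor).Q_mean
        if Q <= q_floor:
            raise RuntimeError("CPI iteration collapsed to stagnant flow")
        p_new = (1.0 - relaxation) * p + relaxation * (-P0 / Q)
        if abs(p_new - p) <= tol * max(1.0, abs(p_new)):
            p = p_new
            break
        p = p_new
    else:
        raise RuntimeError(f"CPI relaxed iteration did not converge in {max_iter} steps")
    dp = -p
    Q = solve_steady(model, ForcingSpec(ForcingMode.CPG, dp), q_floor).Q_mean
    return GlobalQuantities(Q_mean=Q, dp_mean=dp, P_mean=Q * dp), n_done


def closed_form_single_segment(
    a: float, b: float, forcing: ForcingSpec
) -> GlobalQuantities:
    """Independent closed-form steady state for a single segment ``aQ + bQ^2``.

    CFR is direct; CPG uses the quadratic formula; CPI solves the cubic
    ``b Q^3 + a Q^2 - P0 = 0`` by high-precision bisection.  Kept separate
    from :func:`solve_steady` as a cross-checking oracle.
    """
    if forcing.mode is ForcingMode.CFR:
        Q = forcing.target
    elif forcing.mode is ForcingMode.CPG:
        dp0 = forcing.target
        if b == 0.0:
            Q = dp0 / a
        else:
            Q = (-a + math.sqrt(a * a + 4.0 * b * dp0)) / (2.0 * b)
    else:
        P0 = forcing.target

        def g(q: float) -> float:
            return b * q**3 + a * q**2 - P0

        hi = 1.0
        while g(hi) < 0.0:
            hi *= 2.0
        lo = 0.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) > 0.0:
                hi = mid
            else:
                lo = mid
        Q = 0.5 * (lo + hi)
    dp = a * Q + b * Q * Q
    return GlobalQuantities(Q_mean=Q, dp_mean=dp, P_mean=Q * dp)
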