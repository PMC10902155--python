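"""Synthetic pre/post case pairs emulating a resistance-lowering operation.

Every generated pre-op model is calibrated to the reference operating point
(Q0 = 2.67e-4 m^3/s, dp0 = 24.45 Pa); the post-op model differs only by a
one-sided reduction of the operated passage's resistance.  Nuisance
parameters (blend, asymmetry) may be jittered with a seeded generator, but
the calibration point itself is never perturbed, so report arithmetic stays
exact.  Duct-backend recipes produce geometry pairs where the operation is a
reduction of the constriction depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import ComparisonReport, run_comparison
from .forcing import ForcingMode, ForcingSpec
from .lumped import (
    AirwayNetwork,
    CalibrationSpec,
    apply_virtual_surgery,
    calibrate,
    dp_of_Q,
)

__all__ = [
    "REFERENCE_Q0",
    "REFERENCE_DP0",
    "CaseRecipe",
    "make_case",
    "sweep",
]

#: Reference steady-inspiration operating point used to calibrate every
#: pre-op model: mild-intensity flow rate and the matching pressure drop.
REFERENCE_Q0 = 2.67e-4  # m^3/s (about 16 l/min)
REFERENCE_DP0 = 24.45  # Pa


@dataclass(frozen=True)
class CaseRecipe:
    """Deterministic description of one synthetic pre/post pair.

    ``severity`` is the coefficient factor applied to the operated passage
    (1 = sham operation); ``asymmetry`` shifts the pre-op flow split toward
    the left side; ``noise`` jitters nuisance shape parameters only.
    ``layout`` is ``"two_sided"`` (full network, unilateral surgery) or
    ``"single"`` (degenerate single-passage model, surgery scales the whole
    law — the analytically transparent configuration).
    """

    backend: str = "lumped"
    severity: float = 0.75
    asymmetry: float = 0.0
    seed: int = 0
    noise: float = 0.0
    blend: float = 0.5
    common_fraction: float = 0.2
    side: str = "right"
    layout: str = "two_sided"
    # duct-backend shape parameters
    duct_nx: int = 48
    duct_ny: int = 24
    duct_depth_pre: float = 0.4

    def __post_init__(self) -> None:
        if not 0.0 < self.severity <= 1.0:
            raise ValueError(f"severity must be in (0, 1], got {self.severity!r}")
        if self.noise < 0.0:
            raise ValueError(f"noise must be non-negative, got {self.noise!r}")
        if self.backend not in ("lumped", "duct"):
            raise ValueError(f"backend must be 'lumped' or 'duct', got {self.backend!r}")
        if self.layout not in ("two_sided", "single"):
            raise ValueError(f"layout must be 'two_sided' or 'single', got {self.layout!r}")
        if not -1.0 < self.asymmetry < 1.0:
            raise ValueError(f"asymmetry must be in (-1, 1), got {self.asymmetry!r}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _jitter(rng: np.random.Generator, value: float, rel: float, lo: float, hi: float) -> float:
    if rel == 0.0:
        return value
    return float(np.clip(value * (1.0 + rel * rng.uniform(-1.0, 1.0)), lo, hi))


def make_case(recipe: CaseRecipe):
    """Build ``(pre_model, post_model, metadata)`` from a recipe.

    Deterministic for a fixed recipe (including seed).  Lumped pre-op models
    satisfy ``dp_of_Q(Q0) == dp0`` at the reference point by construction;
    metadata records the achieved resistance factor of the operated passage.
    """
    rng = np.random.default_rng(recipe.seed)
    if recipe.backend == "lumped":
        blend = _jitter(rng, recipe.blend, recipe.noise, 0.0, 1.0)
        if recipe.layout == "single":
            split, common_fraction, side = 0.5, 0.0, "both"
        else:
            split = float(np.clip(0.5 * (1.0 + recipe.asymmetry), 0.05, 0.95))
            split = _jitter(rng, split, recipe.noise, 0.05, 0.95)
            common_fraction, side = recipe.common_fraction, recipe.side
        spec = CalibrationSpec(
            Q0=REFERENCE_Q0,
            dp0=REFERENCE_DP0,
            blend=blend,
            split=split,
            common_fraction=common_fraction,
        )
        pre = calibrate(spec)
        post = apply_virtual_surgery(pre, side, recipe.severity)
        metadata = {
            "backend": "lumped",
            "recipe": recipe.to_dict(),
            "calibration": {
                "Q0": REFERENCE_Q0,
                "dp0": REFERENCE_DP0,
                "blend": blend,
                "split": split,
                "common_fraction": common_fraction,
            },
            "achieved_factor": recipe.severity,
            "operated_side": side,
            "dp_pre_at_Q0": dp_of_Q(pre, REFERENCE_Q0),
            "dp_post_at_Q0": dp_of_Q(post, REFERENCE_Q0),
        }
        return pre, post, metadata

    # duct backend: the operation shallows the constriction
    from .duct import DuctGeometry

    depth_pre = recipe.duct_depth_pre
    depth_post = depth_pre * recipe.severity
    common = dict(
        L=0.05,
        h=0.005,
        nx=recipe.duct_nx,
        ny=recipe.duct_ny,
        bump_centre=0.025,
        bump_width=0.02,
    )
    pre = DuctGeometry(bump_depth=depth_pre, **common)
    post = DuctGeometry(bump_depth=depth_post, **common)
    metadata = {
        "backend": "duct",
        "recipe": recipe.to_dict(),
        "depth_pre": depth_pre,
        "depth_post": depth_post,
        "achieved_factor": recipe.severity,
    }
    return pre, post, metadata


def sweep(
    recipes,
    reference_forcing: ForcingSpec | None = None,
    solver_config=None,
) -> pd.DataFrame:
    """Run the full comparison for each recipe; one table row per recipe.

    Individual failures are recorded in the ``error`` column and the sweep
    continues.  Raises on an empty recipe collection.
    """
    recipes = list(recipes)
    if not recipes:
        raise ValueError("sweep needs at least one recipe")
    if reference_forcing is None:
        reference_forcing = ForcingSpec(ForcingMode.CFR, REFERENCE_Q0)

    records = []
    for k, recipe in enumerate(recipes):
        rec: dict = {"case": k, **recipe.to_dict(), "error": None}
        try:
            pre, post, meta = make_case(recipe)
            if recipe.backend == "duct":
                if solver_config is None:
                    raise ValueError("duct recipes need a solver_config")
                pre = (pre, solver_config)
                post = (post, solver_config)
            report = run_comparison(
                pre, post, reference_forcing, backend=recipe.backend
            )
            for mode, row in report.rows.items():
                for key, value in row.pct.items():
                    rec[f"pct_{key}_{mode.value}"] = value
            rec["report"] = report
        except Exception as exc:  # noqa: BLE001 - sweep must survive bad cells
            rec["error"] = f"{type(exc).__name__}: {exc}"
            rec["report"] = None
        records.append(rec)
    return pd.DataFrame.from_records(records)
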