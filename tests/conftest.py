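"""Shared fixtures; the expensive duct runs are session-scoped and reused."""

from __future__ import annotations

import pytest

from noseflow.duct import (
    DuctGeometry,
    SolverConfig,
    poiseuille_flow_rate,
    run_case,
)
from noseflow.forcing import ForcingMode, ForcingSpec
from noseflow.lumped import CalibrationSpec, calibrate

REF_Q0 = 2.67e-4
REF_DP0 = 24.45


@pytest.fixture(scope="session")
def calibrated_network():
    return calibrate(CalibrationSpec(Q0=REF_Q0, dp0=REF_DP0, blend=0.4, split=0.6, common_fraction=0.25))


def _straight(ny: int, nx: int | None = None) -> DuctGeometry:
    return DuctGeometry(L=0.03, h=0.005, nx=nx or max(8, ny // 2), ny=ny)


@pytest.fixture(scope="session")
def straight_channel_refinement():
    """CPG Poiseuille relative flux errors at ny = 8, 16, 32."""
    dp = 8.1e-3
    cfg = SolverConfig(window=10.0, discard_fraction=0.7)
    errors = {}
    for ny in (8, 16, 32):
        geom = _straight(ny)
        gq, _, _ = run_case(geom, ForcingSpec(ForcingMode.CPG, dp), cfg)
        q_exact = poiseuille_flow_rate(dp, geom, cfg)
        errors[ny] = abs(gq.Q_mean - q_exact) / q_exact
    return errors


@pytest.fixture(scope="session")
def straight_channel_fine():
    """CPG Poiseuille with 64 cells across the gap: (globals, exact flux)."""
    dp = 8.1e-3
    geom = _straight(64, nx=32)
    cfg = SolverConfig(window=6.0, discard_fraction=0.65)
    gq, series, fields = run_case(geom, ForcingSpec(ForcingMode.CPG, dp), cfg)
    return gq, poiseuille_flow_rate(dp, geom, cfg), fields


@pytest.fixture(scope="session")
def straight_channel_equivalence():
    """CFR run plus CPG/CPI runs cross-seeded from its converged triple."""
    geom = _straight(32)
    cfg = SolverConfig(window=10.0, discard_fraction=0.7)
    Q0 = 1.25e-3
    out = {}
    out["CFR"], out["series_CFR"], _ = run_case(geom, ForcingSpec(ForcingMode.CFR, Q0), cfg)
    out["CPG"], _, _ = run_case(geom, ForcingSpec(ForcingMode.CPG, out["CFR"].dp_mean), cfg)
    out["CPI"], _, _ = run_case(geom, ForcingSpec(ForcingMode.CPI, out["CFR"].P_mean), cfg)
    out["Q0"] = Q0
    out["geom"] = geom
    out["cfg"] = cfg
    return out


@pytest.fixture(scope="session")
def constricted_pair_runs():
    """Pre (deep bump) vs post (shallow bump) under all three forcings."""
    common = dict(L=0.05, h=0.005, nx=48, ny=24, bump_centre=0.025, bump_width=0.02)
    pre = DuctGeometry(bump_depth=0.4, **common)
    post = DuctGeometry(bump_depth=0.2, **common)
    cfg = SolverConfig(window=8.0, discard_fraction=0.6)
    Q0 = 1.0e-3
    runs: dict = {"geom_pre": pre, "geom_post": post, "cfg": cfg}
    runs["pre_CFR"], _, runs["fields_pre_CFR"] = run_case(
        pre, ForcingSpec(ForcingMode.CFR, Q0), cfg
    )
    triple_dp = runs["pre_CFR"].dp_mean
    triple_P = runs["pre_CFR"].P_mean
    runs["post_CFR"], _, _ = run_case(post, ForcingSpec(ForcingMode.CFR, Q0), cfg)
    runs["pre_CPG"], _, _ = run_case(pre, ForcingSpec(ForcingMode.CPG, triple_dp), cfg)
    runs["post_CPG"], _, _ = run_case(post, ForcingSpec(ForcingMode.CPG, triple_dp), cfg)
    runs["pre_CPI"], _, _ = run_case(pre, ForcingSpec(ForcingMode.CPI, triple_P), cfg)
    runs["post_CPI"], _, _ = run_case(post, ForcingSpec(ForcingMode.CPI, triple_P), cfg)
    return runs
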