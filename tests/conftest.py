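"""Shared fixtures: scenario runs are expensive, so the treatment pair and
its ablated twin are built once per session."""

from __future__ import annotations

import pytest

from pspacsys import build_scenario, run_simulation

PAIR_SEED = 2012
SEASONS = (2012, 2013)


def _run_pair(force_ablation: bool):
    out = {}
    for trt in ("control", "p_added"):
        cfg, weather, events = build_scenario(trt, start_years=SEASONS, seed=PAIR_SEED)
        if force_ablation:
            cfg.engine.force_fp_one = True
            cfg.engine.force_fcp_one = True
        out[trt] = run_simulation(cfg, weather, events)
    return out


@pytest.fixture(scope="session")
def two_season_pair():
    """Control vs P-added two-season runs under identical weather."""
    return _run_pair(force_ablation=False)


@pytest.fixture(scope="session")
def ablated_pair():
    """Same pair with the P feedbacks (fP, fCP) forced to 1."""
    return _run_pair(force_ablation=True)
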