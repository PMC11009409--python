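"""Shared fixtures: reduced-statistics simulations reused across tests.

All simulation fixtures are deterministic (fixed seeds) and sized so the
whole suite stays desk-scale; heavier statistics live in the acceptance
script.
"""

from __future__ import annotations

import numpy as np
import pytest

import moirebeam as mb
from moirebeam.io import RunConfig, build_scene


def run_reduced_sim(protons_per_spot: int = 300, seed: int = 1, **cfg_kwargs):
    """One reduced-statistics end-to-end simulation -> DoseGrid."""
    cfg = RunConfig(protons_per_spot=protons_per_spot, seed=seed, **cfg_kwargs)
    plan, dcs, phantom, settings = build_scene(cfg)
    return mb.simulate(plan, dcs, phantom, settings, cfg.protons_per_spot)


@pytest.fixture(scope="session")
def reference_sim():
    """The reference study condition: 2 mm periods, 50% throughput, 30 deg."""
    return run_reduced_sim(dcs_angle=30.0)


@pytest.fixture(scope="session")
def default_dcs():
    return mb.DualCollimatorSystem.symmetric(
        period=2.0, throughput=0.5, angle_deg=30.0
    )


@pytest.fixture(scope="session")
def beam_layers():
    return mb.synthetic_beam_model(mb.default_energy_layers())


@pytest.fixture(scope="session")
def default_plan(beam_layers):
    return mb.build_plan(mb.Box.default_ptv(), beam_layers)
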