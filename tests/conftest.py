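"""Shared fixtures: a small simulated panel with calibrated background model."""

from __future__ import annotations

import numpy as np
import pytest

from bper.error_model import ErrorModelConfig, calibrate
from bper.panel import PanelPosition, PileupMatrix
from bper.simulate import SimulationConfig, draw_error_profile, make_panel, simulate_control


@pytest.fixture(scope="session")
def sim_setup():
    """300-position panel at ~10,000x with 20 calibrated controls.

    Substitution backgrounds log-uniform in [1e-5, 3e-4], matching the
    analytical-validation design; returns (config, profile, fitted model).
    """
    config = SimulationConfig(seed=20160, n_positions=300, sub_rate_bounds=(1e-5, 3e-4))
    rng = np.random.default_rng(config.seed)
    panel = make_panel(config.n_positions, rng)
    profile = draw_error_profile(panel, rng, config)
    controls = [simulate_control(profile, config, rng, f"c{i:02d}") for i in range(config.n_controls)]
    model = calibrate(controls, ErrorModelConfig())
    return config, profile, model


def clean_controls(n_controls=20, n_positions=5, depth=10_000, counts=None):
    """Hand-built zero-error controls on a tiny fixed panel."""
    panel = [PanelPosition("chr1", 100 + i, "ACGTA"[i % 5]) for i in range(n_positions)]
    out = []
    for c in range(n_controls):
        mats = [dict(counts[c].get(i, {})) if counts else {} for i in range(n_positions)]
        out.append(PileupMatrix(f"ctrl{c:02d}", panel, [depth] * n_positions, mats))
    return out
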