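from __future__ import annotations

import pytest

from fieldhtp.simulate import SimulationConfig, simulate_run


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A clean (no corruption/outliers) 8-plot run, shared read-only."""
    cfg = SimulationConfig(n_plot_rows=4, n_plot_cols=2,
                           measurements_per_plot=10, seed=11)
    out = tmp_path_factory.mktemp("small_sim")
    return simulate_run(cfg, out)


@pytest.fixture(scope="session")
def messy_sim(tmp_path_factory):
    """A run with corruption, outliers, wobble and attitude events."""
    cfg = SimulationConfig(n_plot_rows=4, n_plot_cols=2,
                           measurements_per_plot=30,
                           corruption_rate=0.05, outlier_fraction=0.03,
                           wobble_amplitude=0.15, pitch_roll_event_rate=3,
                           seed=23)
    out = tmp_path_factory.mktemp("messy_sim")
    return simulate_run(cfg, out)
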