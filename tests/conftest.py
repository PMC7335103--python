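"""Shared fixtures: small synthetic scenes reused across the suite."""

import numpy as np
import pytest

from firecomposite import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def null_scene():
    """Null scene (no injected signal) on a 10×10 grid, 2001–2018.

    daily_gap_prob is raised enough that some monthly means fall below the
    15-day rule, and a few cells are cold, so every filter has work to do.
    """
    cfg = SceneConfig(grid_shape=(10, 10), n_fire_cells=80,
                      daily_gap_prob=0.35, obs_fraction=0.9,
                      cold_fraction=0.08, rng_seed=123)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def signal_scene():
    """All-arid scene with the reference fire-preceding z profile injected."""
    cfg = SceneConfig(grid_shape=(15, 15), n_fire_cells=200,
                      humid_fraction=0.0,
                      signal_profile=(0.5, 0.3, 0.0, -0.3, -0.5, -0.6),
                      rng_seed=42)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def null_anomalies(null_scene):
    from firecomposite import daily_to_monthly, monthly_climatology, normalize_anomaly
    monthly = daily_to_monthly(null_scene.soil_moisture, 15)
    return normalize_anomaly(monthly, monthly_climatology(monthly))
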