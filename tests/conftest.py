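"""Shared fixtures: simulated sessions and synthetic study cohorts."""

import numpy as np
import pandas as pd
import pytest

from rspgait.io import Session
from rspgait.simulate import (
    LegParams,
    SimulationParams,
    SessionData,
    find_periodic_gait,
    force_asymmetry_params,
    generate_session,
)


def symmetric_params(k: float = 20.0, **kwargs) -> SimulationParams:
    leg = LegParams(L0=1.0, k=k, touchdown_angle=0.50)
    defaults = dict(noise_sigma_force=0.0, noise_sigma_marker=0.0, n_strides=8, seed=1)
    defaults.update(kwargs)
    return SimulationParams(leg_al=leg, leg_ul=leg, **defaults)


@pytest.fixture(scope="session")
def symmetric_gait():
    """Periodic gait for identical legs (k=20 kN/m, 0.50 rad) at 8 m/s."""
    return find_periodic_gait(symmetric_params())


@pytest.fixture(scope="session")
def symmetric_session() -> SessionData:
    """Noiseless symmetric 8-stride session with truth table."""
    return generate_session(symmetric_params())


@pytest.fixture(scope="session")
def asym_session() -> SessionData:
    """Noiseless session with AL stance-average force ~6% below UL."""
    return generate_session(force_asymmetry_params())


@pytest.fixture(scope="session")
def noisy_session() -> SessionData:
    """Default asymmetric-stiffness session with 5 N force noise."""
    return generate_session(SimulationParams(n_strides=8, seed=7))


def as_session(data: SessionData) -> Session:
    return Session(config=data.config, forces=data.forces, markers=data.markers)


def make_cohort(
    n_subjects: int = 10,
    model_effects: dict | None = None,
    sigma_subject: float = 0.5,
    sigma_resid: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic per-trial v_max cohort: subjects x models x stiffness categories.

    ``model_effects`` maps prosthesis model label to its additive v_max
    effect in m/s (reference implied by 0.0 entries).
    """
    model_effects = model_effects or {"FDM": 0.0, "OSR": 0.0, "OBK": 0.0}
    rng = np.random.default_rng(seed)
    k_rsp = {"FDM": 24.0, "OSR": 20.0, "OBK": 18.0}
    rows = []
    for i in range(n_subjects):
        intercept = 7.5 + rng.normal(0.0, sigma_subject)
        for model, effect in model_effects.items():
            for cat in (-1, 0, 1):
                rows.append(
                    {
                        "subject": f"S{i:02d}",
                        "rsp_model": model,
                        "stiffness_category": cat,
                        "height_offset": int(rng.choice([-2, 0, 2])),
                        "k_rsp": k_rsp[model] + 2.0 * cat,
                        "vmax": intercept + effect + rng.normal(0.0, sigma_resid),
                    }
                )
    return pd.DataFrame(rows)
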