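"""Shared fixtures: cached field solutions and reference geometries.

Field solves are deterministic and reused across tests through a
session-scoped cache keyed by (shape, diameter, erd, resolution).
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from retistim.geometry import ElectrodeShape, ElectrodeSpec, build_layer_stack

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from retistim.volume_conductor import solve_potential


@pytest.fixture(scope="session")
def field_cache():
    cache: dict = {}

    def get(shape=ElectrodeShape.DISK, diameter=100.0, erd=20.0,
            current_ua=-20.0, resolution=1.0, domain_radius=1400.0):
        key = (shape, diameter, erd, resolution, domain_radius)
        if key not in cache:
            stack = build_layer_stack(erd, domain_radius=domain_radius)
            spec = ElectrodeSpec(shape, diameter, erd)
            cache[key] = solve_potential(stack, spec, current_ua=-20.0,
                                         resolution=resolution)
        return cache[key].scaled_to(current_ua)

    return get


@pytest.fixture(scope="session")
def disk100_erd20(field_cache):
    """20 μA cathodic field of the 100 μm disk at ERD 20 μm."""
    return field_cache(ElectrodeShape.DISK, 100.0, 20.0)


@pytest.fixture(scope="session")
def rgc_model():
    """Template cell at the origin (soma depth 24 μm handled by callers)."""
    from retistim.rgc import RGCModel, build_morphology

    return RGCModel(build_morphology(soma_xyz=(0.0, 0.0, 24.0)))


@pytest.fixture(scope="session")
def gaussian_drive(rgc_model):
    """Synthetic smooth extracellular potential along the cell (mV at 1 μA):
    a cathodic gaussian well centred over the sodium-channel band."""
    x = rgc_model.morphology.positions[:, 0]
    return -8.0 * np.exp(-((x + 65.0) ** 2) / (2.0 * 40.0 ** 2))
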