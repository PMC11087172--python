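"""Shared fixtures.

Simulated volumes are the only test data; nothing is read from disk.  The
most expensive scans (full field of view at fine spacing) are session-scoped
and shared across test modules.
"""

from __future__ import annotations

import pytest

from phantomqa import (
    SimulationParams,
    clean_diagnostic_params,
    default_head_phantom,
    simulate_scan,
)

#: Coarse in-plane spacing used wherever the resolution module is not under
#: test; keeps per-scan cost ~0.1 s while every ROI still holds hundreds of
#: voxels.
COARSE = 1.0


@pytest.fixture(scope="session")
def spec():
    return default_head_phantom()


@pytest.fixture(scope="session")
def clean_scan(spec):
    """Full clean diagnostic-quality scan at the default fine spacing."""
    return simulate_scan(spec, clean_diagnostic_params(seed=11))


@pytest.fixture(scope="session")
def coarse_noiseless_scan(spec):
    """Artifact-free full scan at coarse spacing (pure render + identity)."""
    return simulate_scan(spec, SimulationParams(in_plane_spacing=COARSE))


def coarse_params(**overrides) -> SimulationParams:
    overrides.setdefault("in_plane_spacing", COARSE)
    return SimulationParams(**overrides)
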