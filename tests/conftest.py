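"""Shared fixtures: small, fast synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from woundkit.io_library import Frame
from woundkit.synthgen import SimConfig, simulate_sequence

# Compact geometry for unit tests: 250 x 666 um field at 2.6 um/px with a
# 300-um scratch; a few seconds to simulate and segment.
SMALL_KW = dict(
    grid=(96, 256),
    pixel_size_um=2.6,
    scratch_width_um=300.0,
    frame_interval_hours=0.5,
    duration_hours=6.0,
    edge_speed_um_per_h=15.0,
    edge_roughness_um=8.0,
    illumination_gradient_pct=2.0,
    noise_sigma=0.008,
)

#: min gap area in px matched to the small geometry (~300x96 px band)
SMALL_MIN_AREA = 2000


def small_config(**overrides) -> SimConfig:
    kw = dict(SMALL_KW)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_sequence():
    """One seeded small linear-closure sequence with ground truth."""
    return simulate_sequence(small_config(seed=42), position_id="fix")


@pytest.fixture(scope="session")
def small_frame(small_sequence):
    return small_sequence.frames[0]


@pytest.fixture()
def constant_frame():
    """A perfectly flat 16-bit frame (valid empty field)."""
    return Frame(pixels=np.full((64, 64), 20000, dtype=np.uint16),
                 bit_depth=16, pixel_size_um=1.3, t_hours=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
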