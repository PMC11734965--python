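"""Shared fixtures: sampling rate, head model, and cached room responses."""

import numpy as np
import pytest

from binsim import scenes

FS = 16000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def head():
    return scenes.HeadModel()


@pytest.fixture(scope="session")
def hall_brir(head):
    """Hall-preset BRIR for the frontal 1.9-m source (the calibration case)."""
    return scenes.simulate_brir(
        scenes.hall_preset(), scenes.SourcePosition(azimuth=0.0, distance=1.9),
        head, FS,
    )


@pytest.fixture(scope="session")
def anechoic_brirs(head):
    """Anechoic BRIRs at the three azimuths the spatial configurations use."""
    room = scenes.anechoic_preset()
    return {
        az: scenes.simulate_brir(room, scenes.SourcePosition(az, 1.9), head, FS)
        for az in (0.0, 60.0, -60.0)
    }


@pytest.fixture(scope="session")
def hall_brirs(head):
    room = scenes.hall_preset()
    return {
        az: scenes.simulate_brir(room, scenes.SourcePosition(az, 1.9), head, FS)
        for az in (0.0, 60.0, -60.0)
    }


@pytest.fixture(scope="session")
def small_room():
    """A fast reverberant room for monotonicity checks (not the hall preset)."""
    return scenes.RoomSpec(kind="hall", dimensions=(6.0, 5.0), absorption=0.3,
                           max_image_order=60, duration=0.4)
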