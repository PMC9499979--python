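"""Shared synthetic fixtures (session-scoped: scenes are deterministic)."""

import numpy as np
import pytest

from pamscape import (
    SceneSpec,
    ScheduledEvent,
    assemble_scene,
    cuvier_template,
    delphinid_template,
    synth,
)

FS = 200_000.0


@pytest.fixture(scope="session")
def cuvier_pulse():
    return synth.make_fm_pulse(cuvier_template(), FS)


@pytest.fixture(scope="session")
def silent_scene():
    """60 s of ambient noise at the 40 dB re 1 µPa²/Hz instrument floor."""
    rec, truth = assemble_scene(SceneSpec(duration_s=60.0, sample_rate=FS, seed=1))
    return rec, truth


@pytest.fixture(scope="session")
def click_train_scene():
    """10 beaked-whale clicks at the default received level over the floor."""
    spec = SceneSpec(
        duration_s=20.0,
        sample_rate=FS,
        seed=3,
        events=[ScheduledEvent(template=cuvier_template(), start_s=2.0, count=10)],
    )
    return assemble_scene(spec)


@pytest.fixture(scope="session")
def mixed_train_scene():
    """10 beaked-whale clicks plus 5 delphinid confusers."""
    spec = SceneSpec(
        duration_s=20.0,
        sample_rate=FS,
        seed=5,
        events=[
            ScheduledEvent(template=cuvier_template(), start_s=2.0, count=10),
            ScheduledEvent(template=delphinid_template(), start_s=10.0, count=5),
        ],
    )
    return assemble_scene(spec)


@pytest.fixture(scope="session")
def silent_metrics(silent_scene):
    from pamscape import soundscape

    rec, _ = silent_scene
    return soundscape.compute_minute_metrics(rec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
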