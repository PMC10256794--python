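import numpy as np
import pytest

from wmcoupling import ContactSet, SynthConfig, TimeSeriesPanel
from wmcoupling.synth import generate_participant


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_contacts():
    coords = np.array(
        [
            [10.0, 10.0, 10.0],
            [30.0, 12.0, 14.0],
            [18.0, 34.0, 22.0],
            [40.0, 40.0, 40.0],
            [12.0, 40.0, 38.0],
        ]
    )
    return ContactSet(
        ids=tuple(f"c{i}" for i in range(5)),
        coords=coords,
        tissue=("white",) * 5,
    )


def make_panel(values, fs=2000.0, modality="seeg"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = tuple(f"ch{i}" for i in range(values.shape[0]))
    return TimeSeriesPanel(values=values, fs=fs, channel_ids=ids, modality=modality)


@pytest.fixture
def tiny_cfg():
    """A fast, fully-featured synthetic participant configuration."""
    return SynthConfig(
        n_contacts=8,
        box_extent=60.0,
        lfp_duration=12.0,
        bold_n_volumes=60,
        coupling_strength=0.5,
        sc_density=1.0,
        distance_decay=0.01,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_participant_cached():
    cfg = SynthConfig(
        n_contacts=8,
        box_extent=60.0,
        lfp_duration=12.0,
        bold_n_volumes=60,
        coupling_strength=0.5,
        sc_density=1.0,
        distance_decay=0.01,
        seed=42,
    )
    return generate_participant(cfg, render_volume=True)
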