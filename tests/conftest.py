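import numpy as np
import pytest

from spiketexture.data_model import AnalysisWindow
from spiketexture.synthetic import (
    NeuronSpec,
    StudyConfig,
    TrialSimulator,
    main_design,
    make_templates,
    simulate_study,
    speed_design,
)

WINDOW0 = AnalysisWindow(start=0.0)


@pytest.fixture(scope="session")
def window0():
    return WINDOW0


@pytest.fixture(scope="session")
def small_study():
    """10 neurons x 12 textures x 5 repeats at 80 mm/s."""
    return simulate_study(StudyConfig(n_neurons=10, n_textures=12, n_repeats=5), 101)


@pytest.fixture(scope="session")
def pop_study():
    """Scaled-down main design for population analyses: 40 x 20 x 5."""
    return simulate_study(main_design(n_neurons=40, n_textures=20), 42)


@pytest.fixture(scope="session")
def speed_study():
    """Scaled-down speed design: 16 neurons x 10 textures x 4 speeds x 5."""
    return simulate_study(speed_design(n_neurons=16), 7)


@pytest.fixture(scope="session")
def shared24_study():
    """Main-design composition over the 24-texture shared set (141 neurons)."""
    return simulate_study(main_design(n_neurons=141, n_textures=24), 3)


def patterned_neuron_trains(
    group_params: dict,
    templates,
    seed_tag: int,
    n_repeats: int = 5,
    speed: float = 80.0,
):
    """Trains for one hand-built neuron over the given templates."""
    spec = NeuronSpec(**group_params)
    trains = []
    for j, tpl in enumerate(templates):
        sim = TrialSimulator(spec, tpl, [speed], [seed_tag, 4, 0, j])
        trains.extend(sim.trial(speed, k) for k in range(n_repeats))
    return spec, trains


@pytest.fixture(scope="session")
def templates15():
    return make_templates(15, 900)


@pytest.fixture(scope="session")
def group_contrast_trains(templates15):
    """12 PC-like and 12 SA1-like hand-built neurons over 15 shared textures."""
    rng = np.random.default_rng(77)
    out = {"PC-like": [], "SA1-like": []}
    for g, (prec_rng, ps_rng, wts) in {
        "PC-like": ((0.5, 2.0), (0.6, 0.9), (0.05, 0.05, 0.9)),
        "SA1-like": ((10.0, 30.0), (0.05, 0.2), (0.9, 0.05, 0.05)),
    }.items():
        for i in range(12):
            params = dict(
                neuron_id=f"{g}-{i}",
                base_rate=float(rng.uniform(30, 90)),
                rate_tuning_sd=15.0,
                temporal_precision=float(np.exp(rng.uniform(*np.log(prec_rng)))),
                pattern_strength=float(rng.uniform(*ps_rng)),
                submodality_weights=wts,
                group=g,
            )
            out[g].append(patterned_neuron_trains(params, templates15, 3000 + i))
    return out
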