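import numpy as np
import pytest

from cortex_patterns import synthgen
from cortex_patterns.synthgen import GeneratorConfig, simulation_config


@pytest.fixture(scope="session")
def sim_vortex():
    """Default simulated vortex scene (geometry-simulation rendering)."""
    return synthgen.gen_vortex(simulation_config(seed=1))


@pytest.fixture(scope="session")
def instrument_cfg():
    """Default instrument-emulating configuration (29-nm px, 38-nm PSF)."""
    return GeneratorConfig(seed=0)


@pytest.fixture(scope="session")
def benchmark_scenes():
    """Labelled benchmark: 10 scenes per class at default noise."""
    scenes = []
    for s in range(10):
        scenes.append(("vortex", *synthgen.gen_vortex(GeneratorConfig(seed=s))))
        scenes.append(
            (
                "star",
                *synthgen.gen_asterisk(
                    GeneratorConfig(seed=100 + s, image_size=(288, 288)), "star", 5000.0
                ),
            )
        )
        scenes.append(
            (
                "aster",
                *synthgen.gen_asterisk(
                    GeneratorConfig(seed=200 + s, image_size=(288, 288)), "aster", 2400.0
                ),
            )
        )
        scenes.append(
            (
                "random",
                *synthgen.gen_random_network(
                    GeneratorConfig(seed=300 + s, image_size=(288, 288))
                ),
            )
        )
    return scenes


def diameter_sweep_cases():
    """(span_nm, n_arms) cases for the diameter-recovery sweep.

    Small asters carry fewer arms: at 1-2 um the default dozen arms would
    sit closer together than the optical resolution can separate.
    """
    return [(1000.0, 8), (1500.0, 8), (2400.0, None), (4000.0, None), (5000.0, None), (8000.0, None)]


@pytest.fixture(scope="session")
def diameter_sweep():
    """Measured vs true spans over 1-8 um, 3 seeds each, default noise."""
    from cortex_patterns.patterns import measure_diameter

    results = []
    for span, n_arms in diameter_sweep_cases():
        kind = "aster" if span < 3000 else "star"
        for seed in range(3):
            size = int(span / 29 * 1.25) + 60
            img, truth = synthgen.gen_asterisk(
                GeneratorConfig(seed=seed, image_size=(size, size)), kind, span, n_arms=n_arms
            )
            results.append((span, measure_diameter(img, truth.patterns[0].centre_px)))
    return results
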