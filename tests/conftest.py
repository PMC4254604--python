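import pytest
from hypothesis import HealthCheck, settings

from sixocellus.homology import SectorConfig
from sixocellus.synthetic_data import (
    FAMILY_PATTERN_PRIORS,
    GeneratorConfig,
    SpeciesPlan,
    generate_survey,
)
from sixocellus.patterns import PatternName

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def cfg() -> SectorConfig:
    return SectorConfig()


def small_plan() -> list[SpeciesPlan]:
    """A three-family miniature of the default taxon plan."""
    return [
        SpeciesPlan("Buthidae", "Buthus01", "buthi01", 6, FAMILY_PATTERN_PRIORS["Buthidae"]),
        SpeciesPlan("Buthidae", "Buthus02", "buthi02", 1, FAMILY_PATTERN_PRIORS["Buthidae"]),
        SpeciesPlan(
            "Chaerilidae", "Chaerilus01", "chaerili01", 4, {PatternName.T2A: 1.0}
        ),
        SpeciesPlan(
            "Scorpionidae", "Scorpio01", "scorpioni01", 5, {PatternName.T4B: 1.0}
        ),
        SpeciesPlan(
            "Typhlochactidae", "Typhlochactus01", "typhlochacti01", 2,
            {PatternName.ABSENT: 1.0},
        ),
    ]


@pytest.fixture
def small_survey():
    gen = GeneratorConfig(
        taxon_plan=small_plan(),
        position_noise_sd=0.0,
        asymmetry_rate=0.0,
        polymorphism_rate=0.0,
        seed=7,
    )
    return generate_survey(gen)
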