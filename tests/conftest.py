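import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from melatil.config import GeneratorConfig
from melatil.generator import generate_corpus, simulate_cohort


def zero_missingness() -> dict:
    return {
        k: 0.0
        for k in (
            "breslow_mm",
            "mitotic_rate",
            "ulceration",
            "histologic_regression",
            "microsatellites",
            "vascular_lymphatic_invasion",
        )
    }


@pytest.fixture(scope="session")
def canonical_corpus():
    """Corpus with canonical phrasing and no omitted features."""
    cfg = GeneratorConfig(
        n_patients=300,
        seed=42,
        variant_intensity=0.0,
        missingness=zero_missingness(),
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def default_corpus():
    """Corpus at the study conditions (variants + missingness on)."""
    return generate_corpus(GeneratorConfig(n_patients=800, seed=7))


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort-level simulation at the study conditions."""
    return simulate_cohort(GeneratorConfig(n_patients=4000, seed=13))
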