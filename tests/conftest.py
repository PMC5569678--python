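import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from ontosearch.fixtures import FixtureSpec, generate

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def bundle():
    """Default heterogeneous bundle: 3 datasets, case/delimiter/synonym."""
    return generate(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def bundle_casedelim():
    """Two datasets perturbed only by case and delimiter changes."""
    return generate(FixtureSpec(n_datasets=2,
                                perturbation_modes=("case", "delimiter"),
                                seed=5))


@pytest.fixture(scope="session")
def bundle_affix():
    """One dataset whose classes have affixed one-to-many twins."""
    return generate(FixtureSpec(n_datasets=1, perturbation_modes=("affix",),
                                dataset_names=("Omimlike",), seed=7))


@pytest.fixture(scope="session")
def bundle_synonym():
    """One dataset whose vocabulary is synonym-substituted."""
    return generate(FixtureSpec(n_datasets=1, perturbation_modes=("synonym",),
                                dataset_names=("Orphanetlike",), seed=7))
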