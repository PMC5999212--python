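"""Shared fixtures: small synthetic studies generated at test time."""

import warnings

import pytest

from hatchscan.config import SimConfig, TraitArchitecture
from hatchscan.containers import TRAITS
from hatchscan.simulate import simulate_study


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_study():
    """300 loci, 40 per population; depths and alignments included."""
    cfg = SimConfig(
        n_loci=300, samples_per_population=40, n_founders=40, seed=11
    )
    return simulate_study(cfg, with_depths=True, with_alignments=True)


@pytest.fixture(scope="session")
def trait_study():
    """Mid-sized study with one strongly genetic trait for association tests."""
    arch = {t: TraitArchitecture(h2=0.0) for t in TRAITS}
    arch["return_day"] = TraitArchitecture(
        n_causal=5, h2=0.8, effect_kind="standardized", min_causal_maf=0.1
    )
    cfg = SimConfig(
        n_loci=400,
        samples_per_population=50,
        n_founders=50,
        trait_architectures=arch,
        seed=23,
    )
    return simulate_study(cfg)
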