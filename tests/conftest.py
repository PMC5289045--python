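import numpy as np
import pytest

from plastmarker import synthetic as syn


def small_synth_config(seed: int = 1, **overrides) -> syn.SynthConfig:
    """A scaled-down trio config that keeps tests inside the time budget.

    Genome length is reduced from the ~151 kb default; genotype counts,
    coverage, error rate and the diversity contrast keep their defaults.
    """
    kw = dict(
        length=24_000,
        seed=seed,
        intraspecific_counts=(218, 31, 31),
        coverage=300.0,
    )
    kw.update(overrides)
    return syn.SynthConfig(**kw)


@pytest.fixture(scope="session")
def trio():
    cfg = small_synth_config(seed=11)
    ancestor = syn.generate_ancestor(cfg)
    genomes, truth = syn.derive_species(ancestor, cfg)
    return cfg, ancestor, genomes, truth


@pytest.fixture(scope="session")
def ancestor_full():
    """Default-size ancestor (151 kb), for size-sensitive checks."""
    cfg = syn.SynthConfig(seed=1)
    return cfg, syn.generate_ancestor(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
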