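import numpy as np
import pytest

from noiavar import EffectEstimates, ModelSpec


@pytest.fixture
def spec3():
    """Three loci, two modelled pairs."""
    return ModelSpec(("A", "B", "C"), (("A", "B"), ("B", "C")))


@pytest.fixture
def spec2():
    return ModelSpec(("A", "B"), (("A", "B"),))


def random_effects(spec, rng, scale=1.0, mu=0.0, with_cov=True, cov_scale=0.2):
    """Random effect set (and a random valid covariance) for a spec."""
    labels = ("mu",) + tuple(spec.design_columns())
    values = np.concatenate([[mu], rng.normal(0.0, scale, len(labels) - 1)])
    cov = None
    if with_cov:
        A = rng.normal(0.0, cov_scale, (len(labels), len(labels)))
        cov = A @ A.T
    return EffectEstimates(labels, values, cov)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
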