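import numpy as np
import pytest

from treecl.core import TreeArrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_records(rng):
    """A small batch of random but valid tree records as arrays."""
    n = 200
    size = rng.lognormal(np.log(150), 0.8, n)
    BA = rng.lognormal(np.log(25), 0.4, n)
    BAL = rng.beta(2, 2, n) * BA
    return TreeArrays(
        size_m=size,
        dt=rng.uniform(5, 10, n),
        BA=BA,
        BAL=BAL,
        T=rng.normal(285, 3, n),
        P=rng.lognormal(np.log(10), 0.3, n),
        N=rng.lognormal(np.log(9), 0.5, n),
        S=rng.lognormal(np.log(6), 0.5, n),
        growth_G=rng.normal(2, 0.5, n),
        survived_y=(rng.random(n) < 0.85).astype(float),
    )


def random_growth_params(rng, spec):
    """Random valid growth parameters for a spec (for oracle comparisons)."""
    from treecl.core import param_names, params_from_vector

    draw = {
        "a": rng.uniform(0.5, 5), "z": rng.uniform(0, 1),
        "a2": rng.uniform(-0.05, 0.05), "a3": rng.uniform(-0.5, 0.5),
        "t1": rng.uniform(270, 300), "t2": rng.uniform(0.05, 3),
        "p1": rng.uniform(4, 18), "p2": rng.uniform(0.1, 3),
        "n1": rng.uniform(2, 30), "n2": rng.uniform(0.1, 3),
        "s1": rng.uniform(1, 15), "s2": rng.uniform(0.2, 4),
        "s3": rng.uniform(0, 0.9), "sigma": rng.uniform(0.1, 2),
    }
    names = param_names(spec)
    return params_from_vector(spec, [draw[nm] for nm in names])


def random_survival_params(rng, spec):
    from treecl.core import param_names, params_from_vector

    draw = {
        "a": rng.uniform(0.9, 1.0),
        "zc1": rng.uniform(0, 1), "zc2": rng.uniform(0, 0.5),
        "zc3": rng.uniform(0, 1e-3), "zc4": rng.uniform(0.2, 1.5),
        "br1": rng.uniform(0, 0.5), "br2": rng.uniform(0.2, 2),
        "br3": rng.uniform(0, 1),
        "z1": rng.uniform(50, 400), "z2": rng.uniform(0.5, 8),
        "ba1": rng.uniform(10, 50), "ba2": rng.uniform(0.5, 8),
        "bl1": rng.uniform(2, 40), "bl2": rng.uniform(0.5, 8),
        "t1": rng.uniform(270, 300), "t2": rng.uniform(0.5, 8),
        "p1": rng.uniform(4, 18), "p2": rng.uniform(0.5, 8),
        "n1": rng.uniform(2, 30), "n2": rng.uniform(0.5, 8),
        "s1": rng.uniform(1, 15), "s2": rng.uniform(0.2, 4),
        "s3": rng.uniform(0, 0.9),
    }
    names = param_names(spec)
    return params_from_vector(spec, [draw[nm] for nm in names])
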