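import numpy as np
import pytest

from csccp import GeneratorSpec, MassPeak, ScaffoldConfiguration


@pytest.fixture
def two_by_two():
    """The running 2-position example: W=[[1,2],[1,2]], P=[[.9,.1],[.8,.2]].

    All four selections, brute-forced by hand:
      (0,0): mass 2, prob 0.72   (0,1): mass 3, prob 0.18
      (1,0): mass 3, prob 0.08   (1,1): mass 4, prob 0.02
    """
    return ScaffoldConfiguration(
        scaffold_id="TOY",
        config_index=0,
        K=[2, 2],
        W=[[1.0, 2.0], [1.0, 2.0]],
        P=[[0.9, 0.1], [0.8, 0.2]],
    )


@pytest.fixture
def oracle_spec():
    """Generator bounds that keep every instance brute-forceable."""
    return GeneratorSpec(
        n_range=(1, 6), k_range=(1, 5), weight_range=(0.5, 15.0), digits=2
    )


@pytest.fixture
def peak_d0():
    def make(w_min, w_max):
        return MassPeak(float(w_min), float(w_max), D=0)

    return make
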