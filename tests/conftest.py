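import numpy as np
import pytest

from hadamax import StateSpace, load_trna_example

#: printed values of the worked 3x3 tRNA sub-landscape, 2-dp display
TRNA_EPSILON = [-0.17, -0.21, 0.02, -0.24, -0.53, 0.19, -0.05, 0.33, 0.08]
TRNA_EPSILON_ERR = [0.02, 0.06, 0.02, 0.05, 0.16, 0.04, 0.03, 0.07, 0.04]

#: small spaces exercising homogeneous, biallelic and heterogeneous cases
SMALL_SPACES = [
    (2,),
    (3,),
    (5,),
    (2, 2),
    (2, 3),
    (3, 3),
    (4, 2),
    (2, 2, 2),
    (2, 3, 4),
    (3, 3, 3),
    (4, 4, 4),
    (2, 2, 2, 2),
]


@pytest.fixture(scope="session")
def trna():
    land, alphabet = load_trna_example()
    return land, alphabet


@pytest.fixture(params=SMALL_SPACES, ids=lambda c: "x".join(map(str, c)))
def small_space(request):
    return StateSpace(request.param)


def round_half_away(x, ndigits=2):
    f = 10**ndigits
    return np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f
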