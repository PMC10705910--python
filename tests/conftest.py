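import math

import numpy as np
import pytest

from sdmet.datasets import (
    CARBOHYDRATE_ION_KEYS,
    load_carbohydrate_library,
    load_metabolite_table,
)
from sdmet.spectra import match_ions


@pytest.fixture(scope="session")
def carb_library():
    """Bundled relative-intensity spectra of CB_A, CB_B, 4DG, 2DG."""
    return load_carbohydrate_library()


@pytest.fixture(scope="session")
def carb_table(carb_library):
    """The four carbohydrate spectra aligned on the six common ion slots."""
    return match_ions(list(carb_library), list(CARBOHYDRATE_ION_KEYS), 0.5)


@pytest.fixture(scope="session")
def metabolite_records():
    return load_metabolite_table()


def brute_force_pearson(x, y):
    """Direct summation of the Pearson formula (independent oracle)."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def mix_to_correlation(x, z, r):
    """Gram-Schmidt construction of a vector with exact sample correlation r
    to x (test-side helper, independent of the package's generator)."""
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    xc = x - x.mean()
    zc = z - z.mean()
    zc = zc - (zc @ xc) / (xc @ xc) * xc
    y = r * xc / np.linalg.norm(xc) + math.sqrt(1 - r * r) * zc / np.linalg.norm(zc)
    return y
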