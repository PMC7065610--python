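import numpy as np
import pandas as pd
import pytest

import ftirct as ft


@pytest.fixture(scope="session")
def axis():
    """The full instrument grid, 4000 -> 752 cm^-1 at 4 cm^-1."""
    return ft.default_axis()


@pytest.fixture(scope="session")
def fp_axis():
    """The fingerprint imaging grid, 1800 -> 752 cm^-1 at 4 cm^-1."""
    return ft.fingerprint_axis()


@pytest.fixture(scope="session")
def collagen(axis):
    return ft.generate_pure_spectrum(ft.collagen_model(), axis)


@pytest.fixture(scope="session")
def c4s(axis):
    return ft.generate_pure_spectrum(ft.c4s_model(), axis)


@pytest.fixture(scope="session")
def pure_set(axis, collagen, c4s):
    """Three clean replicates of each pure component, as one dataset."""
    ids = [f"coll_{i}" for i in range(3)] + [f"c4s_{i}" for i in range(3)]
    mat = np.stack([collagen.intensity] * 3 + [c4s.intensity] * 3)
    labels = pd.DataFrame(
        {"component": ["collagen_I"] * 3 + ["C4S"] * 3},
        index=pd.Index(ids, name="id"),
    )
    return ft.SpectrumSet(axis, mat, labels)


@pytest.fixture(scope="session")
def pure_processed(pure_set):
    """The pure dataset after the full crop/SG/EMSC chain."""
    return ft.preprocess_pipeline(pure_set, ft.SGParams(), region=(750, 4000)).data


@pytest.fixture(scope="session")
def mixture_design_processed(axis):
    """Clean binary mixtures at C-4-S fractions 0, 0.1, 0.5, 1 after preprocessing."""
    fracs = [0.0, 0.1, 0.5, 1.0]
    rows = [
        ft.generate_mixture_spectrum(
            {"collagen_I": 1 - f, "C4S": f}, axis
        ).intensity
        for f in fracs
    ]
    labels = pd.DataFrame(
        {"c4s_fraction": fracs},
        index=pd.Index([f"mix_{int(100 * f)}" for f in fracs], name="id"),
    )
    mix = ft.SpectrumSet(axis, np.stack(rows), labels)
    return ft.preprocess_pipeline(mix, ft.SGParams(), region=(750, 4000)).data


def make_set(axis, matrix, ids=None, **label_cols):
    """Small helper: build a SpectrumSet from a raw matrix."""
    matrix = np.atleast_2d(matrix)
    if ids is None:
        ids = [f"s{i}" for i in range(matrix.shape[0])]
    labels = pd.DataFrame(label_cols, index=pd.Index(ids, name="id"))
    return ft.SpectrumSet(axis, matrix, labels)
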