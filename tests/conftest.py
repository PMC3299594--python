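import numpy as np
import pandas as pd
import pytest

from kinaselike import (
    GeneratorSpec,
    LibraryTable,
    fixture_molecules,
    generate_descriptor_table,
    kbd_reference_matrix,
    kbd_reference_profile,
    score_library,
)
from kinaselike.constants import DESCRIPTOR_NAMES


@pytest.fixture(scope="session")
def kbd_profile():
    return kbd_reference_profile()


@pytest.fixture(scope="session")
def kbd_matrix():
    return kbd_reference_matrix()


@pytest.fixture(scope="session")
def fixtures():
    return fixture_molecules()


def make_table(rows, name="test", ids=None, **extra_cols):
    """Build a LibraryTable from a list/array of 9-descriptor rows."""
    arr = np.asarray(rows, dtype=float)
    df = pd.DataFrame(arr, columns=list(DESCRIPTOR_NAMES))
    df.insert(0, "id", ids if ids is not None else [f"m{i}" for i in range(len(arr))])
    for k, v in extra_cols.items():
        df[k] = v
    return LibraryTable(df, name=name)


@pytest.fixture(scope="session")
def kbd_like_table(kbd_profile):
    """A 2,000-row synthetic table drawn from the reference marginals."""
    return generate_descriptor_table(GeneratorSpec.from_table1("KBD", n=2000, rng_seed=42))


@pytest.fixture(scope="session")
def scored_kbd_like(kbd_like_table, kbd_profile):
    return score_library(kbd_like_table, kbd_profile)
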