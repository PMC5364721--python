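import numpy as np
import pandas as pd
import pytest

from angiomine import load_builtin_panel
from angiomine.profiles import ExpressionTable


@pytest.fixture(scope="session")
def human_panel():
    return load_builtin_panel("human")


@pytest.fixture(scope="session")
def mouse_panel():
    return load_builtin_panel("mouse")


def make_table(values: dict, tissues, species="human", actin="ACTB",
               hk=("GAPDH", "HPRT1", "GUSB")):
    """Build a tiny ExpressionTable from {symbol: row} mapping."""
    df = pd.DataFrame({g: np.asarray(v, dtype=float) for g, v in values.items()},
                      index=list(tissues)).T
    return ExpressionTable(species=species, values=df, actin_symbol=actin,
                           housekeeping_symbols=tuple(hk))


@pytest.fixture(scope="session")
def paperlike():
    from angiomine.synthetic_data import paperlike_fixture
    return paperlike_fixture()
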