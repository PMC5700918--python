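import numpy as np
import pandas as pd
import pytest

from sfdispersal.synthetic import (BIOASSAY_COLUMNS, BioassayDesign,
                                   BioassayParams, generate_bioassay)


@pytest.fixture
def default_design():
    return BioassayDesign()


@pytest.fixture
def default_params():
    return BioassayParams()


@pytest.fixture
def small_bioassay():
    """A deterministic 2-block table drawn with a fixed seed."""
    design = BioassayDesign(n_blocks=2)
    return generate_bioassay(design, BioassayParams(), rng=7)


def make_record(on_fed, on_notfed, off_fed, off_notfed, unrecovered,
                block=1, strain="SS", variety="NONBT", interval_h=6):
    released = on_fed + on_notfed + off_fed + off_notfed + unrecovered
    return pd.DataFrame([[block, strain, variety, interval_h, released,
                          on_fed, on_notfed, off_fed, off_notfed, unrecovered]],
                        columns=BIOASSAY_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(202401)
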