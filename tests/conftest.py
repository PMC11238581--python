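import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from vesifit.mds import ChannelGeometry, RadiusFitter, get_fitter
from vesifit.physchem import SolventProps


@pytest.fixture(scope="session")
def solvent() -> SolventProps:
    return SolventProps()


@pytest.fixture(scope="session")
def geometry() -> ChannelGeometry:
    return ChannelGeometry()


@pytest.fixture(scope="session")
def fitter(geometry, solvent) -> RadiusFitter:
    """Shared basis fitter; building the basis dominates sizing cost."""
    return get_fitter(geometry, solvent)
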