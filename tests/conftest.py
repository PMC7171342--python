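import numpy as np
import pytest

from amnioscan import default_library
from amnioscan.extraction import IntensityMatrix, PeakList
from amnioscan.library import LipidLibrary, LipidSpecies


@pytest.fixture(scope="session")
def library():
    """The bundled default 151-species panel."""
    return default_library()


@pytest.fixture
def tiny_library():
    """Hand-built 5-species panel: 2 lecithins, 1 ether PC, 1 SM, 1 PE."""
    return LipidLibrary(
        species=[
            LipidSpecies.from_name("PC(16:0/18:1)", 759.5778, "[M+H]+", 8.0),
            LipidSpecies.from_name("PC(18:0/18:2)", 785.5935, "[M+H]+", 9.0),
            LipidSpecies.from_name("PC(O-16:0/18:1)", 745.5986, "[M+H]+", 8.5),
            LipidSpecies.from_name("SM(d18:1/16:0)", 702.5676, "[M+H]+", 7.0),
            LipidSpecies.from_name("PE(16:0/16:0)", 691.5152, "[M-H]-", 7.5),
        ]
    )


@pytest.fixture
def tiny_peaklist(tiny_library):
    """One peak exactly at each tiny-library target, intensity 100*(j+1)."""
    peaks = np.array(
        [[s.mz, s.expected_rt, 100.0 * (j + 1)] for j, s in enumerate(tiny_library)]
    )
    return PeakList(sample_id="A", peaks=peaks)


def make_matrix(values, names=None, sample_ids=None, normalized=False):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return IntensityMatrix(
        sample_ids=sample_ids or [f"S{i}" for i in range(n)],
        species_names=names or [f"sp{j}" for j in range(p)],
        values=values,
        normalized=normalized,
    )
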