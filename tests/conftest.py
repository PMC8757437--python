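"""Shared fixtures: a tiny hand-written SDfile and generated docking sets."""

import pytest

from confmeta.sdf_core import parse_sdfile
from confmeta.synthdata import generate_fixture

# three-entry hand-written SDfile: a water-like molecule, an ethanol-like
# fragment and a bare molecule with no data items
TINY_SDF = """\
WATER
  hand-written test entry

  3  2  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
    0.9600    0.0000    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.2400    0.9300    0.0000 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
M  END
>  <mol_weight>
174.05

>  <pairs>
1:2.41 7:1.98

>  <note>
abc

$$$$
ETHANOLIC
  second entry

  3  2  0  0  0  0  0  0  0  0999 V2000
    1.0000    2.0000    3.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    2.5400    2.0000    3.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    3.1000    3.3000    3.0000 O   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  2  3  1  0
M  END
>  <mol_weight>
46

>  <tags>
4 8 15

$$$$
BARE
  entry with no data items

  1  0  0  0  0  0  0  0  0  0999 V2000
    5.0000    5.0000    5.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END

$$$$
"""


@pytest.fixture
def tiny_ens():
    return parse_sdfile(TINY_SDF)


@pytest.fixture(scope="session")
def small_fixture():
    """6 molecules x 4 conformers, enough structure for grouping tests."""
    return generate_fixture(n_molecules=6, n_confs=4, seed=11, planted_fraction=0.25)


@pytest.fixture(scope="session")
def full_fixture():
    """The study-scale set: 99 molecules x 10 conformers."""
    return generate_fixture(n_molecules=99, n_confs=10, seed=1)


@pytest.fixture
def small_ens(small_fixture):
    return parse_sdfile(small_fixture.sdf_text)
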