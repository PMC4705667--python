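import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from methylclash import make_ideal_duplex, make_probe_environment


@pytest.fixture(scope="session")
def duplex_gaattc():
    return make_ideal_duplex("GAATTC")


@pytest.fixture(scope="session")
def duplex_aacgtt():
    return make_ideal_duplex("AACGTT")


@pytest.fixture()
def probe_env_m5c():
    """m5C site with a carbon probe at 3.5 A and an oxygen probe at 2.2 A."""
    return make_probe_environment([("C", 3.5), ("O", 2.2)], "m5C", seed=3)


FIXTURE_PDB = """\
HEADER    TEST FIXTURE
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.685   7.161  -4.923  1.00 10.00           C
ATOM      4  O   ALA A   1      13.600   7.305  -5.735  1.00 10.00           O
ATOM      5  CB AALA A   1      10.521   6.218  -4.118  0.60 10.00           C
ATOM      6  CB BALA A   1      10.411   6.318  -4.218  0.40 10.00           C
ATOM      7  HA  ALA A   1      12.100   5.100  -5.000  1.00 10.00           H
ATOM      8  N1  DC  B   1       2.478  -4.479   2.410  1.00 10.00           N
ATOM      9  C2  DC  B   1       1.437  -5.315   2.107  1.00 10.00           C
ATOM     10  O2  DC  B   1       0.743  -5.080   1.114  1.00 10.00           O
ATOM     11  N3  DC  B   1       1.197  -6.383   2.893  1.00 10.00           N
ATOM     12  C4  DC  B   1       1.957  -6.627   3.958  1.00 10.00           C
ATOM     13  N4  DC  B   1       1.680  -7.692   4.702  1.00 10.00           N
ATOM     14  C5  DC  B   1       3.028  -5.781   4.287  1.00 10.00           C
ATOM     15  C6  DC  B   1       3.258  -4.728   3.496  1.00 10.00           C
ATOM     16  H5  DC  B   1       3.600  -5.950   5.100  1.00 10.00           H
TER
HETATM   17  O   HOH W   1       5.000   5.000   5.000  1.00 20.00           O
END
"""


@pytest.fixture()
def fixture_pdb(tmp_path):
    """One ALA (with an altloc pair and a hydrogen) + one DC + one water."""
    path = tmp_path / "fixture.pdb"
    path.write_text(FIXTURE_PDB)
    return path
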