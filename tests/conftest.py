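import numpy as np
import pytest
from hypothesis import settings

from cysredox.structure import parse_structure

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


TRIPEPTIDE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00  0.00           C
ATOM      6  N   ALA A   2       3.300   1.500   0.200  1.00  0.00           N
ATOM      7  CA  ALA A   2       4.000   2.800   0.200  1.00  0.00           C
ATOM      8  C   ALA A   2       5.500   2.600   0.300  1.00  0.00           C
ATOM      9  O   ALA A   2       6.000   1.500   0.500  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.600   3.600   1.450  1.00  0.00           C
ATOM     11  N   ALA A   3       6.200   3.700   0.200  1.00  0.00           N
ATOM     12  CA  ALA A   3       7.650   3.700   0.300  1.00  0.00           C
ATOM     13  C   ALA A   3       8.200   5.100   0.200  1.00  0.00           C
ATOM     14  O   ALA A   3       7.500   6.100   0.100  1.00  0.00           O
ATOM     15  CB  ALA A   3       8.250   2.900   1.450  1.00  0.00           C
END
"""


@pytest.fixture
def tripeptide():
    return parse_structure(TRIPEPTIDE_PDB, structure_id="tri")


def make_cys_pair_pdb(d: float) -> str:
    """Two CYS residues whose SG atoms are d angstrom apart."""
    lines = []
    serial = 1
    for i, x0 in enumerate((0.0, d)):
        num = i + 1
        for name, elem, off in (
            ("N", "N", (-1.0, 2.0, 0.0)),
            ("CA", "C", (0.0, 2.8, 0.0)),
            ("C", "C", (1.0, 3.6, 0.0)),
            ("O", "O", (2.0, 3.3, 0.0)),
            ("CB", "C", (0.0, 1.4, 0.0)),
            ("SG", "S", (0.0, 0.0, 0.0)),
        ):
            x, y, z = x0 + off[0], off[1], off[2]
            lines.append(
                f"ATOM  {serial:>5}  {name:<3} CYS A{num:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           {elem:>2}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
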