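"""Shared fixtures: small peptides, PDB snippets, a toy docking instance."""

import numpy as np
import pytest

from incdock import fixtures, structio, torsion

MINIMAL_ALA_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.697   7.155  -4.974  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  SER A   1      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  C   SER A   1      12.000  11.400  10.000  1.00  0.00           C
ATOM      4  O   SER A   1      13.200  11.500  10.000  1.00  0.00           O
ATOM      5  CB ASER A   1      11.900   9.200  11.200  0.60  0.00           C
ATOM      6  OG ASER A   1      11.500   7.900  11.100  0.60  0.00           O
ATOM      7  CB BSER A   1      11.950   9.100  11.300  0.40  0.00           C
ATOM      8  OG BSER A   1      11.550   7.800  11.200  0.40  0.00           O
END
"""

WATER_PDB = """\
ATOM      1  N   GLY A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.450  10.000  10.000  1.00  0.00           C
ATOM      3  C   GLY A   1      12.000  11.400  10.000  1.00  0.00           C
ATOM      4  O   GLY A   1      13.200  11.550  10.000  1.00  0.00           O
ATOM      5  N   GLY A   2      11.150  12.420  10.000  1.00  0.00           N
ATOM      6  CA  GLY A   2      11.550  13.820  10.000  1.00  0.00           C
ATOM      7  C   GLY A   2      13.050  13.990  10.000  1.00  0.00           C
ATOM      8  O   GLY A   2      13.550  15.110  10.000  1.00  0.00           O
ATOM      9  N   GLY A   3      13.800  12.900  10.000  1.00  0.00           N
ATOM     10  CA  GLY A   3      15.250  12.950  10.000  1.00  0.00           C
HETATM   11  O   HOH A 101      20.000  20.000  20.000  1.00  0.00           O
HETATM   12  O   HOH A 102      21.000  21.000  21.000  1.00  0.00           O
HETATM   13  O   HOH A 103      22.000  21.000  21.000  1.00  0.00           O
HETATM   14  O   WAT A 104      23.000  21.000  21.000  1.00  0.00           O
HETATM   15  O   HOH A 105      24.000  21.000  21.000  1.00  0.00           O
END
"""


@pytest.fixture(scope="session")
def tri_ala():
    """Tri-alanine peptide with its torsion tree."""
    return fixtures.build_peptide("AAA", seed=11)


@pytest.fixture(scope="session")
def nine_mer():
    """The 9-mer tumour-antigen peptide used in the worked examples."""
    return fixtures.build_peptide("EVDPIGHLY", seed=11)


@pytest.fixture(scope="session")
def eight_mer_29():
    """An 8-mer constructed to carry exactly 29 rotatable bonds."""
    return fixtures.build_peptide("KAKAYAAG", seed=11)


@pytest.fixture(scope="session")
def toy_instance():
    """A small planted re-docking instance shared across engine tests."""
    return fixtures.make_redock_instance("AGA", seed=1, screen=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
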