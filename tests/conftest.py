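import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from qprob.synth import make_extended, make_helix

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def helix12():
    return make_helix(12)


@pytest.fixture(scope="session")
def extended10():
    return make_extended(10)


TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       4.000   2.800   0.100  1.00  0.00           C
ATOM      6  C   GLY A   2       5.500   2.700   0.000  1.00  0.00           C
ATOM      7  N   VAL A   3       6.100   3.900   0.000  1.00  0.00           N
ATOM      8  CA  VAL A   3       7.550   4.000  -0.200  1.00  0.00           C
ATOM      9  C   VAL A   3       8.200   5.400   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


def dssp_line(i, resnum, aa, ss, acc, phi=-57.0, psi=-47.0):
    """One fixed-width DSSP data line (synthetic, matching the column layout)."""
    line = [" "] * 136
    def put(start, text):
        for k, ch in enumerate(text):
            line[start + k] = ch
    put(0, f"{i:5d}")
    if resnum is not None:
        put(5, f"{resnum:5d}")
    put(11, "A")
    put(13, aa)
    put(16, ss)
    put(34, f"{acc:4d}")
    put(38, f"{0:7d}"); put(46, "0.0")
    put(50, f"{0:6d}"); put(57, "0.0")
    put(61, f"{0:6d}"); put(68, "0.0")
    put(72, f"{0:6d}"); put(79, "0.0")
    put(103, f"{phi:6.1f}"); put(109, f"{psi:6.1f}")
    return "".join(line)


DSSP_HEADER = (
    "==== Secondary Structure Definition by the program DSSP ====\n"
    "REFERENCE synthetic fixture\n"
    "  5  1  1  0  0 TOTAL NUMBER OF RESIDUES\n"
    "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N    "
    "N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA\n"
)


@pytest.fixture
def dssp_file(tmp_path):
    """Synthetic 5-line DSSP file: H, G, E, chain break, blank code."""
    rows = [
        dssp_line(1, 1, "A", "H", 100),
        dssp_line(2, 2, "G", "G", 50),
        dssp_line(3, 3, "V", "E", 0),
        "    4      ! " + " " * 100,
        dssp_line(5, 5, "K", " ", 75),
    ]
    path = tmp_path / "model.dssp"
    path.write_text(DSSP_HEADER + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
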