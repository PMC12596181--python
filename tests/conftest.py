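import numpy as np
import pytest

from cryoset import DensityMap, Entry, MetadataTable

TOY_PDB = """\
HELIX    1   1 ALA A    5  ALA A   10  1                                   6
SHEET    1   A 1 ALA A  12  ALA A  13  0
ATOM      1  N   ALA A   4       1.000   1.000   1.000  1.00 20.00           N
ATOM      2  CA  ALA A   4       2.000   1.000   1.000  1.00 20.00           C
ATOM      3  CA  ALA A   5       3.000   2.000   1.000  1.00 20.00           C
ATOM      4  CA  ALA A   6       4.000   3.000   1.000  1.00 20.00           C
ATOM      5  CA  ALA A   7       5.000   4.000   1.000  1.00 20.00           C
ATOM      6  CA  ALA A   8       6.000   5.000   1.000  1.00 20.00           C
ATOM      7  CA  ALA A   9       7.000   6.000   1.000  1.00 20.00           C
ATOM      8  CA  ALA A  10       8.000   7.000   1.000  1.00 20.00           C
ATOM      9  CA  ALA A  11       9.000   8.000   1.000  1.00 20.00           C
ATOM     10  CA  ALA A  12      10.000   9.000   1.000  1.00 20.00           C
ATOM     11  CA  ALA A  13      11.000  10.000   1.000  1.00 20.00           C
TER      12      ALA A  13
ATOM     13  P     A B   1       2.000   8.000   3.000  1.00 20.00           P
ATOM     14  P     U B   2       3.000   8.000   6.000  1.00 20.00           P
ATOM     15  P     G B   3       4.000   8.000   9.000  1.00 20.00           P
ATOM     16  P     C B   4       5.000   8.000  12.000  1.00 20.00           P
TER      17        C B   4
HETATM   18 MG    MG C   1       6.000   6.000   6.000  1.00 20.00          MG
HETATM   19  O   HOH C   2       7.000   7.000   7.000  1.00 20.00           O
END
"""


@pytest.fixture
def toy_pdb_path(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_entry(emdb_id, resolution=3.0, q_score=0.5, xrefs=(), title=None,
               pdb_id="1ABC", contour=0.1):
    return Entry(
        emdb_id=emdb_id,
        title=title if title is not None else f"t-{emdb_id}",
        resolution=resolution,
        pdb_id=pdb_id,
        q_score=q_score,
        contour_level=contour,
        xrefs_uniprot=frozenset(xrefs),
    )


def random_table(rng, n, n_accessions=8, p_empty=0.1):
    """Random metadata table with overlapping cross-reference sets."""
    pool = [f"U{i}" for i in range(n_accessions)]
    entries = []
    for i in range(n):
        if rng.random() < p_empty:
            xrefs = ()
        else:
            k = int(rng.integers(1, n_accessions))
            xrefs = rng.choice(pool, size=k, replace=False).tolist()
        entries.append(
            make_entry(
                f"EMD-{1000 + i}",
                resolution=float(np.round(rng.uniform(2.0, 4.5), 3)),
                q_score=float(np.round(rng.uniform(0.1, 0.8), 3)),
                xrefs=xrefs,
            )
        )
    return MetadataTable(entries)


@pytest.fixture
def ramp_map():
    """32^3 map at 2 A voxels whose value equals the x index."""
    grid = np.broadcast_to(
        np.arange(32, dtype=float)[:, None, None], (32, 32, 32)
    ).copy()
    return DensityMap(grid, voxel_size=(2.0, 2.0, 2.0), origin=(5.0, -3.0, 0.0))
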