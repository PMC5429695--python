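"""Shared fixtures: hand-built chains, planted-geometry folds, tiny files."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cohdoc.structure import Atom, Chain, Residue, Structure
from cohdoc.synthetic import (
    DockerinSpec,
    _build_backbone,
    _rotation_about_axis,
    make_cohesin_plateau,
    make_symmetric_dockerin,
)

# ---------------------------------------------------------------------------
# geometry helpers (independent of the package's assignment logic)


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle in degrees; the standard Newman-projection convention."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    return math.degrees(math.atan2(np.dot(np.cross(b1n, v), w), np.dot(v, w)))


def backbone_chain(N, CA, C, O, name3="GLY", start_auth=1, chain_id="A") -> Chain:
    residues = []
    for k in range(len(CA)):
        residues.append(
            Residue(
                start_auth + k,
                name3,
                [
                    Atom("N", "N", N[k]),
                    Atom("CA", "C", CA[k]),
                    Atom("C", "C", C[k]),
                    Atom("O", "O", O[k]),
                ],
            )
        )
    return Chain(chain_id, residues)


def make_ideal_helix(n_res: int = 15, chain_id: str = "A") -> Chain:
    phis = [math.radians(-57.0)] * n_res
    psis = [math.radians(-47.0)] * n_res
    return backbone_chain(*_build_backbone(phis, psis), chain_id=chain_id)


def _ideal_strand(n_res: int):
    phis = [math.radians(-139.0)] * n_res
    psis = [math.radians(135.0)] * n_res
    return _build_backbone(phis, psis)


# Rigid placement constants for the antiparallel pairing were chosen so that
# successive strands carry a planted ladder of N-H...O=C hydrogen bonds
# (verified in the tests by direct O...N distance computation).
_PAIR_D1, _PAIR_D2, _PAIR_SHIFT = 3.6, -0.8, 0.0


def _strand_frames(n_res: int):
    N1, CA1, C1, O1 = _ideal_strand(n_res)
    axis = CA1[-1] - CA1[0]
    axis /= np.linalg.norm(axis)
    centroid = CA1.mean(axis=0)
    perp = O1[0] - CA1[0]
    perp -= np.dot(perp, axis) * axis
    perp /= np.linalg.norm(perp)
    perp2 = np.cross(axis, perp)
    R = _rotation_about_axis(perp, math.pi)  # antiparallel: reverses the axis
    offset = _PAIR_D1 * perp + _PAIR_D2 * perp2 + _PAIR_SHIFT * axis

    def pair_transform(P):
        return (R @ (P - centroid).T).T + centroid + offset

    return (N1, CA1, C1, O1), pair_transform


def make_beta_hairpin(n_res: int = 8, chain_id: str = "A") -> Chain:
    """Two antiparallel strands with planted inter-strand H-bond geometry."""
    (N1, CA1, C1, O1), T = _strand_frames(n_res)
    chain = backbone_chain(N1, CA1, C1, O1, start_auth=1, chain_id=chain_id)
    second = backbone_chain(T(N1), T(CA1), T(C1), T(O1), start_auth=n_res + 3)
    chain.residues += second.residues
    return chain


def make_meander(n_strands: int = 4, n_res: int = 8, chain_id: str = "A") -> Chain:
    """n_strands antiparallel strands, adjacency 1-2-3-...; one sheet."""
    (N1, CA1, C1, O1), T = _strand_frames(n_res)
    frames = [(N1, CA1, C1, O1)]
    for _ in range(n_strands - 1):
        N1, CA1, C1, O1 = (T(x) for x in (N1, CA1, C1, O1))
        frames.append((N1, CA1, C1, O1))
    chain = Chain(chain_id, [])
    for k, (N, CA, C, O) in enumerate(frames):
        part = backbone_chain(N, CA, C, O, start_auth=1 + k * (n_res + 2))
        chain.residues += part.residues
    return chain


# ---------------------------------------------------------------------------
# tiny hand-written PDB fixtures

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       1.458   1.000   0.000  0.40  0.00           C
ATOM      4  OG ASER A   1       2.000   2.000   0.000  0.50  0.00           O
ATOM      5  OG BSER A   1       2.000   3.000   0.000  0.50  0.00           O
END
"""


@pytest.fixture()
def two_atom_pdb(tmp_path):
    path = tmp_path / "two_atom.pdb"
    path.write_text(TWO_ATOM_PDB)
    return path


@pytest.fixture()
def altloc_pdb(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    return path


def ten_residue_chain(chain_id: str = "A") -> Chain:
    return make_ideal_helix(10, chain_id=chain_id)


# ---------------------------------------------------------------------------
# session-scoped synthetic complexes (deterministic, reused across tests)


@pytest.fixture(scope="session")
def default_spec() -> DockerinSpec:
    return DockerinSpec()


@pytest.fixture(scope="session")
def symmetric_dockerin(default_spec) -> Structure:
    return make_symmetric_dockerin(default_spec)


@pytest.fixture(scope="session")
def symmetric_complex(symmetric_dockerin, default_spec) -> Structure:
    return make_cohesin_plateau(symmetric_dockerin, default_spec)
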