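"""Rigid-body superposition and rmsd.

``kabsch_superpose`` computes the least-squares optimal proper rotation and
translation between two paired point sets (SVD formulation, reflections
excluded).  ``superpose_chains`` builds the atom pairing by global sequence
alignment of two homologous chains and then superposes the mutually present
atoms — the operation underlying rmsd figures such as "0.45 Å over the
cohesin main chain" quoted for cohesin-dockerin complexes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import GeometryError
from .structure import Chain, chain_sequence

MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Transform:
    """Proper rigid motion x -> R @ x + t (Å)."""

    rotation: np.ndarray     # (3, 3), orthonormal, det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return Transform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    @property
    def angle_degrees(self) -> float:
        """Rotation angle from the trace, in [0, 180] degrees."""
        cos_theta = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos_theta, -1.0, 1.0))))

    @staticmethod
    def identity() -> "Transform":
        return Transform(np.eye(3), np.zeros(3))


@dataclass
class SuperpositionResult:
    """Optimal fit of a source point set onto a target."""

    transform: Transform
    rmsd: float
    n_atoms: int
    pairing: list[tuple] = field(default_factory=list)


def kabsch_superpose(
    P: np.ndarray, Q: np.ndarray, pairing: list[tuple] | None = None
) -> SuperpositionResult:
    """Least-squares superpose source points P onto target points Q.

    Returns the proper rotation/translation minimizing the rmsd of
    ``R @ P + t`` against ``Q``.  Requires >= 3 non-collinear pairs.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError(f"point set size mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise GeometryError("need >= 3 paired 3D points")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinearity check: rank of the centred source cloud
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) point set")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P0 @ R.T - Q0
    rmsd = float(np.sqrt((diff**2).sum() / P.shape[0]))
    return SuperpositionResult(
        transform=Transform(R, t),
        rmsd=rmsd,
        n_atoms=P.shape[0],
        pairing=list(pairing) if pairing is not None else [],
    )


def rmsd_unfitted(P: np.ndarray, Q: np.ndarray) -> float:
    """Plain rmsd of a pairing without any superposition."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return float(np.sqrt(((P - Q) ** 2).sum() / P.shape[0]))


def _global_alignment(seq_a: str, seq_b: str):
    """Identity-scored global alignment with affine gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner.align(seq_a, seq_b)[0]


def aligned_residue_pairs(chain_a: Chain, chain_b: Chain) -> list[tuple]:
    """Residue pairs (res_a, res_b) from global sequence alignment."""
    res_a = chain_a.polymer_residues()
    res_b = chain_b.polymer_residues()
    alignment = _global_alignment(chain_sequence(chain_a), chain_sequence(chain_b))
    pairs = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((res_a[i], res_b[j]))
    return pairs


def superpose_chains(
    chain_a: Chain, chain_b: Chain, atom_set: str = "ca"
) -> SuperpositionResult:
    """Superpose chain_a onto chain_b over alignment-paired atoms.

    ``atom_set``: "ca" for Cα only, "main" for N/CA/C/O.  Only atoms present
    in both aligned residues are paired.
    """
    names = ("CA",) if atom_set.lower() in ("ca", "calpha") else MAIN_CHAIN_ATOMS
    P, Q, pairing = [], [], []
    for ra, rb in aligned_residue_pairs(chain_a, chain_b):
        for name in names:
            atom_a, atom_b = ra.atom(name), rb.atom(name)
            if atom_a is None or atom_b is None:
                continue
            P.append(atom_a.position)
            Q.append(atom_b.position)
            pairing.append(
                ((ra.auth_number, ra.name, name), (rb.auth_number, rb.name, name))
            )
    if len(P) < 3:
        raise GeometryError(
            f"alignment of chains {chain_a.id}/{chain_b.id} yields "
            f"{len(P)} paired atoms (< 3)"
        )
    return kabsch_superpose(np.array(P), np.array(Q), pairing=pairing)
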