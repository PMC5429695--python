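"""Ca²⁺ site detection and EF-hand-like coordination-offset classification.

Dockerin repeats each bind one calcium through a loop whose ligating
residues follow characteristic sequence offsets.  The canonical arrangement
is n, n+2, n+4, n+11 plus a water molecule; the atypical variant seen in the
second repeat is n, n+6, n+12 plus a water.  Classification depends only on
the offset set and the water count, so it is invariant to how the
coordinating residues are listed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Chain, Structure

CA_LIGAND_CUTOFF = 3.0  # Å; typical Ca-O distances run 2.2-2.6 Å

CANONICAL_OFFSETS = frozenset({0, 2, 4, 11})
ATYPICAL_OFFSETS = frozenset({0, 6, 12})


@dataclass
class CalciumSite:
    """One calcium ion with its protein and water coordination shell."""

    ion_chain: str
    ion_auth_number: int
    ion_position: np.ndarray
    coordinating_residues: list[tuple[int, str, str, float]]  # (auth, resname, atom, Å)
    water_count: int = 0

    @property
    def offsets(self) -> tuple[int, ...]:
        """Sorted auth-number offsets relative to the first ligating residue."""
        numbers = sorted({auth for auth, _, _, _ in self.coordinating_residues})
        if not numbers:
            return ()
        return tuple(a - numbers[0] for a in numbers)

    @property
    def first_residue(self) -> int | None:
        numbers = [auth for auth, _, _, _ in self.coordinating_residues]
        return min(numbers) if numbers else None


@dataclass
class CoordinationCall:
    pattern: str               # canonical | atypical | other
    low_confidence: bool = False


def _calcium_ions(structure: Structure, chain: Chain):
    """CA ions belonging to ``chain``, else ions nearest to it.

    Deposited entries place ions either in the protein chain or in a
    separate hetero chain; both layouts are handled.
    """
    in_chain, elsewhere = [], []
    for ch in structure.chains:
        for res in ch.residues:
            if res.name != "CA" or not res.is_ion:
                continue
            atom = res.atoms[0]
            if atom.element.upper() not in ("CA", ""):
                continue
            target = in_chain if ch.id == chain.id else elsewhere
            target.append((ch.id, res.auth_number, atom.position))
    if in_chain:
        return in_chain
    # assign stray ions to this chain when their nearest protein atom is here
    protein_atoms = {
        ch.id: np.array(
            [a.position for r in ch.polymer_residues() for a in r.atoms]
        )
        for ch in structure.chains
        if ch.polymer_residues()
    }
    assigned = []
    for cid, auth, pos in elsewhere:
        best_chain, best_d = None, np.inf
        for pid, coords in protein_atoms.items():
            d = np.min(np.linalg.norm(coords - pos, axis=1))
            if d < best_d:
                best_chain, best_d = pid, d
        if best_chain == chain.id:
            assigned.append((cid, auth, pos))
    return assigned


def detect_calcium_sites(
    structure: Structure, chain: Chain | str, cutoff: float = CA_LIGAND_CUTOFF
) -> list[CalciumSite]:
    """Collect, per Ca ion on the chain, protein O/N and water O ligands.

    Sites are ordered by the first coordinating residue's auth number (the
    N-terminal-repeat site first), falling back to ion appearance order.
    """
    if isinstance(chain, str):
        chain = structure.chain(chain)
    sites = []
    for _cid, ion_auth, ion_pos in _calcium_ions(structure, chain):
        ligands: list[tuple[int, str, str, float]] = []
        waters = 0
        for res in chain.polymer_residues():
            for atom in res.atoms:
                if atom.element.upper() not in ("O", "N"):
                    continue
                d = float(np.linalg.norm(atom.position - ion_pos))
                if d <= cutoff:
                    ligands.append((res.auth_number, res.name, atom.name, d))
        for ch in structure.chains:
            for res in ch.residues:
                if not res.is_water:
                    continue
                for atom in res.atoms:
                    if atom.element.upper() == "O" and (
                        float(np.linalg.norm(atom.position - ion_pos)) <= cutoff
                    ):
                        waters += 1
        sites.append(
            CalciumSite(
                ion_chain=chain.id,
                ion_auth_number=ion_auth,
                ion_position=ion_pos,
                coordinating_residues=sorted(ligands),
                water_count=waters,
            )
        )
    sites.sort(key=lambda s: (s.first_residue is None, s.first_residue, s.ion_auth_number))
    return sites


def classify_coordination_pattern(site: CalciumSite) -> CoordinationCall:
    """Match the ligating-residue offset set against the known arrangements.

    Matching is exact-set: extra coordinating residues beyond the pattern
    demote the call to "other" (waters never do).  Fewer than three
    coordinating residues gives a low-confidence "other".
    """
    distinct = {auth for auth, _, _, _ in site.coordinating_residues}
    if len(distinct) < 3:
        return CoordinationCall("other", low_confidence=True)
    offsets = frozenset(site.offsets)
    if offsets == CANONICAL_OFFSETS and site.water_count >= 1:
        return CoordinationCall("canonical")
    if offsets == ATYPICAL_OFFSETS and site.water_count >= 1:
        return CoordinationCall("atypical")
    return CoordinationCall("other")
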