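"""Main-chain hydrogen-bond secondary-structure assignment (H/E/C).

A deliberately minimal assigner in the Kabsch-Sander style: amide hydrogens
are reconstructed from the previous peptide plane, H-bond energies use the
electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)   [kcal/mol]

with a bond below -0.5 kcal/mol.  Helices come from consecutive i -> i+4
bonds, strands from bridge ladders (parallel and antiparallel patterns), and
sheets from transitive strand pairing.  This is enough to recover the
strand/helix topology of a cohesin β-sandwich; turns, bends and solvent
accessibility are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Chain

HBOND_ENERGY_CUTOFF = -0.5   # kcal/mol
MIN_STRAND_LENGTH = 2
PEPTIDE_BOND_MAX = 2.5       # Å, C(i-1)-N(i) continuity check
COUPLING_CONSTANT = 0.084 * 332.0


@dataclass
class SecondaryStructure:
    """Per-residue labels plus strand/sheet bookkeeping for one chain."""

    labels: list[str]                       # H/E/C per polymer residue
    auth_numbers: list[int]                 # parallel to labels
    strand_segments: list[tuple[int, int]]  # (first_auth, last_auth), seq order
    helix_segments: list[tuple[int, int]]
    sheets: list[list[int]]                 # strand indices (1-based), grouped
    strand_adjacency: dict[tuple[int, int], int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def label_of(self, auth_number: int) -> str:
        try:
            return self.labels[self.auth_numbers.index(auth_number)]
        except ValueError:
            return "C"

    @property
    def n_strands(self) -> int:
        return len(self.strand_segments)

    @property
    def n_helices(self) -> int:
        return len(self.helix_segments)


def _main_chain_arrays(chain: Chain):
    residues = chain.polymer_residues()
    n = len(residues)
    coords = {name: np.full((n, 3), np.nan) for name in ("N", "CA", "C", "O")}
    for i, res in enumerate(residues):
        for name in coords:
            atom = res.atom(name)
            if atom is not None:
                coords[name][i] = atom.position
    return residues, coords


def _amide_hydrogens(residues, coords) -> np.ndarray:
    """H position 1 Å from N along the previous C=O direction (DSSP rule)."""
    n = len(residues)
    H = np.full((n, 3), np.nan)
    for i in range(1, n):
        if residues[i].name == "PRO":
            continue
        c_prev, o_prev, n_i = coords["C"][i - 1], coords["O"][i - 1], coords["N"][i]
        if np.isnan(c_prev).any() or np.isnan(o_prev).any() or np.isnan(n_i).any():
            continue
        if np.linalg.norm(c_prev - n_i) > PEPTIDE_BOND_MAX:
            continue  # chain break
        direction = c_prev - o_prev
        H[i] = n_i + direction / np.linalg.norm(direction)
    return H


def _hbond_matrix(residues, coords, H) -> np.ndarray:
    """bond[i, j] True when CO of residue i accepts the NH of residue j."""
    n = len(residues)
    bond = np.zeros((n, n), dtype=bool)
    C, O, N = coords["C"], coords["O"], coords["N"]
    for j in range(n):  # donor NH_j
        if np.isnan(H[j]).any() or np.isnan(N[j]).any():
            continue
        for i in range(n):  # acceptor CO_i
            if abs(i - j) < 2:
                continue
            if np.isnan(C[i]).any() or np.isnan(O[i]).any():
                continue
            r_on = np.linalg.norm(O[i] - N[j])
            if r_on > 5.2:  # beyond any plausible H-bond
                continue
            r_ch = np.linalg.norm(C[i] - H[j])
            r_oh = np.linalg.norm(O[i] - H[j])
            r_cn = np.linalg.norm(C[i] - N[j])
            energy = COUPLING_CONSTANT * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if energy < HBOND_ENERGY_CUTOFF:
                bond[i, j] = True
    return bond


def _segments(flags: list[bool], auth: list[int], min_len: int) -> list[tuple[int, int]]:
    segments, start = [], None
    for i, on in enumerate(flags + [False]):
        if on and start is None:
            start = i
        elif not on and start is not None:
            if i - start >= min_len:
                segments.append((auth[start], auth[i - 1]))
            start = None
    return segments


def assign_secondary_structure(chain: Chain) -> SecondaryStructure:
    """Assign H/E/C labels and strand/sheet topology from main-chain H-bonds."""
    residues, coords = _main_chain_arrays(chain)
    n = len(residues)
    auth = [r.auth_number for r in residues]
    warnings = []
    n_incomplete = sum(
        1 for i in range(n) if any(np.isnan(coords[k][i]).any() for k in coords)
    )
    if n_incomplete:
        warnings.append(
            f"{n_incomplete} residues missing main-chain atoms; labelled C"
        )
    H = _amide_hydrogens(residues, coords)
    bond = _hbond_matrix(residues, coords, H)

    helix = [False] * n
    # two consecutive i -> i+4 turns make residues i+1 .. i+4 helical
    for i in range(n - 5):
        if bond[i, i + 4] and bond[i + 1, i + 5]:
            for k in range(i + 1, i + 5):
                helix[k] = True

    def hb(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and bond[i, j]

    bridges: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 3, n):
            parallel = (hb(i - 1, j) and hb(j, i + 1)) or (
                hb(j - 1, i) and hb(i, j + 1)
            )
            antiparallel = (hb(i, j) and hb(j, i)) or (
                hb(i - 1, j + 1) and hb(j - 1, i + 1)
            )
            if parallel or antiparallel:
                bridges.append((i, j))

    strand = [False] * n
    for i, j in bridges:
        strand[i] = strand[j] = True
    # helix assignment wins where the patterns overlap spuriously
    strand = [s and not h for s, h in zip(strand, helix)]
    # close single-residue gaps inside ladders (pleating makes alternate
    # residues carry the bridges)
    for i in range(1, n - 1):
        if not strand[i] and strand[i - 1] and strand[i + 1] and not helix[i]:
            strand[i] = True

    strand_segments = _segments(strand, auth, MIN_STRAND_LENGTH)
    helix_segments = _segments(helix, auth, 4)

    labels = []
    in_strand_seg = set()
    for first, last in strand_segments:
        for a in auth:
            if first <= a <= last:
                in_strand_seg.add(a)
    for i in range(n):
        if helix[i]:
            labels.append("H")
        elif auth[i] in in_strand_seg and strand[i]:
            labels.append("E")
        else:
            labels.append("C")

    def strand_index_of(residue_pos: int) -> int | None:
        a = auth[residue_pos]
        for k, (first, last) in enumerate(strand_segments):
            if first <= a <= last and labels[residue_pos] == "E":
                return k + 1
        return None

    adjacency: dict[tuple[int, int], int] = {}
    for i, j in bridges:
        si, sj = strand_index_of(i), strand_index_of(j)
        if si is None or sj is None or si == sj:
            continue
        key = (min(si, sj), max(si, sj))
        adjacency[key] = adjacency.get(key, 0) + 1

    sheets = _connected_strand_groups(len(strand_segments), adjacency)
    return SecondaryStructure(
        labels=labels,
        auth_numbers=auth,
        strand_segments=strand_segments,
        helix_segments=helix_segments,
        sheets=sheets,
        strand_adjacency=adjacency,
        warnings=warnings,
    )


def _connected_strand_groups(n_strands, adjacency) -> list[list[int]]:
    parent = list(range(n_strands + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in adjacency:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for s in range(1, n_strands + 1):
        groups.setdefault(find(s), []).append(s)
    # only groups with >= 2 strands constitute sheets
    return [sorted(g) for g in groups.values() if len(g) >= 2]


def sheet_topology(ss: SecondaryStructure, chain: Chain | None = None) -> list[list[int]]:
    """Order each sheet's strands by spatial adjacency.

    Walks the strand-pairing graph from an end strand; for cyclic sheets
    (β-barrels) the walk starts at the lowest strand index.
    """
    ordered_sheets = []
    for sheet in ss.sheets:
        neighbours: dict[int, list[int]] = {s: [] for s in sheet}
        for (a, b), _count in ss.strand_adjacency.items():
            if a in neighbours and b in neighbours:
                neighbours[a].append(b)
                neighbours[b].append(a)
        ends = sorted(s for s in sheet if len(neighbours[s]) == 1)
        start = ends[0] if ends else min(sheet)
        order, seen = [start], {start}
        while True:
            nxt = [s for s in neighbours[order[-1]] if s not in seen]
            if not nxt:
                break
            # prefer the most strongly paired continuation
            nxt.sort(key=lambda s: -ss.strand_adjacency.get(
                (min(s, order[-1]), max(s, order[-1])), 0))
            order.append(nxt[0])
            seen.add(nxt[0])
        # strands not reached by the walk (branched sheets) appended in index order
        order += sorted(s for s in sheet if s not in seen)
        ordered_sheets.append(order)
    return ordered_sheets
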