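"""Synthetic fixtures: idealized dockerins, a cohesin-like plateau, ITC data.

The dockerin generator builds one repeat — an 11-residue calcium-binding
loop followed by an ideal α-helix (φ=-57°, ψ=-47°) — from internal
coordinates with standard bond lengths and angles, then places the second
repeat as an exact copy rotated 180° about a two-fold axis.  Loop dihedrals
were designed numerically so that the ligating residues at loop offsets
0/2/4 and the helix N-cap (offset 11) reach a common Ca²⁺ position, giving
each repeat a canonical {0,2,4,11}-offset coordination shell plus one
water.  Side chains are geometric idealizations (atoms placed along the
outward Cβ direction), sufficient for contact detection and compatibility
analysis; fixtures are geometric, not energetic.

All fixtures are written/read through the package's own structure module,
so every generated object is also a parser round-trip test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import GenerationError
from .itc import ItcDataset, ItcProtocol, ThermoParams, simulate_titration, write_itc
from .structure import AA1TO3, Atom, Chain, Residue, Structure

# ---------------------------------------------------------------------------
# backbone internal-coordinate machinery

B_NCA, B_CAC, B_CN, B_CO = 1.458, 1.525, 1.329, 1.231
A_NCAC, A_CACN, A_CNCA = math.radians(111.2), math.radians(116.2), math.radians(121.7)
A_CACO = math.radians(120.8)
HELIX_PHI, HELIX_PSI = math.radians(-57.0), math.radians(-47.0)

# Designed loop dihedrals (degrees): with these, the Cα atoms of loop
# residues 0, 2, 4 sit 6.65 Å and the first helix residue 8.15 Å from a
# common ion position, matching Asp/Glu side-chain reach + a 2.35 Å Ca-O bond.
LOOP_PHIS_DEG = (-70.7, -112.5, -148.4, -134.8, -31.4, -44.7,
                 -71.9, -70.2, -87.6, -40.6, -56.3)
LOOP_PSIS_DEG = (-68.5, 151.0, -49.2, 113.4, -23.1, 131.7,
                 46.8, 5.7, 33.4, -56.2, -32.4)

LIGAND_OFFSETS = (0, 2, 4, 11)   # within-repeat offsets of the Ca ligands
CA_O_BOND = 2.35                 # Å, planted ion-ligand distance

DEFAULT_LOOP_SEQ = "DKDGDGSAAGK"      # ligands D0, D2, D4
DEFAULT_HELIX_SEQ = "EISALVAQMKALGY"  # E: ligand 11; I(+1)/V(+5): contacts
DEFAULT_CONTACT_HELIX_OFFSETS = (1, 5)  # helix residues that face the cohesin


def _nerf(a, b, c, bond, angle, torsion):
    """Place atom D from three predecessors by internal coordinates."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _build_backbone(phis, psis):
    """N/CA/C/O arrays for a chain with the given dihedrals (ω = 180°)."""
    n_res = len(phis)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_NCA, 0.0, 0.0])]
    prev_c = np.array([-0.5, 0.87, 0.0])  # virtual atom fixing the first plane
    C = [_nerf(prev_c, N[0], CA[0], B_CAC, A_NCAC, phis[0])]
    O = []
    for i in range(1, n_res):
        N.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], B_CN, A_CACN, psis[i - 1]))
        # carbonyl O bonded to C(i-1), trans to the new amide N
        O.append(_nerf(N[i - 1], CA[i - 1], C[i - 1], B_CO, A_CACO,
                       math.pi + psis[i - 1]))
        CA.append(_nerf(CA[i - 1], C[i - 1], N[i], B_NCA, A_CNCA, math.pi))
        C.append(_nerf(C[i - 1], N[i], CA[i], B_CAC, A_NCAC, phis[i]))
    O.append(_nerf(N[-1], CA[-1], C[-1], B_CO, A_CACO, math.pi + psis[-1]))
    return np.array(N), np.array(CA), np.array(C), np.array(O)


# ---------------------------------------------------------------------------
# idealized side chains: (atom name, distance along Cβ direction, lateral)

SIDE_CHAIN_TEMPLATES: dict[str, list[tuple[str, float, float]]] = {
    "GLY": [],
    "ALA": [("CB", 1.53, 0.0)],
    "VAL": [("CB", 1.53, 0.0), ("CG1", 2.5, 0.8), ("CG2", 2.5, -0.8)],
    "ILE": [("CB", 1.53, 0.0), ("CG1", 2.55, 0.8), ("CG2", 2.55, -0.8),
            ("CD1", 3.9, 0.8)],
    "LEU": [("CB", 1.53, 0.0), ("CG", 2.9, 0.0), ("CD1", 4.0, 0.0),
            ("CD2", 3.7, -1.1)],
    "SER": [("CB", 1.53, 0.0), ("OG", 2.9, 0.0)],
    "THR": [("CB", 1.53, 0.0), ("OG1", 2.8, 0.7), ("CG2", 2.8, -0.7)],
    "CYS": [("CB", 1.53, 0.0), ("SG", 3.3, 0.0)],
    "MET": [("CB", 1.53, 0.0), ("CG", 2.9, 0.0), ("SD", 4.5, 0.0),
            ("CE", 5.9, 0.0)],
    "ASP": [("CB", 1.53, 0.0), ("CG", 3.05, 0.0), ("OD1", 4.30, 0.0),
            ("OD2", 3.6, -1.1)],
    "ASN": [("CB", 1.53, 0.0), ("CG", 3.05, 0.0), ("OD1", 4.30, 0.0),
            ("ND2", 3.6, -1.1)],
    "GLU": [("CB", 1.53, 0.0), ("CG", 2.9, 0.0), ("CD", 4.3, 0.0),
            ("OE1", 5.82, 0.0), ("OE2", 5.3, -1.1)],
    "GLN": [("CB", 1.53, 0.0), ("CG", 2.9, 0.0), ("CD", 4.3, 0.0),
            ("OE1", 5.82, 0.0), ("NE2", 5.3, -1.1)],
    "LYS": [("CB", 1.53, 0.0), ("CG", 2.9, 0.0), ("CD", 4.2, 0.0),
            ("CE", 5.5, 0.0), ("NZ", 6.9, 0.0)],
    "ARG": [("CB", 1.53, 0.0), ("CG", 2.9, 0.0), ("CD", 4.2, 0.0),
            ("NE", 5.5, 0.0), ("CZ", 6.8, 0.0), ("NH1", 7.9, 0.8),
            ("NH2", 7.9, -0.8)],
    "HIS": [("CB", 1.53, 0.0), ("CG", 3.0, 0.0), ("ND1", 4.2, 1.1),
            ("CD2", 4.2, -1.1), ("CE1", 5.4, 1.1), ("NE2", 5.5, 0.0)],
    "PHE": [("CB", 1.53, 0.0), ("CG", 3.0, 0.0), ("CD1", 4.2, 1.2),
            ("CD2", 4.2, -1.2), ("CE1", 5.6, 1.2), ("CE2", 5.6, -1.2),
            ("CZ", 6.3, 0.0)],
    "TYR": [("CB", 1.53, 0.0), ("CG", 3.0, 0.0), ("CD1", 4.2, 1.2),
            ("CD2", 4.2, -1.2), ("CE1", 5.6, 1.2), ("CE2", 5.6, -1.2),
            ("CZ", 6.3, 0.0), ("OH", 7.7, 0.0)],
    "TRP": [("CB", 1.53, 0.0), ("CG", 3.0, 0.0), ("CD1", 4.2, 1.1),
            ("CD2", 4.2, -1.1), ("NE1", 5.5, 1.1), ("CE2", 5.6, 0.0),
            ("CE3", 4.9, -2.2), ("CZ2", 6.9, 0.0), ("CZ3", 6.2, -2.2),
            ("CH2", 7.0, -1.1)],
    "PRO": [("CB", 1.5, 0.0), ("CG", 2.4, 0.8), ("CD", 1.9, 1.5)],
}


def _element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch
    return "C"


def sidechain_reach(res_name: str, atom_name: str) -> float:
    """Distance from Cα to a template atom, in Å."""
    for name, along, lateral in SIDE_CHAIN_TEMPLATES[res_name]:
        if name == atom_name:
            return math.hypot(along, lateral)
    raise KeyError(f"{res_name} has no template atom {atom_name}")


def _default_cb_direction(n_pos, ca_pos, c_pos) -> np.ndarray:
    cb = _nerf(c_pos, n_pos, ca_pos, 1.53, math.radians(110.5), math.radians(123.0))
    u = cb - ca_pos
    return u / np.linalg.norm(u)


def _build_residue(
    name3: str,
    n_pos,
    ca_pos,
    c_pos,
    o_pos,
    direction: np.ndarray | None = None,
) -> Residue:
    """Backbone plus an idealized side chain along ``direction`` (or Cβ)."""
    atoms = [
        Atom("N", "N", n_pos),
        Atom("CA", "C", ca_pos),
        Atom("C", "C", c_pos),
        Atom("O", "O", o_pos),
    ]
    template = SIDE_CHAIN_TEMPLATES[name3]
    if template:
        u = direction
        if u is None:
            u = _default_cb_direction(n_pos, ca_pos, c_pos)
        ref = n_pos - ca_pos
        lateral = np.cross(u, ref)
        norm = np.linalg.norm(lateral)
        if norm < 1e-6:
            lateral = np.cross(u, np.array([0.0, 0.0, 1.0]))
            norm = np.linalg.norm(lateral)
        lateral = lateral / norm
        for atom_name, along, lat in template:
            pos = ca_pos + along * u + lat * lateral
            atoms.append(Atom(atom_name, _element_of(atom_name), pos))
    return Residue(auth_number=0, name=name3, atoms=atoms)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle), math.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


# ---------------------------------------------------------------------------
# dockerin specification and builder

@dataclass
class DockerinSpec:
    """Parameters of the idealized two-repeat dockerin fixture."""

    repeat_length: int = 25
    helix_length: int = 14
    sequence_repeat1: str = DEFAULT_LOOP_SEQ + DEFAULT_HELIX_SEQ
    substitutions: list[tuple[int, str]] = field(default_factory=list)
    # (1-based position within the repeat, one-letter code), applied to repeat2
    rotation_axis_jitter: float = 0.0   # degrees of axis tilt
    coordinate_jitter: float = 0.0      # Å, Gaussian noise on all atoms
    seed: int | None = None
    helix_separation: float = 12.0      # Å between the two helix axes
    linker_length: int = 4              # Gly residues bridging the repeats

    def __post_init__(self) -> None:
        if len(self.sequence_repeat1) != self.repeat_length:
            raise GenerationError(
                f"sequence length {len(self.sequence_repeat1)} != repeat_length "
                f"{self.repeat_length}"
            )
        if self.repeat_length < self.helix_length + 4:
            raise GenerationError("repeat_length must be >= helix_length + 4")
        for pos, aa in self.substitutions:
            if not 1 <= pos <= self.repeat_length:
                raise GenerationError(f"substitution position {pos} outside repeat")
            if aa.upper() not in AA1TO3:
                raise GenerationError(f"unknown residue code {aa!r}")

    @property
    def loop_length(self) -> int:
        return self.repeat_length - self.helix_length

    def contact_positions_repeat1(self, first_auth: int = 1) -> tuple[int, ...]:
        """Auth numbers of the designated cohesin-facing helix-1 residues."""
        helix_start = first_auth + self.loop_length
        return tuple(helix_start + k for k in DEFAULT_CONTACT_HELIX_OFFSETS)


def _repeat_dihedrals(spec: DockerinSpec) -> tuple[np.ndarray, np.ndarray]:
    loop = spec.loop_length
    if loop == len(LOOP_PHIS_DEG):
        loop_phis = np.radians(LOOP_PHIS_DEG)
        loop_psis = np.radians(LOOP_PSIS_DEG)
    else:
        # generic compact coil for non-default loop lengths (no guarantee the
        # calcium geometry closes; the default loop is the designed one)
        loop_phis = np.radians(np.resize(LOOP_PHIS_DEG, loop))
        loop_psis = np.radians(np.resize(LOOP_PSIS_DEG, loop))
    phis = np.concatenate([loop_phis, np.full(spec.helix_length, HELIX_PHI)])
    psis = np.concatenate([loop_psis, np.full(spec.helix_length, HELIX_PSI)])
    return phis, psis


def _fit_ion_position(CA, ligand_indices, radii) -> np.ndarray:
    P = CA[list(ligand_indices)]
    r = np.asarray(radii)

    def res(X):
        return np.linalg.norm(P - X, axis=1) - r

    start = P.mean(axis=0) + np.array([0.0, 0.0, 5.0])
    best = None
    for flip in (1.0, -1.0):
        X0 = P.mean(axis=0) + flip * np.array([0.0, 0.0, 5.0])
        sol = least_squares(res, X0)
        if best is None or sol.cost < best.cost:
            best = sol
    return best.x


def _ligand_terminal(res_name3: str) -> str:
    return {"ASP": "OD1", "GLU": "OE1", "ASN": "OD1", "GLN": "OE1",
            "SER": "OG", "THR": "OG1"}.get(res_name3, "OD1")


def _build_repeat1(spec: DockerinSpec):
    """Residues of repeat 1 plus its Ca ion and water positions."""
    phis, psis = _repeat_dihedrals(spec)
    N, CA, C, O = _build_backbone(phis, psis)
    seq3 = [AA1TO3[aa] for aa in spec.sequence_repeat1.upper()]
    ligand_idx = [k for k in LIGAND_OFFSETS if k < spec.repeat_length]
    radii = [
        sidechain_reach(seq3[k], _ligand_terminal(seq3[k])) + CA_O_BOND
        for k in ligand_idx
    ]
    ion = _fit_ion_position(CA, ligand_idx, radii)
    residues = []
    for i, name3 in enumerate(seq3):
        direction = None
        if i in ligand_idx:
            u = ion - CA[i]
            direction = u / np.linalg.norm(u)
        res = _build_residue(name3, N[i], CA[i], C[i], O[i], direction)
        if i not in ligand_idx and SIDE_CHAIN_TEMPLATES[name3]:
            # keep stray side chains out of the designed coordination shell
            closest = min(
                np.linalg.norm(a.position - ion)
                for a in res.atoms
                if a.name not in ("N", "CA", "C", "O")
            )
            if closest < 3.4:
                away = CA[i] - ion
                away = away / np.linalg.norm(away)
                res = _build_residue(name3, N[i], CA[i], C[i], O[i], away)
        residues.append(res)
    tips = np.array([
        residues[k].atom(_ligand_terminal(seq3[k])).position for k in ligand_idx
    ])
    away = ion - tips.mean(axis=0)
    away = away / np.linalg.norm(away)
    water = ion + CA_O_BOND * away
    helix_ca = CA[spec.loop_length:]
    return residues, ion, water, helix_ca


def _helix_axis(helix_ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = helix_ca.mean(axis=0)
    _, _, vt = np.linalg.svd(helix_ca - centroid)
    axis = vt[0]
    if np.dot(helix_ca[-1] - helix_ca[0], axis) < 0:
        axis = -axis
    return centroid, axis


def _clash_check(coords_a: np.ndarray, coords_b: np.ndarray, tolerance: float = 2.2):
    from scipy.spatial import cKDTree

    tree = cKDTree(coords_b)
    dmin = tree.query(coords_a, k=1)[0].min()
    if dmin < tolerance:
        raise GenerationError(
            f"geometry self-clash: inter-repeat atom distance {dmin:.2f} Å "
            f"< {tolerance} Å"
        )


def make_symmetric_dockerin(spec: DockerinSpec | None = None) -> Structure:
    """Two-repeat dockerin with exact internal 180° two-fold symmetry.

    Repeat 2 is the 180°-rotated copy of repeat 1 (optionally with side-chain
    substitutions — see :func:`make_asymmetric_dockerin`).  The chain is D;
    calcium ions are hetero residues 101/102, waters 111/112.
    """
    spec = spec or DockerinSpec()
    if spec.substitutions:
        raise GenerationError(
            "symmetric fixture takes no substitutions; use make_asymmetric_dockerin"
        )
    return _make_dockerin(spec)


def make_asymmetric_dockerin(spec: DockerinSpec) -> Structure:
    """Symmetric dockerin with repeat-2 side-chain substitutions applied."""
    if not spec.substitutions:
        raise GenerationError("asymmetric fixture requires >= 1 substitution")
    return _make_dockerin(spec)


def _make_dockerin(spec: DockerinSpec) -> Structure:
    rng = np.random.default_rng(spec.seed)
    residues1, ion1, water1, helix_ca = _build_repeat1(spec)

    centroid, h = _helix_axis(helix_ca)
    # two-fold axis u perpendicular to the helix; repeat 2 lands on the side
    # opposite the calcium loop
    w = ion1 - centroid
    w = w - np.dot(w, h) * h
    w = w / np.linalg.norm(w)
    u = np.cross(h, w)
    if spec.rotation_axis_jitter > 0:
        tilt = math.radians(spec.rotation_axis_jitter)
        tilt_axis = np.cross(u, rng.normal(size=3))
        tilt_axis /= np.linalg.norm(tilt_axis)
        u = _rotation_about_axis(tilt_axis, tilt) @ u
    axis_point = centroid - (spec.helix_separation / 2.0) * w
    R = _rotation_about_axis(u, math.pi)

    def transform(p: np.ndarray) -> np.ndarray:
        return axis_point + R @ (p - axis_point)

    # repeat 2: transformed copy, with substitutions rebuilt on the new frame
    subs = {pos - 1: AA1TO3[aa.upper()] for pos, aa in spec.substitutions}
    residues2 = []
    for i, res in enumerate(residues1):
        moved = [
            Atom(a.name, a.element, transform(a.position), a.occupancy)
            for a in res.atoms
        ]
        new = Residue(auth_number=0, name=res.name, atoms=moved)
        if i in subs and subs[i] != res.name:
            backbone = {a.name: a.position for a in moved}
            old_cb = new.atom("CB")
            direction = None
            if old_cb is not None:
                d = old_cb.position - backbone["CA"]
                direction = d / np.linalg.norm(d)
            new = _build_residue(
                subs[i], backbone["N"], backbone["CA"], backbone["C"],
                backbone["O"], direction,
            )
        residues2.append(new)
    ion2, water2 = transform(ion1), transform(water1)

    coords1 = np.array([a.position for r in residues1 for a in r.atoms])
    coords2 = np.array([a.position for r in residues2 for a in r.atoms])
    _clash_check(coords1, coords2)

    # short Gly linker interpolated between the repeat termini
    linker_residues = []
    if spec.linker_length > 0:
        start = residues1[-1].atom("C").position
        end = residues2[0].atom("N").position
        seg = end - start
        perp = np.cross(seg, u)
        perp = perp / max(np.linalg.norm(perp), 1e-9)
        for k in range(spec.linker_length):
            t = (k + 1) / (spec.linker_length + 1)
            ca = start + t * seg + 1.2 * perp * math.sin(math.pi * t)
            step = seg / np.linalg.norm(seg)
            linker_residues.append(
                Residue(
                    auth_number=0,
                    name="GLY",
                    atoms=[
                        Atom("N", "N", ca - 1.2 * step),
                        Atom("CA", "C", ca),
                        Atom("C", "C", ca + 1.2 * step),
                        Atom("O", "O", ca + 1.2 * step + 1.23 * perp),
                    ],
                )
            )

    ordered = residues1 + linker_residues + residues2
    for auth, res in enumerate(ordered, start=1):
        res.auth_number = auth

    hetero = [
        Residue(101, "CA", [Atom("CA", "CA", ion1, is_hetero=True)]),
        Residue(102, "CA", [Atom("CA", "CA", ion2, is_hetero=True)]),
        Residue(111, "HOH", [Atom("O", "O", water1, is_hetero=True)]),
        Residue(112, "HOH", [Atom("O", "O", water2, is_hetero=True)]),
    ]
    chain = Chain(id="D", residues=ordered + hetero)

    if spec.coordinate_jitter > 0:
        for res in chain.residues:
            for atom in res.atoms:
                atom.position = atom.position + rng.normal(
                    0.0, spec.coordinate_jitter, 3
                )
    return Structure(id="synthetic-dockerin", chains=[chain], source_format="pdb")


# ---------------------------------------------------------------------------
# cohesin-like plateau

def make_cohesin_plateau(
    doc: Structure,
    spec: DockerinSpec | None = None,
    contact_gap: float = 4.0,
    translate: float = 0.0,
    plant_his_at: int | None = None,
) -> Structure:
    """Combine the dockerin with a flat apolar two-strand ribbon (chain C).

    Leucines on the inner strand are placed so their Cδ1 sits ``contact_gap``
    Å from the tip carbon of each designated helix-1 contact residue —
    emulating the flat hydrophobic platform of a cohesin β-sheet.
    ``translate`` shifts the whole slab outward (useful as a no-contact
    control); ``plant_his_at`` adds a histidine whose Nδ1 is hydrogen-bond
    distance from the Oγ of the given dockerin serine residue.
    """
    spec = spec or DockerinSpec()
    doc_chain = doc.chain("D")
    targets = []
    for auth in spec.contact_positions_repeat1(first_auth=1):
        res = doc_chain.residue(auth)
        if res is None:
            raise GenerationError(f"designated contact residue {auth} absent")
        tip = max(
            (a for a in res.atoms if a.name not in ("N", "CA", "C", "O")),
            key=lambda a: np.linalg.norm(a.position - res.atom("CA").position),
            default=None,
        )
        if tip is None:
            raise GenerationError(f"contact residue {auth} ({res.name}) has no side chain")
        targets.append((res, tip))

    helix_ca = np.array([
        doc_chain.residue(a).atom("CA").position
        for a in range(spec.loop_length + 1, spec.loop_length + spec.helix_length + 1)
        if doc_chain.residue(a) is not None
    ])
    centroid, axis = _helix_axis(helix_ca)

    leu_reach = sidechain_reach("LEU", "CD1")
    leu_ca = []
    for res, tip in targets:
        out = tip.position - centroid
        out = out - np.dot(out, axis) * axis
        out = out / np.linalg.norm(out)
        leu_ca.append((tip.position + (contact_gap + leu_reach) * out, tip.position))

    # inner strand: G L G L G along the line through the two leucine Cα sites
    p0, p1 = leu_ca[0][0], leu_ca[1][0]
    line = p1 - p0
    spacing = np.linalg.norm(line) / 2.0
    line_dir = line / np.linalg.norm(line)
    outward_mean = (p0 + p1) / 2.0 - centroid
    outward_mean /= np.linalg.norm(outward_mean)
    shift = translate * outward_mean
    perp = np.cross(line_dir, outward_mean)
    perp = perp / np.linalg.norm(perp)

    def strand_residue(name3, ca, direction=None):
        n_pos = ca - 1.2 * line_dir + 0.4 * perp
        c_pos = ca + 1.2 * line_dir + 0.4 * perp
        o_pos = c_pos + 1.23 * outward_mean
        return _build_residue(name3, n_pos, ca, c_pos, o_pos, direction)

    residues = []
    slots = [
        ("GLY", p0 - spacing * line_dir, None),
        ("LEU", p0, leu_ca[0][1]),
        ("GLY", p0 + spacing * line_dir, None),
        ("LEU", p1, leu_ca[1][1]),
        ("GLY", p1 + spacing * line_dir, None),
    ]
    for name3, ca, target in slots:
        direction = None
        if target is not None:
            d = target - ca
            direction = d / np.linalg.norm(d)
        residues.append(strand_residue(name3, ca + shift, direction))
    # outer strand: alanines stacked further out, antiparallel sense
    for k in range(5):
        ca = slots[4 - k][1] + 4.8 * outward_mean + shift
        residues.append(strand_residue("ALA", ca, outward_mean))

    if plant_his_at is not None:
        ser = doc_chain.residue(plant_his_at)
        if ser is None or ser.name != "SER" or ser.atom("OG") is None:
            raise GenerationError(
                f"plant_his_at={plant_his_at} must name a serine with an OG atom"
            )
        og = ser.atom("OG").position
        cb = ser.atom("CB").position
        e = og - cb
        e = e / np.linalg.norm(e)
        f = np.cross(e, perp)
        f = f / np.linalg.norm(f)
        nd1 = og + 2.9 * e
        g = np.cross(e, f)
        cg = nd1 + 1.37 * (f + 0.25 * e) / np.linalg.norm(f + 0.25 * e)
        ca_pos = nd1 + 2.5 * e + 1.5 * f
        his = Residue(
            auth_number=0,
            name="HIS",
            atoms=[
                Atom("N", "N", ca_pos + 1.45 * e),
                Atom("CA", "C", ca_pos),
                Atom("C", "C", ca_pos + 1.5 * g),
                Atom("O", "O", ca_pos + 1.5 * g + 1.23 * g),
                Atom("CB", "C", ca_pos - 1.0 * f + 0.6 * e),
                Atom("CG", "C", cg),
                Atom("ND1", "N", nd1),
                Atom("CD2", "C", cg + 1.4 * f),
                Atom("CE1", "C", nd1 + 1.32 * (f - 0.3 * e) / np.linalg.norm(f - 0.3 * e)),
                Atom("NE2", "N", nd1 + 2.3 * f),
            ],
        )
        residues.append(his)

    for auth, res in enumerate(residues, start=1):
        res.auth_number = auth
    coh = Chain(id="C", residues=residues)
    doc_coords = np.array(
        [a.position for r in doc_chain.residues for a in r.atoms]
    )
    coh_coords = np.array([a.position for r in residues for a in r.atoms])
    if translate == 0.0:
        _clash_check(coh_coords, doc_coords, tolerance=2.0)
    return Structure(
        id="synthetic-complex",
        chains=[Chain(id="D", residues=doc_chain.residues), coh],
        source_format="pdb",
    )


# ---------------------------------------------------------------------------
# ITC fixture

def make_itc_dataset(
    params: ThermoParams,
    protocol: ItcProtocol,
    noise_sd: float = 0.0,
    seed: int | None = None,
    path=None,
) -> ItcDataset:
    """Simulate a titration and optionally write the delimited-text file."""
    dataset = simulate_titration(protocol, params, noise_sd=noise_sd, seed=seed)
    if path is not None:
        write_itc(dataset, path)
    return dataset
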