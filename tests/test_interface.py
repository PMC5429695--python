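"""Contact detection on planted geometries and the synthetic complex."""

import numpy as np
import pytest

from cohdoc.interface import (
    detect_hydrophobic_contacts,
    detect_polar_contacts,
    interface_report,
)
from cohdoc.structure import Atom, Chain, Residue, Structure


def residue(auth, name, atoms: dict) -> Residue:
    return Residue(
        auth, name, [Atom(n, n[0], np.asarray(p, float)) for n, p in atoms.items()]
    )


def two_chain(res_a, res_b) -> Structure:
    return Structure("fix", [Chain("A", res_a), Chain("B", res_b)])


def ser_his_pair(d_og_nd1: float = 2.9) -> Structure:
    """Ser OG donor and His ND1 acceptor, antecedent angles satisfied."""
    ser = residue(
        1,
        "SER",
        {
            "N": [-3.0, 0, 0],
            "CA": [-2.0, 0, 0],
            "C": [-2.0, 1.5, 0],
            "O": [-2.0, 2.7, 0],
            "CB": [-1.0, 0, 0],
            "OG": [0.0, 0, 0],
        },
    )
    his = residue(
        1,
        "HIS",
        {
            "N": [d_og_nd1 + 3.5, 0, 0],
            "CA": [d_og_nd1 + 2.8, 0.9, 0],
            "C": [d_og_nd1 + 2.8, 2.4, 0],
            "O": [d_og_nd1 + 2.8, 3.6, 0],
            "CB": [d_og_nd1 + 2.3, -0.5, 0],
            "CG": [d_og_nd1 + 1.37, 0.6, 0],
            "ND1": [d_og_nd1, 0, 0],
        },
    )
    return two_chain([ser], [his])


class TestPolarContacts:
    def test_distant_chains_have_no_contacts(self):
        a = residue(1, "SER", {"N": [0, 0, 0], "CA": [1.4, 0, 0],
                               "C": [2, 1, 0], "O": [2, 2.2, 0],
                               "CB": [1.4, -1.5, 0], "OG": [1.4, -2.9, 0]})
        b = residue(1, "SER", {"N": [50, 0, 0], "CA": [51.4, 0, 0],
                               "C": [52, 1, 0], "O": [52, 2.2, 0],
                               "CB": [51.4, -1.5, 0], "OG": [51.4, -2.9, 0]})
        assert detect_polar_contacts(two_chain([a], [b]), "A", "B") == []

    def test_planted_ser_his_hydrogen_bond(self):
        contacts = detect_polar_contacts(ser_his_pair(2.9), "A", "B")
        assert len(contacts) == 1
        c = contacts[0]
        assert c.kind == "hbond"
        assert {c.atom_a.atom_name, c.atom_b.atom_name} == {"OG", "ND1"}
        assert c.distance == pytest.approx(2.9, abs=1e-6)

    def test_pair_beyond_cutoff_not_reported(self):
        assert detect_polar_contacts(ser_his_pair(3.8), "A", "B") == []

    def test_salt_bridge_tagged_beyond_hbond_distance(self):
        lys = residue(
            1,
            "LYS",
            {"N": [-5, 0, 0], "CA": [-4, 0, 0], "C": [-4, 1.5, 0],
             "O": [-4, 2.7, 0], "CB": [-3, 0, 0], "CG": [-2.4, 0, 0],
             "CD": [-1.8, 0, 0], "CE": [-1.2, 0, 0], "NZ": [0, 0, 0]},
        )
        glu = residue(
            1,
            "GLU",
            {"N": [7.3, 0, 0], "CA": [6.6, 0.9, 0], "C": [6.6, 2.4, 0],
             "O": [6.6, 3.6, 0], "CB": [6.0, 0, 0], "CG": [5.3, 0, 0],
             "CD": [4.6, 0, 0], "OE1": [4.6, -1.2, 0], "OE2": [3.8, 0, 0]},
        )
        contacts = detect_polar_contacts(two_chain([lys], [glu]), "A", "B")
        kinds = {c.kind for c in contacts}
        assert "salt_bridge" in kinds
        bridge = [c for c in contacts if c.kind == "salt_bridge"][0]
        assert bridge.distance == pytest.approx(3.8, abs=1e-6)

    def test_symmetric_in_chain_order(self, symmetric_complex):
        ab = detect_polar_contacts(symmetric_complex, "D", "C")
        ba = detect_polar_contacts(symmetric_complex, "C", "D")

        def keyset(contacts, flip):
            out = set()
            for c in contacts:
                pair = (
                    (c.atom_a.chain, c.atom_a.auth_number, c.atom_a.atom_name),
                    (c.atom_b.chain, c.atom_b.auth_number, c.atom_b.atom_name),
                )
                out.add((pair[1], pair[0]) if flip else pair)
            return out

        assert keyset(ab, False) == keyset(ba, True)


class TestHydrophobicContacts:
    def test_glycine_chains_cannot_make_hydrophobic_contacts(self):
        a = residue(1, "GLY", {"N": [0, 0, 0], "CA": [1.4, 0, 0],
                               "C": [2, 1, 0], "O": [2, 2.2, 0]})
        b = residue(1, "GLY", {"N": [10, 0, 0], "CA": [11.4, 0, 0],
                               "C": [12, 1, 0], "O": [12, 2.2, 0]})
        assert detect_hydrophobic_contacts(two_chain([a], [b]), "A", "B") == []

    def test_planted_leu_ile_pair_reported_once_per_residue_pair(self):
        leu = residue(
            1,
            "LEU",
            {"N": [-4, 0, 0], "CA": [-3, 0, 0], "C": [-3, 1.5, 0],
             "O": [-3, 2.7, 0], "CB": [-2, 0, 0], "CG": [-1.4, 0, 0],
             "CD1": [0, 0, 0], "CD2": [-1.4, -1.2, 0]},
        )
        ile = residue(
            1,
            "ILE",
            {"N": [8, 0, 0], "CA": [7, 0.9, 0], "C": [7, 2.4, 0],
             "O": [7, 3.6, 0], "CB": [6, 0, 0], "CG1": [5.3, 0, 0],
             "CG2": [6, -1.2, 0], "CD1": [4.0, 0, 0]},
        )
        contacts = detect_hydrophobic_contacts(two_chain([leu], [ile]), "A", "B")
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.0, abs=1e-6)
        atom_level = detect_hydrophobic_contacts(
            two_chain([leu], [ile]), "A", "B", atom_level=True
        )
        assert len(atom_level) >= 1
        assert min(c.distance for c in atom_level) == pytest.approx(4.0, abs=1e-6)

    def test_monotone_in_cutoff(self, symmetric_complex):
        tight = detect_hydrophobic_contacts(symmetric_complex, "D", "C", cutoff=4.0)
        loose = detect_hydrophobic_contacts(symmetric_complex, "D", "C", cutoff=4.5)
        tight_pairs = {c.residue_pair for c in tight}
        loose_pairs = {c.residue_pair for c in loose}
        assert tight_pairs <= loose_pairs


class TestInterfaceReport:
    def test_h1_tagging_of_planted_contact(self):
        structure = ser_his_pair(2.9)
        report = interface_report(structure, "A", "B", helix_ranges={"H1": (1, 5)})
        assert report.counts_per_helix == {"H1": 1, "H3": 0, "other": 0}

    def test_empty_interface_is_a_report_not_an_error(self):
        structure = ser_his_pair(3.8)
        report = interface_report(structure, "A", "B")
        assert report.counts_per_kind == {
            "hbond": 0, "salt_bridge": 0, "hydrophobic": 0
        }

    def test_synthetic_complex_contacts_land_in_helix1(
        self, symmetric_complex, default_spec
    ):
        helix_start = default_spec.loop_length + 1
        helix_end = default_spec.loop_length + default_spec.helix_length
        report = interface_report(
            symmetric_complex, "D", "C",
            helix_ranges={"H1": (helix_start, helix_end)},
        )
        assert report.counts_per_kind["hydrophobic"] >= 2
        assert report.counts_per_helix["H1"] == len(report.contacts)
        assert set(report.contact_residues("D")) == set(
            default_spec.contact_positions_repeat1()
        )
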