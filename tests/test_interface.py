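import numpy as np
import pytest

from hlhkit import synthetic
from hlhkit.interface import (
    detect_hydrogen_bonds,
    detect_other_interactions,
    detect_salt_bridges,
    dock_to_bdna,
    groove_assignment,
    interaction_report,
    mutate_residues,
    rewiring,
)
from hlhkit.structio import Atom, Chain, Residue, Structure


def _salt_fixture(distance: float) -> Structure:
    dna = Residue("C", 7, "DA", [
        Atom("P", "P", (0, -1.5, 0)),
        Atom("OP2", "O", (0, 0, 0)),
    ])
    lys = Residue("A", 65, "LYS", [Atom("NZ", "N", (0, distance, 0))])
    return Structure([[Chain("A", "protein", [lys]), Chain("C", "dna", [dna])]])


def _hbond_fixture(distance: float, carbon_bound: bool = False) -> Structure:
    heavy = "CD" if carbon_bound else "NH1"
    element = "C" if carbon_bound else "N"
    arg = Residue("A", 60, "ARG", [
        Atom(heavy, element, (0, 1.0, 0)),
        Atom("HH12", "H", (0, 0, 0)),
    ])
    dna = Residue("C", 7, "DA", [Atom("OP1", "O", (0, -distance, 0))])
    return Structure([[Chain("A", "protein", [arg]), Chain("C", "dna", [dna])]])


PARTNERS = (("A",), ("C",))


class TestSaltBridges:
    def test_printed_style_contact_detected(self):
        recs = detect_salt_bridges(_salt_fixture(2.53), PARTNERS)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(2.53)
        assert {recs[0].from_spec, recs[0].to_spec} == {"A:Lys65:NZ", "C:A7:OP2"}

    @pytest.mark.parametrize("distance, expected", [
        (4.99, 1), (5.00, 1), (5.01, 0), (5.05, 0),
    ])
    def test_inclusive_cutoff_boundary(self, distance, expected):
        assert len(detect_salt_bridges(_salt_fixture(distance), PARTNERS)) == expected

    def test_like_charges_never_pair(self):
        lys = Residue("A", 1, "LYS", [Atom("NZ", "N", (0, 0, 0))])
        arg = Residue("B", 2, "ARG", [Atom("NH1", "N", (0, 2.5, 0))])
        st = Structure([[Chain("A", "protein", [lys]), Chain("B", "protein", [arg])]])
        assert detect_salt_bridges(st, (("A",), ("B",))) == []


class TestHydrogenBonds:
    def test_polar_hydrogen_contact_detected(self):
        recs = detect_hydrogen_bonds(_hbond_fixture(1.87), PARTNERS)
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(1.87)
        assert recs[0].from_spec == "A:Arg60:HH12"

    @pytest.mark.parametrize("distance, expected", [(2.49, 1), (2.50, 1), (2.51, 0)])
    def test_inclusive_cutoff_boundary(self, distance, expected):
        assert len(detect_hydrogen_bonds(_hbond_fixture(distance), PARTNERS)) == expected

    def test_carbon_bound_hydrogen_is_not_a_donor(self):
        assert detect_hydrogen_bonds(_hbond_fixture(1.8, carbon_bound=True), PARTNERS) == []


class TestOtherInteractions:
    def test_attractive_charge_at_printed_maximum(self):
        arg = Residue("A", 99, "ARG", [Atom("NH2", "N", (0, 0, 0))])
        asp = Residue("A", 21, "ASP", [Atom("OD1", "O", (5.53, 0, 0))])
        st = Structure([[Chain("A", "protein", [arg, asp])]])
        recs = [r for r in detect_other_interactions(st, "intra")
                if r.category == "electrostatic_attractive"]
        assert len(recs) == 1
        assert recs[0].distance == pytest.approx(5.53)

    def test_stacked_bases_detected(self, bdna_a10):
        recs = [r for r in detect_other_interactions(bdna_a10, "intra")
                if r.category == "pi_pi_stacked"]
        assert recs, "consecutive bases of an ideal duplex should stack"
        assert all(r.distance <= 5.5 for r in recs)

    def test_distant_side_chains_ignored(self):
        a = Residue("A", 1, "LEU", [Atom("CB", "C", (0, 0, 0)), Atom("CG", "C", (1.5, 0, 0))])
        b = Residue("A", 9, "LEU", [Atom("CB", "C", (9.0, 0, 0))])
        st = Structure([[Chain("A", "protein", [a, b])]])
        assert [r for r in detect_other_interactions(st, "intra")
                if r.category == "alkyl"] == []


class TestInteractionReport:
    def test_showcase_emits_exactly_one_record_per_category(self, showcase):
        st, expected = showcase
        recs = interaction_report(st, ("A",), ("C",))
        assert len(recs) == 6
        by_cat = {r.category: r.distance for r in recs}
        assert by_cat == pytest.approx(expected)

    def test_every_distance_within_its_category_cutoff(self, showcase):
        cutoffs = {"salt_bridge": 5.0, "hydrogen_bond": 2.5,
                   "electrostatic_attractive": 5.6, "pi_pi_stacked": 5.5,
                   "alkyl": 5.5, "pi_alkyl": 6.0}
        recs = interaction_report(showcase[0], ("A",), ("C",))
        for r in recs:
            assert r.distance <= cutoffs[r.category]

    def test_partner_order_symmetric(self, showcase):
        fwd = interaction_report(showcase[0], ("A",), ("C",))
        rev = interaction_report(showcase[0], ("C",), ("A",))
        assert {(r.category, frozenset((r.from_spec, r.to_spec))) for r in fwd} == \
               {(r.category, frozenset((r.from_spec, r.to_spec))) for r in rev}

    def test_protein_only_intra_mode_has_no_phosphate_records(self, hlh_structure):
        recs = interaction_report(hlh_structure)
        assert all("OP" not in r.from_spec and "OP" not in r.to_spec for r in recs)

    def test_stable_under_chain_relabeling(self, showcase):
        st = showcase[0].copy()
        for chain in st.chains:
            if chain.id == "C":
                chain.id = "E"
                for res in chain.residues:
                    res.chain_id = "E"
        relabeled = interaction_report(st, ("A",), ("E",))
        original = interaction_report(showcase[0], ("A",), ("C",))
        assert [(r.category, r.distance) for r in relabeled] == \
               [(r.category, r.distance) for r in original]

    def test_empty_selection_rejected(self, showcase):
        with pytest.raises(ValueError, match="empty"):
            interaction_report(showcase[0], ("Z",), ("C",))


def _arg_phosphate_complex() -> Structure:
    """One full-side-chain arginine whose guanidinium sits by a phosphate."""
    protein = synthetic.add_ideal_side_chains(
        synthetic.build_ideal_helix("R", []))
    protein.chains[0].residues[0].number = 60
    for res in protein.chains[0].residues:
        res.number = 60
    nh1 = protein.chains[0].residue(60).atom("NH1").position
    dna = Residue("C", 7, "DA", [
        Atom("P", "P", nh1 + (0, 4.5, 0)),
        Atom("OP2", "O", nh1 + (0, 3.0, 0)),
    ])
    protein.models[0].append(Chain("C", "dna", [dna]))
    return protein


class TestMutation:
    def test_charge_reversal_removes_salt_bridge(self):
        wt = _arg_phosphate_complex()
        assert detect_salt_bridges(wt, PARTNERS)
        mut = mutate_residues(wt, {("A", 60): "GLU"})
        assert detect_salt_bridges(mut, PARTNERS) == []
        assert mut.chain("A").residue(60).name == "GLU"

    def test_same_type_substitution_keeps_report(self):
        wt = _arg_phosphate_complex()
        same = mutate_residues(wt, {("A", 60): "ARG"})
        before = [(r.category, r.distance) for r in interaction_report(wt, ("A",), ("C",))]
        after = [(r.category, r.distance) for r in interaction_report(same, ("A",), ("C",))]
        assert before == after

    def test_glycine_target_rejected(self):
        st = synthetic.build_ideal_helix("G", [])
        with pytest.raises(ValueError, match="CB"):
            mutate_residues(st, {("A", 1): "GLU"})

    def test_unsupported_type_rejected(self):
        st = synthetic.build_ideal_helix("R", [])
        with pytest.raises(ValueError, match="unsupported"):
            mutate_residues(st, {("A", 1): "TRP"})


def _bridge_records(residues):
    recs = []
    for num in residues:
        st = _salt_fixture(3.0)
        st.chain("A").residues[0].number = num
        recs.extend(detect_salt_bridges(st, PARTNERS))
    return recs


class TestRewiring:
    def test_published_wild_type_vs_mutant_residue_sets(self):
        wt = _bridge_records([60, 61, 65, 96, 99, 100])
        mut = _bridge_records([66, 93, 93, 95])  # one residue bridges twice
        report = rewiring(wt, mut)
        assert len(report.lost) == 6
        assert len(report.gained) == 3  # keyed at residue level
        assert report.conserved == set()

    def test_identical_inputs_no_changes(self):
        recs = _bridge_records([60, 61])
        report = rewiring(recs, recs)
        assert report.lost == set() and report.gained == set()
        assert len(report.conserved) == 2

    def test_subset_means_nothing_gained(self):
        wt = _bridge_records([60, 61, 65])
        mut = _bridge_records([60])
        report = rewiring(wt, mut)
        assert report.gained == set()
        assert len(report.lost) == 2


class TestDocking:
    def test_neutral_protein_never_scores_positive(self, bdna_a10):
        neutral = synthetic.build_neutral_peptide(10)
        clusters = dock_to_bdna(neutral, bdna_a10, n_poses=100, seed=0)
        assert max(p.score for c in clusters for p in c) <= 0.0

    def test_same_seed_identical_ranking(self, bdna_a10):
        cationic = synthetic.build_cationic_peptide(10)
        a = dock_to_bdna(cationic, bdna_a10, n_poses=100, seed=3)
        b = dock_to_bdna(cationic, bdna_a10, n_poses=100, seed=3)
        assert [[p.score for p in c] for c in a] == [[p.score for p in c] for c in b]

    def test_cationic_outranks_neutral(self, bdna_a10):
        cationic = synthetic.build_cationic_peptide(10)
        neutral = synthetic.build_neutral_peptide(10)
        top_c = dock_to_bdna(cationic, bdna_a10, n_poses=200, seed=1)[0][0].score
        top_n = dock_to_bdna(neutral, bdna_a10, n_poses=200, seed=1)[0][0].score
        assert top_c > top_n


class TestGrooveAssignment:
    def test_minor_groove_midpoint(self, bdna_a10):
        theta = np.radians(5 * 36.0)
        point = np.array([4.5 * np.cos(theta), 4.5 * np.sin(theta), 5 * 3.38])
        assert groove_assignment(bdna_a10, point) == "minor"

    def test_opposite_sector_is_major(self, bdna_a10):
        theta = np.radians(5 * 36.0)
        point = np.array([-5.5 * np.cos(theta), -5.5 * np.sin(theta), 5 * 3.38])
        assert groove_assignment(bdna_a10, point) == "major"

    def test_far_point_distal(self, bdna_a10):
        assert groove_assignment(bdna_a10, (50.0, 50.0, 0.0)) == "distal"

    def test_point_by_phosphorus_is_backbone(self, bdna_a10):
        p = bdna_a10.chain("C").residue(3).atom("P").position
        assert groove_assignment(bdna_a10, p + np.array([0.5, 0, 0])) == "backbone"
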