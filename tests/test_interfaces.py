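import itertools

import numpy as np
import pytest

from spiralscan import (
    CYND_SCREW,
    RegionDefinition,
    ScrewParameters,
    SurfaceLabel,
    build_helical_assembly,
    classify_surface_pairs,
    find_contacts,
    region_interface_report,
)
from spiralscan.helix import AssemblyCopy, AssemblyModel, Handedness
from spiralscan.structure import AtomRecord, StructureModel
from spiralscan.synthetic import make_c2_dimer, make_toy_protomer


def _two_copy_assembly(gap):
    """Two single-atom-pair copies whose nearest inter-copy distance is ``gap``."""
    a = StructureModel([
        AtomRecord("A", 1, "GLY", "CA", "C", np.array([0.0, 0.0, 0.0])),
        AtomRecord("A", 2, "GLY", "CA", "C", np.array([10.0, 0.0, 0.0])),
    ])
    b = StructureModel([
        AtomRecord("A", 1, "GLY", "CA", "C", np.array([0.0, 0.0, gap])),
        AtomRecord("A", 2, "GLY", "CA", "C", np.array([10.0, 0.0, gap + 10.0])),
    ])
    return AssemblyModel(
        copies=[AssemblyCopy(0, a, 0.0, 0.0), AssemblyCopy(1, b, -77.0, 1.62)],
        source=a,
        screw=CYND_SCREW,
    )


def _brute_force(assembly, cutoff):
    pairs = set()
    for (ci, cj) in itertools.combinations(range(assembly.n_copies), 2):
        for a in assembly.copies[ci].model.atoms:
            if a.het or a.element.upper() == "H":
                continue
            for b in assembly.copies[cj].model.atoms:
                if b.het or b.element.upper() == "H":
                    continue
                d = float(np.linalg.norm(a.position - b.position))
                if d <= cutoff:
                    pairs.add((
                        ci, cj, a.chain_id, a.residue_number, a.atom_name,
                        b.chain_id, b.residue_number, b.atom_name,
                    ))
    return pairs


class TestFindContacts:
    def test_cutoff_boundary_inclusion_and_exclusion(self):
        asm = _two_copy_assembly(gap=4.4)
        hit = find_contacts(asm, cutoff=4.5)
        assert len(hit) == 1 and hit[0].distance == pytest.approx(4.4)
        assert find_contacts(asm, cutoff=4.3) == []

    def test_single_copy_rejected(self, small_protomer):
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 1)
        with pytest.raises(ValueError):
            find_contacts(asm)

    @pytest.mark.parametrize("n_copies,cutoff", [(3, 4.5), (5, 3.5), (4, 6.0)])
    def test_matches_brute_force_oracle(self, small_protomer, n_copies, cutoff):
        asm = build_helical_assembly(small_protomer, CYND_SCREW, n_copies)
        found = find_contacts(asm, cutoff)
        got = {
            (c.copy_i, c.copy_j, *c.residue_i, c.atom_i, *c.residue_j, c.atom_j)
            for c in found
        }
        assert got == _brute_force(asm, cutoff)

    def test_hydrogens_and_het_excluded(self):
        a = StructureModel([
            AtomRecord("A", 1, "GLY", "CA", "C", np.zeros(3)),
            AtomRecord("A", 1, "GLY", "H", "H", np.array([0.0, 0.0, 1.0])),
            AtomRecord("A", 2, "HOH", "O", "O", np.array([0.0, 0.0, 2.0]), het=True),
        ])
        b = StructureModel([
            AtomRecord("A", 1, "GLY", "CA", "C", np.array([0.0, 0.0, 3.0])),
        ])
        asm = AssemblyModel(
            copies=[AssemblyCopy(0, a, 0.0, 0.0), AssemblyCopy(1, b, 0.0, 0.0)],
            source=a,
        )
        found = find_contacts(asm, cutoff=3.5)
        assert len(found) == 1
        assert found[0].atom_i == "CA" and found[0].distance == pytest.approx(3.0)

    def test_output_sorted_and_canonical(self, small_protomer):
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 4)
        found = find_contacts(asm)
        assert found, "planted interface should produce contacts"
        assert all(c.copy_i < c.copy_j for c in found)
        keys = [(c.copy_i, c.copy_j, c.distance) for c in found]
        assert keys == sorted(keys)

    def test_c_surface_contacts_identical_along_the_spiral(self, small_protomer):
        """Noiseless screw: the (k, k+1) contact set is the same for every k."""
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 6)
        per_pair = {}
        for c in find_contacts(asm):
            if c.copy_j - c.copy_i == 1:
                per_pair.setdefault(c.copy_i, set()).add(
                    (c.residue_i, c.residue_j, c.atom_i, c.atom_j, round(c.distance, 6))
                )
        assert len(per_pair) == 5
        assert len({frozenset(v) for v in per_pair.values()}) == 1

    def test_c2_dimer_contacts_twofold_consistent(self, demo_dimer):
        """If residue a of copy k touches b of copy k+1, b of k touches a of k+1."""
        asm = build_helical_assembly(demo_dimer, CYND_SCREW, 3)
        consec = {
            (c.copy_i, c.copy_j, c.residue_i[1], c.residue_j[1])
            for c in find_contacts(asm)
            if c.copy_j - c.copy_i == 1
        }
        assert consec
        assert all((i, j, b, a) in consec for (i, j, a, b) in consec)


class TestClassifySurfacePairs:
    def test_consecutive_pairs_are_c_surface(self, small_assembly):
        labels = classify_surface_pairs(small_assembly)
        assert labels[(0, 1)] is SurfaceLabel.C
        assert labels[(3, 4)] is SurfaceLabel.C

    def test_cynd_cross_groove_at_five_steps(self, small_protomer):
        # 5 x 77 = 385 deg; 25 deg from a full turn, inside the default 30
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 6)
        labels = classify_surface_pairs(asm)
        assert labels[(0, 5)] is SurfaceLabel.CROSS_GROOVE
        assert labels[(0, 3)] is SurfaceLabel.NONE

    def test_sixfold_twist_exact_turn_any_tolerance(self, small_protomer):
        asm = build_helical_assembly(
            small_protomer, ScrewParameters(2.68, 60.0, Handedness.LEFT), 7
        )
        labels = classify_surface_pairs(asm, groove_tolerance_deg=0.0)
        assert labels[(0, 6)] is SurfaceLabel.CROSS_GROOVE

    def test_declared_dimer_pairs_get_a_surface(self, small_assembly):
        labels = classify_surface_pairs(small_assembly, dimer_pairs=[(0, 1), (2, 3)])
        assert labels[(0, 1)] is SurfaceLabel.A
        assert labels[(2, 3)] is SurfaceLabel.A
        assert labels[(1, 2)] is SurfaceLabel.C

    def test_missing_screw_metadata_rejected(self, small_protomer):
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 3)
        asm.screw = None
        with pytest.raises(ValueError, match="screw"):
            classify_surface_pairs(asm)


class TestRegionReport:
    def test_planted_patch_fills_region1_only(self, small_protomer):
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 4)
        contacts = find_contacts(asm)
        labels = classify_surface_pairs(asm)
        report = region_interface_report(
            contacts,
            (RegionDefinition("region1", 20, 29), RegionDefinition("region2", 40, 50)),
            SurfaceLabel.C,
            labels,
        )
        assert report.per_region["region1"].interface_residues == list(range(20, 30))
        assert report.per_region["region1"].contact_fraction == pytest.approx(1.0)
        assert report.per_region["region2"].interface_residues == []
        assert report.per_region["region2"].contact_fraction == 0.0
        assert report.residues_outside_regions == []
        assert not report.empty_warning

    def test_per_residue_table_nonzero_exactly_at_planted_patch(self):
        protomer = make_toy_protomer(
            n_residues=240, radius=50.0,
            interface_residues=set(range(60, 71)) | set(range(225, 234)),
            seed=5,
        )
        asm = build_helical_assembly(protomer, CYND_SCREW, 4)
        report = region_interface_report(find_contacts(asm))
        planted = set(range(60, 71)) | set(range(225, 234))
        assert set(report.per_residue_contacts) == planted

    def test_empty_contacts_warn_with_zero_counts(self):
        report = region_interface_report([], (RegionDefinition("r", 1, 10),))
        assert report.empty_warning
        assert report.per_region["r"].interface_residues == []
        assert report.per_residue_contacts == {}

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            region_interface_report(
                [], (RegionDefinition("a", 1, 10), RegionDefinition("b", 5, 20))
            )

    def test_contact_relation_invariant_under_copy_relabelling(self, small_protomer):
        """Canonical ordering makes the contact set independent of copy order."""
        asm = build_helical_assembly(small_protomer, CYND_SCREW, 3)
        reversed_asm = AssemblyModel(
            copies=[
                AssemblyCopy(i, asm.copies[2 - i].model, 0.0, 0.0) for i in range(3)
            ],
            source=small_protomer,
            screw=CYND_SCREW,
        )
        fwd = {
            frozenset([(c.copy_i, *c.residue_i, c.atom_i), (c.copy_j, *c.residue_j, c.atom_j)])
            for c in find_contacts(asm)
        }
        # relabel reversed copies back through the permutation
        perm = {0: 2, 1: 1, 2: 0}
        rev = {
            frozenset([(perm[c.copy_i], *c.residue_i, c.atom_i),
                       (perm[c.copy_j], *c.residue_j, c.atom_j)])
            for c in find_contacts(reversed_asm)
        }
        assert fwd == rev


def test_dimer_contact_map_symmetric_under_chain_swap(demo_protomer):
    """Within a C2 dimer, the A->B contact map equals the B->A map."""
    dimer = make_c2_dimer(demo_protomer)
    asm = AssemblyModel(
        copies=[
            AssemblyCopy(0, StructureModel(
                [a for a in dimer.atoms if a.chain_id == "A"], "A"), 0.0, 0.0),
            AssemblyCopy(1, StructureModel(
                [a for a in dimer.atoms if a.chain_id == "B"], "B"), 0.0, 0.0),
        ],
        source=dimer,
    )
    ab = {(c.residue_i[1], c.residue_j[1]) for c in find_contacts(asm, cutoff=12.0)}
    assert ab == {(b, a) for (a, b) in ab}
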