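import numpy as np
import pytest

from atdqc import structure as st
from atdqc import synthetic as synth
from atdqc.structure import (
    Atom,
    EmptyStructureError,
    Residue,
    ResidueRef,
    classify_peptide_bond,
)


class TestReadStructure:
    def test_minimal_pdb(self, minimal_pdb):
        s = st.read_structure(minimal_pdb, "pdb")
        assert len(s.chains) == 1
        assert len(s.chains[0].polymer) == 3
        assert [r.name for r in s.chains[0].polymer] == ["ALA", "GLY", "PRO"]

    def test_water_only_is_empty(self, water_only_pdb):
        with pytest.raises(EmptyStructureError):
            st.read_structure(water_only_pdb, "pdb")

    def test_garbage_file_is_format_error(self, tmp_path):
        p = tmp_path / "junk.pdb"
        p.write_text("this is not a coordinate file\n")
        with pytest.raises((st.FormatError, EmptyStructureError)):
            st.read_structure(p, "pdb")

    def test_pdb_round_trip_through_writer(self, tmp_path, atd_dimer):
        p = tmp_path / "dimer.pdb"
        p.write_text(st.write_pdb(atd_dimer))
        back = st.read_structure(p, "pdb")
        assert back.n_polymer_residues == atd_dimer.n_polymer_residues
        assert [c.id for c in back.polymer_chains] == ["A", "B"]
        # coordinates survive to PDB precision (1e-3 A)
        a0 = atd_dimer.chains[0].polymer[0].atom("CA").coords
        b0 = back.chains[0].polymer[0].atom("CA").coords
        np.testing.assert_allclose(a0, b0, atol=1e-3)

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.30 20.00           N\n"
            "ATOM      2  N  BALA A   1       9.000   0.000   0.000  0.70 20.00           N\n"
            "ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00 20.00           C\n"
            "ATOM      4  C   ALA A   1       2.010   1.420   0.000  1.00 20.00           C\n"
            "END\n"
        )
        p = tmp_path / "alt.pdb"
        p.write_text(text)
        s = st.read_structure(p, "pdb")
        n = s.chains[0].polymer[0].atom("N")
        assert n.coords[0] == pytest.approx(9.0)
        assert n.occupancy == pytest.approx(0.7)


def _angdiff(a, b):
    """Circular distance in degrees (so 180 and -180 coincide)."""
    return abs((a - b + 180.0) % 360.0 - 180.0)


class TestTorsions:
    def test_ideal_helix_round_trip(self):
        spec = [(-57.0, -47.0, 180.0)] * 8
        s = synth.build_peptide("AAAAAAAA", spec)
        recs = st.backbone_torsions(s, "A")
        for i, r in enumerate(recs):
            if r.phi is not None:
                assert _angdiff(r.phi, -57.0) < 1e-6
            if r.psi is not None:
                assert _angdiff(r.psi, -47.0) < 1e-6
            if i > 0:
                assert _angdiff(r.omega, 180.0) < 1e-6

    def test_terminal_angles_undefined(self):
        s = synth.build_peptide("AA", [(-57.0, -47.0, 180.0)] * 2)
        recs = st.backbone_torsions(s, "A")
        assert recs[0].phi is None and recs[0].omega is None
        assert recs[-1].psi is None
        assert recs[1].phi is not None

    def test_chain_break_undefines_angles(self):
        s = synth.build_peptide("AAAA", [(-57.0, -47.0, 180.0)] * 4)
        # translate the last two residues far away -> C(2)-N(3) >> 2.5 A
        for res in s.chains[0].residues[2:]:
            for a in res.atoms:
                a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        recs = st.backbone_torsions(s, "A")
        assert recs[2].phi is None and recs[2].omega is None
        assert recs[1].psi is None
        assert recs[3].phi is not None  # continuity resumes after the break


class TestClassifyPeptideBond:
    @pytest.mark.parametrize(
        "omega,expected",
        [
            (5.0, "cis"),
            (-178.0, "trans"),
            (90.0, "cis"),  # boundary included on the cis side
            (-90.0, "trans"),  # open end of the interval
            (90.000001, "trans"),
            (-89.999999, "cis"),
            (180.0, "trans"),
            (0.0, "cis"),
        ],
    )
    def test_boundary_behavior(self, omega, expected):
        assert classify_peptide_bond(omega) == expected

    def test_undefined_refused(self):
        with pytest.raises(ValueError):
            classify_peptide_bond(None)

    def test_total_on_fine_grid(self):
        for w in np.arange(-179.99, 180.0, 0.37):
            assert classify_peptide_bond(float(w)) in ("cis", "trans")


class TestGlyProMotifs:
    def test_synthetic_dimer_cross_subunit(self, atd_dimer):
        sites = st.find_glypro_motifs(atd_dimer)
        assert len(sites) == 2
        assert all(s.cross_subunit for s in sites)
        assert {(s.donor_chain, s.acceptor_chain) for s in sites} == {("A", "B"), ("B", "A")}
        assert all(s.gly_ref.name == "GLY" and s.pro_ref.name == "PRO" for s in sites)

    def test_conformations_by_family(self, atd_dimer, dtd_dimer):
        for s in st.find_glypro_motifs(atd_dimer):
            assert s.bond_call.conformation == "trans"
        for s in st.find_glypro_motifs(dtd_dimer):
            assert s.bond_call.conformation == "cis"

    def test_no_glypro_gives_empty_list(self):
        s = synth.build_peptide("AAAAAAAA", [(-57.0, -47.0, 180.0)] * 8)
        assert st.find_glypro_motifs(s) == []


class TestCarbonylOrientation:
    def _constructed_site(self, o_gly, o_pro, pocket=(0.0, 0.0, 10.0)):
        """Minimal two-residue motif with explicit carbonyl O positions."""
        gly = Residue("GLY", 1)
        gly.atoms += [
            Atom("N", "N", [-1.3, -1.0, 0.0]),
            Atom("CA", "C", [-1.5, 0.0, 0.0]),
            Atom("C", "C", [-1.0, 0.0, 0.0]),
            Atom("O", "O", o_gly),
        ]
        pro = Residue("PRO", 2)
        pro.atoms += [
            Atom("N", "N", [-0.3, 1.1, 0.0]),
            Atom("CA", "C", [0.6, 1.6, 0.0]),
            Atom("C", "C", [1.0, 0.0, 0.0]),
            Atom("O", "O", o_pro),
        ]
        chain = st.Chain("A", [gly, pro])
        structure = st.Structure("constructed", [chain])
        site = st.MotifSite(
            donor_chain="A",
            acceptor_chain="A",
            gly_ref=ResidueRef("A", 1, "", "GLY"),
            pro_ref=ResidueRef("A", 2, "", "PRO"),
            cross_subunit=False,
            bond_call=None,
            pocket_centroid=np.asarray(pocket, float),
        )
        return site, structure

    def test_both_along_axis_outward(self):
        site, s = self._constructed_site([-1.0, 0.0, 1.2], [1.0, 0.0, 1.2])
        rep = st.carbonyl_orientation(site, s)
        assert rep.parallelism_angle == pytest.approx(0.0, abs=1e-9)
        assert rep.label == "outward-parallel"

    def test_both_against_axis_inward(self):
        site, s = self._constructed_site([-1.0, 0.0, -1.2], [1.0, 0.0, -1.2])
        rep = st.carbonyl_orientation(site, s)
        assert rep.label == "inward-parallel"

    def test_perpendicular_pair_non_parallel(self):
        site, s = self._constructed_site([-1.0, 0.0, 1.2], [2.2, 0.0, 0.0])
        rep = st.carbonyl_orientation(site, s)
        assert rep.parallelism_angle == pytest.approx(90.0, abs=1e-9)
        assert rep.label == "non-parallel"

    def test_reflection_flips_outward_inward(self):
        """Mirroring both O atoms through the carbonyl-C midplane
        perpendicular to the pocket axis flips outward <-> inward."""
        o_g, o_p = [-1.0, 0.0, 1.2], [1.0, 0.0, 1.2]
        site, s = self._constructed_site(o_g, o_p)
        lab1 = st.carbonyl_orientation(site, s).label
        refl = lambda o, c: [o[0], o[1], 2 * c[2] - o[2]]
        site2, s2 = self._constructed_site(
            refl(o_g, [-1.0, 0.0, 0.0]), refl(o_p, [1.0, 0.0, 0.0])
        )
        lab2 = st.carbonyl_orientation(site2, s2).label
        assert {lab1, lab2} == {"outward-parallel", "inward-parallel"}

    def test_missing_oxygen_is_error(self):
        site, s = self._constructed_site([-1.0, 0.0, 1.2], [1.0, 0.0, 1.2])
        s.chains[0].residues[0].atoms = [
            a for a in s.chains[0].residues[0].atoms if a.name != "O"
        ]
        with pytest.raises(st.OrientationUndefinedError):
            st.carbonyl_orientation(site, s)

    def test_family_dimers(self, atd_dimer, dtd_dimer):
        """The trans dimer's carbonyls face away from the pocket, the cis
        dimer's into it (threshold 60 deg accommodates the ideal-geometry
        cis floor of ~51 deg between the two C=O vectors)."""
        s_atd = st.find_glypro_motifs(atd_dimer)[0]
        s_dtd = st.find_glypro_motifs(dtd_dimer)[0]
        rep_atd = st.carbonyl_orientation(s_atd, atd_dimer, parallel_threshold=60.0)
        rep_dtd = st.carbonyl_orientation(s_dtd, dtd_dimer, parallel_threshold=60.0)
        assert rep_atd.label == "inward-parallel"
        assert rep_dtd.label == "outward-parallel"


class TestSuperposition:
    def test_self_superposition(self, atd_dimer):
        rep = st.align_and_superpose(atd_dimer, atd_dimer)
        assert rep.rmsd == pytest.approx(0.0, abs=1e-9)
        n_ca = sum(
            1
            for c in atd_dimer.polymer_chains
            for r in c.polymer
            if r.atom("CA") is not None
        )
        assert rep.n_pairs == n_ca

    def test_noisy_copy_rmsd_matches_expectation(self, atd_dimer):
        """Gaussian noise sigma on one copy gives rmsd ~ sigma*sqrt(3)."""
        sigma = 0.5
        vals = []
        for rep_i in range(20):
            noisy = synth.build_deacylase_dimer("ATD", seed=100 + rep_i, noise_sd=sigma)
            rep = st.align_and_superpose(atd_dimer, noisy, prune_cutoff=None)
            vals.append(rep.rmsd)
        assert np.mean(vals) == pytest.approx(sigma * np.sqrt(3), rel=0.05)

    def test_pruning_monotone(self, atd_dimer):
        noisy = synth.build_deacylase_dimer("ATD", seed=9, noise_sd=1.2)
        free = st.align_and_superpose(atd_dimer, noisy, prune_cutoff=None)
        pruned = st.align_and_superpose(atd_dimer, noisy, prune_cutoff=2.0)
        assert pruned.rmsd <= free.rmsd
        assert pruned.n_pairs <= free.n_pairs


class TestRigidityAndContacts:
    def test_uniform_b_gives_zero_z(self):
        spec = [(-57.0, -47.0, 180.0)] * 6
        s = synth.build_peptide("AAGPAA", spec, bfactors=[20.0] * 6)
        site = st.find_glypro_motifs(s)[0]
        assert st.motif_rigidity(s, site).motif_z == 0.0

    def test_low_motif_b_is_rigid(self):
        spec = [(-57.0, -47.0, 180.0)] * 6
        s = synth.build_peptide("AAGPAA", spec, bfactors=[30, 30, 10, 10, 30, 30])
        rep = st.motif_rigidity(s, st.find_glypro_motifs(s)[0])
        assert rep.motif_z < 0

    def test_all_zero_b_is_error(self):
        spec = [(-57.0, -47.0, 180.0)] * 6
        s = synth.build_peptide("AAGPAA", spec, bfactors=[0.0] * 6)
        with pytest.raises(ValueError):
            st.motif_rigidity(s, st.find_glypro_motifs(s)[0])

    def test_dimer_motif_is_rigid(self, atd_dimer, dtd_dimer):
        for d in (atd_dimer, dtd_dimer):
            site = st.find_glypro_motifs(d)[0]
            assert st.motif_rigidity(d, site).motif_z < 0

    def test_constructed_arginine_contact(self):
        spec = [(-57.0, -47.0, 180.0)] * 6
        s = synth.build_peptide("AAGPAA", spec)
        site = st.find_glypro_motifs(s)[0]
        gly_o = s.chains[0].polymer[2].atom("O").coords
        probe = st.Residue("ARG", 99)
        probe.atoms += [
            Atom("N", "N", gly_o + [40.0, 0, 0]),
            Atom("CA", "C", gly_o + [41.5, 0, 0]),
            Atom("NH1", "N", gly_o + [0.0, 2.9, 0.0]),  # guanidinium N at 2.9 A
        ]
        s.chains[0].residues.append(probe)
        contacts = st.motif_contacts(s, ResidueRef("A", 99, "", "ARG"), site, cutoff=3.5)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(2.9, abs=1e-6)
        assert contacts[0].donor[1] == "NH1"
        assert contacts[0].same_chain is True

    def test_distant_probe_no_contacts(self):
        spec = [(-57.0, -47.0, 180.0)] * 6
        s = synth.build_peptide("AAGPAA", spec)
        site = st.find_glypro_motifs(s)[0]
        probe = st.Residue("ARG", 99)
        probe.atoms.append(Atom("NH1", "N", [500.0, 500.0, 500.0]))
        s.chains[0].residues.append(probe)
        assert st.motif_contacts(s, ResidueRef("A", 99, "", "ARG"), site) == []
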