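"""SASA, buried interface area, contacts, salt bridges, charge composition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biotite.structure as bst

from ftszlat import (
    Atom,
    ContactSpec,
    InterfaceReport,
    RadiusSet,
    Residue,
    StructureError,
    StructureModel,
    analyze_interface,
    buried_area,
    charge_complementarity,
    interface_residues,
    make_contact_dimer,
    residue_pair_distance,
    salt_bridges,
    sasa,
)


def atom_model(positions, elements=None, names=None):
    """A one-chain model of free pseudo-atoms (one residue per atom)."""
    n = len(positions)
    elements = elements or ["C"] * n
    names = names or [f"C{i}" for i in range(n)]
    residues = [
        Residue("ALA", i + 1, [Atom(names[i], elements[i], positions[i])]) for i in range(n)
    ]
    return StructureModel({"A": residues})


def collinear_sasa_oracle(z_centers, ext_radii, n_theta=1_000_000):
    """Reference SASA for spheres on a common axis, by polar quadrature.

    Axial symmetry makes exposure a function of the polar angle alone:
    a surface point of sphere i at angle θ is occluded iff it falls
    inside some neighbour's extended sphere.  Midpoint quadrature over θ
    with weight sinθ/2 integrates the exposed fraction directly —
    independent of the point-grid estimator under test.
    """
    theta = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    w = np.sin(theta) * (math.pi / n_theta) / 2.0
    areas = []
    for i, (zi, Ri) in enumerate(zip(z_centers, ext_radii)):
        z = zi + Ri * np.cos(theta)
        rho2 = (Ri * np.sin(theta)) ** 2
        exposed = np.ones(n_theta, dtype=bool)
        for j, (zj, Rj) in enumerate(zip(z_centers, ext_radii)):
            if j == i:
                continue
            exposed &= rho2 + (z - zj) ** 2 > Rj * Rj
        areas.append(float(np.sum(w[exposed]) * 4.0 * math.pi * Ri * Ri))
    return np.array(areas)


class TestSasa:
    def test_single_sphere_closed_form(self):
        """One C atom: SASA = 4π(1.7 + 1.4)² ≈ 120.76 Å², exact on any grid."""
        model = atom_model([(0.0, 0.0, 0.0)])
        total = sasa(model, n_sphere_points=960).sum()
        assert total == pytest.approx(4 * math.pi * 3.1**2, rel=1e-9)

    def test_separated_atoms_fully_exposed(self):
        model = atom_model([(0, 0, 0), (10.0, 0, 0)], elements=["C", "O"])
        areas = sasa(model, n_sphere_points=960)
        assert areas.iloc[0] == pytest.approx(4 * math.pi * (1.70 + 1.4) ** 2, rel=1e-9)
        assert areas.iloc[1] == pytest.approx(4 * math.pi * (1.52 + 1.4) ** 2, rel=1e-9)

    def test_linear_triatomic_against_quadrature_oracle(self):
        """Three overlapping collinear atoms agree with the 10⁶-point oracle within 1%."""
        z = [0.0, 2.2, 4.1]
        model = atom_model([(0, 0, zi) for zi in z], elements=["C", "N", "O"])
        areas = sasa(model, n_sphere_points=960).to_numpy()
        ext = np.array([1.70, 1.55, 1.52]) + 1.4
        oracle = collinear_sasa_oracle(z, ext)
        np.testing.assert_allclose(areas, oracle, rtol=0.01)

    def test_grid_convergence_960_vs_9600(self, contact_dimer):
        """Doubling-order grid refinement moves totals by < 1%."""
        coarse = sasa(contact_dimer, n_sphere_points=960).sum()
        fine = sasa(contact_dimer, n_sphere_points=9600).sum()
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_cross_check_against_biotite(self, contact_dimer):
        """Independent Shrake–Rupley implementation agrees within grid error."""
        atoms = []
        arr = bst.AtomArray(contact_dimer.n_atoms)
        i = 0
        for cid, res, atom in contact_dimer.iter_atoms():
            arr.chain_id[i] = cid
            arr.res_id[i] = res.seq_id
            arr.res_name[i] = res.name
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
            arr.coord[i] = atom.coords
            i += 1
        ref = bst.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii="Single").sum()
        ours = sasa(contact_dimer, n_sphere_points=960).sum()
        assert ours == pytest.approx(ref, rel=0.04)  # radius sets differ slightly

    def test_unknown_element_named_in_error(self):
        model = atom_model([(0, 0, 0)], elements=["XX"], names=["XX1"])
        with pytest.raises(StructureError, match="XX"):
            sasa(model)
        assert sasa(model, radii=RadiusSet({"C": 1.7}, fallback=1.7)).sum() > 0

    def test_too_few_points_rejected(self, contact_dimer):
        with pytest.raises(ValueError, match="100"):
            sasa(contact_dimer, n_sphere_points=50)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_adding_an_atom_never_increases_sasa(self, seed):
        """Monotonicity: occlusion only grows as atoms are added."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-3.0, 3.0, (5, 3))
        before = sasa(atom_model(pts[:4]), n_sphere_points=240).to_numpy()
        after = sasa(atom_model(pts), n_sphere_points=240).to_numpy()[:4]
        assert np.all(after <= before + 1e-9)


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self):
        dimer = make_contact_dimer(ContactSpec([("LYS", "GLU", 30.0)]))
        assert buried_area(dimer, ["A"], ["B"]) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry_in_sides(self, contact_dimer):
        ab = buried_area(contact_dimer, ["A"], ["B"])
        ba = buried_area(contact_dimer, ["B"], ["A"])
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab > 0

    def test_conventions_differ_by_factor_two(self, contact_dimer):
        per_side = buried_area(contact_dimer, ["A"], ["B"], convention="per_side")
        total = buried_area(contact_dimer, ["A"], ["B"], convention="total")
        assert total == pytest.approx(2 * per_side, rel=1e-12)

    def test_collinear_toy_matches_quadrature_oracle(self):
        """Buried area of a planted collinear dimer within 2% of the oracle."""
        za, zb = [0.0, 2.0], [5.0, 7.2]
        model = StructureModel(
            {
                "A": [Residue("ALA", i + 1, [Atom("CA", "C", (0, 0, z))]) for i, z in enumerate(za)],
                "B": [Residue("ALA", i + 1, [Atom("CA", "C", (0, 0, z))]) for i, z in enumerate(zb)],
            }
        )
        got = buried_area(model, ["A"], ["B"], convention="total", n_sphere_points=9600)
        ext = [1.7 + 1.4] * 2
        oracle = (
            collinear_sasa_oracle(za, ext).sum()
            + collinear_sasa_oracle(zb, ext).sum()
            - collinear_sasa_oracle(za + zb, ext + ext).sum()
        )
        assert got == pytest.approx(oracle, rel=0.02)

    def test_overlapping_sides_rejected(self, contact_dimer):
        with pytest.raises(StructureError, match="overlap"):
            buried_area(contact_dimer, ["A"], ["A"])


class TestContactsAndBridges:
    def test_distant_chains_no_contacts(self):
        dimer = make_contact_dimer(ContactSpec([("LYS", "GLU", 30.0)]))
        assert interface_residues(dimer, ["A"], ["B"], 4.5) == ([], [])
        assert salt_bridges(dimer, ["A"], ["B"]) == []

    def test_planted_contact_found_exactly(self):
        dimer = make_contact_dimer(ContactSpec([("LYS", "GLU", 4.0), ("ALA", "ALA", 8.0)]))
        res_a, res_b = interface_residues(dimer, ["A"], ["B"], 4.5)
        assert [(r.name, r.seq_id) for r in res_a] == [("LYS", 1)]
        assert [(r.name, r.seq_id) for r in res_b] == [("GLU", 1)]

    def test_cutoff_monotonicity(self, contact_dimer):
        small_a, small_b = interface_residues(contact_dimer, ["A"], ["B"], 3.0)
        big_a, big_b = interface_residues(contact_dimer, ["A"], ["B"], 6.5)
        assert set(small_a) <= set(big_a) and set(small_b) <= set(big_b)

    def test_planted_salt_bridge(self, contact_dimer):
        bridges = salt_bridges(contact_dimer, ["A"], ["B"], cutoff=4.0)
        assert len(bridges) == 1
        (b,) = bridges
        assert (b.basic.name, b.acidic.name) == ("LYS", "GLU")
        assert b.distance == pytest.approx(2.8, abs=0.01)
        # the 6.0 Å ARG-ASP pair is outside the 4.0 Å cutoff but distance-measurable
        d = residue_pair_distance(contact_dimer, ("A", 2), ("B", 2), "charged_group")
        assert d == pytest.approx(6.0, abs=0.01)

    def test_acid_on_side_a_still_detected(self):
        dimer = make_contact_dimer(ContactSpec([("GLU", "ARG", 3.0)]))
        bridges = salt_bridges(dimer, ["A"], ["B"])
        assert len(bridges) == 1
        assert bridges[0].basic.name == "ARG"

    def test_hydrophobic_interface_has_no_bridges(self):
        dimer = make_contact_dimer(ContactSpec([("ALA", "LEU", 3.5)]))
        assert salt_bridges(dimer, ["A"], ["B"]) == []

    def test_residue_distance_modes(self, contact_dimer):
        assert residue_pair_distance(contact_dimer, ("A", 1), ("A", 1)) == 0.0
        planted = residue_pair_distance(contact_dimer, ("A", 1), ("B", 1), "min_heavy")
        assert planted == pytest.approx(2.8, abs=0.01)
        with pytest.raises(StructureError, match="not found"):
            residue_pair_distance(contact_dimer, ("A", 99), ("B", 1))
        with pytest.raises(StructureError, match="charged"):
            residue_pair_distance(
                make_contact_dimer(ContactSpec([("ALA", "LEU", 3.5)])), ("A", 1), ("B", 1),
                "charged_group",
            )


class TestChargeComplementarity:
    def test_interface2_residue_census(self):
        """The H3/H4/H5 face: 5 basic + 3 acidic residues per subunit."""
        face = [("ARG", 76), ("LYS", 77), ("GLU", 80), ("LYS", 83), ("GLU", 87),
                ("ARG", 119), ("LYS", 120), ("GLU", 153)]
        refs_a = [_ref("A", n, s) for n, s in face]
        refs_b = [_ref("B", n, s) for n, s in face]
        report = InterfaceReport(870.0 / 2, 870.0, refs_a, refs_b, [])
        summary = charge_complementarity(report)
        assert (summary.basic_a, summary.acidic_a) == (5, 3)
        assert (summary.basic_b, summary.acidic_b) == (5, 3)
        assert summary.matched_pairs == 0

    def test_empty_interface_all_zero(self):
        summary = charge_complementarity(InterfaceReport(0.0, 0.0))
        assert vars(summary) == dict(
            basic_a=0, acidic_a=0, basic_b=0, acidic_b=0, matched_pairs=0, histidines=0
        )

    def test_single_bridge_counts_one_match(self, contact_dimer):
        report = analyze_interface(contact_dimer, ["A"], ["B"])
        summary = charge_complementarity(report)
        assert summary.matched_pairs == 1
        assert summary.basic_a == 1 and summary.acidic_b == 1


def _ref(chain, name, seq_id):
    from ftszlat import ResidueRef

    return ResidueRef(chain, seq_id, name)
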