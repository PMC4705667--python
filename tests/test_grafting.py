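"""Methyl template geometry, base superposition and grafting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from methylclash import (GraftingError, base_plane_deviation, build_template,
                         graft_methyl, make_ideal_duplex, superpose_base)
from methylclash.grafting import cis_methyl_coord
from methylclash.structure import Atom, Residue, ResidueKind

from oracles import plane_deviation, quaternion_superpose


def _residue_from_template(template, rng=None, noise=0.0, rotation=None,
                           translation=None):
    """Build a nucleotide residue from template base coordinates, optionally
    rigidly moved and perturbed."""
    base = {"m5C": "DC", "m4C": "DC", "m6A": "DA"}[template.methyl_type]
    residue = Residue(base, 1, "X", ResidueKind.NUCLEOTIDE)
    for name, coord in template.base_atoms.items():
        c = np.array(coord, dtype=float)
        if rotation is not None:
            c = rotation @ c
        if translation is not None:
            c = c + translation
        if noise:
            c = c + rng.normal(0.0, noise, 3)
        element = "C" if name.startswith("C") else name[0]
        residue.atoms.append(Atom(name, element, c, residue=residue))
    return residue


class TestTemplates:
    @pytest.mark.parametrize("methyl_type,attach", [("m5C", "C5"),
                                                    ("m6A", "N6"),
                                                    ("m4C", "N4")])
    def test_attachment_and_bond_length(self, methyl_type, attach):
        t = build_template(methyl_type)
        assert t.attachment_atom == attach
        bond = np.linalg.norm(t.methyl_coord - t.base_atoms[attach])
        assert bond == pytest.approx(t.bond_length, abs=1e-9)
        assert 1.40 <= t.bond_length <= 1.55

    @pytest.mark.parametrize("methyl_type", ["m5C", "m6A", "m4C"])
    def test_methyl_in_base_plane(self, methyl_type):
        t = build_template(methyl_type)
        ring = np.array([t.base_atoms[n] for n in t.ring_names])
        assert plane_deviation(ring, t.methyl_coord) < 1e-6

    def test_trans_is_hoogsteen_side(self):
        t6 = build_template("m6A")
        assert (np.linalg.norm(t6.methyl_coord - t6.base_atoms["N7"])
                < np.linalg.norm(t6.methyl_coord - t6.base_atoms["N1"]))
        t4 = build_template("m4C")
        assert (np.linalg.norm(t4.methyl_coord - t4.base_atoms["C5"])
                < np.linalg.norm(t4.methyl_coord - t4.base_atoms["N3"]))

    def test_cis_is_mirror_with_same_bond_length(self):
        for methyl_type in ("m6A", "m4C"):
            t = build_template(methyl_type)
            cis = cis_methyl_coord(t)
            attach = t.base_atoms[t.attachment_atom]
            assert np.linalg.norm(cis - attach) == pytest.approx(t.bond_length,
                                                                 abs=1e-6)
            assert not np.allclose(cis, t.methyl_coord)

    def test_cis_undefined_for_c_linked_methyl(self):
        with pytest.raises(ValueError):
            cis_methyl_coord(build_template("m5C"))

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            build_template("m7G")


class TestSuperposition:
    def test_identity_case(self):
        t = build_template("m5C")
        target = _residue_from_template(t)
        transform, rmsd = superpose_base(t, target)
        assert rmsd < 1e-9
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(transform.translation, 0.0, atol=1e-9)

    def test_recovers_known_transform(self):
        t = build_template("m6A")
        rotation = Rotation.from_rotvec(np.radians(37.0)
                                        * np.array([0.3, -0.5, 0.81])
                                        / np.linalg.norm([0.3, -0.5, 0.81])
                                        ).as_matrix()
        translation = np.array([5.0, -3.0, 2.0])
        target = _residue_from_template(t, rotation=rotation,
                                        translation=translation)
        transform, rmsd = superpose_base(t, target)
        assert rmsd < 1e-9
        assert np.allclose(transform.rotation, rotation, atol=1e-9)
        assert np.allclose(transform.translation, translation, atol=1e-9)
        assert transform.is_proper

    def test_noisy_target_matches_quaternion_oracle(self):
        rng = np.random.default_rng(7)
        t = build_template("m5C")
        rotation = Rotation.random(random_state=11).as_matrix()
        target = _residue_from_template(t, rng=rng, noise=0.05,
                                        rotation=rotation,
                                        translation=np.array([1.0, 2.0, -4.0]))
        transform, rmsd = superpose_base(t, target)
        P = np.array([t.base_atoms[n] for n in t.ring_names])
        Q = np.array([target.get_atom(n).coord for n in t.ring_names])
        R_o, t_o, rmsd_o = quaternion_superpose(P, Q)
        assert rmsd == pytest.approx(rmsd_o, abs=1e-9)
        assert np.allclose(transform.rotation, R_o, atol=1e-7)

    def test_optimality_vs_random_transforms(self):
        """The fitted RMSD beats 1000 random rigid placements."""
        rng = np.random.default_rng(42)
        t = build_template("m4C")
        target = _residue_from_template(t, rng=rng, noise=0.2,
                                        rotation=Rotation.random(random_state=5).as_matrix(),
                                        translation=np.array([2.0, 1.0, 0.5]))
        _, rmsd = superpose_base(t, target)
        P = np.array([t.base_atoms[n] for n in t.ring_names])
        Q = np.array([target.get_atom(n).coord for n in t.ring_names])
        for i in range(1000):
            R = Rotation.random(random_state=100 + i).as_matrix()
            moved = P @ R.T
            moved = moved - moved.mean(axis=0) + Q.mean(axis=0)
            random_rmsd = np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1)))
            assert rmsd <= random_rmsd + 1e-12

    def test_missing_atoms_reported(self):
        t = build_template("m6A")
        target = _residue_from_template(t)
        target.atoms = [a for a in target.atoms if a.name not in ("N7", "C8")]
        with pytest.raises(GraftingError, match="N7"):
            superpose_base(t, target)


class TestGrafting:
    def test_m5c_on_ideal_duplex(self, duplex_aacgtt):
        target = duplex_aacgtt.find_residue("A", 3)
        g = graft_methyl(target, "m5C")
        assert base_plane_deviation(g) < 1e-6
        bond = np.linalg.norm(g.coord - target.get_atom("C5").coord)
        assert bond == pytest.approx(1.50, abs=1e-3)
        assert g.radius == 2.0

    def test_m6a_trans_and_cis_sides(self, duplex_gaattc):
        target = duplex_gaattc.find_residue("A", 3)
        trans = graft_methyl(target, "m6A", "trans")
        cis = graft_methyl(target, "m6A", "cis")
        n7 = target.get_atom("N7").coord
        n1 = target.get_atom("N1").coord
        assert np.linalg.norm(trans.coord - n7) < np.linalg.norm(trans.coord - n1)
        assert np.linalg.norm(cis.coord - n1) < np.linalg.norm(cis.coord - n7)

    def test_incompatible_base_rejected(self, duplex_gaattc):
        adenine = duplex_gaattc.find_residue("A", 3)
        with pytest.raises(ValueError):
            graft_methyl(adenine, "m5C")
        thymine = duplex_gaattc.find_residue("A", 4)
        with pytest.raises(ValueError):
            graft_methyl(thymine, "m6A")

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 10 ** 6))
    def test_grafting_equivariance(self, seed):
        """Rigidly moving the target moves the grafted methyl identically."""
        rng = np.random.default_rng(seed)
        t = build_template("m6A")
        target = _residue_from_template(t, rng=rng, noise=0.05)
        g0 = graft_methyl(target, "m6A")
        R = Rotation.random(random_state=seed).as_matrix()
        shift = rng.uniform(-10, 10, 3)
        moved = Residue("DA", 1, "X", ResidueKind.NUCLEOTIDE)
        for a in target.atoms:
            moved.atoms.append(Atom(a.name, a.element, R @ a.coord + shift,
                                    residue=moved))
        g1 = graft_methyl(moved, "m6A")
        assert np.allclose(g1.coord, R @ g0.coord + shift, atol=1e-9)

    def test_plane_deviation_constructed_and_oracle(self, duplex_aacgtt):
        target = duplex_aacgtt.find_residue("A", 3)
        g = graft_methyl(target, "m5C")
        # displace by hand 0.25 A along the plane normal
        ring = np.array([a.coord for a in target.base_ring_atoms().values()])
        centroid = ring.mean(axis=0)
        _, _, vt = np.linalg.svd(ring - centroid)
        g.coord = g.coord + 0.25 * vt[2]
        assert base_plane_deviation(g) == pytest.approx(0.25, abs=1e-9)

    def test_plane_deviation_on_puckered_base_matches_oracle(self):
        """On a non-planar (experimentally distorted) base the deviation is
        finite and equals the independent point-to-plane computation."""
        rng = np.random.default_rng(3)
        t = build_template("m5C")
        target = _residue_from_template(t, rng=rng, noise=0.08)
        g = graft_methyl(target, "m5C")
        ring = np.array([a.coord for a in target.base_ring_atoms().values()])
        expected = plane_deviation(ring, g.coord)
        assert base_plane_deviation(g) == pytest.approx(expected, abs=1e-12)
        assert expected > 0

    def test_intermethyl_distance_symmetric_site(self, duplex_gaattc):
        """Methylating both strands of the palindromic GAATTC site gives two
        methyls at a symmetric, well-separated distance in the ideal duplex."""
        a_top = duplex_gaattc.find_residue("A", 3)
        # complementary adenine of the palindrome on the other strand
        a_bottom = duplex_gaattc.find_residue("B", 3)
        assert a_bottom.name == "DA"
        g1 = graft_methyl(a_top, "m6A")
        g2 = graft_methyl(a_bottom, "m6A")
        d = np.linalg.norm(g1.coord - g2.coord)
        assert d > 2.0  # no artificial overlap in the ideal geometry
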