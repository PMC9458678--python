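"""Coordinate I/O, superposition grafting and structural metrics."""

import numpy as np
import pytest

from saxsens.structures import (
    DomainDefinition,
    ca_distance_features,
    center_of_mass,
    domain_distance,
    load_domains,
    max_dimension,
    radius_of_gyration,
    read_coordinates,
    superpose_and_graft,
    write_pdb,
)
from saxsens.structures import Ensemble

from conftest import make_conformer, random_rotation

PDB_3MODEL = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   1.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.000   1.000   0.000  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  CA  ALA A   1       0.000   2.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.000   2.000   0.000  1.00  0.00           C
ENDMDL
END
"""

PDB_1ATOM = """\
ATOM      1  CA  ALA A   1       1.500   2.500   3.500  1.00  0.00           C
END
"""


class TestReadCoordinates:
    def test_single_model_single_atom(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_1ATOM)
        ens = read_coordinates(p)
        assert len(ens) == 1 and ens[0].n_atoms == 1
        np.testing.assert_allclose(ens[0].coords[0], [1.5, 2.5, 3.5])

    def test_multimodel_coordinates_match_file(self, tmp_path):
        p = tmp_path / "three.pdb"
        p.write_text(PDB_3MODEL)
        ens = read_coordinates(p)
        assert len(ens) == 3
        for k, conf in enumerate(ens):
            np.testing.assert_allclose(conf.coords[:, 1], [float(k)] * 2)
            np.testing.assert_allclose(conf.coords[:, 0], [0.0, 3.0])

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("END\n")
        with pytest.raises(ValueError):
            read_coordinates(p)

    def test_xyz_roundtrip_values(self, tmp_path):
        p = tmp_path / "toy.xyz"
        p.write_text("2\nframe0\nC 0.0 0.0 0.0\nC 1.0 2.0 2.0\n")
        ens = read_coordinates(p, format="xyz")
        assert len(ens) == 1
        np.testing.assert_allclose(ens[0].coords[1], [1.0, 2.0, 2.0])

    def test_malformed_xyz_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nframe0\nC 0.0 0.0\nC 1 2 3\n")
        with pytest.raises(ValueError, match="bad.xyz:3"):
            read_coordinates(p, format="xyz")

    def test_pdb_writer_roundtrip(self, tmp_path):
        p = tmp_path / "rt.pdb"
        conf = make_conformer([[0.0, 0.0, 0.0], [3.125, -2.5, 7.0]],
                              resnames=["ALA", "GLY"])
        write_pdb(Ensemble([conf, conf]), p)
        back = read_coordinates(p)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].coords, conf.coords, atol=1e-3)


class TestConformerInvariants:
    def test_nonfinite_coordinates_rejected(self):
        with pytest.raises(ValueError):
            make_conformer([[np.nan, 0, 0]])

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            make_conformer([[0, 0, 0]], masses=[0.0])

    def test_decreasing_resids_rejected(self):
        with pytest.raises(ValueError):
            make_conformer([[0, 0, 0], [1, 0, 0]], resids=[5, 3])


class TestCenterOfMass:
    def test_single_atom(self):
        conf = make_conformer([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(center_of_mass(conf), [1, 2, 3])

    def test_equal_masses_symmetric(self):
        conf = make_conformer([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(center_of_mass(conf), [1, 0, 0])

    def test_unequal_masses(self):
        conf = make_conformer([[0, 0, 0], [4, 0, 0]], masses=[1.0, 3.0])
        np.testing.assert_allclose(center_of_mass(conf), [3, 0, 0])

    def test_empty_selection_is_error(self):
        conf = make_conformer([[0, 0, 0]])
        with pytest.raises(ValueError):
            center_of_mass(conf, DomainDefinition("x", 100, 200))


class TestDistancesAndRg:
    def test_domain_distance_identity_and_analytic(self):
        conf = make_conformer([[0, 0, 0], [3, 0, 0]], resids=[1, 2])
        a = DomainDefinition("a", 1, 1)
        b = DomainDefinition("b", 2, 2)
        assert domain_distance(conf, a, a) == 0.0
        assert domain_distance(conf, a, b) == pytest.approx(3.0)

    def test_rg_single_atom_and_pair(self):
        assert radius_of_gyration(make_conformer([[5, 5, 5]])) == 0.0
        conf = make_conformer([[0, 0, 0], [0, 0, 6]])
        assert radius_of_gyration(conf) == pytest.approx(3.0)

    def test_max_dimension_pair_and_cube(self):
        conf = make_conformer([[0, 0, 0], [0, 5, 0]])
        assert max_dimension(conf) == pytest.approx(5.0)
        corners = [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
        assert max_dimension(make_conformer(corners)) == pytest.approx(np.sqrt(3))

    def test_max_dimension_needs_two_atoms(self):
        with pytest.raises(ValueError):
            max_dimension(make_conformer([[0, 0, 0]]))

    def test_rigid_motion_invariance(self, random_conformer, rng):
        """Rg, Dmax and COM distances are unchanged by rotation+translation."""
        conf = random_conformer
        r = random_rotation(rng)
        t = rng.normal(scale=50.0, size=3)
        moved = conf.transformed(r, t)
        assert radius_of_gyration(moved) == pytest.approx(
            radius_of_gyration(conf), abs=1e-9)
        assert max_dimension(moved) == pytest.approx(max_dimension(conf), abs=1e-9)
        a = DomainDefinition("a", 1, 25)
        b = DomainDefinition("b", 26, 50)
        assert domain_distance(moved, a, b) == pytest.approx(
            domain_distance(conf, a, b), abs=1e-9)

    def test_rg_never_exceeds_dmax(self, rng):
        for _ in range(10):
            conf = make_conformer(rng.normal(size=(20, 3)) * 10)
            assert radius_of_gyration(conf) <= max_dimension(conf)


class TestSuperposeAndGraft:
    def _two_domain(self, offset=0.0):
        coords = []
        names, resids = [], []
        for i in range(8):
            for j, nm in enumerate(("N", "CA", "C")):
                coords.append([3.0 * i + 0.8 * j, offset, (i % 2) * 1.0])
                names.append(nm)
                resids.append(i + 1)
        return make_conformer(coords, names=names, resids=resids,
                              resnames=["ALA"] * len(coords))

    def test_identity_graft_is_noop(self):
        conf = self._two_domain()
        out = superpose_and_graft(conf, conf, (3, 6), (5, 8))
        np.testing.assert_allclose(out.coords, conf.coords, atol=1e-9)

    def test_rotated_donor_recovered(self, rng):
        """A donor rotated 90° about z superposes back to RMSD ~ 0."""
        target = self._two_domain()
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        donor = target.transformed(rot, np.array([10.0, -4.0, 2.0]))
        out = superpose_and_graft(target, donor, (1, 8), (5, 8))
        np.testing.assert_allclose(out.coords, target.coords, atol=1e-6)

    def test_graft_takes_donor_fragment(self):
        target = self._two_domain()
        donor = self._two_domain()
        donor.coords = donor.coords.copy()
        # displace donor residues 7-8 perpendicular to the alignment region
        mask = donor.resids >= 7
        donor.coords[mask] += [0.0, 5.0, 0.0]
        out = superpose_and_graft(target, donor, (1, 4), (7, 8))
        np.testing.assert_allclose(
            out.coords[out.resids >= 7],
            target.coords[target.resids >= 7] + [0.0, 5.0, 0.0],
            atol=1e-9,
        )

    def test_empty_alignment_is_error(self):
        conf = self._two_domain()
        with pytest.raises(ValueError):
            superpose_and_graft(conf, conf, (100, 120), (1, 2))


class TestCaDistanceFeatures:
    def test_three_residue_feature_count_and_values(self):
        conf = make_conformer([[0, 0, 0], [3, 0, 0], [7, 0, 0]], resids=[1, 2, 3])
        ens = Ensemble([conf])
        feats = ca_distance_features(ens, [DomainDefinition("d", 1, 3)])
        assert feats.values.shape == (1, 3)
        # canonical order: (1,2), (1,3), (2,3)
        np.testing.assert_allclose(feats.values[0], [3.0, 7.0, 4.0])

    def test_translation_invariance(self):
        conf = make_conformer([[0, 0, 0], [3, 0, 0], [7, 2, 0]], resids=[1, 2, 3])
        moved = conf.transformed(np.eye(3), np.array([10.0, 20.0, 30.0]))
        ens = Ensemble([conf, moved])
        feats = ca_distance_features(ens, [DomainDefinition("d", 1, 3)])
        np.testing.assert_allclose(feats.values[0], feats.values[1], atol=1e-12)

    def test_inter_domain_only_drops_intra_pairs(self):
        conf = make_conformer([[0, 0, 0], [1, 0, 0], [10, 0, 0], [11, 0, 0]],
                              resids=[1, 2, 5, 6])
        ens = Ensemble([conf])
        d1, d2 = DomainDefinition("a", 1, 2), DomainDefinition("b", 5, 6)
        full = ca_distance_features(ens, [d1, d2])
        inter = ca_distance_features(ens, [d1, d2], inter_domain_only=True)
        assert full.values.shape[1] == 6
        assert inter.values.shape[1] == 4

    def test_missing_ca_is_error(self):
        conf = make_conformer([[0, 0, 0], [1, 0, 0]], names=["N", "CA"],
                              resids=[1, 2])
        with pytest.raises(ValueError):
            ca_distance_features(Ensemble([conf]), [DomainDefinition("d", 1, 1)])


def test_load_domains_yaml(tmp_path):
    p = tmp_path / "domains.yaml"
    p.write_text(
        "- {name: RING1, start: 699, end: 751}\n"
        "- {name: IBR, start: 796, end: 841, chain: A}\n"
    )
    doms = load_domains(p)
    assert [d.name for d in doms] == ["RING1", "IBR"]
    assert doms[1].chain == "A"
    assert (doms[0].start, doms[0].end) == (699, 751)
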