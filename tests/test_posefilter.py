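"""Six-criterion pose filter, Gromos clustering, RMSF."""

import numpy as np
import pytest
import biotite.structure as struc
from scipy.spatial.distance import cdist

from vsdkit import posefilter as pf
from vsdkit import synthetic


def make_atoms(records):
    """records: (chain, res_id, res_name, atom_name, element, xyz)."""
    arr = struc.AtomArray(len(records))
    for i, (chain, rid, rname, aname, el, xyz) in enumerate(records):
        arr.chain_id[i] = chain
        arr.res_id[i] = rid
        arr.res_name[i] = rname
        arr.atom_name[i] = aname
        arr.element[i] = el
        arr.coord[i] = xyz
    return arr


def single_atom(chain, xyz, rname="ALA", aname="CB", el="C", rid=1):
    return make_atoms([(chain, rid, rname, aname, el, xyz)])


class TestContactArea:
    def test_separated_partners_zero(self):
        pose = pf.Pose(
            receptor=single_atom("R", (0, 0, 0)),
            ligand=single_atom("L", (100, 0, 0)),
        )
        assert pf.contact_area(pose) == 0.0

    def test_two_sphere_analytic_oracle(self):
        # two carbon atoms at distance d: each buries a spherical cap of
        # area 2*pi*R*(R - d/2) on the expanded sphere R = r_vdw + probe
        d = 3.0
        pose = pf.Pose(
            receptor=single_atom("R", (0, 0, 0)),
            ligand=single_atom("L", (d, 0, 0)),
        )
        r_vdw = 1.7  # single-atom radius for carbon
        R = r_vdw + 1.4
        analytic = 2 * np.pi * R * (R - d / 2)
        assert pf.contact_area(pose) == pytest.approx(analytic, rel=0.01)

    def test_symmetric_in_partner_order(self, compliant_pose):
        swapped = pf.Pose(
            receptor=compliant_pose.ligand, ligand=compliant_pose.receptor
        )
        assert pf.contact_area(swapped) == pytest.approx(
            pf.contact_area(compliant_pose), rel=1e-6
        )


class TestGoodContacts:
    def test_constructed_ionic_pair(self):
        rec = make_atoms([
            ("R", 53, "GLU", "CD", "C", (0, 0, 0)),
            ("R", 53, "GLU", "OE1", "O", (1.2, 0, 0)),
        ])
        lig = make_atoms([
            ("L", 24, "LYS", "CE", "C", (5.8, 0, 0)),
            ("L", 24, "LYS", "NZ", "N", (4.4, 0, 0)),
        ])
        out = pf.good_contacts(pf.Pose(receptor=rec, ligand=lig))
        assert out["count"] == 1
        assert out["contacts"][0]["type"] == "ionic"

    def test_ionic_distance_cutoff(self):
        rec = make_atoms([("R", 53, "GLU", "OE1", "O", (0, 0, 0))])
        lig = make_atoms([("L", 24, "LYS", "NZ", "N", (4.2, 0, 0))])
        out = pf.good_contacts(pf.Pose(receptor=rec, ligand=lig))
        assert out["count"] == 0

    def test_hbond_angle_requirement(self):
        # donor OG with antecedent CB; acceptor placed to give a ~90 deg
        # antecedent-donor-acceptor angle -> rejected
        lig = make_atoms([
            ("L", 5, "SER", "CB", "C", (0, 1.5, 0)),
            ("L", 5, "SER", "OG", "O", (0, 0, 0)),
        ])
        rec_bad = make_atoms([("R", 7, "GLU", "OE1", "O", (0, 1.5, 3.0))])
        rec_good = make_atoms([("R", 7, "GLU", "OE1", "O", (0, -3.0, 0))])
        assert pf.good_contacts(pf.Pose(receptor=rec_bad, ligand=lig))["count"] == 0
        out = pf.good_contacts(pf.Pose(receptor=rec_good, ligand=lig))
        assert out["count"] == 1 and out["contacts"][0]["type"] == "hbond"

    def test_parallel_stacking_detected(self):
        def ring(chain, rid, z):
            ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
            return [
                (chain, rid, "PHE", name, "C",
                 (1.4 * np.cos(a), 1.4 * np.sin(a), z))
                for name, a in zip(("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), ang)
            ]

        pose = pf.Pose(
            receptor=make_atoms(ring("R", 1, 0.0)),
            ligand=make_atoms(ring("L", 2, 3.8)),
        )
        out = pf.good_contacts(pose)
        assert out["count"] == 1
        assert out["contacts"][0]["kind"] == "parallel"

    def test_separated_partners_no_contacts(self, compliant_pose):
        far = pf.Pose(
            receptor=compliant_pose.receptor,
            ligand=compliant_pose.ligand.copy(),
        )
        far.ligand.coord += np.array([100.0, 0, 0])
        assert pf.good_contacts(far)["count"] == 0


class TestComplementarity:
    def _blob(self, chain, el, x0):
        rng = np.random.default_rng(4)
        recs = []
        for i, xyz in enumerate(rng.normal(0, 2, (20, 3)) + [x0, 0, 0]):
            name = ("C" if el == "C" else "O") + "X"  # avoid backbone names
            recs.append((chain, i + 1, "UNK", name, el, xyz))
        return make_atoms(recs)

    def test_hydrophobic_on_hydrophobic_matches(self):
        pose = pf.Pose(
            receptor=self._blob("R", "C", 0.0), ligand=self._blob("L", "C", 4.0)
        )
        assert pf.hydrophobic_complementarity(pose) == pytest.approx(1.0)

    def test_hydrophobic_on_polar_mismatches(self):
        pose = pf.Pose(
            receptor=self._blob("R", "C", 0.0), ligand=self._blob("L", "O", 4.0)
        )
        assert pf.hydrophobic_complementarity(pose) == pytest.approx(-1.0)

    def test_no_contact_undefined(self):
        pose = pf.Pose(
            receptor=self._blob("R", "C", 0.0), ligand=self._blob("L", "C", 100.0)
        )
        assert pf.hydrophobic_complementarity(pose) is None


class TestAnchorAndProximity:
    def test_missing_anchor_residue_rejected(self, compliant_pose):
        lig = compliant_pose.ligand
        truncated = lig[lig.res_id != 24]
        pose = pf.Pose(receptor=compliant_pose.receptor, ligand=truncated)
        with pytest.raises(ValueError):
            pf.ionic_anchor_check(pose)

    def test_bridge_from_unlisted_residue_does_not_count(self):
        rec = make_atoms([("R", 53, "GLU", "OE1", "O", (0, 0, 0))])
        lig = make_atoms([
            ("L", 6, "ARG", "NH1", "N", (3.0, 0, 0)),   # unlisted arginine
            ("L", 24, "LYS", "NZ", "N", (50, 0, 0)),
            ("L", 28, "LYS", "NZ", "N", (50, 5, 0)),
            ("L", 29, "ARG", "NH1", "N", (50, 10, 0)),
        ])
        out = pf.ionic_anchor_check(pf.Pose(receptor=rec, ligand=lig))
        assert not out["pass"]

    def test_proximity_strict_cutoff(self):
        rec = make_atoms([("R", 50, "ALA", "CB", "C", (0, 0, 0))])
        for d, expect in ((3.9, True), (4.0, False)):
            lig = make_atoms([("L", 27, "ILE", "CD1", "C", (d, 0, 0))])
            out = pf.proximity_check(pf.Pose(receptor=rec, ligand=lig))
            assert out["pass"] is expect
            assert out["min_distance"] == pytest.approx(d)

    def test_min_distance_matches_brute_force(self, compliant_pose):
        out = pf.proximity_check(compliant_pose)
        mask = compliant_pose.ligand.res_id == 27
        brute = cdist(
            compliant_pose.ligand.coord[mask], compliant_pose.receptor.coord
        ).min()
        assert out["min_distance"] == pytest.approx(brute)


class TestOrientation:
    def test_angles_from_construction(self):
        up_pose, _ = synthetic.gen_toy_complex({"orientation": False}, seed=0)
        down_pose, _ = synthetic.gen_toy_complex(None, seed=0)
        assert pf.orientation_check(down_pose)["angle"] < 30.0
        assert pf.orientation_check(up_pose)["angle"] > 150.0

    def test_sphere_frame_mode(self, compliant_pose):
        # micelle-sphere frame centered far below the ligand: inward points
        # downward, so the compliant (downward) cluster still passes
        frame = pf.MembraneFrame(
            sphere_center=(0.0, 0.0, -24.0), sphere_radius=24.0
        )
        pose = pf.Pose(
            receptor=compliant_pose.receptor,
            ligand=compliant_pose.ligand,
            frame=frame,
        )
        assert pf.orientation_check(pose)["pass"]


class TestFilterPoses:
    def test_survivors_are_intersection_of_criteria(self):
        poses, truths = synthetic.gen_pose_suite(seed=0)
        reports, survivors = pf.filter_poses(poses)
        for rep in reports:
            assert rep.passed == all(rep.criteria.values())
        passing = [p for p, r in zip(poses, reports) if r.passed]
        assert survivors == passing

    def test_rigid_transform_invariance(self, compliant_pose):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True)
        shift = np.array([5.0, -3.0, 7.0])
        rec = compliant_pose.receptor.copy()
        lig = compliant_pose.ligand.copy()
        rec.coord = rot.apply(rec.coord) + shift
        lig.coord = rot.apply(lig.coord) + shift
        frame = pf.MembraneFrame(normal=tuple(rot.apply([0.0, 0.0, 1.0])))
        moved = pf.Pose(receptor=rec, ligand=lig, frame=frame)
        a = pf.evaluate_pose(compliant_pose)
        b = pf.evaluate_pose(moved)
        assert b.contact_area == pytest.approx(a.contact_area, rel=0.02)
        assert b.n_good_contacts == a.n_good_contacts
        assert b.complementarity == pytest.approx(a.complementarity, abs=0.02)
        assert b.orientation_angle == pytest.approx(a.orientation_angle, abs=0.5)
        assert b.passed


class TestGromosCluster:
    def test_identical_conformers_single_cluster(self):
        coords = np.tile(np.random.default_rng(1).normal(size=(12, 3)), (6, 1, 1))
        clusters = pf.gromos_cluster(coords, cutoff_nm=0.25)
        assert len(clusters) == 1
        assert sorted(clusters[0]["members"]) == list(range(6))

    def test_two_separated_bundles(self, rng):
        # two genuinely different shapes (independent draws): superposition
        # cannot align them, unlike a pure rotation of the same shape
        base1 = rng.normal(size=(15, 3)) * 6
        base2 = rng.normal(size=(15, 3)) * 6
        ens = np.stack(
            [base1 + rng.normal(0, 0.05, (15, 3)) for _ in range(5)]
            + [base2 + rng.normal(0, 0.05, (15, 3)) for _ in range(5)]
        )
        clusters = pf.gromos_cluster(ens, cutoff_nm=0.25)
        assert [len(c["members"]) for c in clusters] == [5, 5]

    def test_partition_property_and_brute_force_centers(self, rng):
        ens = rng.normal(size=(15, 10, 3)) * 2
        clusters = pf.gromos_cluster(ens, cutoff_nm=0.4)
        members = sorted(m for c in clusters for m in c["members"])
        assert members == list(range(15))
        # first center must have the global maximum neighbor count
        centered = ens - ens.mean(axis=1, keepdims=True)
        from scipy.spatial.transform import Rotation

        n = len(ens)
        rmsd = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, rssd = Rotation.align_vectors(centered[i], centered[j])
                rmsd[i, j] = rmsd[j, i] = rssd / np.sqrt(ens.shape[1])
        counts = (rmsd <= 4.0).sum(axis=1)
        assert counts[clusters[0]["center"]] == counts.max()

    def test_cluster_count_nonincreasing_in_cutoff(self, rng):
        ens = rng.normal(size=(12, 8, 3)) * 3
        ns = [
            len(pf.gromos_cluster(ens, cutoff_nm=c)) for c in (0.1, 0.3, 0.6, 1.2)
        ]
        assert ns == sorted(ns, reverse=True)


class TestRMSF:
    def test_static_ensemble_zero(self):
        frame = np.random.default_rng(2).normal(size=(20, 3))
        out = pf.rmsf(np.tile(frame, (5, 1, 1)))
        np.testing.assert_allclose(out.rmsf_nm, 0.0, atol=1e-12)

    def test_planted_isotropic_jitter(self, rng):
        sigma = 0.5  # A
        base = rng.normal(size=(30, 3)) * 8
        frames = np.stack(
            [base + rng.normal(0, sigma, base.shape) for _ in range(500)]
        )
        out = pf.rmsf(frames)
        assert out.rmsf_nm.mean() * 10 == pytest.approx(
            sigma * np.sqrt(3), rel=0.05
        )

    def test_rigid_motion_removed_by_superposition(self, rng):
        from scipy.spatial.transform import Rotation

        base = rng.normal(size=(25, 3)) * 8
        frames = []
        for i in range(10):
            rot = Rotation.from_euler("xyz", rng.uniform(-90, 90, 3), degrees=True)
            frames.append(rot.apply(base) + rng.uniform(-20, 20, 3))
        out = pf.rmsf(np.stack(frames))
        np.testing.assert_allclose(out.rmsf_nm, 0.0, atol=1e-8)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            pf.rmsf(np.zeros((1, 5, 3)))
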