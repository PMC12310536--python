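"""Body model: composition, masses, forward kinematics, sites, rescaling."""

import numpy as np
import pytest

from flysim import units
from flysim.body import (
    ConfigurationError,
    ContractError,
    GeomSpec,
    KinematicTree,
    Pose,
    SegmentSpec,
    attach_keypoint_sites,
    build_default_fly,
    com,
    default_walking_sites,
    forward_kinematics,
    leg_validation_sites,
    load_yaml,
    rescale,
    save_yaml,
    total_mass,
    tree_from_dict,
    tree_to_dict,
)
from flysim.rotations import IDENTITY_QUAT, quat_from_axis_angle


def _simple_chain(n_links=2, link_len=1.0, axis=(0, 0, 1.0)):
    segs = [
        SegmentSpec("base", None, np.zeros((0, 3)), np.zeros((0, 2)),
                    np.zeros(3), IDENTITY_QUAT, 1.0, GeomSpec("sphere", (0.1,)))
    ]
    for i in range(n_links):
        segs.append(
            SegmentSpec(
                f"link{i}", "base" if i == 0 else f"link{i-1}",
                np.array([axis]), np.array([[-np.pi, np.pi]]),
                np.array([link_len, 0, 0]) if i else np.zeros(3),
                IDENTITY_QUAT, 1.0, GeomSpec("capsule", (0.05, link_len / 2)),
            )
        )
    return KinematicTree(segments=segs, root="base")


class TestDefaultFly:
    def test_full_variant_segment_count(self, default_tree):
        assert default_tree.n_segments == 67

    def test_composition_by_part(self, default_tree):
        names = [s.name for s in default_tree.segments]
        assert sum(n.startswith("abdomen") for n in names) == 7
        assert sum(n.startswith("proboscis") for n in names) == 4
        assert sum(n.startswith("antenna") for n in names) == 2
        assert sum(n.startswith("wing") for n in names) == 2
        assert sum(n.startswith("haltere") for n in names) == 2
        assert sum(n.startswith("T") for n in names) == 48

    def test_total_mass_matches_printed_sum(self, default_tree):
        total_mg = units.kg_to_mg(total_mass(default_tree))
        assert round(float(total_mg), 3) == 0.983

    def test_per_part_masses(self, default_tree):
        mg = lambda name: units.kg_to_mg(default_tree.segment(name).mass)
        assert mg("head") == pytest.approx(0.15)
        assert mg("thorax") == pytest.approx(0.34)
        assert mg("wing_L") == pytest.approx(0.008)
        ab = sum(
            units.kg_to_mg(s.mass)
            for s in default_tree.segments
            if s.name.startswith("abdomen")
        )
        assert ab == pytest.approx(0.38)
        leg = sum(
            units.kg_to_mg(s.mass)
            for s in default_tree.segments
            if s.name.startswith("T1_L")
        )
        assert leg == pytest.approx(0.0162)

    def test_flight_variant_freezes_leg_dofs(self):
        tree = build_default_fly("flight")
        assert tree.n_segments == 67  # legs stay in the tree
        actuated = set(tree.actuated_joint_indices().tolist())
        for leg in ("T1_L", "T2_R", "T3_L"):
            sl = tree.joint_slice(f"{leg}_femur")
            assert not actuated.intersection(range(sl.start, sl.stop))
        for side in "LR":
            sl = tree.joint_slice(f"wing_{side}")
            assert actuated.issuperset(range(sl.start, sl.stop))

    def test_walking_variant_freezes_wings(self):
        tree = build_default_fly("walking")
        actuated = set(tree.actuated_joint_indices().tolist())
        for side in "LR":
            sl = tree.joint_slice(f"wing_{side}")
            assert not actuated.intersection(range(sl.start, sl.stop))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigurationError):
            build_default_fly("swimming")

    def test_tendon_groups_disjoint(self, default_tree):
        flat = [j for g in default_tree.tendon_couplings for j in g]
        assert len(flat) == len(set(flat))
        assert len(default_tree.tendon_couplings) == 7  # abdomen + 6 tarsi


class TestForwardKinematics:
    def test_identity_pose_gives_rest_offsets(self):
        tree = _simple_chain()
        frames, _ = forward_kinematics(tree, tree.zero_pose())
        assert np.allclose(frames["link0"][0], [0, 0, 0])
        assert np.allclose(frames["link1"][0], [1, 0, 0])

    def test_two_link_right_angle(self):
        # 90 degrees about z at link1: its frame sits at (1, 0, 0) and a
        # +x-offset child point maps to +y
        tree = _simple_chain(n_links=2)
        tree = attach_keypoint_sites(tree, [("tip", "link1", [1.0, 0, 0])])
        q = np.array([0.0, np.pi / 2])
        _, sites = forward_kinematics(
            tree, Pose(np.zeros(3), IDENTITY_QUAT, q)
        )
        assert np.allclose(sites["tip"], [1.0, 1.0, 0.0], atol=1e-12)

    def test_matches_naive_matrix_oracle(self, rng):
        # independent oracle: chain of homogeneous 4x4 transforms
        def oracle(tree, pose):
            mats = {}
            out = {}
            for s in tree.segments:
                if s.parent is None:
                    m = np.eye(4)
                    m[:3, 3] = pose.root_position
                else:
                    m = mats[s.parent].copy()
                    t = np.eye(4)
                    t[:3, 3] = s.rest_pos
                    m = m @ t
                for axis, ang in zip(
                    s.joint_axes, pose.q[tree.joint_slice(s.name)]
                ):
                    r = np.eye(4)
                    c, sn = np.cos(ang), np.sin(ang)
                    x, y, z = axis
                    r[:3, :3] = np.array(
                        [
                            [c + x * x * (1 - c), x * y * (1 - c) - z * sn,
                             x * z * (1 - c) + y * sn],
                            [y * x * (1 - c) + z * sn, c + y * y * (1 - c),
                             y * z * (1 - c) - x * sn],
                            [z * x * (1 - c) - y * sn, z * y * (1 - c) + x * sn,
                             c + z * z * (1 - c)],
                        ]
                    )
                    m = m @ r
                mats[s.name] = m
                out[s.name] = m[:3, 3]
            return out

        for _ in range(5):
            # random 10-segment chain with random axes
            segs = [
                SegmentSpec("s0", None, np.zeros((0, 3)), np.zeros((0, 2)),
                            np.zeros(3), IDENTITY_QUAT, 1.0,
                            GeomSpec("sphere", (0.1,)))
            ]
            for i in range(1, 10):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                segs.append(
                    SegmentSpec(
                        f"s{i}", f"s{i-1}", np.array([axis]),
                        np.array([[-np.pi, np.pi]]), rng.normal(size=3) * 0.1,
                        IDENTITY_QUAT, 1.0, GeomSpec("sphere", (0.01,)),
                    )
                )
            tree = KinematicTree(segments=segs, root="s0")
            pose = Pose(rng.normal(size=3), IDENTITY_QUAT,
                        rng.uniform(-np.pi, np.pi, tree.n_joints))
            frames, _ = forward_kinematics(tree, pose)
            expected = oracle(tree, pose)
            for name, pos in expected.items():
                assert np.allclose(frames[name][0], pos, atol=1e-10)

    def test_dimension_mismatch_rejected(self, default_tree):
        with pytest.raises(ContractError):
            forward_kinematics(
                default_tree, Pose(np.zeros(3), IDENTITY_QUAT, np.zeros(3))
            )


class TestMassProperties:
    def test_single_segment_com(self):
        tree = _simple_chain(n_links=0)
        assert np.allclose(com(tree, tree.zero_pose()), 0.0)

    def test_symmetric_masses_com_at_midpoint(self):
        segs = [
            SegmentSpec("root", None, np.zeros((0, 3)), np.zeros((0, 2)),
                        np.zeros(3), IDENTITY_QUAT, 0.0,
                        GeomSpec("sphere", (0.01,))),
            SegmentSpec("a", "root", np.zeros((0, 3)), np.zeros((0, 2)),
                        [1.0, 0, 0], IDENTITY_QUAT, 2.0,
                        GeomSpec("sphere", (0.01,))),
            SegmentSpec("b", "root", np.zeros((0, 3)), np.zeros((0, 2)),
                        [-1.0, 0, 0], IDENTITY_QUAT, 2.0,
                        GeomSpec("sphere", (0.01,))),
        ]
        tree = KinematicTree(segments=segs, root="root")
        assert np.allclose(com(tree, tree.zero_pose()), 0.0, atol=1e-15)

    def test_mass_conserved_under_rescale(self, default_tree):
        scaled = rescale(default_tree, 2.0)
        assert scaled.total_mass() == pytest.approx(default_tree.total_mass())
        assert scaled.n_segments == default_tree.n_segments


class TestSites:
    def test_default_walking_sites_count(self, sites_tree):
        assert len(sites_tree.sites) == 13
        _, positions = forward_kinematics(sites_tree, sites_tree.zero_pose())
        assert len(positions) == 13

    def test_leg_validation_sites(self, default_tree):
        tree = attach_keypoint_sites(default_tree, leg_validation_sites("T2_R"))
        assert len(tree.sites) == 5

    def test_zero_offset_site_at_segment_origin(self, default_tree):
        tree = attach_keypoint_sites(default_tree, [("o", "head", np.zeros(3))])
        frames, sites = forward_kinematics(tree, tree.zero_pose())
        assert np.allclose(sites["o"], frames["head"][0])

    def test_unknown_segment_rejected(self, default_tree):
        with pytest.raises(ConfigurationError):
            attach_keypoint_sites(default_tree, [("x", "nope", np.zeros(3))])


class TestRescale:
    def test_identity_factor(self, default_tree):
        scaled = rescale(default_tree, 1.0)
        for a, b in zip(scaled.segments, default_tree.segments):
            assert np.allclose(a.rest_pos, b.rest_pos)

    def test_factor_two_doubles_offsets(self, default_tree):
        scaled = rescale(default_tree, 2.0)
        for a, b in zip(scaled.segments, default_tree.segments):
            assert np.allclose(a.rest_pos, 2.0 * b.rest_pos)

    def test_per_segment_scaling_moves_keypoints(self, sites_tree):
        factors = {f"T1_L_{s}": 1.5 for s in
                   ("coxa", "femur", "tibia", "tarsus_1", "tarsus_2",
                    "tarsus_3", "tarsus_4", "claw")}
        scaled = rescale(sites_tree, factors)
        _, s0 = forward_kinematics(sites_tree, sites_tree.zero_pose())
        _, s1 = forward_kinematics(scaled, scaled.zero_pose())
        # the scaled leg's tip moves; other keypoints do not
        assert not np.allclose(s0["tip_T1_L"], s1["tip_T1_L"])
        assert np.allclose(s0["tip_T3_R"], s1["tip_T3_R"])

    def test_nonpositive_factor_rejected(self, default_tree):
        with pytest.raises(ContractError):
            rescale(default_tree, -1.0)


class TestPoseClamping:
    def test_clamping_is_idempotent(self, default_tree, rng):
        q = rng.uniform(-4, 4, default_tree.n_joints)
        p = Pose(np.zeros(3), IDENTITY_QUAT, q).clamped(default_tree)
        p2 = p.clamped(default_tree)
        assert np.array_equal(p.q, p2.q)
        lims = default_tree.joint_limits()
        assert np.all(p.q >= lims[:, 0]) and np.all(p.q <= lims[:, 1])


class TestSerialization:
    def test_yaml_round_trip_lossless(self, tmp_path, sites_tree):
        path = tmp_path / "fly.yaml"
        save_yaml(sites_tree, path)
        back = load_yaml(path)
        assert back.n_segments == sites_tree.n_segments
        for a, b in zip(back.segments, sites_tree.segments):
            assert a.name == b.name and a.parent == b.parent
            assert np.allclose(a.rest_pos, b.rest_pos, atol=1e-9)
            assert np.allclose(a.joint_limits, b.joint_limits, atol=1e-9)
            assert abs(a.mass - b.mass) < 1e-9
        assert back.tendon_couplings == sites_tree.tendon_couplings
        assert [s.name for s in back.sites] == [s.name for s in sites_tree.sites]

    def test_dict_round_trip(self, default_tree):
        back = tree_from_dict(tree_to_dict(default_tree))
        assert back.total_mass() == pytest.approx(default_tree.total_mass())
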