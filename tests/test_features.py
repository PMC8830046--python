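"""Feature battery: s6, lambda, distances, angles, order parameters,
hydrogen bonds, the 83-column schema, and isometry invariance."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pathcommit as pc
from pathcommit.features import (
    build_feature_table,
    coordination_angles,
    count_hbonds,
    default_md_schema,
    knn_distances,
    lambda_coord,
    s6,
    steinhardt_q,
    tetrahedral_order,
)
from pathcommit.toy_dynamics import SolvationConfig

from oracles import steinhardt_legendre


def _config(positions, roles, ion=(0, 0, 0)):
    return SolvationConfig(
        ion_position=np.array(ion, dtype=float),
        ligand_positions=np.array(positions, dtype=float),
        ligand_roles=roles,
    )


def _isometry(cfg: SolvationConfig, seed=0) -> SolvationConfig:
    R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
    t = np.array([0.3, -0.7, 1.1])
    return SolvationConfig(
        ion_position=cfg.ion_position @ R.T + t,
        ligand_positions=cfg.ligand_positions @ R.T + t,
        ligand_roles=list(cfg.ligand_roles),
    )


class TestS6:
    def test_octahedron_any_exchanger(self, octahedron):
        for ex in range(6):
            assert s6(octahedron, ex) == pytest.approx(1.2)

    def test_five_plus_far_exchanger(self):
        pos = [[0.21, 0, 0], [-0.21, 0, 0], [0, 0.21, 0], [0, -0.21, 0],
               [0, 0, 0.21], [0, 0, -0.42]]
        cfg = _config(pos, ["water_O"] * 6)
        assert s6(cfg, 5) == pytest.approx(5 * 0.21 + 0.42)

    def test_permutation_invariant(self, octahedron):
        perm = [3, 1, 5, 0, 4, 2]
        shuffled = _config(octahedron.ligand_positions[perm],
                           ["water_O"] * 6)
        assert s6(shuffled, 0) == pytest.approx(s6(octahedron, perm[0]))

    def test_too_few_waters(self):
        cfg = _config([[0.2, 0, 0]] * 5, ["water_O"] * 5)
        with pytest.raises(ValueError, match="6 water"):
            s6(cfg, 0)


class TestLambda:
    def test_inner_sphere_anchor(self):
        assert lambda_coord(0.18, 1.47) == pytest.approx(math.pi / 2)

    def test_outer_sphere_anchor(self):
        assert lambda_coord(0.42, 1.18) == pytest.approx(0.0)

    def test_equal_offsets_give_quarter_pi(self):
        assert lambda_coord(0.28, 1.18 + 0.10) == pytest.approx(math.pi / 4)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lambda_coord(float("nan"), 1.2)


class TestDistancesAngles:
    def test_knn_octahedron(self, octahedron):
        assert np.allclose(knn_distances(octahedron, 6), 0.2)

    def test_k1_is_global_minimum(self):
        pos = [[0.5, 0, 0], [0.19, 0, 0], [0, 0.3, 0], [0, 0, 0.25],
               [0.4, 0.1, 0], [0, 0.33, 0.1]]
        cfg = _config(pos, ["water_O"] * 6)
        assert knn_distances(cfg, 1)[0] == pytest.approx(0.19)

    def test_rotation_invariant(self, octahedron):
        rot = _isometry(octahedron)
        assert np.allclose(knn_distances(octahedron, 6),
                           knn_distances(rot, 6), atol=1e-12)

    @pytest.mark.parametrize(
        "water, expected",
        [([-0.2, 0, 0], 180.0), ([0.25, 0, 0], 0.0), ([0, 0.2, 0], 90.0)],
    )
    def test_angle_geometry(self, water, expected):
        cfg = _config([[0.2, 0, 0], water],
                      ["phosphate_O1P", "water_O"])
        assert coordination_angles(cfg, 1)[0] == pytest.approx(expected)

    def test_missing_apex_raises(self, octahedron):
        with pytest.raises(ValueError, match="phosphate_O1P"):
            coordination_angles(octahedron, 3)


class TestSteinhardt:
    @pytest.mark.parametrize("l", [3, 4, 6])
    def test_single_neighbor_is_one(self, l):
        cfg = _config([[0.0, 0.1, 0.2]], ["water_O"])
        assert steinhardt_q(cfg, l, shell=cfg.ligand_positions) == (
            pytest.approx(1.0, abs=1e-12)
        )

    @pytest.mark.parametrize("l", [4, 6])
    def test_octahedron_matches_addition_theorem_oracle(self, octahedron, l):
        got = steinhardt_q(octahedron, l, shell=octahedron.ligand_positions)
        want = steinhardt_legendre(octahedron.ligand_positions, l)
        assert got == pytest.approx(want, abs=1e-10)

    def test_octahedron_frozen_values(self, octahedron):
        # sqrt(7/12) and 1/(2 sqrt 2), from the addition-theorem oracle
        q4 = steinhardt_q(octahedron, 4, shell=octahedron.ligand_positions)
        q6 = steinhardt_q(octahedron, 6, shell=octahedron.ligand_positions)
        assert q4 == pytest.approx(math.sqrt(7.0 / 12.0), abs=1e-12)
        assert q6 == pytest.approx(math.sqrt(0.125), abs=1e-12)

    def test_rotation_invariant_to_1e10(self, octahedron):
        rot = _isometry(octahedron, seed=5)
        vec0 = octahedron.ligand_positions - octahedron.ion_position
        vec1 = rot.ligand_positions - rot.ion_position
        for l in (3, 4, 6):
            assert steinhardt_q(octahedron, l, shell=vec0) == pytest.approx(
                steinhardt_q(rot, l, shell=vec1), abs=1e-10
            )

    def test_empty_shell_raises(self, octahedron):
        with pytest.raises(ValueError, match="empty shell"):
            steinhardt_q(octahedron, 4, shell=np.empty((0, 3)))


class TestTetrahedralOrder:
    def test_perfect_tetrahedron_is_one(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                         dtype=float) * 0.1
        pos = np.vstack([[0.0, 0.0, 0.0], verts])
        cfg = _config(pos, ["water_O"] * 5, ion=(1, 1, 1))
        assert tetrahedral_order(cfg, 0) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_neighbors_negative(self):
        pos = [[0, 0, 0], [0.1, 0, 0], [0.2, 0, 0], [-0.1, 0, 0],
               [-0.2, 0, 0]]
        cfg = _config(pos, ["water_O"] * 5, ion=(1, 1, 1))
        assert tetrahedral_order(cfg, 0) < 0.0

    def test_relabeling_invariant(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(5, 3)) * 0.1
        cfg = _config(pts, ["water_O"] * 5, ion=(1, 1, 1))
        perm = np.array([0, 3, 1, 4, 2])
        cfg2 = _config(pts[perm], ["water_O"] * 5, ion=(1, 1, 1))
        assert tetrahedral_order(cfg, 0) == pytest.approx(
            tetrahedral_order(cfg2, 0), abs=1e-12
        )

    def test_too_few_neighbors(self):
        cfg = _config([[0, 0, 0], [0.1, 0, 0]], ["water_O"] * 2)
        with pytest.raises(ValueError):
            tetrahedral_order(cfg, 0)


class TestHBonds:
    def test_distant_waters_no_bond(self):
        pos = [[0, 0, 0], [0.1, 0, 0], [0.5, 0, 0], [0.6, 0, 0]]
        roles = ["water_O", "water_H", "water_O", "water_H"]
        cfg = _config(pos, roles, ion=(0, 0, 1))
        assert count_hbonds(cfg, [0], [2]) == 0

    def test_ideal_linear_bond(self):
        pos = [[0, 0, 0], [0.1, 0, 0], [0.28, 0, 0], [0.38, 0, 0]]
        roles = ["water_O", "water_H", "water_O", "water_H"]
        cfg = _config(pos, roles, ion=(0, 0, 1))
        assert count_hbonds(cfg, [0], [2]) == 1

    def test_directed_definition(self):
        # donor 0 points its H at 2; 2 points its H away from 0
        pos = [[0, 0, 0], [0.1, 0, 0], [0.28, 0, 0], [0.28, 0.1, 0]]
        roles = ["water_O", "water_H", "water_O", "water_H"]
        cfg = _config(pos, roles, ion=(0, 0, 1))
        assert count_hbonds(cfg, [0], [2]) == 1
        assert count_hbonds(cfg, [2], [0]) == 0

    def test_missing_hydrogens_raise(self, octahedron):
        with pytest.raises(ValueError, match="hydrogen"):
            count_hbonds(octahedron, [0], [1])


class TestFeatureTable:
    def test_default_schema_has_83_unique_columns(self):
        schema = default_md_schema()
        assert schema.count == 83
        assert len(set(schema.names)) == 83
        assert set(schema.groups) == {
            "distance", "angle", "derived", "steinhardt", "tetrahedral",
            "hbond",
        }

    def test_octahedron_row_s6(self, octahedron):
        X, schema = build_feature_table([octahedron])
        assert X.shape == (1, 83)
        assert X[0, schema.names.index("s6")] == pytest.approx(1.2)

    def test_difference_feature(self):
        pos = [[0.21, 0, 0], [-0.21, 0, 0], [0, 0.21, 0], [0, -0.21, 0],
               [0, 0, 0.21], [0, 0, -0.35], [0.3, 0.01, 0]]
        roles = ["water_O"] * 6 + ["phosphate_O1P"]
        cfg = _config(pos, roles)
        X, schema = build_feature_table([cfg], exchanging_index=5)
        r_I = X[0, schema.names.index("r_I")]
        r_ex = X[0, schema.names.index("r_ex")]
        diff = X[0, schema.names.index("r_I_minus_r_ex")]
        assert diff == pytest.approx(r_I - r_ex)
        assert diff == pytest.approx(np.hypot(0.3, 0.01) - 0.35)

    def test_strict_mode_names_unresolvable_feature(self, octahedron):
        # six waters cannot fill the 20-distance block: r_7 is named
        with pytest.raises(ValueError, match="r_7.*unresolvable"):
            build_feature_table([octahedron], strict=True)

    def test_toy_mode_passthrough(self):
        X = np.arange(6.0).reshape(2, 3)
        out, schema = build_feature_table(X, toy_names=["x", "z1", "n1"])
        assert np.array_equal(out, X)
        assert schema.names == ["x", "z1", "n1"]

    def test_all_features_isometry_invariant(self):
        """Every geometric feature is unchanged by a rigid rotation +
        translation of a generic (tie-free) configuration."""
        rng = np.random.default_rng(31)
        waters, roles = [], []
        for _ in range(24):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            o = u * rng.uniform(0.2, 0.55)
            waters.append(o)
            roles.append("water_O")
            for _ in range(2):
                hdir = rng.normal(size=3)
                hdir /= np.linalg.norm(hdir)
                waters.append(o + 0.1 * hdir)
                roles.append("water_H")
        for role, d in [("phosphate_O1P", 0.29), ("phosphate_O2P", 0.45),
                        ("phosphate_P", 0.38), ("chloride", 0.8),
                        ("other_RNA", 0.6), ("other_RNA", 0.7)]:
            u = rng.normal(size=3)
            waters.append(u / np.linalg.norm(u) * d)
            roles.append(role)
        cfg = _config(waters, roles)
        for seed in (9, 10):
            X0, _ = build_feature_table([cfg])
            X1, _ = build_feature_table([_isometry(cfg, seed=seed)])
            assert np.allclose(X0, X1, atol=1e-9)

    def test_feature_ranges(self):
        series = pc.fixture_solvation_series()
        X, schema = build_feature_table(series, exchanging_index=5)
        assert np.all(np.isfinite(X))
        for j, (name, group) in enumerate(zip(schema.names, schema.groups)):
            if group == "distance":
                assert np.all(X[:, j] >= 0), name
            if group == "angle":
                assert np.all((X[:, j] >= 0) & (X[:, j] <= 180)), name
            if group == "steinhardt":
                assert np.all((X[:, j] >= 0) & (X[:, j] <= 1 + 1e-12)), name
            if group == "tetrahedral":
                assert np.all(X[:, j] <= 1 + 1e-12), name
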