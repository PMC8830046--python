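"""Structural feature battery for ion coordination shells.

Implements the descriptors used to characterise a divalent ion and its
hydration environment: the effective hydration distance s6 (sum of the
ion's distances to its five closest water oxygens plus the exchanging
water), the knowledge-based reaction coordinate

    lambda = atan2(s6 - s6_ref, r_I - rI_ref),   s6_ref = 1.18 nm,
                                                 rI_ref = 0.18 nm,

(lambda = pi/2 at the inner-sphere minimum, 0 at the outer-sphere
minimum), nearest-neighbour distances, coordination angles, rotationally
invariant Steinhardt order parameters q_l, the tetrahedral order
parameter, and geometric hydrogen-bond counts.  ``build_feature_table``
assembles the default 83-column schema used for committor regression.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.special import sph_harm_y

from . import defaults
from .toy_dynamics import SolvationConfig

__all__ = [
    "FeatureSchema",
    "s6",
    "lambda_coord",
    "knn_distances",
    "coordination_angles",
    "steinhardt_q",
    "tetrahedral_order",
    "count_hbonds",
    "build_feature_table",
    "default_md_schema",
]

#: first hydration shell: water oxygens within this distance of the ion (nm)
FIRST_SHELL_RADIUS = 0.30
#: second shell: within (FIRST_SHELL_RADIUS, SECOND_SHELL_RADIUS]
SECOND_SHELL_RADIUS = 0.50
#: geometric hydrogen-bond criterion
HBOND_OO_CUTOFF = 0.35       # nm, donor-acceptor oxygen distance
HBOND_ANGLE_CUTOFF = 30.0    # degrees, H-donor-acceptor angle
#: fill-in distance for absent reference atoms in non-strict table building
PAD_DISTANCE = 1.0           # nm


@dataclasses.dataclass
class FeatureSchema:
    names: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("feature names must be unique")
        if len(self.groups) != len(self.names):
            raise ValueError("one group tag per feature is required")

    @property
    def count(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# scalar features
# ---------------------------------------------------------------------------

def _water_distances(config: SolvationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(indices, distances) of water oxygens, unsorted."""
    idx = np.array(
        [i for i, r in enumerate(config.ligand_roles) if r == "water_O"], dtype=int
    )
    if idx.size == 0:
        return idx, np.empty(0)
    d = np.linalg.norm(config.ligand_positions[idx] - config.ion_position, axis=1)
    return idx, d


def s6(config: SolvationConfig, exchanging_index: int) -> float:
    """Effective hydration distance: sum of the ion's distances to its five
    closest water oxygens (the exchanging water excluded from that five)
    plus the distance to the exchanging water.  Units nm.
    """
    idx, d = _water_distances(config)
    if idx.size < 6:
        raise ValueError(f"s6 requires >= 6 water oxygens, found {idx.size}")
    if exchanging_index not in idx:
        raise ValueError("exchanging_index must point at a water oxygen")
    ex_pos = config.ligand_positions[exchanging_index]
    r_ex = float(np.linalg.norm(ex_pos - config.ion_position))
    others = d[idx != exchanging_index]
    return float(np.sort(others)[:5].sum() + r_ex)


def lambda_coord(
    r_I: float,
    s6_value: float,
    r_I_ref: float = defaults.RI_REF,
    s6_ref: float = defaults.S6_REF,
) -> float:
    """Knowledge-based reaction coordinate combining r_I and s6.

    lambda = atan2(s6 - s6_ref, r_I - r_I_ref), principal value in
    (-pi, pi].  The reference values (s6_ref = 1.18 nm, r_I_ref = 0.18 nm)
    are the positions of the two free-energy minima, so lambda = pi/2 is
    the inner-sphere and lambda = 0 the outer-sphere coordination.
    """
    if not (np.isfinite(r_I) and np.isfinite(s6_value)):
        raise ValueError("lambda_coord requires finite inputs")
    return math.atan2(s6_value - s6_ref, r_I - r_I_ref)


def knn_distances(config: SolvationConfig, k: int) -> np.ndarray:
    """Ascending distances from the ion to its k closest water oxygens."""
    idx, d = _water_distances(config)
    if idx.size < k:
        raise ValueError(f"need >= {k} water oxygens, found {idx.size}")
    return np.sort(d)[:k]


def coordination_angles(
    config: SolvationConfig, k: int, apex_role: str = "phosphate_O1P"
) -> np.ndarray:
    """Angles (degrees) at the ion between the apex ligand and the k
    closest water oxygens, waters ordered by distance."""
    apex = config.positions_of(apex_role)
    if apex.shape[0] == 0:
        raise ValueError(f"no ligand with role {apex_role!r} present")
    idx, d = _water_distances(config)
    if idx.size < k:
        raise ValueError(f"need >= {k} water oxygens, found {idx.size}")
    order = np.argsort(d)[:k]
    v1 = apex[0] - config.ion_position
    v2 = config.ligand_positions[idx[order]] - config.ion_position
    cosang = (v2 @ v1) / (np.linalg.norm(v1) * np.linalg.norm(v2, axis=1))
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _shell_vectors(config: SolvationConfig, shell: int) -> np.ndarray:
    idx, d = _water_distances(config)
    if shell == 1:
        mask = d <= FIRST_SHELL_RADIUS
    elif shell == 2:
        mask = (d > FIRST_SHELL_RADIUS) & (d <= SECOND_SHELL_RADIUS)
    else:
        raise ValueError("shell must be 1 or 2")
    return config.ligand_positions[idx[mask]] - config.ion_position


def steinhardt_q(
    config: SolvationConfig,
    l: int,
    shell: int | np.ndarray = 1,
) -> float:
    """Rotationally invariant Steinhardt order parameter q_l.

        q_l = sqrt( 4 pi / (2l+1) * sum_m |<Y_lm>|^2 )

    averaged over the bond vectors from the ion to the shell members.
    ``shell`` may be 1, 2, or an explicit (n, 3) array of bond vectors.
    """
    if isinstance(shell, np.ndarray):
        vecs = np.atleast_2d(shell)
    else:
        vecs = _shell_vectors(config, shell)
    if vecs.shape[0] == 0:
        raise ValueError("empty shell: no bond vectors for steinhardt_q")
    r = np.linalg.norm(vecs, axis=1)
    theta = np.arccos(np.clip(vecs[:, 2] / r, -1.0, 1.0))   # polar
    phi = np.arctan2(vecs[:, 1], vecs[:, 0])                # azimuth
    acc = 0.0
    for m in range(-l, l + 1):
        ylm = sph_harm_y(l, m, theta, phi)
        acc += abs(ylm.mean()) ** 2
    return float(math.sqrt(4.0 * math.pi / (2 * l + 1) * acc))


def tetrahedral_order(config: SolvationConfig, center: int) -> float:
    """Tetrahedral order parameter of a ligand with respect to its four
    nearest neighbouring ligands:

        q_tet = 1 - (3/8) sum_{j<k} (cos psi_jk + 1/3)^2

    q_tet = 1 for a perfect tetrahedron, 0 on average for an ideal gas,
    negative for degenerate (e.g. collinear) arrangements.
    """
    pos = config.ligand_positions
    c = pos[center]
    others = np.delete(pos, center, axis=0)
    if others.shape[0] < 4:
        raise ValueError("tetrahedral_order requires >= 4 neighbours")
    d = np.linalg.norm(others - c, axis=1)
    nb = others[np.argsort(d)[:4]] - c
    nb /= np.linalg.norm(nb, axis=1)[:, None]
    total = 0.0
    for j in range(3):
        for k in range(j + 1, 4):
            cospsi = float(nb[j] @ nb[k])
            total += (cospsi + 1.0 / 3.0) ** 2
    return 1.0 - 3.0 / 8.0 * total


def _assign_hydrogens(config: SolvationConfig) -> dict[int, list[int]]:
    """Map each water oxygen index to the indices of its hydrogens
    (each hydrogen belongs to the nearest water oxygen)."""
    o_idx, _ = _water_distances(config)
    h_idx = [i for i, r in enumerate(config.ligand_roles) if r == "water_H"]
    assignment: dict[int, list[int]] = {int(i): [] for i in o_idx}
    if not h_idx or o_idx.size == 0:
        return assignment
    o_pos = config.ligand_positions[o_idx]
    for h in h_idx:
        d = np.linalg.norm(o_pos - config.ligand_positions[h], axis=1)
        assignment[int(o_idx[np.argmin(d)])].append(h)
    return assignment


def count_hbonds(
    config: SolvationConfig,
    donor_set: list[int],
    acceptor_set: list[int],
) -> int:
    """Directed geometric hydrogen-bond count from donors to acceptors.

    A bond is counted when the donor-acceptor oxygen distance is below
    0.35 nm and the H-donor-acceptor angle is below 30 degrees.  Donors
    must be water oxygens with assigned hydrogens; swapping the sets
    counts the reverse bonds only.
    """
    hydrogens = _assign_hydrogens(config)
    count = 0
    for don in donor_set:
        if don not in hydrogens:
            raise ValueError(f"donor {don} is not a water oxygen")
        if not hydrogens[don]:
            raise ValueError(f"donor {don} has no hydrogens assigned")
        dpos = config.ligand_positions[don]
        for acc in acceptor_set:
            if acc == don:
                continue
            apos = config.ligand_positions[acc]
            if np.linalg.norm(apos - dpos) >= HBOND_OO_CUTOFF:
                continue
            for h in hydrogens[don]:
                hv = config.ligand_positions[h] - dpos
                av = apos - dpos
                cosang = (hv @ av) / (np.linalg.norm(hv) * np.linalg.norm(av))
                if math.degrees(math.acos(np.clip(cosang, -1, 1))) < HBOND_ANGLE_CUTOFF:
                    count += 1
                    break
    return count


# ---------------------------------------------------------------------------
# the default 83-column schema
# ---------------------------------------------------------------------------

def default_md_schema() -> FeatureSchema:
    """The 83-feature schema for coordination-shell configurations.

    Composition: 20 ion-water distances r_1..r_20; 20 coordination angles
    a_1..a_20 (apex O1P); 6 ion-site distances (r_I, r_O2P, r_P, r_N7,
    r_O6, r_Cl); r_ex, the derived difference r_I - r_ex, and s6; q_3,
    q_4, q_6 for the first and second hydration shell; two tetrahedral
    order parameters (two closest waters); 26 hydrogen-bond counts
    (per-water first-shell donations h1_w01..h1_w20, h1_O1P, h1_ex,
    first/second-shell totals, RNA-water, and the exchanging water's
    second-shell donations).
    """
    names: list[str] = []
    groups: list[str] = []

    def add(ns: list[str], g: str) -> None:
        names.extend(ns)
        groups.extend([g] * len(ns))

    add([f"r_{i}" for i in range(1, 21)], "distance")
    add([f"a_{i}" for i in range(1, 21)], "angle")
    add(["r_I", "r_O2P", "r_P", "r_N7", "r_O6", "r_Cl"], "distance")
    add(["r_ex", "r_I_minus_r_ex", "s6"], "derived")
    add(["q3_s1", "q4_s1", "q6_s1", "q3_s2", "q4_s2", "q6_s2"], "steinhardt")
    add(["q_tet_1", "q_tet_2"], "tetrahedral")
    add([f"h1_w{i:02d}" for i in range(1, 21)], "hbond")
    add(["h1_O1P", "h1_ex", "h1_total", "h2_total", "h_rna_water", "h2_ex"], "hbond")
    return FeatureSchema(names=names, groups=groups)


def _role_distance(config: SolvationConfig, role: str, nth: int = 0) -> float | None:
    pos = config.positions_of(role)
    if pos.shape[0] <= nth:
        return None
    d = np.sort(np.linalg.norm(pos - config.ion_position, axis=1))
    return float(d[nth])


def _md_feature_row(
    config: SolvationConfig,
    schema: FeatureSchema,
    exchanging_index: int | None,
    strict: bool,
) -> np.ndarray:
    idx, d = _water_distances(config)
    order = idx[np.argsort(d)]
    dsort = np.sort(d)
    n_w = idx.size

    def resolve(name: str, value: float | None, fallback: float) -> float:
        if value is not None:
            return value
        if strict:
            raise ValueError(f"feature {name!r} is unresolvable for this config")
        return fallback

    if exchanging_index is None:
        # default: the farthest water oxygen is the exchanging one
        if n_w == 0:
            raise ValueError("configuration has no water oxygens")
        exchanging_index = int(order[-1])
    r_ex = float(
        np.linalg.norm(
            config.ligand_positions[exchanging_index] - config.ion_position
        )
    )
    r_I = _role_distance(config, "phosphate_O1P")
    hydrogens = _assign_hydrogens(config)
    have_h = any(hydrogens.values())

    first_shell = [int(i) for i, dd in zip(idx, d) if dd <= FIRST_SHELL_RADIUS]
    second_shell = [
        int(i) for i, dd in zip(idx, d)
        if FIRST_SHELL_RADIUS < dd <= SECOND_SHELL_RADIUS
    ]
    rna = [
        i for i, r in enumerate(config.ligand_roles)
        if r in ("phosphate_O1P", "phosphate_O2P", "other_RNA")
    ]

    def hb(donors: list[int], acceptors: list[int]) -> float | None:
        donors = [dn for dn in donors if hydrogens.get(dn)]
        if not have_h or not donors or not acceptors:
            return 0.0 if not strict else None
        return float(count_hbonds(config, donors, acceptors))

    values: dict[str, float] = {}
    for i in range(1, 21):
        values[f"r_{i}"] = (
            float(dsort[i - 1]) if i <= n_w
            else resolve(f"r_{i}", None, PAD_DISTANCE)
        )
    if r_I is not None and n_w > 0:
        k = min(20, n_w)
        angs = coordination_angles(config, k)
        for i in range(1, 21):
            values[f"a_{i}"] = float(angs[i - 1]) if i <= k else resolve(
                f"a_{i}", None, 0.0
            )
    else:
        for i in range(1, 21):
            values[f"a_{i}"] = resolve(f"a_{i}", None, 0.0)
    values["r_I"] = resolve("r_I", r_I, PAD_DISTANCE)
    values["r_O2P"] = resolve(
        "r_O2P", _role_distance(config, "phosphate_O2P"), PAD_DISTANCE
    )
    values["r_P"] = resolve("r_P", _role_distance(config, "phosphate_P"), PAD_DISTANCE)
    values["r_N7"] = resolve("r_N7", _role_distance(config, "other_RNA"), PAD_DISTANCE)
    values["r_O6"] = resolve(
        "r_O6", _role_distance(config, "other_RNA", nth=1), PAD_DISTANCE
    )
    values["r_Cl"] = resolve("r_Cl", _role_distance(config, "chloride"), PAD_DISTANCE)
    values["r_ex"] = r_ex
    values["r_I_minus_r_ex"] = values["r_I"] - r_ex
    values["s6"] = (
        s6(config, exchanging_index) if n_w >= 6
        else resolve("s6", None, 6 * PAD_DISTANCE)
    )
    for shell_tag, shell_no in (("s1", 1), ("s2", 2)):
        vecs = _shell_vectors(config, shell_no)
        for l in (3, 4, 6):
            name = f"q{l}_{shell_tag}"
            values[name] = (
                steinhardt_q(config, l, shell_no) if vecs.shape[0] > 0
                else resolve(name, None, 0.0)
            )
    for j, name in enumerate(("q_tet_1", "q_tet_2")):
        if n_w > j and config.ligand_positions.shape[0] - 1 >= 4:
            values[name] = tetrahedral_order(config, int(order[j]))
        else:
            values[name] = resolve(name, None, 0.0)
    for i in range(1, 21):
        name = f"h1_w{i:02d}"
        if i <= n_w:
            w = int(order[i - 1])
            values[name] = resolve(
                name, hb([w], [s for s in first_shell if s != w]), 0.0
            )
        else:
            values[name] = resolve(name, None, 0.0)
    o1p = [i for i, r in enumerate(config.ligand_roles) if r == "phosphate_O1P"]
    values["h1_O1P"] = resolve("h1_O1P", hb(first_shell, o1p) if o1p else 0.0, 0.0)
    values["h1_ex"] = resolve(
        "h1_ex", hb([exchanging_index], [s for s in first_shell
                                         if s != exchanging_index]), 0.0
    )
    values["h1_total"] = resolve("h1_total", hb(first_shell, first_shell), 0.0)
    values["h2_total"] = resolve("h2_total", hb(second_shell, second_shell), 0.0)
    values["h_rna_water"] = resolve(
        "h_rna_water", hb(first_shell + second_shell, rna) if rna else 0.0, 0.0
    )
    values["h2_ex"] = resolve(
        "h2_ex", hb([exchanging_index], second_shell), 0.0
    )
    return np.array([values[n] for n in schema.names], dtype=float)


def build_feature_table(
    configs: list[SolvationConfig] | np.ndarray,
    schema: FeatureSchema | None = None,
    exchanging_index: int | None = None,
    strict: bool = False,
    toy_names: list[str] | None = None,
) -> tuple[np.ndarray, FeatureSchema]:
    """Assemble a feature matrix.

    For coordination-shell configs the default 83-column schema is used
    (``strict=True`` raises, naming the feature, when a reference atom is
    missing; the default pads with documented fill values).  For toy
    configurations (a plain coordinate array) each column is a coordinate
    and the names default to x, z*, noise*.
    """
    if isinstance(configs, np.ndarray):
        X = np.atleast_2d(configs)
        if toy_names is None:
            toy_names = [f"c{i}" for i in range(X.shape[1])]
        sch = schema or FeatureSchema(
            names=list(toy_names), groups=["derived"] * X.shape[1]
        )
        return X.astype(float), sch
    sch = schema or default_md_schema()
    rows = [
        _md_feature_row(c, sch, exchanging_index, strict) for c in configs
    ]
    return np.array(rows, dtype=float), sch
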