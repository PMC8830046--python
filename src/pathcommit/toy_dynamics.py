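"""Langevin toy systems standing in for the MD engine.

The reference system is a particle in a quartic double well along a
"distance-like" coordinate ``x``, harmonically coupled to a configurable
number of bath ("solvent") coordinates, plus uncoupled free coordinates
that serve as pure-noise features:

    V(x, z) = h ((x/a)^2 - 1)^2 + sum_j (kappa_j / 2) (z_j - x)^2

with ``h`` the barrier height in k_BT and ``a`` half the well separation
(wells at x = +/- a, barrier top at x = 0).  The bath mimics the active
role of the solvent: each z_j relaxes toward x with its own stiffness, so
slow bath coordinates lag the reactive motion exactly the way hydration
shells lag an exchanging ligand.  Dynamics are underdamped Langevin
integrated with the BAOAB splitting, which samples the canonical ensemble
at the configured temperature.

Also provided: Maxwell-Boltzmann velocity draws, a brute-force committor
estimator (the ground-truth oracle used throughout), shooting-point
dataset generation, and ideal coordination-shell geometries
(octahedron / tetrahedron / square pyramid) for the feature battery.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np

from . import defaults
from .data import ShootingDataset

__all__ = [
    "PotentialSpec",
    "PhasePoint",
    "Trajectory",
    "StateDef",
    "SolvationConfig",
    "CommittorResult",
    "default_double_well_spec",
    "default_states",
    "evaluate_potential",
    "integrate_langevin",
    "draw_maxwell_boltzmann",
    "brute_force_committor",
    "generate_shooting_dataset",
    "make_ideal_shell",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PotentialSpec:
    """Configuration of a toy potential plus its Langevin parameters.

    kinds
    -----
    ``double_well_bath``
        quartic double well in x, harmonic bath coupling, free noise
        coordinates.  Dimension = 1 + n_bath + n_noise_features.
    ``harmonic_well``
        single harmonic well ``(stiffness/2) x^2`` (closed-form reference
        system).  Dimension = 1 + n_noise_features.
    ``custom_grid_2d``
        bivariate potential given on a rectangular grid, evaluated with a
        cubic spline.  Dimension = 2 + n_noise_features.
    """

    kind: str = "double_well_bath"
    barrier_height: float = defaults.TOY_BARRIER_HEIGHT
    well_separation: float = 2.0
    coupling_strengths: Sequence[float] | None = None
    n_bath: int = defaults.TOY_N_BATH
    n_noise_features: int = 0
    friction: float = defaults.TOY_FRICTION
    temperature: float = 1.0
    mass: float = 1.0
    stiffness: float = 1.0
    grid_x: np.ndarray | None = None
    grid_y: np.ndarray | None = None
    grid_V: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("double_well_bath", "harmonic_well", "custom_grid_2d"):
            raise ValueError(f"unknown potential kind: {self.kind!r}")
        if self.kind != "double_well_bath":
            self.n_bath = 0
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be > 0")
        if self.n_bath < 0:
            raise ValueError("n_bath must be >= 0")
        if self.friction <= 0 or self.temperature <= 0 or self.mass <= 0:
            raise ValueError("friction, temperature and mass must be > 0")
        if self.coupling_strengths is None:
            lo, hi = defaults.TOY_COUPLING_RANGE
            self.coupling_strengths = (
                np.geomspace(lo, hi, self.n_bath) if self.n_bath else np.empty(0)
            )
        self.coupling_strengths = np.asarray(self.coupling_strengths, dtype=float)
        if self.coupling_strengths.shape != (self.n_bath,):
            raise ValueError("coupling_strengths must have one entry per bath dof")
        if self.kind == "custom_grid_2d":
            if self.grid_x is None or self.grid_y is None or self.grid_V is None:
                raise ValueError("custom_grid_2d requires grid_x, grid_y, grid_V")
        self._spline = None

    @property
    def n_dim(self) -> int:
        base = 2 if self.kind == "custom_grid_2d" else 1
        return base + self.n_bath + self.n_noise_features

    @property
    def n_physical(self) -> int:
        """Coordinates that feel a force (everything but the noise dofs)."""
        return self.n_dim - self.n_noise_features

    def spline(self):
        if self._spline is None:
            from scipy.interpolate import RectBivariateSpline

            self._spline = RectBivariateSpline(self.grid_x, self.grid_y, self.grid_V)
        return self._spline

    def stability_limit(self) -> float:
        """Upper bound on the usable timestep.

        BAOAB is stable for dt < 2/omega_max with omega the stiffest
        harmonic frequency.  For the double well the stiffest force
        constant is max(8h/a^2 at the wells, max kappa_j).
        """
        a = self.well_separation / 2.0
        if self.kind == "double_well_bath":
            k = max(8.0 * self.barrier_height / a**2,
                    float(np.max(self.coupling_strengths, initial=0.0)))
        elif self.kind == "harmonic_well":
            k = self.stiffness
        else:
            k = 100.0  # conservative guess for gridded potentials
        return 2.0 / math.sqrt(k / self.mass)


@dataclasses.dataclass
class PhasePoint:
    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have equal length")


@dataclasses.dataclass
class Trajectory:
    """Uniformly spaced phase points from one Langevin integration."""

    positions: np.ndarray          # (n_frames, n_dim)
    velocities: np.ndarray         # (n_frames, n_dim)
    timestep: float
    t0: float = 0.0
    spec_ref: str = ""
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.timestep * np.arange(self.n_frames)

    @property
    def duration(self) -> float:
        return self.timestep * (self.n_frames - 1)

    def frame(self, i: int) -> PhasePoint:
        return PhasePoint(self.positions[i], self.velocities[i], self.times[i])

    def reversed(self) -> "Trajectory":
        return Trajectory(
            positions=self.positions[::-1].copy(),
            velocities=-self.velocities[::-1],
            timestep=self.timestep,
            t0=self.t0,
            spec_ref=self.spec_ref,
            rng_seed=self.rng_seed,
        )


@dataclasses.dataclass
class StateDef:
    """Threshold rule over a scalar collective coordinate.

    ``contains`` is true where ``side * (coord - threshold) > 0``, i.e.
    side=+1 selects coord > threshold and side=-1 selects coord < threshold.
    The default coordinate is the reactive position x (component 0).
    """

    name: str
    threshold: float
    side: int = 1
    coord: Callable[[np.ndarray], np.ndarray] | None = None

    def coordinate(self, positions: np.ndarray) -> np.ndarray:
        if self.coord is not None:
            return self.coord(positions)
        return np.asarray(positions)[..., 0]

    def contains(self, positions: np.ndarray) -> np.ndarray:
        return self.side * (self.coordinate(positions) - self.threshold) > 0


def default_states(threshold: float = 0.8) -> tuple[StateDef, StateDef]:
    """A at x > +threshold, B at x < -threshold (wells at +/-1)."""
    return (
        StateDef("A", threshold, side=+1),
        StateDef("B", -threshold, side=-1),
    )


_SHELL_ROLES = (
    "water_O",
    "water_H",
    "phosphate_O1P",
    "phosphate_O2P",
    "phosphate_P",
    "chloride",
    "other_RNA",
)


@dataclasses.dataclass
class SolvationConfig:
    """An ion and its coordination shell (positions in nm)."""

    ion_position: np.ndarray
    ligand_positions: np.ndarray
    ligand_roles: list[str]

    def __post_init__(self) -> None:
        self.ion_position = np.asarray(self.ion_position, dtype=float).reshape(3)
        self.ligand_positions = np.atleast_2d(
            np.asarray(self.ligand_positions, dtype=float)
        )
        if self.ligand_positions.shape[1] != 3:
            raise ValueError("ligand positions must be 3-vectors")
        if len(self.ligand_roles) != self.ligand_positions.shape[0]:
            raise ValueError("role list length must equal position list length")
        for role in self.ligand_roles:
            if role not in _SHELL_ROLES:
                raise ValueError(f"unknown ligand role: {role!r}")

    def positions_of(self, role: str) -> np.ndarray:
        mask = [r == role for r in self.ligand_roles]
        return self.ligand_positions[np.asarray(mask, dtype=bool)]


@dataclasses.dataclass
class CommittorResult:
    p_A: float
    n_A: int
    n_B: int
    n_unresolved: int
    resolved: bool

    @property
    def n_trials(self) -> int:
        return self.n_A + self.n_B + self.n_unresolved


# ---------------------------------------------------------------------------
# potential evaluation
# ---------------------------------------------------------------------------

def _energy_forces(spec: PotentialSpec, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized energy/force for replicas P of shape (n, n_dim)."""
    P = np.atleast_2d(P)
    E = np.zeros(P.shape[0])
    F = np.zeros_like(P)
    a = spec.well_separation / 2.0
    if spec.kind == "double_well_bath":
        x = P[:, 0]
        u = (x / a) ** 2 - 1.0
        E += spec.barrier_height * u**2
        F[:, 0] -= spec.barrier_height * 4.0 * u * x / a**2
        if spec.n_bath:
            z = P[:, 1 : 1 + spec.n_bath]
            kap = spec.coupling_strengths
            d = z - x[:, None]
            E += 0.5 * (kap * d**2).sum(axis=1)
            F[:, 1 : 1 + spec.n_bath] -= kap * d
            F[:, 0] += (kap * d).sum(axis=1)
    elif spec.kind == "harmonic_well":
        x = P[:, 0]
        E += 0.5 * spec.stiffness * x**2
        F[:, 0] -= spec.stiffness * x
    else:  # custom_grid_2d
        sp = spec.spline()
        x, y = P[:, 0], P[:, 1]
        E += sp.ev(x, y)
        F[:, 0] -= sp.ev(x, y, dx=1)
        F[:, 1] -= sp.ev(x, y, dy=1)
    return E, F


def evaluate_potential(
    spec: PotentialSpec, positions: np.ndarray
) -> tuple[float, np.ndarray]:
    """Potential energy and force at one configuration.

    Noise coordinates contribute zero energy and force (they diffuse
    freely).  Raises on a dimension mismatch, naming the expected length.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 1 or positions.shape[0] != spec.n_dim:
        raise ValueError(
            f"expected a length-{spec.n_dim} configuration for kind "
            f"{spec.kind!r}, got shape {positions.shape}"
        )
    E, F = _energy_forces(spec, positions[None, :])
    return float(E[0]), F[0]


# ---------------------------------------------------------------------------
# Langevin integration (BAOAB)
# ---------------------------------------------------------------------------

def draw_maxwell_boltzmann(
    n_dof: int, temperature: float, mass: float, rng_seed: int | np.random.Generator
) -> np.ndarray:
    """I.i.d. Gaussian velocities with zero mean and variance k_BT/m."""
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return rng.normal(0.0, math.sqrt(temperature / mass), size=n_dof)


def _baoab_coeffs(spec: PotentialSpec, dt: float) -> tuple[float, float]:
    c1 = math.exp(-spec.friction * dt)
    c2 = math.sqrt(spec.temperature / spec.mass * (1.0 - c1 * c1))
    return c1, c2


def _step_baoab(
    spec: PotentialSpec,
    X: np.ndarray,
    V: np.ndarray,
    F: np.ndarray,
    dt: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One BAOAB step for replica arrays of shape (n, n_dim); returns X,V,F."""
    V = V + 0.5 * dt * F / spec.mass
    X = X + 0.5 * dt * V
    V = c1 * V + c2 * rng.standard_normal(V.shape)
    X = X + 0.5 * dt * V
    _, F = _energy_forces(spec, X)
    V = V + 0.5 * dt * F / spec.mass
    return X, V, F


def integrate_langevin(
    spec: PotentialSpec,
    start: PhasePoint,
    n_steps: int,
    timestep: float = defaults.TOY_TIMESTEP,
    rng_seed: int | np.random.Generator = 0,
    stride: int = 1,
) -> Trajectory:
    """Underdamped Langevin trajectory via the BAOAB splitting.

    The timestep must respect ``spec.stability_limit()``; the default toy
    parameters allow dt up to ~0.25, and dt = 0.01 is used throughout.
    Bit-exact reproducible from the seed.  Raises if the energy turns
    non-finite, reporting the offending step index.
    """
    if timestep <= 0:
        raise ValueError("timestep must be > 0")
    if start.positions.shape[0] != spec.n_dim:
        raise ValueError(
            f"start point has {start.positions.shape[0]} dofs, spec needs {spec.n_dim}"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    c1, c2 = _baoab_coeffs(spec, timestep)
    X = start.positions[None, :].copy()
    V = start.velocities[None, :].copy()
    _, F = _energy_forces(spec, X)
    n_saved = n_steps // stride + 1
    pos = np.empty((n_saved, spec.n_dim))
    vel = np.empty((n_saved, spec.n_dim))
    pos[0], vel[0] = X[0], V[0]
    k = 1
    for step in range(1, n_steps + 1):
        X, V, F = _step_baoab(spec, X, V, F, timestep, c1, c2, rng)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError(
                f"non-finite configuration at integration step {step}"
            )
        if step % stride == 0:
            pos[k], vel[k] = X[0], V[0]
            k += 1
    seed_repr = rng_seed if isinstance(rng_seed, int) else None
    return Trajectory(
        positions=pos[:k],
        velocities=vel[:k],
        timestep=timestep * stride,
        t0=start.time,
        spec_ref=spec.kind,
        rng_seed=seed_repr,
    )


# ---------------------------------------------------------------------------
# brute-force committor
# ---------------------------------------------------------------------------

def _propagate_to_states(
    spec: PotentialSpec,
    X: np.ndarray,
    V: np.ndarray,
    states: tuple[StateDef, StateDef],
    max_steps: int,
    dt: float,
    rng: np.random.Generator,
    check_every: int = 10,
) -> np.ndarray:
    """Run replicas until absorption into A (label 1) or B (label 2).

    Returns per-replica labels; 0 marks replicas unresolved at the horizon.
    """
    state_A, state_B = states
    n = X.shape[0]
    labels = np.zeros(n, dtype=np.int8)
    alive = np.arange(n)
    c1, c2 = _baoab_coeffs(spec, dt)
    _, F = _energy_forces(spec, X)
    step = 0
    while step < max_steps and alive.size:
        for _ in range(min(check_every, max_steps - step)):
            X, V, F = _step_baoab(spec, X, V, F, dt, c1, c2, rng)
            step += 1
        in_A = state_A.contains(X)
        in_B = state_B.contains(X)
        done = in_A | in_B
        if np.any(done):
            labels[alive[in_A]] = 1
            labels[alive[in_B]] = 2
            keep = ~done
            alive, X, V, F = alive[keep], X[keep], V[keep], F[keep]
    return labels


def brute_force_committor(
    spec: PotentialSpec,
    config: np.ndarray,
    states: tuple[StateDef, StateDef],
    n_trials: int = defaults.N_COMMITTOR_TRIALS,
    horizon: float = 50.0,
    rng_seed: int | np.random.Generator = 0,
    timestep: float = defaults.TOY_TIMESTEP,
    check_every: int = 10,
) -> CommittorResult:
    """Estimate p_A by launching trial trajectories with fresh velocities.

    Each of ``n_trials`` replicas starts from ``config`` with
    Maxwell-Boltzmann velocities and runs until it first enters A or B or
    until ``horizon`` time units elapse.  Unresolved trials are excluded
    from p_A = n_A/(n_A+n_B) and reported; a result with no resolved trial
    is flagged (``resolved=False``) rather than silently zero.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config = np.asarray(config, dtype=float)
    if config.shape != (spec.n_dim,):
        raise ValueError(f"config must have length {spec.n_dim}")
    state_A, state_B = states
    if state_A.contains(config[None, :])[0] and state_B.contains(config[None, :])[0]:
        raise ValueError("states A and B are not disjoint at this configuration")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    X = np.broadcast_to(config, (n_trials, spec.n_dim)).copy()
    V = rng.normal(
        0.0,
        math.sqrt(spec.temperature / spec.mass),
        size=(n_trials, spec.n_dim),
    )
    labels = _propagate_to_states(
        spec, X, V, states, max_steps=int(round(horizon / timestep)), dt=timestep,
        rng=rng, check_every=check_every,
    )
    n_A = int(np.sum(labels == 1))
    n_B = int(np.sum(labels == 2))
    n_un = n_trials - n_A - n_B
    resolved = (n_A + n_B) > 0
    p_A = n_A / (n_A + n_B) if resolved else math.nan
    return CommittorResult(p_A=p_A, n_A=n_A, n_B=n_B, n_unresolved=n_un,
                           resolved=resolved)


# ---------------------------------------------------------------------------
# shooting datasets
# ---------------------------------------------------------------------------

def sample_equilibrium_configs(
    spec: PotentialSpec,
    n_points: int,
    region: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw configurations from the window-restricted canonical density.

    For the double well the conditional bath distribution given x is
    Gaussian (mean x, variance k_BT/kappa_j), so the draw is exact:
    x from exp(-V_dw(x)/k_BT) restricted to the window (rejection from a
    uniform proposal), bath from the Gaussian conditional, and noise
    coordinates from a standard normal.
    """
    lo, hi = region
    if not hi > lo:
        raise ValueError("empty region sample: region upper bound must exceed lower")
    a = spec.well_separation / 2.0
    xs = np.empty(n_points)
    filled = 0
    vmin = None
    while filled < n_points:
        prop = rng.uniform(lo, hi, size=2 * (n_points - filled) + 16)
        u = (prop / a) ** 2 - 1.0
        V = spec.barrier_height * u**2
        if vmin is None:
            grid = np.linspace(lo, hi, 512)
            vmin = float(np.min(spec.barrier_height * ((grid / a) ** 2 - 1) ** 2))
        acc = rng.random(prop.size) < np.exp(-(V - vmin) / spec.temperature)
        take = prop[acc][: n_points - filled]
        xs[filled : filled + take.size] = take
        filled += take.size
    P = np.empty((n_points, spec.n_dim))
    P[:, 0] = xs
    if spec.n_bath:
        sig = np.sqrt(spec.temperature / spec.coupling_strengths)
        P[:, 1 : 1 + spec.n_bath] = xs[:, None] + rng.normal(
            size=(n_points, spec.n_bath)
        ) * sig
    if spec.n_noise_features:
        P[:, 1 + spec.n_bath :] = rng.standard_normal(
            (n_points, spec.n_noise_features)
        )
    return P


def generate_shooting_dataset(
    spec: PotentialSpec,
    n_points: int,
    n_trials: int = defaults.N_COMMITTOR_TRIALS,
    region: tuple[float, float] = (-0.5, 0.5),
    rng_seed: int = 0,
    horizon: float = 50.0,
    configs: np.ndarray | None = None,
) -> ShootingDataset:
    """Label configurations in the transition region with committor counts.

    Configurations are drawn by window-restricted equilibrium sampling
    (or supplied explicitly, e.g. harvested from TPS paths) and each is
    labelled (n_A, n_B) by the brute-force committor.  The feature table
    holds the physical coordinates plus the injected pure-noise columns.
    """
    if spec.kind != "double_well_bath":
        raise ValueError("shooting datasets are defined for double_well_bath")
    rng = np.random.default_rng(rng_seed)
    if configs is None:
        if n_points > 0:
            configs = sample_equilibrium_configs(spec, n_points, region, rng)
        else:
            configs = np.empty((0, spec.n_dim))
    else:
        configs = np.atleast_2d(np.asarray(configs, dtype=float))
        n_points = configs.shape[0]
    names = (
        ["x"]
        + [f"z{j+1}" for j in range(spec.n_bath)]
        + [f"noise{j+1}" for j in range(spec.n_noise_features)]
    )
    states = default_states()
    n_A = np.zeros(n_points, dtype=int)
    n_B = np.zeros(n_points, dtype=int)
    for i in range(n_points):
        res = brute_force_committor(
            spec, configs[i], states, n_trials=n_trials, horizon=horizon,
            rng_seed=rng,
        )
        n_A[i], n_B[i] = res.n_A, res.n_B
    return ShootingDataset(
        features=configs,
        feature_names=names,
        n_A=n_A,
        n_B=n_B,
        n_trials=np.full(n_points, n_trials),
    )


def default_double_well_spec(**overrides) -> PotentialSpec:
    """The standard study system: h=8 k_BT, 8 log-spaced bath dofs."""
    params = dict(
        kind="double_well_bath",
        barrier_height=defaults.TOY_BARRIER_HEIGHT,
        n_bath=defaults.TOY_N_BATH,
        n_noise_features=defaults.TOY_N_NOISE,
        friction=defaults.TOY_FRICTION,
    )
    params.update(overrides)
    return PotentialSpec(**params)


# ---------------------------------------------------------------------------
# ideal coordination shells
# ---------------------------------------------------------------------------

_GEOMETRIES = {
    "octahedron": np.array(
        [
            [1, 0, 0], [-1, 0, 0],
            [0, 1, 0], [0, -1, 0],
            [0, 0, 1], [0, 0, -1],
        ],
        dtype=float,
    ),
    "tetrahedron": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    / math.sqrt(3.0),
    # apex on the C4v axis, four basal ligands in the plane below
    "square_pyramid": np.array(
        [
            [0, 0, 1],
            [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
        ],
        dtype=float,
    ),
}


def make_ideal_shell(
    geometry: str, ion_ligand_distance: float, roles: list[str] | None = None
) -> SolvationConfig:
    """Exact vertex coordinates of the named polyhedron centred on the ion.

    All ligands sit at ``ion_ligand_distance`` (nm) from the ion at the
    origin; roles default to water oxygens.
    """
    if ion_ligand_distance <= 0:
        raise ValueError("ion_ligand_distance must be > 0")
    try:
        verts = _GEOMETRIES[geometry]
    except KeyError:
        raise ValueError(
            f"unknown geometry {geometry!r}; choose from {sorted(_GEOMETRIES)}"
        ) from None
    positions = verts * ion_ligand_distance
    if roles is None:
        roles = ["water_O"] * len(positions)
    return SolvationConfig(
        ion_position=np.zeros(3), ligand_positions=positions, ligand_roles=roles
    )
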