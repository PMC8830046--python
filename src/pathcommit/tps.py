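"""Two-way shooting transition path sampling.

A Markov chain in trajectory space: from the current reactive path a time
slice is picked uniformly at random, all velocities are redrawn from the
Maxwell-Boltzmann distribution, and the dynamics is integrated forward and
backward in time so that the two segments concatenate to the fixed path
length.  Trial paths are accepted iff their endpoints lie in different
metastable states; rejected moves repeat the previous path in the
ensemble.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from . import defaults
from .toy_dynamics import (
    PhasePoint,
    PotentialSpec,
    StateDef,
    Trajectory,
    integrate_langevin,
)

__all__ = [
    "PathEnsemble",
    "ShootingRecord",
    "two_way_shoot",
    "run_tps",
    "bootstrap_initial_path",
    "transition_time",
]


@dataclasses.dataclass
class ShootingRecord:
    move_index: int
    slice_index: int
    accepted: bool


@dataclasses.dataclass
class PathEnsemble:
    """Fixed-length path ensemble produced by a TPS run."""

    paths: list[Trajectory]
    accepted: list[bool]
    shooting_records: list[ShootingRecord]

    @property
    def acceptance_rate(self) -> float:
        if not self.shooting_records:
            return 0.0
        return sum(r.accepted for r in self.shooting_records) / len(
            self.shooting_records
        )

    @property
    def n_paths(self) -> int:
        return len(self.paths)


def _endpoint_states(
    path: Trajectory, states: tuple[StateDef, StateDef]
) -> tuple[str | None, str | None]:
    out = []
    for idx in (0, -1):
        pos = path.positions[idx][None, :]
        label = None
        for s in states:
            if s.contains(pos)[0]:
                label = s.name
        out.append(label)
    return out[0], out[1]


def is_reactive(path: Trajectory, states: tuple[StateDef, StateDef]) -> bool:
    a, b = _endpoint_states(path, states)
    return a is not None and b is not None and a != b


def two_way_shoot(
    spec: PotentialSpec,
    current_path: Trajectory,
    states: tuple[StateDef, StateDef],
    rng_seed: int | np.random.Generator = 0,
    move_index: int = 0,
) -> tuple[Trajectory, bool, ShootingRecord]:
    """One two-way shooting move from the current reactive path.

    The slice is uniform over interior frames (endpoints cannot seed a
    two-way shot of fixed total length); velocities are fully redrawn.
    The backward segment is integrated with reversed velocities and then
    time-reversed, so the trial path is a genuine dynamical path of the
    same length.  Accepted iff the endpoints lie in different states.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    L = current_path.n_frames
    if L < 3:
        raise ValueError("path must have at least 3 frames for a two-way shot")
    dt = current_path.timestep
    i = int(rng.integers(1, L - 1))
    x0 = current_path.positions[i]
    v0 = rng.normal(
        0.0, math.sqrt(spec.temperature / spec.mass), size=spec.n_dim
    )
    fwd = integrate_langevin(
        spec, PhasePoint(x0, v0), n_steps=L - 1 - i, timestep=dt, rng_seed=rng
    )
    bwd = integrate_langevin(
        spec, PhasePoint(x0, -v0), n_steps=i, timestep=dt, rng_seed=rng
    )
    rev = bwd.reversed()
    positions = np.vstack([rev.positions[:-1], fwd.positions])
    velocities = np.vstack([rev.velocities[:-1], fwd.velocities])
    trial = Trajectory(
        positions=positions, velocities=velocities, timestep=dt,
        spec_ref=spec.kind,
    )
    accepted = is_reactive(trial, states)
    return trial, accepted, ShootingRecord(move_index, i, accepted)


def run_tps(
    spec: PotentialSpec,
    initial_path: Trajectory,
    n_moves: int,
    states: tuple[StateDef, StateDef],
    rng_seed: int = 0,
) -> PathEnsemble:
    """Markov chain of fixed-length reactive paths.

    Rejected moves repeat the previous path in the ensemble, so the
    ensemble always holds ``n_moves + 1`` entries.  Reproducible from the
    seed.
    """
    if not is_reactive(initial_path, states):
        raise ValueError("initial path is not reactive (endpoints not in A and B)")
    rng = np.random.default_rng(rng_seed)
    paths = [initial_path]
    accepted = [True]
    records: list[ShootingRecord] = []
    current = initial_path
    for m in range(n_moves):
        trial, ok, rec = two_way_shoot(spec, current, states, rng, move_index=m)
        records.append(rec)
        if ok:
            current = trial
        paths.append(current)
        accepted.append(ok)
    return PathEnsemble(paths=paths, accepted=accepted, shooting_records=records)


def bootstrap_initial_path(
    spec: PotentialSpec,
    states: tuple[StateDef, StateDef],
    boost_temperature: float,
    n_frames: int,
    timestep: float = defaults.TOY_TIMESTEP,
    rng_seed: int = 0,
    max_steps: int = 10_000_000,
    chunk: int = 50_000,
) -> Trajectory:
    """Harvest an initial reactive path from boosted-temperature dynamics.

    Runs Langevin dynamics at ``boost_temperature`` until a transition
    between the states (defined at production thresholds) is observed and
    a fixed-length window with endpoints in different states can be cut
    out.  Raises if no crossing occurs within ``max_steps``, advising a
    larger boost.
    """
    if boost_temperature < spec.temperature:
        raise ValueError("boost_temperature must be >= the production temperature")
    hot = dataclasses.replace(spec, temperature=boost_temperature)
    hot.__post_init__()
    rng = np.random.default_rng(rng_seed)
    state_A, state_B = states
    # start from the A-side well with thermal velocities
    x0 = np.zeros(spec.n_dim)
    x0[0] = spec.well_separation / 2.0
    if spec.n_bath:
        x0[1 : 1 + spec.n_bath] = x0[0]
    v0 = rng.normal(0.0, math.sqrt(boost_temperature / spec.mass), spec.n_dim)
    start = PhasePoint(x0, v0)
    prev: Trajectory | None = None
    steps_done = 0
    while steps_done < max_steps:
        seg = integrate_langevin(
            hot, start, n_steps=chunk, timestep=timestep, rng_seed=rng
        )
        steps_done += chunk
        if prev is None:
            pos = seg.positions
            vel = seg.velocities
        else:
            pos = np.vstack([prev.positions[:-1], seg.positions])
            vel = np.vstack([prev.velocities[:-1], seg.velocities])
        in_A = state_A.contains(pos)
        in_B = state_B.contains(pos)
        window = _find_reactive_window(in_A, in_B, n_frames)
        if window is not None:
            s = window
            return Trajectory(
                positions=pos[s : s + n_frames].copy(),
                velocities=vel[s : s + n_frames].copy(),
                timestep=timestep,
                spec_ref=spec.kind,
                rng_seed=rng_seed,
            )
        prev = Trajectory(
            positions=pos[-n_frames:], velocities=vel[-n_frames:], timestep=timestep
        )
        start = PhasePoint(pos[-1], vel[-1])
    raise RuntimeError(
        f"no reactive crossing within {max_steps} steps; "
        "increase boost_temperature or the step budget"
    )


def _find_reactive_window(
    in_A: np.ndarray, in_B: np.ndarray, n_frames: int
) -> int | None:
    """First start index s such that frames s and s+n_frames-1 lie in
    different states; None if no such window exists."""
    n = in_A.size
    if n < n_frames:
        return None
    head_A, head_B = in_A[: n - n_frames + 1], in_B[: n - n_frames + 1]
    tail_A, tail_B = in_A[n_frames - 1 :], in_B[n_frames - 1 :]
    ok = (head_A & tail_B) | (head_B & tail_A)
    idx = np.flatnonzero(ok)
    return int(idx[0]) if idx.size else None


def transition_time(path: Trajectory, states: tuple[StateDef, StateDef]) -> float:
    """Duration between last exit from the initial state and first entry
    into the final state along a reactive path."""
    if not is_reactive(path, states):
        raise ValueError("transition_time requires a reactive path")
    state_A, state_B = states
    in_A = state_A.contains(path.positions)
    in_B = state_B.contains(path.positions)
    initial, final = (in_A, in_B) if in_A[0] else (in_B, in_A)
    i_exit = int(np.flatnonzero(initial).max())
    after = np.flatnonzero(final[i_exit + 1 :])
    i_enter = i_exit + 1 + int(after[0])
    return (i_enter - i_exit) * path.timestep
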