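"""Umbrella sampling, WHAM free-energy profiles and the TST rate bound.

Umbrella windows apply a harmonic bias (k/2)(xi - c)^2 to a collective
coordinate of the toy system; the unbiased free-energy profile is
reconstructed with the weighted histogram analysis method (WHAM) by
self-consistent iteration of

    P_j = n_j / sum_i N_i exp[(f_i - B_ij)/k_BT]
    f_i = -k_BT ln sum_j P_j exp(-B_ij/k_BT)

until the window offsets f_i stop changing.  1D and 2D coordinates are
supported.  Convergence is diagnosed by block analysis (default 8
contiguous blocks).  The transition-state-theory rate

    k_TST = sqrt(k_BT / 2 pi m_eff) * exp(-F(x*)/k_BT)
            / integral_reactant exp(-F/k_BT) dx

is an upper bound on the true rate: recrossings of the dividing surface
only lower the observed rate, never raise it.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from . import defaults
from .toy_dynamics import (
    PhasePoint,
    PotentialSpec,
    StateDef,
    _baoab_coeffs,
    _energy_forces,
)

__all__ = [
    "UmbrellaWindow",
    "FreeEnergyProfile",
    "run_umbrella",
    "wham",
    "block_analysis",
    "tst_rate",
    "direct_rate",
]


@dataclasses.dataclass
class UmbrellaWindow:
    coordinate: str
    center: np.ndarray          # (d,)
    force_constant: np.ndarray  # (d,)
    samples: np.ndarray         # (n, d)

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.force_constant = np.broadcast_to(
            np.asarray(self.force_constant, dtype=float), self.center.shape
        ).copy()
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[:, None]
        if np.any(self.force_constant <= 0):
            raise ValueError("force_constant must be > 0")
        if self.samples.shape[0] == 0:
            raise ValueError("window has no samples after equilibration discard")


@dataclasses.dataclass
class FreeEnergyProfile:
    """Binned free energy in k_BT, minimum shifted to zero."""

    grid: tuple[np.ndarray, ...]    # bin centers per dimension
    F: np.ndarray                   # shape matches the grid
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = self.occupancy > 0
        if occ.any():
            self.F = self.F - np.nanmin(self.F[occ])

    @property
    def ndim(self) -> int:
        return len(self.grid)

    def interp(self, x: float) -> float:
        """Linear interpolation of a 1D profile."""
        if self.ndim != 1:
            raise ValueError("interp supports 1D profiles only")
        return float(np.interp(x, self.grid[0], self.F))

    def marginal(self, axis: int, temperature: float = 1.0) -> "FreeEnergyProfile":
        """Integrate a 2D profile over one coordinate."""
        if self.ndim != 2:
            raise ValueError("marginal requires a 2D profile")
        keep = 1 - axis
        with np.errstate(over="ignore"):
            w = np.exp(-np.where(self.occupancy > 0, self.F, np.inf) / temperature)
        marg = w.sum(axis=axis)
        occ = self.occupancy.sum(axis=axis)
        with np.errstate(divide="ignore"):
            F = -temperature * np.log(marg)
        return FreeEnergyProfile(grid=(self.grid[keep],), F=F, occupancy=occ)


# ---------------------------------------------------------------------------
# biased sampling
# ---------------------------------------------------------------------------

_COORD_DIMS = {"x": (0,), "xy": (0, 1)}


def run_umbrella(
    spec: PotentialSpec,
    coordinate: str,
    centers: np.ndarray,
    force_constant: float | np.ndarray,
    steps_per_window: int,
    discard: int,
    rng_seed: int = 0,
    timestep: float = defaults.TOY_TIMESTEP,
    stride: int = 1,
) -> list[UmbrellaWindow]:
    """Harmonically biased Langevin runs, one per window center.

    ``coordinate`` is 'x' (component 0) or 'xy' (components 0 and 1 of a
    2D potential).  The first ``discard`` steps of each window are
    dropped as equilibration.  Warns when the sample histograms of
    adjacent windows overlap by less than 1% and raises on zero overlap.
    """
    if coordinate not in _COORD_DIMS:
        raise ValueError(f"unknown coordinate {coordinate!r}")
    dims = _COORD_DIMS[coordinate]
    if discard >= steps_per_window:
        raise ValueError("discard must be smaller than steps_per_window")
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    if centers.ndim == 1 and len(dims) == 2:
        raise ValueError("2D coordinate needs (n_windows, 2) centers")
    centers2 = centers[:, None] if centers.ndim == 1 else centers
    kvec = np.broadcast_to(
        np.asarray(force_constant, dtype=float), (len(dims),)
    ).copy()
    rng = np.random.default_rng(rng_seed)
    c1, c2 = _baoab_coeffs(spec, timestep)
    windows = []
    for c in centers2:
        X = np.zeros((1, spec.n_dim))
        for d, cd in zip(dims, c):
            X[0, d] = cd
        if spec.kind == "double_well_bath" and spec.n_bath:
            X[0, 1 : 1 + spec.n_bath] = X[0, 0]
        V = rng.normal(0.0, math.sqrt(spec.temperature / spec.mass),
                       size=(1, spec.n_dim))

        def force(Xa: np.ndarray) -> np.ndarray:
            _, F = _energy_forces(spec, Xa)
            for d, cd, kk in zip(dims, c, kvec):
                F[:, d] -= kk * (Xa[:, d] - cd)
            return F

        F = force(X)
        n_keep = (steps_per_window - discard - 1) // stride + 1
        samples = np.empty((n_keep, len(dims)))
        k_out = 0
        for step in range(steps_per_window):
            V = V + 0.5 * timestep * F / spec.mass
            X = X + 0.5 * timestep * V
            V = c1 * V + c2 * rng.standard_normal(V.shape)
            X = X + 0.5 * timestep * V
            F = force(X)
            V = V + 0.5 * timestep * F / spec.mass
            if step >= discard and (step - discard) % stride == 0:
                samples[k_out] = X[0, list(dims)]
                k_out += 1
        windows.append(
            UmbrellaWindow(
                coordinate=coordinate, center=c, force_constant=kvec,
                samples=samples[:k_out],
            )
        )
    _check_overlap(windows)
    return windows


def _check_overlap(windows: list[UmbrellaWindow]) -> None:
    if len(windows) < 2 or windows[0].samples.shape[1] != 1:
        return
    order = np.argsort([w.center[0] for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        sa = windows[a].samples[:, 0]
        sb = windows[b].samples[:, 0]
        lo, hi = max(sa.min(), sb.min()), min(sa.max(), sb.max())
        if hi <= lo:
            raise ValueError(
                f"zero histogram overlap between windows at "
                f"{windows[a].center[0]:.4g} and {windows[b].center[0]:.4g}; "
                "use tighter window spacing"
            )
        frac = min(np.mean((sa >= lo) & (sa <= hi)),
                   np.mean((sb >= lo) & (sb <= hi)))
        if frac < 0.01:
            warnings.warn(
                f"adjacent windows at {windows[a].center[0]:.4g} and "
                f"{windows[b].center[0]:.4g} overlap by less than 1%",
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# WHAM
# ---------------------------------------------------------------------------

def wham(
    windows: list[UmbrellaWindow],
    n_bins: int = 100,
    tolerance: float = defaults.WHAM_TOL,
    temperature: float = 1.0,
    max_iter: int = defaults.WHAM_MAX_ITER,
    bin_edges: list[np.ndarray] | None = None,
) -> FreeEnergyProfile:
    """Self-consistent WHAM reconstruction of the unbiased profile.

    Iterates until the largest change in the window free-energy offsets
    drops below ``tolerance``; raises (reporting the residual) when the
    iteration cap is reached first.
    """
    if len(windows) < 2:
        raise ValueError("wham needs at least 2 windows")
    d = windows[0].samples.shape[1]
    all_s = np.vstack([w.samples for w in windows])
    edges = bin_edges or [
        np.linspace(all_s[:, j].min(), all_s[:, j].max(), n_bins + 1)
        for j in range(d)
    ]
    centers = [0.5 * (e[:-1] + e[1:]) for e in edges]
    counts = np.histogramdd(all_s, bins=edges)[0].ravel()
    if d == 1:
        mesh = [centers[0]]
    else:
        mesh = [m.ravel() for m in np.meshgrid(*centers, indexing="ij")]
    n_win = len(windows)
    n_pts = np.array([w.samples.shape[0] for w in windows], dtype=float)
    # bias energy of every window at every bin center
    B = np.zeros((n_win, counts.size))
    for i, w in enumerate(windows):
        for j in range(d):
            B[i] += 0.5 * w.force_constant[j] * (mesh[j] - w.center[j]) ** 2
    expB = np.exp(-B / temperature)
    f = np.zeros(n_win)
    for it in range(max_iter):
        denom = (n_pts * np.exp(f / temperature)) @ expB
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(denom > 0, counts / denom, 0.0)
        z = expB @ P
        with np.errstate(divide="ignore"):
            f_new = -temperature * np.log(z)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)))
        f = f_new
        if resid < tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {resid:.3g})"
        )
    with np.errstate(divide="ignore"):
        F = np.where(P > 0, -temperature * np.log(P), np.inf)
    shape = tuple(len(c) for c in centers)
    return FreeEnergyProfile(
        grid=tuple(centers), F=F.reshape(shape), occupancy=counts.reshape(shape)
    )


def block_analysis(
    windows: list[UmbrellaWindow],
    n_blocks: int = defaults.N_BLOCKS,
    n_bins: int = 100,
    temperature: float = 1.0,
) -> tuple[list[FreeEnergyProfile], np.ndarray]:
    """WHAM on contiguous sample blocks; returns per-block profiles and
    the per-bin spread (std across blocks on commonly occupied bins)."""
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    d = windows[0].samples.shape[1]
    all_s = np.vstack([w.samples for w in windows])
    edges = [
        np.linspace(all_s[:, j].min(), all_s[:, j].max(), n_bins + 1)
        for j in range(d)
    ]
    profiles = []
    for b in range(n_blocks):
        block_windows = []
        for w in windows:
            n = w.samples.shape[0]
            lo, hi = (b * n) // n_blocks, ((b + 1) * n) // n_blocks
            if hi <= lo:
                raise ValueError("blocks too short: a window has no samples")
            block_windows.append(
                UmbrellaWindow(
                    coordinate=w.coordinate, center=w.center,
                    force_constant=w.force_constant, samples=w.samples[lo:hi],
                )
            )
        profiles.append(
            wham(block_windows, n_bins=n_bins, temperature=temperature,
                 bin_edges=edges)
        )
    Fs = np.full((n_blocks,) + profiles[0].F.shape, np.nan)
    for b, p in enumerate(profiles):
        occ = p.occupancy > 0
        Fs[b][occ] = p.F[occ]
    # profiles are defined up to a constant: gauge each block on the
    # commonly occupied bins so the spread measures shape, not offset
    common = np.all([p.occupancy > 0 for p in profiles], axis=0)
    if common.any():
        for b in range(n_blocks):
            Fs[b] -= Fs[b][common].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spread = np.nanstd(Fs, axis=0)
    return profiles, spread


def tst_rate(
    profile: FreeEnergyProfile,
    barrier_position: float,
    temperature: float = 1.0,
    effective_mass: float = 1.0,
    reactant_side: str = "left",
) -> float:
    """Transition-state-theory rate upper bound from a 1D profile.

    k_TST = sqrt(k_BT/2 pi m_eff) exp(-F(x*)/k_BT) /
            integral_reactant exp(-F/k_BT) dx.

    The thermal flux prefactor is the Maxwell-Boltzmann average of the
    forward velocity, <v theta(v)> = sqrt(k_BT / 2 pi m).  Warns when the
    requested barrier position is not a local maximum of F.
    """
    if profile.ndim != 1:
        raise ValueError("tst_rate requires a 1D profile")
    x = profile.grid[0]
    if not x[0] < barrier_position < x[-1]:
        raise ValueError("barrier_position must lie inside the profile grid")
    occ = profile.occupancy > 0
    xo, Fo = x[occ], profile.F[occ]
    Fb = float(np.interp(barrier_position, xo, Fo))
    # sanity check with 0.1 k_BT slack so bin noise does not trigger it:
    # at a genuine barrier top F cannot rise nearby
    half = 0.075 * (xo[-1] - xo[0])
    window = Fo[np.abs(xo - barrier_position) <= half]
    if window.size and Fb < float(window.max()) - 0.1:
        warnings.warn(
            "barrier_position is not a local maximum of F",
            stacklevel=2,
        )
    mask = xo < barrier_position if reactant_side == "left" else xo > barrier_position
    if not np.any(mask):
        raise ValueError("no occupied bins on the reactant side")
    pop = float(np.trapezoid(np.exp(-Fo[mask] / temperature), xo[mask]))
    flux = math.sqrt(temperature / (2.0 * math.pi * effective_mass))
    return flux * math.exp(-Fb / temperature) / pop


# ---------------------------------------------------------------------------
# direct-simulation rate (oracle for the TST bound)
# ---------------------------------------------------------------------------

def direct_rate(
    spec: PotentialSpec,
    states: tuple[StateDef, StateDef],
    total_time: float,
    n_replicas: int = 8,
    rng_seed: int = 0,
    timestep: float = defaults.TOY_TIMESTEP,
) -> tuple[float, int]:
    """A->B transition rate from long unbiased Langevin runs.

    Replicas start in the A-side well; the rate is the number of A->B
    commitment events divided by the total time spent since last entering
    A.  Returns (rate, n_events).
    """
    state_A, state_B = states
    rng = np.random.default_rng(rng_seed)
    X = np.zeros((n_replicas, spec.n_dim))
    X[:, 0] = spec.well_separation / 2.0
    if spec.kind == "double_well_bath" and spec.n_bath:
        X[:, 1 : 1 + spec.n_bath] = X[:, :1]
    V = rng.normal(0.0, math.sqrt(spec.temperature / spec.mass), X.shape)
    c1, c2 = _baoab_coeffs(spec, timestep)
    _, F = _energy_forces(spec, X)
    n_steps = int(round(total_time / timestep))
    current = np.zeros(n_replicas, dtype=np.int8)  # 1 in A, 2 in B
    current[:] = 1
    time_in_A = 0.0
    events = 0
    check = 5
    for step in range(0, n_steps, check):
        for _ in range(min(check, n_steps - step)):
            V = V + 0.5 * timestep * F / spec.mass
            X = X + 0.5 * timestep * V
            V = c1 * V + c2 * rng.standard_normal(V.shape)
            X = X + 0.5 * timestep * V
            _, F = _energy_forces(spec, X)
            V = V + 0.5 * timestep * F / spec.mass
        in_A = state_A.contains(X)
        in_B = state_B.contains(X)
        from_A = current == 1
        time_in_A += check * timestep * float(np.sum(from_A))
        events += int(np.sum(from_A & in_B))
        current[in_A] = 1
        current[in_B] = 2
    if time_in_A == 0:
        raise RuntimeError("replicas never resided in state A")
    return events / time_in_A, events
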