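"""Fixture factory binding the toy dynamics to the statistical structure
the analysis assumes.

Two families of reproducible fixtures:

* shooting datasets without dynamics: features from a two-component
  Gaussian mixture (the two "basins"), committor labels
  n_A ~ Binomial(n_trials, p_true(X)) from a named committor law, with
  the generating law stored for oracle tests.  This isolates the
  learning stack from sampling noise; full-dynamics labels are produced
  by :func:`pathcommit.toy_dynamics.generate_shooting_dataset`.
* a deterministic geometric morph from inner-sphere (ion-site contact,
  lambda = pi/2) through a transition arrangement to outer-sphere
  (site replaced by the exchanging water, lambda = 0).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable

import numpy as np

from . import defaults
from .data import ShootingDataset
from .toy_dynamics import SolvationConfig

__all__ = [
    "FixtureSpec",
    "sigmoid_law",
    "fixture_shooting_data",
    "fixture_solvation_series",
]


@dataclasses.dataclass
class FixtureSpec:
    name: str
    params: dict
    seed: int


def sigmoid_law(
    weights: np.ndarray | list[float], scale: float = 3.0
) -> Callable[[np.ndarray], np.ndarray]:
    """Committor law p(X) = sigmoid(scale * w . X) over the first
    len(weights) features."""
    w = np.asarray(weights, dtype=float)

    def law(X: np.ndarray) -> np.ndarray:
        z = scale * (np.atleast_2d(X)[:, : w.size] @ w)
        return 1.0 / (1.0 + np.exp(-z))

    law.__name__ = "sigmoid_law"
    return law


def fixture_shooting_data(
    n_points: int,
    n_features: int,
    committor_law: Callable[[np.ndarray], np.ndarray] | None = None,
    n_trials: int = defaults.N_COMMITTOR_TRIALS,
    seed: int = 0,
    n_informative: int = 1,
    mixture_sep: float = 1.0,
) -> ShootingDataset:
    """Binomially labelled shooting data with a known committor law.

    The first ``n_informative`` features are drawn from a symmetric
    two-component Gaussian mixture (means +/- ``mixture_sep``, unit
    variance component sd); the remaining features are pure standard
    normal noise.  Labels are n_A ~ Binomial(n_trials, p_true) with
    p_true from ``committor_law`` (default: sigmoid(3 x_1)).  The
    generating law values are stored in ``p_true`` and the default
    72/8/20 split is assigned.
    """
    if n_informative > n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_points, n_features))
    comp = rng.integers(0, 2, size=n_points) * 2 - 1
    X[:, :n_informative] += mixture_sep * comp[:, None] * 0.5
    if committor_law is None:
        committor_law = sigmoid_law([1.0] + [0.0] * (n_informative - 1))
    p_true = np.asarray(committor_law(X), dtype=float).reshape(n_points)
    if np.any((p_true < 0) | (p_true > 1)):
        raise ValueError("committor_law must map features into [0, 1]")
    n_A = rng.binomial(n_trials, p_true)
    data = ShootingDataset(
        features=X,
        feature_names=[f"f{i+1}" for i in range(n_features)],
        n_A=n_A,
        n_B=n_trials - n_A,
        n_trials=np.full(n_points, n_trials),
        p_true=p_true,
    )
    data.assign_split(rng_seed=int(rng.integers(2**31)))
    return data


def fixture_solvation_series(
    seed: int = 0, n_frames: int = 9
) -> list[SolvationConfig]:
    """Deterministic inner-to-outer-sphere morph of a coordination shell.

    Frame 0 is the inner-sphere arrangement (site contact at the
    reference distance r_I = 0.18 nm, exchanging water far: lambda =
    pi/2 exactly); the last frame is outer-sphere (exchanging water
    joined the shell so that s6 = 1.18 nm while the site has retreated:
    lambda = 0 exactly); lambda is strictly monotone along the series.
    Five shell waters stay at 0.21 nm throughout, so s6 = 1.05 + r_ex.
    The seed is accepted for interface uniformity; the morph itself is
    deterministic.
    """
    del seed  # deterministic fixture
    base = 0.21
    dirs5 = np.array(
        [[-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=float
    )
    ex_dir = np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)
    o1p_dir = np.array([1.0, 0.0, 0.0])
    t_vals = np.linspace(0.0, 1.0, n_frames)
    r_I = defaults.RI_REF + t_vals * (0.42 - defaults.RI_REF)
    r_ex = (defaults.S6_REF - 5 * base) + (1 - t_vals) * (
        0.42 - (defaults.S6_REF - 5 * base)
    )
    configs = []
    for ri, rex in zip(r_I, r_ex):
        positions = np.vstack(
            [dirs5 * base, ex_dir * rex, o1p_dir * ri]
        )
        roles = ["water_O"] * 6 + ["phosphate_O1P"]
        configs.append(
            SolvationConfig(
                ion_position=np.zeros(3),
                ligand_positions=positions,
                ligand_roles=roles,
            )
        )
    return configs
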