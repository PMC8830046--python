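"""Committor records, transition-state identification and p(p_A) diagnostics.

For each shooting point, ``n_trials`` trajectories (default 100) are
launched with fresh Maxwell-Boltzmann velocities and the committor is the
fraction that relaxes into state A.  A configuration is a transition state
when 0.45 < p_A < 0.55.  The quality of a candidate reaction coordinate is
judged by comparing the distribution p(p_A) on one of its level sets with
the binomial reference expected for the ideal coordinate: for the ideal
coordinate at its 0.5 level set, p_A is Binomial(n_trials, 1/2)/n_trials,
so any broadening beyond that reference signals missing coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import defaults
from .toy_dynamics import PotentialSpec, StateDef, brute_force_committor

__all__ = [
    "CommittorRecord",
    "CommittorDistribution",
    "committor_batch",
    "committor_distribution",
    "binomial_reference",
    "coordinate_quality",
    "total_variation",
]


@dataclasses.dataclass
class CommittorRecord:
    config_id: int
    p_A: float
    n_A: int
    n_B: int
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_A + self.n_B > self.n_trials:
            raise ValueError("n_A + n_B cannot exceed n_trials")

    @property
    def is_transition_state(self) -> bool:
        lo, hi = defaults.TS_WINDOW
        return lo < self.p_A < hi


@dataclasses.dataclass
class CommittorDistribution:
    """Histogram of committor values over a set of shooting points."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_points: int
    n_trials_per_point: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have one entry per bin")

    @property
    def density(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def committor_batch(
    spec: PotentialSpec,
    configs: np.ndarray,
    states: tuple[StateDef, StateDef],
    n_trials: int = defaults.N_COMMITTOR_TRIALS,
    rng_seed: int = 0,
    horizon: float = 50.0,
) -> list[CommittorRecord]:
    """Brute-force committor for each configuration (default 100 trials)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    configs = np.atleast_2d(np.asarray(configs, dtype=float))
    rng = np.random.default_rng(rng_seed)
    records = []
    for i, cfg in enumerate(configs):
        res = brute_force_committor(
            spec, cfg, states, n_trials=n_trials, horizon=horizon, rng_seed=rng
        )
        if not res.resolved:
            raise RuntimeError(
                f"all {n_trials} trials unresolved for configuration {i}; "
                "increase the horizon"
            )
        records.append(
            CommittorRecord(
                config_id=i, p_A=res.p_A, n_A=res.n_A, n_B=res.n_B,
                n_trials=n_trials,
            )
        )
    return records


def _edges(bin_width: float) -> np.ndarray:
    n_bins = int(round(1.0 / bin_width))
    return np.linspace(0.0, 1.0, n_bins + 1)


def committor_distribution(
    records: Sequence[CommittorRecord],
    selector: Callable[[CommittorRecord], bool] | None = None,
    bin_width: float = defaults.HIST_BIN_WIDTH,
) -> CommittorDistribution:
    """Histogram of p_A over the selected records (default: all)."""
    if selector is None:
        selected = list(records)
    else:
        selected = [r for r in records if selector(r)]
    if not selected:
        name = getattr(selector, "__name__", repr(selector))
        raise ValueError(f"selector {name} matched no records")
    p = np.array([r.p_A for r in selected])
    edges = _edges(bin_width)
    # numpy closes the rightmost bin, so p_A = 1 lands in it
    counts, _ = np.histogram(p, bins=edges)
    return CommittorDistribution(
        bin_edges=edges,
        counts=counts,
        n_points=len(selected),
        n_trials_per_point=selected[0].n_trials,
    )


def binomial_reference(
    n_trials: int,
    n_points: int,
    bin_width: float = defaults.HIST_BIN_WIDTH,
) -> CommittorDistribution:
    """Expected p(p_A) for an ideal reaction coordinate at its 0.5 level.

    The committor of each point is k/n_trials with k ~ Binomial(n, 1/2);
    the exact binomial mass is accumulated into the histogram bins and
    scaled to ``n_points``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = np.arange(n_trials + 1)
    pmf = stats.binom.pmf(k, n_trials, 0.5)
    vals = k / n_trials
    edges = _edges(bin_width)
    idx = np.clip(np.searchsorted(edges, vals, side="right") - 1, 0, edges.size - 2)
    counts = np.zeros(edges.size - 1)
    np.add.at(counts, idx, pmf * n_points)
    return CommittorDistribution(
        bin_edges=edges, counts=counts, n_points=n_points,
        n_trials_per_point=n_trials,
    )


def total_variation(
    d1: CommittorDistribution, d2: CommittorDistribution
) -> float:
    """Total-variation distance between two normalized histograms."""
    if not np.allclose(d1.bin_edges, d2.bin_edges):
        raise ValueError("distributions must share bin edges")
    return 0.5 * float(np.abs(d1.density - d2.density).sum())


def coordinate_quality(
    records: Sequence[CommittorRecord],
    coordinate_values: np.ndarray,
    level: float,
    halfwidth: float,
    bin_width: float = defaults.HIST_BIN_WIDTH,
) -> tuple[float, CommittorDistribution, CommittorDistribution]:
    """Divergence between p(p_A) on a coordinate level set and the ideal.

    Selects records whose coordinate value lies within ``level +/-
    halfwidth`` (the half-widths 0.05 for lambda and 0.02 nm for r_I
    follow the standard subset definitions), histograms their p_A, and
    returns the total-variation distance to the binomial reference plus
    both distributions for plotting.
    """
    coordinate_values = np.asarray(coordinate_values, dtype=float)
    if coordinate_values.size != len(records):
        raise ValueError("one coordinate value per record is required")
    mask = np.abs(coordinate_values - level) <= halfwidth
    if not np.any(mask):
        raise ValueError(
            f"empty level set: no record with coordinate within "
            f"{level} +/- {halfwidth}"
        )
    selected = [r for r, m in zip(records, mask) if m]
    observed = committor_distribution(selected, bin_width=bin_width)
    reference = binomial_reference(
        selected[0].n_trials, len(selected), bin_width=bin_width
    )
    return total_variation(observed, reference), observed, reference
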