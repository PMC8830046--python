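"""Permutation feature relevance of a trained committor model.

Single-feature relevance: feature column i is replaced by a random
permutation of itself (preserving the marginal distribution exactly),
the likelihood loss l_i is re-evaluated, and

    r_s^i = (l_i - l_opt) / (l_max - l_opt)

with l_opt the loss of the intact model and l_max the largest
single-permutation loss, so the most informative feature scores exactly 1.

Combined relevance: a greedy forward procedure.  At each step the
remaining feature whose permutation (with all previously chosen
permutations maintained) raises the loss least is permuted next, until
all N features are permuted — N(N+1)/2 permuted-dataset evaluations in
total.  The cumulative relevance is

    r_c(n) = (l(n) - l_opt) / (l_rand - l_opt)

with l_rand the all-permuted loss, so r_c(N) = 1 by construction.  One
fixed permutation per feature is drawn from the run seed and reused
across steps, which keeps the greedy sequence deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data import ShootingDataset
from .net import CommittorModel, nll_loss

__all__ = ["RelevanceReport", "single_relevance", "combined_relevance",
           "relevance_report"]


@dataclasses.dataclass
class RelevanceReport:
    feature_names: list[str]
    r_single: np.ndarray          # normalized single relevance per feature
    single_rank: np.ndarray       # 1 = least relevant (smallest r_s)
    removal_order: list[int]      # combined: feature indices, rank 1 first
    r_combined: np.ndarray        # r_c(n), n = 1..N
    l_opt: float
    l_max: float
    l_rand: float
    n_evaluations: int
    degenerate: bool = False

    def combined_rank(self) -> np.ndarray:
        """Rank in the removal sequence per feature (1 = removed first,
        i.e. least important)."""
        rank = np.empty(len(self.feature_names), dtype=int)
        for pos, feat in enumerate(self.removal_order):
            rank[feat] = pos + 1
        return rank


def _dataset_loss(model: CommittorModel, X: np.ndarray,
                  n_A: np.ndarray, n_B: np.ndarray) -> float:
    return nll_loss(model.predict_p(X), n_A, n_B)


def _permutations(n_points: int, n_features: int,
                  rng: np.random.Generator) -> list[np.ndarray]:
    return [rng.permutation(n_points) for _ in range(n_features)]


def single_relevance(
    model: CommittorModel,
    data: ShootingDataset,
    rng_seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Normalized single-feature relevance r_s for every feature.

    Returns (r_s, info) with info holding the raw permuted losses, l_opt
    and l_max.  A degenerate report (l_max == l_opt: no feature matters)
    is flagged in info rather than raising.
    """
    rng = np.random.default_rng(rng_seed)
    X = data.features
    nA, nB = data.n_A, data.n_B
    perms = _permutations(data.n_points, data.n_features, rng)
    l_opt = _dataset_loss(model, X, nA, nB)
    losses = np.empty(data.n_features)
    for i in range(data.n_features):
        Xp = X.copy()
        Xp[:, i] = X[perms[i], i]
        losses[i] = _dataset_loss(model, Xp, nA, nB)
    l_max = float(losses.max())
    degenerate = not l_max > l_opt
    if degenerate:
        r_s = np.zeros(data.n_features)
    else:
        r_s = (losses - l_opt) / (l_max - l_opt)
    info = {"losses": losses, "l_opt": l_opt, "l_max": l_max,
            "degenerate": degenerate}
    return r_s, info


def combined_relevance(
    model: CommittorModel,
    data: ShootingDataset,
    rng_seed: int = 0,
) -> tuple[list[int], np.ndarray, dict]:
    """Greedy combined-feature relevance.

    Returns (removal_order, r_c, info).  removal_order[0] is the feature
    whose permutation raised the loss least (rank 1, least important);
    r_c[n-1] is the normalized loss after permuting the first n features.
    info counts the permuted-dataset evaluations (exactly N(N+1)/2).
    """
    rng = np.random.default_rng(rng_seed)
    X = data.features
    nA, nB = data.n_A, data.n_B
    N = data.n_features
    perms = _permutations(data.n_points, N, rng)
    l_opt = _dataset_loss(model, X, nA, nB)

    Xcur = X.copy()
    remaining = list(range(N))
    order: list[int] = []
    losses_seq: list[float] = []
    n_eval = 0
    while remaining:
        best_i, best_loss = None, np.inf
        for i in remaining:
            Xtry = Xcur.copy()
            Xtry[:, i] = X[perms[i], i]
            loss = _dataset_loss(model, Xtry, nA, nB)
            n_eval += 1
            if loss < best_loss:
                best_i, best_loss = i, loss
        Xcur[:, best_i] = X[perms[best_i], best_i]
        remaining.remove(best_i)
        order.append(best_i)
        losses_seq.append(best_loss)
    l_rand = losses_seq[-1]
    losses_arr = np.array(losses_seq)
    degenerate = not l_rand > l_opt
    r_c = (
        np.zeros(N) if degenerate else (losses_arr - l_opt) / (l_rand - l_opt)
    )
    info = {"losses": losses_arr, "l_opt": l_opt, "l_rand": l_rand,
            "n_evaluations": n_eval, "degenerate": degenerate}
    return order, r_c, info


def relevance_report(
    model: CommittorModel,
    data: ShootingDataset,
    rng_seed: int = 0,
) -> RelevanceReport:
    """Full single + combined relevance analysis of a trained model."""
    r_s, sinfo = single_relevance(model, data, rng_seed=rng_seed)
    order, r_c, cinfo = combined_relevance(model, data, rng_seed=rng_seed)
    single_rank = np.argsort(np.argsort(r_s)) + 1
    return RelevanceReport(
        feature_names=list(data.feature_names),
        r_single=r_s,
        single_rank=single_rank,
        removal_order=order,
        r_combined=r_c,
        l_opt=sinfo["l_opt"],
        l_max=sinfo["l_max"],
        l_rand=cinfo["l_rand"],
        n_evaluations=cinfo["n_evaluations"],
        degenerate=sinfo["degenerate"] or cinfo["degenerate"],
    )
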