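"""Random-search architecture optimization for the committor network.

Architectures are drawn uniformly from the hyperparameter space (hidden
layers 1-6, neurons 32-256, ReLU/SELU, one dropout layer at one of four
positions with rate 0-40%, Adam learning rate log-uniform in
[1e-4, 1e-2]).  Each sampled spec is trained, candidates are ranked by
validation loss, the best subset is refined with the plateau learning-rate
schedule, and the final model is the one whose predicted transition states
(0.45 < p_pred < 0.55) produce the sharpest peak in the histogram of
their true committor values — the operational definition of "best
reaction coordinate".
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import defaults
from .data import ShootingDataset
from .net import CommittorModel, MLPSpec, refine, train

__all__ = ["SearchTrial", "SearchResult", "sample_spec", "random_search",
           "select_final"]


@dataclasses.dataclass
class SearchTrial:
    trial_id: int
    spec: MLPSpec
    validation_loss: float
    model: CommittorModel | None
    error: str | None = None


@dataclasses.dataclass
class SearchResult:
    trials: list[SearchTrial]
    best_subset: list[int]      # trial ids ordered by validation loss

    def best_models(self) -> list[CommittorModel]:
        by_id = {t.trial_id: t for t in self.trials}
        return [by_id[i].model for i in self.best_subset]


def sample_spec(rng_seed: int | np.random.Generator) -> MLPSpec:
    """Draw one architecture uniformly from the search space."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return MLPSpec(
        n_hidden_layers=int(rng.integers(1, 7)),
        neurons_per_layer=int(rng.integers(32, 257)),
        activation=str(rng.choice(["relu", "selu"])),
        dropout_position=str(
            rng.choice(["none", "after_input", "middle", "before_output"])
        ),
        dropout_rate=float(rng.uniform(0.0, 0.40)),
        learning_rate=float(10.0 ** rng.uniform(-4.0, -2.0)),
    )


def random_search(
    data: ShootingDataset,
    n_trials: int = defaults.DEFAULT_SEARCH_TRIALS,
    rng_seed: int = 0,
    epochs: int = defaults.SEARCH_EPOCHS,
    best_subset_size: int = defaults.BEST_SUBSET_SIZE,
    batch_size: int = defaults.BATCH_SIZE,
) -> SearchResult:
    """Train ``n_trials`` randomly sampled architectures and rank them.

    A failing trial is recorded with its error message and excluded from
    the ranking rather than aborting the search.  Reproducible from the
    seed: the trial sequence and per-trial training seeds derive from it.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    root = np.random.SeedSequence(rng_seed)
    spec_rng = np.random.default_rng(root.spawn(1)[0])
    train_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(n_trials)]
    trials: list[SearchTrial] = []
    for t in range(n_trials):
        spec = sample_spec(spec_rng)
        try:
            model = train(
                spec, data, epochs=epochs, batch_size=batch_size,
                rng_seed=train_seeds[t],
            )
            trials.append(
                SearchTrial(t, spec, model.validation_loss, model)
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            trials.append(SearchTrial(t, spec, np.inf, None, error=str(exc)))
    ok = [t for t in trials if t.model is not None]
    ok.sort(key=lambda t: t.validation_loss)
    best = [t.trial_id for t in ok[:best_subset_size]]
    return SearchResult(trials=trials, best_subset=best)


def _peak_height(model, data: ShootingDataset) -> float | None:
    """Peak of the true-committor histogram over the model's predicted
    transition states; None when no transition state is predicted."""
    p_pred = model.predict_p(data.features)
    lo, hi = defaults.TS_WINDOW
    mask = (p_pred > lo) & (p_pred < hi)
    if not np.any(mask):
        return None
    p_ref = data.p_true if data.p_true is not None else data.p_A
    vals = p_ref[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None
    n_bins = int(round(1.0 / defaults.HIST_BIN_WIDTH))
    counts, _ = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    return float(counts.max() / counts.sum())


def select_final(
    candidates: list[CommittorModel],
    data: ShootingDataset,
) -> CommittorModel:
    """Choose the model with the highest peak in the transition-state
    committor histogram; ties break toward the lower validation loss.

    Candidates that predict no transition state at all are excluded with
    a warning.
    """
    if not candidates:
        raise ValueError("select_final needs at least one candidate")
    scored = []
    for i, model in enumerate(candidates):
        peak = _peak_height(model, data)
        if peak is None:
            warnings.warn(
                f"candidate {i} predicts no transition states; excluded",
                stacklevel=2,
            )
            continue
        val = getattr(model, "validation_loss", np.inf)
        scored.append((peak, -val, i, model))
    if not scored:
        raise ValueError("no candidate predicts any transition state")
    scored.sort(key=lambda s: (s[0], s[1]), reverse=True)
    return scored[0][3]


def tune(
    data: ShootingDataset,
    n_trials: int = defaults.DEFAULT_SEARCH_TRIALS,
    rng_seed: int = 0,
    epochs: int = defaults.SEARCH_EPOCHS,
    refine_epochs: int = defaults.REFINE_EPOCHS,
    best_subset_size: int = defaults.BEST_SUBSET_SIZE,
    batch_size: int = defaults.BATCH_SIZE,
) -> tuple[CommittorModel, SearchResult]:
    """Full protocol: random search, refine the best subset, select final."""
    result = random_search(
        data, n_trials=n_trials, rng_seed=rng_seed, epochs=epochs,
        best_subset_size=best_subset_size, batch_size=batch_size,
    )
    refined = [
        refine(m, data, max_epochs=refine_epochs, batch_size=batch_size,
               rng_seed=rng_seed + 1 + i)
        for i, m in enumerate(result.best_models())
    ]
    try:
        final = select_final(refined, data)
    except ValueError:
        # tiny datasets may yield no predicted transition state at all;
        # fall back to the validation-loss ranking
        warnings.warn(
            "no candidate predicts transition states; falling back to the "
            "lowest validation loss", stacklevel=2,
        )
        final = min(refined, key=lambda m: m.validation_loss)
    return final, result
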