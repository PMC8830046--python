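"""Shooting-point datasets: feature matrices with committor trial counts.

A shooting dataset couples an ``N x F`` feature matrix to, for each row,
the number of committor trial trajectories that relaxed into state A
(``n_A``) and state B (``n_B``) out of ``n_trials`` launched.  Rows carry a
train/validation/test split tag; the default split is 72/8/20.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import defaults

SPLIT_TAGS = ("train", "validation", "test")


@dataclasses.dataclass
class ShootingDataset:
    """Feature matrix plus per-row committor trial counts.

    Attributes
    ----------
    features : (N, F) float array
    feature_names : length-F list of column names
    n_A, n_B : (N,) integer arrays, trials committed to A / B
    n_trials : (N,) integer array, trials launched per point
    split_tags : (N,) array of ``train | validation | test``
    p_true : optional (N,) array with the generating committor law,
        kept when the dataset is synthetic so oracle tests can use it
    """

    features: np.ndarray
    feature_names: list[str]
    n_A: np.ndarray
    n_B: np.ndarray
    n_trials: np.ndarray
    split_tags: np.ndarray | None = None
    p_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2D array")
        n = self.features.shape[0]
        self.n_A = np.asarray(self.n_A, dtype=int)
        self.n_B = np.asarray(self.n_B, dtype=int)
        self.n_trials = np.broadcast_to(
            np.asarray(self.n_trials, dtype=int), (n,)
        ).copy()
        for name, arr in (("n_A", self.n_A), ("n_B", self.n_B)):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per row")
        if np.any(self.n_A + self.n_B > self.n_trials):
            raise ValueError("n_A + n_B exceeds n_trials for some row")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match feature count")
        if self.split_tags is not None:
            self.split_tags = np.asarray(self.split_tags, dtype=object)
            bad = set(self.split_tags) - set(SPLIT_TAGS)
            if bad:
                raise ValueError(f"unknown split tags: {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def p_A(self) -> np.ndarray:
        """Empirical committor n_A/(n_A+n_B); NaN where no trial resolved."""
        resolved = self.n_A + self.n_B
        with np.errstate(invalid="ignore"):
            return np.where(resolved > 0, self.n_A / np.maximum(resolved, 1), np.nan)

    def rows(self, tag: str) -> np.ndarray:
        """Boolean mask of rows carrying the given split tag."""
        if self.split_tags is None:
            raise ValueError("dataset has no split; call assign_split first")
        return self.split_tags == tag

    def assign_split(
        self,
        rng_seed: int,
        fractions: tuple[float, float, float] = (
            defaults.TRAIN_FRACTION,
            defaults.VALIDATION_FRACTION,
            defaults.TEST_FRACTION,
        ),
    ) -> "ShootingDataset":
        """Randomly tag rows train/validation/test (default 72/8/20)."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        rng = np.random.default_rng(rng_seed)
        order = rng.permutation(self.n_points)
        n_train = int(round(fractions[0] * self.n_points))
        n_val = int(round(fractions[1] * self.n_points))
        tags = np.empty(self.n_points, dtype=object)
        tags[order[:n_train]] = "train"
        tags[order[n_train : n_train + n_val]] = "validation"
        tags[order[n_train + n_val :]] = "test"
        self.split_tags = tags
        return self

    def subset(self, mask: np.ndarray) -> "ShootingDataset":
        return ShootingDataset(
            features=self.features[mask],
            feature_names=list(self.feature_names),
            n_A=self.n_A[mask],
            n_B=self.n_B[mask],
            n_trials=self.n_trials[mask],
            split_tags=None if self.split_tags is None else self.split_tags[mask],
            p_true=None if self.p_true is None else self.p_true[mask],
        )

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["n_A"] = self.n_A
        df["n_B"] = self.n_B
        df["n_trials"] = self.n_trials
        if self.split_tags is not None:
            df["split"] = self.split_tags
        if self.p_true is not None:
            df["p_true"] = self.p_true
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ShootingDataset":
        meta = {"n_A", "n_B", "n_trials", "split", "p_true"}
        names = [c for c in df.columns if c not in meta]
        return cls(
            features=df[names].to_numpy(dtype=float),
            feature_names=names,
            n_A=df["n_A"].to_numpy(),
            n_B=df["n_B"].to_numpy(),
            n_trials=df["n_trials"].to_numpy(),
            split_tags=df["split"].to_numpy() if "split" in df else None,
            p_true=df["p_true"].to_numpy() if "p_true" in df else None,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShootingDataset":
        return cls.from_frame(pd.read_csv(path))
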