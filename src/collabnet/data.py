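"""Tabular dataset container and delimited-text I/O.

A :class:`LabeledDataset` is a feature matrix plus an outcome vector, with
two optional extras used by the synthetic benchmarks: the true conditional
medians (reference for MAE) and a handle to the closed-form ground-truth
oracle of the generating process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "train_test_split"]

OUTCOME_COLUMN = "y"
TRUE_MEDIAN_COLUMN = "true_median"


@dataclass
class LabeledDataset:
    features: np.ndarray
    outcomes: np.ndarray
    true_median: Optional[np.ndarray] = None
    oracle: Optional[object] = None
    feature_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.outcomes = np.asarray(self.outcomes, dtype=float).ravel()
        n = self.features.shape[0]
        if n < 2 or self.features.shape[1] < 1:
            raise ValueError("need at least 2 samples and 1 feature")
        if self.outcomes.shape[0] != n:
            raise ValueError("features and outcomes disagree on n")
        if not (np.isfinite(self.features).all() and np.isfinite(self.outcomes).all()):
            raise ValueError("features and outcomes must be finite")
        if self.true_median is not None:
            self.true_median = np.asarray(self.true_median, dtype=float).ravel()
            if self.true_median.shape[0] != n:
                raise ValueError("true_median length mismatch")
        if self.feature_names is None:
            self.feature_names = [f"x{j}" for j in range(self.features.shape[1])]
        elif len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            features=self.features[idx],
            outcomes=self.outcomes[idx],
            true_median=None if self.true_median is None else self.true_median[idx],
            oracle=self.oracle,
            feature_names=list(self.feature_names),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[OUTCOME_COLUMN] = self.outcomes
        if self.true_median is not None:
            df[TRUE_MEDIAN_COLUMN] = self.true_median
        return df

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, outcome_column: str = OUTCOME_COLUMN
    ) -> "LabeledDataset":
        if outcome_column not in df.columns:
            raise ValueError(f"missing outcome column {outcome_column!r}")
        aux = [outcome_column]
        true_median = None
        if TRUE_MEDIAN_COLUMN in df.columns:
            true_median = df[TRUE_MEDIAN_COLUMN].to_numpy(dtype=float)
            aux.append(TRUE_MEDIAN_COLUMN)
        feat_cols = [c for c in df.columns if c not in aux]
        return cls(
            features=df[feat_cols].to_numpy(dtype=float),
            outcomes=df[outcome_column].to_numpy(dtype=float),
            true_median=true_median,
            feature_names=feat_cols,
        )

    @classmethod
    def from_csv(cls, path: str, outcome_column: str = OUTCOME_COLUMN) -> "LabeledDataset":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_frame(pd.read_csv(path, sep=sep), outcome_column)


def train_test_split(
    dataset: LabeledDataset,
    rng: np.random.Generator,
    test_fraction: float = 0.3,
) -> Tuple[LabeledDataset, LabeledDataset]:
    """Random split (default 7:3) of a dataset into train and test parts."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0,1)")
    perm = rng.permutation(dataset.n)
    n_test = int(round(dataset.n * test_fraction))
    n_test = min(max(n_test, 1), dataset.n - 1)
    return dataset.subset(perm[n_test:]), dataset.subset(perm[:n_test])
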