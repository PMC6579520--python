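"""Shared lightweight containers used across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class FeatureTrajectory:
    """Per-frame feature vectors for one trajectory.

    Attributes
    ----------
    features : (n_frames, n_features) float array
    group_id : seed-group label (trajectories started from the same seed
        conformation share a group; the grouping unit for cross-validation).
    column_labels : optional list naming each feature column.
    """

    features: np.ndarray
    group_id: int = 0
    column_labels: list | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim == 1:
            self.features = self.features[:, None]

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class TrajectorySet:
    """A set of feature trajectories with seed-group labels and, for synthetic
    data, the generating ground-truth label sequences."""

    trajectories: list
    group_ids: np.ndarray = None
    true_macro_paths: list | None = None
    true_micro_paths: list | None = None

    def __post_init__(self) -> None:
        if self.group_ids is None:
            self.group_ids = np.array([t.group_id for t in self.trajectories])
        self.group_ids = np.asarray(self.group_ids)
        if len(self.group_ids) != len(self.trajectories):
            raise ValueError("group_ids must label every trajectory")
        for paths in (self.true_macro_paths, self.true_micro_paths):
            if paths is not None:
                for p, t in zip(paths, self.trajectories):
                    if len(p) != len(t):
                        raise ValueError(
                            "ground-truth label sequence length does not match trajectory"
                        )

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def features(self) -> list:
        return [t.features for t in self.trajectories]


@dataclass
class DiscreteTrajectorySet:
    """Integer state sequences with group labels.

    states must lie in ``[0, n_states)``; ``frame_time`` is the physical time
    per frame (seconds by convention; 1.0 for unitless synthetic data).
    """

    dtrajs: list
    n_states: int
    frame_time: float = 1.0
    group_ids: np.ndarray = None
    centers: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dtrajs = [np.asarray(d, dtype=np.int64).ravel() for d in self.dtrajs]
        for d in self.dtrajs:
            if len(d) < 1:
                raise ValueError("empty discrete trajectory")
            if d.min() < 0 or d.max() >= self.n_states:
                raise ValueError("state labels out of [0, n_states)")
        if self.group_ids is None:
            self.group_ids = np.zeros(len(self.dtrajs), dtype=int)
        self.group_ids = np.asarray(self.group_ids)

    def __len__(self) -> int:
        return len(self.dtrajs)
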