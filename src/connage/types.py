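"""Shared domain types: subjects, BOLD node time series, motion traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, InvalidConfigError

OLDER = "older"
YOUNGER = "younger"


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic / covariate row for one subject."""

    subject_id: str
    group: str  # "older" | "younger"
    age: float  # years
    gender: str  # "F" | "M"
    education_years: float
    gmv: float  # whole-brain gray-matter volume, arbitrary units

    def __post_init__(self):
        if self.group not in (OLDER, YOUNGER):
            raise InvalidConfigError(f"unknown group {self.group!r}")
        if self.gender not in ("F", "M"):
            raise InvalidConfigError(f"unknown gender {self.gender!r}")
        if not self.gmv > 0:
            raise InvalidConfigError("gmv must be positive")


@dataclass
class BoldTimeSeries:
    """T x N matrix of node signals with repetition time and node labels."""

    values: np.ndarray
    tr: float  # seconds
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidConfigError("time series must be a 2-D T x N matrix")
        if self.values.shape[0] < 8:
            raise InsufficientDataError(
                f"need at least 8 time points, got {self.values.shape[0]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("time series contains non-finite values")
        if not self.tr > 0:
            raise InvalidConfigError("tr must be positive")
        if not self.node_labels:
            self.node_labels = [f"node{i}" for i in range(self.values.shape[1])]
        if len(self.node_labels) != self.values.shape[1]:
            raise InvalidConfigError("node_labels length must match N")
        if len(set(self.node_labels)) != len(self.node_labels):
            raise InvalidConfigError("node labels must be unique")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    def index_of(self, label: str) -> int:
        return self.node_labels.index(label)


@dataclass
class MotionTrace:
    """M x 6 rigid-body parameters: 3 translations (mm), 3 rotations (deg)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise InvalidConfigError("motion trace must be M x 6")
        if self.values.shape[0] < 2:
            raise InsufficientDataError("motion trace needs at least 2 rows")
        if not np.all(np.isfinite(self.values)):
            raise InvalidConfigError("motion trace contains non-finite values")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def translations(self) -> np.ndarray:
        return self.values[:, :3]

    @property
    def rotations(self) -> np.ndarray:
        return self.values[:, 3:]
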