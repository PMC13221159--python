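"""Feature-block container shared by every pipeline stage.

A :class:`FeatureBlock` is a participant x feature matrix with feature
names, participant ids and a block tag (``linguistic``, ``acoustic`` or
``fused``).  All stages of the pipeline consume and produce these blocks,
so alignment by participant id is checked once here rather than ad hoc
at every stage boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureBlock", "BlockSet"]

_VALID_TAGS = ("linguistic", "acoustic", "fused")


@dataclass
class FeatureBlock:
    """Participant x feature real matrix with names and a block tag.

    Parameters
    ----------
    values
        2-D array of shape ``(n_participants, n_features)``.  Values must
        be finite.
    feature_names
        Unique feature names, one per column.
    participant_ids
        Participant identifiers, one per row, aligned with ``values``.
    block_tag
        One of ``linguistic``, ``acoustic`` or ``fused``.
    """

    values: np.ndarray
    feature_names: list[str]
    participant_ids: list[str]
    block_tag: str = "linguistic"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.feature_names = [str(n) for n in self.feature_names]
        self.participant_ids = [str(i) for i in self.participant_ids]
        if self.block_tag not in _VALID_TAGS:
            raise ValueError(f"block_tag must be one of {_VALID_TAGS}, got {self.block_tag!r}")
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(f"{len(self.feature_names)} feature names for {p} columns")
        if len(self.participant_ids) != n:
            raise ValueError(f"{len(self.participant_ids)} participant ids for {n} rows")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if len(set(self.participant_ids)) != n:
            raise ValueError("participant ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    # ------------------------------------------------------------------
    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def take_rows(self, indices: Sequence[int]) -> "FeatureBlock":
        """Row subset (e.g. a CV fold), preserving id alignment."""
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            values=self.values[idx],
            participant_ids=[self.participant_ids[i] for i in idx],
            feature_names=list(self.feature_names),
        )

    def aligned_with(self, other: "FeatureBlock") -> bool:
        return self.participant_ids == other.participant_ids

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "id", self.participant_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, block_tag: str) -> "FeatureBlock":
        if "id" not in frame.columns:
            raise ValueError("frame must contain an 'id' column")
        ids = frame["id"].astype(str).tolist()
        data = frame.drop(columns=["id"])
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric feature cells: {exc}") from exc
        return cls(values, list(data.columns), ids, block_tag)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, block_tag: str) -> "FeatureBlock":
        return cls.from_frame(pd.read_csv(path), block_tag)


@dataclass
class BlockSet:
    """A paired linguistic + acoustic view of one cohort.

    The evaluation stage needs access to the raw blocks (not a pre-fused
    matrix) because PCA, orthogonalization and standardization must be
    refit inside every training fold.
    """

    linguistic: FeatureBlock
    acoustic: FeatureBlock | None = None

    def __post_init__(self) -> None:
        if self.acoustic is not None and not self.linguistic.aligned_with(self.acoustic):
            raise ValueError("linguistic and acoustic blocks are not id-aligned")

    @property
    def n_participants(self) -> int:
        return self.linguistic.n_participants
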