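"""Core in-memory containers: signals, feature vectors and feature tables.

A :class:`SignalRecord` holds one subject's single-channel waveform with its
sampling rate and modality tag.  A :class:`FeatureTable` is a thin wrapper
around a pandas DataFrame keyed by ``subject_id`` with a binary ``label``
column; every per-subject matrix that flows between pipeline stages
(extracted features, fusion products, classifier inputs) uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, InputError, SchemaError

MODALITIES = ("fiber", "audio")


@dataclass
class SignalRecord:
    """Single-channel waveform for one subject.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    modality : {"fiber", "audio"}
        Which sensor produced the waveform.
    rate : float
        Sampling rate in Hz, strictly positive.
    samples : ndarray
        Finite, non-empty 1-D float array.
    """

    subject_id: str
    modality: str
    rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise InputError(f"unknown modality {self.modality!r}")
        if not self.rate > 0:
            raise InputError("sampling rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        # emptiness is tolerated only as the degenerate output of splicing an
        # empty segment set; every consuming operation rejects empty input
        if not np.all(np.isfinite(self.samples)):
            raise InputError("signal contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    def replace(self, samples: np.ndarray) -> "SignalRecord":
        """Return a copy of this record carrying new samples."""
        return SignalRecord(self.subject_id, self.modality, self.rate, samples)


@dataclass
class FeatureVector:
    """Named feature values for one subject."""

    subject_id: str
    names: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.names) != self.values.size:
            raise AlignmentError("names and values lengths differ")
        if len(set(self.names)) != len(self.names):
            raise SchemaError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            raise InputError("feature values contain non-finite entries")


class FeatureTable:
    """Aligned per-subject feature matrix with binary labels.

    Backed by a DataFrame whose index is ``subject_id``; ``label`` is kept
    separately and re-attached on round trips through delimited text.
    """

    def __init__(self, frame: pd.DataFrame, labels: Sequence[int] | None = None):
        frame = frame.copy()
        if "label" in frame.columns:
            if labels is not None:
                raise SchemaError("labels given both in frame and separately")
            labels = frame.pop("label").to_numpy()
        if labels is None:
            raise SchemaError("FeatureTable requires labels")
        labels = np.asarray(labels)
        if labels.shape[0] != frame.shape[0]:
            raise AlignmentError("label count does not match row count")
        if not np.isin(labels, (0, 1)).all():
            raise SchemaError("labels must be binary 0/1")
        self._frame = frame.astype(float)
        self._labels = labels.astype(int)

    # -- accessors ---------------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def labels(self) -> np.ndarray:
        return self._labels

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self._frame.index]

    @property
    def feature_names(self) -> list[str]:
        return [str(c) for c in self._frame.columns]

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def n_subjects(self) -> int:
        return self._frame.shape[0]

    def __len__(self) -> int:
        return self._frame.shape[0]

    # -- construction ------------------------------------------------------
    @classmethod
    def from_vectors(cls, vectors: Iterable[FeatureVector],
                     labels: Sequence[int]) -> "FeatureTable":
        vectors = list(vectors)
        if not vectors:
            raise InputError("no feature vectors supplied")
        names = vectors[0].names
        for v in vectors:
            if v.names != names:
                raise SchemaError(f"feature names differ for {v.subject_id}")
        frame = pd.DataFrame(
            np.vstack([v.values for v in vectors]),
            index=[v.subject_id for v in vectors],
            columns=list(names),
        )
        return cls(frame, labels)

    # -- manipulation ------------------------------------------------------
    def select(self, names: Sequence[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self._frame.columns]
        if missing:
            raise SchemaError(f"unknown feature columns: {missing}")
        return FeatureTable(self._frame[list(names)], self._labels)

    def subset_rows(self, index: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(index, dtype=int)
        return FeatureTable(self._frame.iloc[idx], self._labels[idx])

    def with_values(self, values: np.ndarray, names: Sequence[str]) -> "FeatureTable":
        frame = pd.DataFrame(values, index=self._frame.index, columns=list(names))
        return FeatureTable(frame, self._labels)

    def to_frame(self) -> pd.DataFrame:
        out = self._frame.copy()
        out["label"] = self._labels
        return out

    def align_check(self, other: "FeatureTable") -> None:
        if self.subject_ids != other.subject_ids:
            raise AlignmentError("subject ids are not aligned between tables")
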