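"""Word-by-word Pearson correlations over binary response profiles.

Each word's response profile is the 0/1 vector of which subjects produced
it.  The Pearson correlation of two binary profiles is the phi coefficient
of their 2x2 contingency table; the resulting symmetric matrix is the
weighted adjacency that the PMFG filter consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .fluency_data import ResponseMatrix

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "InsufficientDataError", "word_correlations"]


class InsufficientDataError(ValueError):
    """Raised when there are too few subjects to estimate correlations."""


@dataclass
class CorrelationMatrix:
    """Symmetric word x word correlation matrix with vocabulary labels.

    ``excluded_words`` lists zero-variance words (produced by every subject
    or by none after restriction) that were removed before estimation: their
    correlation is undefined.
    """

    vocabulary: list[str]
    values: np.ndarray
    excluded_words: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.vocabulary)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match vocabulary size {n}"
            )
        if len(set(self.vocabulary)) != n:
            raise ValueError("vocabulary labels must be unique")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("correlation matrix must be symmetric")

    @property
    def n_words(self) -> int:
        return len(self.vocabulary)

    def restrict(self, vocab: Sequence[str]) -> "CorrelationMatrix":
        """Submatrix on ``vocab`` (order preserved as given)."""
        index = {w: i for i, w in enumerate(self.vocabulary)}
        unknown = [w for w in vocab if w not in index]
        if unknown:
            raise KeyError(f"words not in correlation vocabulary: {unknown[:5]}")
        idx = np.array([index[w] for w in vocab], dtype=int)
        return CorrelationMatrix(
            vocabulary=list(vocab), values=self.values[np.ix_(idx, idx)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.vocabulary, columns=self.vocabulary)

    def to_csv(self, path: str | Path) -> None:
        """Labelled CSV at full floating precision (exact round-trip)."""
        self.to_dataframe().to_csv(path, index_label="word", float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationMatrix":
        frame = pd.read_csv(path, index_col="word", float_precision="round_trip")
        frame.index = frame.index.astype(str)
        return cls(vocabulary=list(frame.columns), values=frame.to_numpy(dtype=float))


def word_correlations(m: ResponseMatrix) -> CorrelationMatrix:
    """Pearson (phi) correlation matrix of the word response profiles.

    Zero-variance columns cannot be correlated and are excluded with a
    warning; they are reported in ``excluded_words`` rather than silently
    kept.  Requires at least two subjects.
    """
    if m.shape[0] < 2:
        raise InsufficientDataError(
            f"need at least 2 subjects to correlate profiles, got {m.shape[0]}"
        )
    cells = m.data.to_numpy(dtype=float)
    variances = cells.var(axis=0)
    keep = variances > 0
    excluded = [w for w, k in zip(m.vocabulary, keep) if not k]
    if excluded:
        logger.warning(
            "excluding %d zero-variance word(s) from group %r: %s",
            len(excluded),
            m.group_label,
            excluded[:10],
        )
    vocab = [w for w, k in zip(m.vocabulary, keep) if k]
    if len(vocab) < 2:
        raise InsufficientDataError(
            "fewer than 2 words with variable response profiles"
        )
    values = np.corrcoef(cells[:, keep], rowvar=False)
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(vocabulary=vocab, values=values, excluded_words=excluded)
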