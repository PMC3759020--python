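"""Loading, normalisation and matricisation of verbal-fluency responses.

A category fluency task yields, per subject, an ordered list of word tokens
(e.g. animal names produced in 60 seconds).  This module turns those lists
into the binary subjects x words incidence matrices that the correlation
stage consumes, and selects the word-matched vocabulary used to compare two
groups on a common footing.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FluencyDataset",
    "ResponseMatrix",
    "FluencyFormatError",
    "EmptyInputError",
    "EmptyVocabularyError",
    "load_fluency",
    "write_fluency",
    "build_response_matrix",
    "select_wmcn_vocabulary",
    "restrict",
    "normalize_token",
]


class FluencyFormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


class EmptyInputError(ValueError):
    """Raised when an input file contains no responses."""


class EmptyVocabularyError(ValueError):
    """Raised when a vocabulary selection step yields no words."""


def normalize_token(token: str) -> str:
    """Normalise a raw response token: strip surrounding whitespace, case-fold.

    No stemming or synonym merging is applied; spelling variants can be
    collapsed by passing a ``variant_map`` to :func:`load_fluency`.
    """
    return token.strip().casefold()


@dataclass
class FluencyDataset:
    """Group-labelled collection of per-subject ordered response lists.

    ``subjects`` preserves response order within each subject; subjects with
    no valid responses are dropped at load time with a logged warning.
    """

    group_label: str
    subjects: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"duplicate subject ids in group {self.group_label!r}"
            )
        for sid, responses in self.subjects:
            if not responses:
                raise ValueError(
                    f"subject {sid!r} in group {self.group_label!r} has no responses"
                )

    @property
    def subject_ids(self) -> list[str]:
        return [sid for sid, _ in self.subjects]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def vocabulary(self) -> list[str]:
        """Union of all tokens produced by the group, sorted lexicographically."""
        return sorted({w for _, responses in self.subjects for w in responses})


@dataclass
class ResponseMatrix:
    """Binary subjects x vocabulary incidence matrix for one group.

    ``data`` has subject ids as the index, the (lexicographically sorted)
    vocabulary as columns, and 0/1 cells: 1 iff the subject produced the word
    at least once.  Repetitions collapse to 1 (binary coding).
    """

    group_label: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("response matrix cells must be 0 or 1")
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValueError("vocabulary labels must be unique")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def vocabulary(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def word_counts(self) -> pd.Series:
        """Number of subjects that produced each word (column sums)."""
        return self.data.sum(axis=0)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="subject")

    @classmethod
    def from_csv(cls, path: str | Path, group_label: str) -> "ResponseMatrix":
        frame = pd.read_csv(path, index_col="subject").astype(np.int8)
        frame.index = frame.index.astype(str)
        return cls(group_label=group_label, data=frame)


_REQUIRED_COLUMNS = ("group", "subject", "order", "word")


def _rows_to_datasets(
    rows: Iterable[tuple[str, str, int, str]],
    variant_map: Mapping[str, str] | None,
) -> dict[str, FluencyDataset]:
    variant_map = {normalize_token(k): normalize_token(v) for k, v in (variant_map or {}).items()}
    per_group: dict[str, dict[str, list[tuple[int, str]]]] = {}
    for group, subject, order, word in rows:
        token = normalize_token(word)
        token = variant_map.get(token, token)
        if not token:
            continue
        per_group.setdefault(str(group), {}).setdefault(str(subject), []).append(
            (int(order), token)
        )
    datasets: dict[str, FluencyDataset] = {}
    for group in sorted(per_group):
        subjects: list[tuple[str, list[str]]] = []
        for subject in sorted(per_group[group]):
            ordered = [w for _, w in sorted(per_group[group][subject], key=lambda t: t[0])]
            if not ordered:
                logger.warning(
                    "dropping subject %r in group %r: no valid responses", subject, group
                )
                continue
            subjects.append((subject, ordered))
        datasets[group] = FluencyDataset(group_label=group, subjects=subjects)
    return datasets


def load_fluency(
    path: str | Path,
    format: str | None = None,
    variant_map: Mapping[str, str] | None = None,
) -> dict[str, FluencyDataset]:
    """Load long-format fluency responses; returns one dataset per group label.

    CSV layout: columns ``group, subject, order, word`` (UTF-8).  JSON layout:
    a mapping ``{group: {subject: [word, ...]}}`` with responses in production
    order.  Tokens are normalised (trim + case-fold) and an optional
    ``variant_map`` merges spelling variants after normalisation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise EmptyInputError(f"{path} is empty")
            missing = [c for c in _REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise FluencyFormatError(
                    f"{path} is missing required columns: {missing}"
                )
            rows = [
                (r["group"], r["subject"], int(r["order"]), r["word"]) for r in reader
            ]
    elif fmt == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if not isinstance(payload, dict):
            raise FluencyFormatError(f"{path}: JSON root must be a group mapping")
        rows = [
            (group, subject, order, word)
            for group, subjects in payload.items()
            for subject, words in subjects.items()
            for order, word in enumerate(words, start=1)
        ]
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if not rows:
        raise EmptyInputError(f"{path} contains no responses")
    return _rows_to_datasets(rows, variant_map)


def write_fluency(
    datasets: Mapping[str, FluencyDataset] | Sequence[FluencyDataset],
    path: str | Path,
    format: str | None = None,
) -> None:
    """Write datasets in the long CSV / JSON layout read by :func:`load_fluency`."""
    if isinstance(datasets, Mapping):
        items = [datasets[k] for k in sorted(datasets)]
    else:
        items = sorted(datasets, key=lambda d: d.group_label)
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(_REQUIRED_COLUMNS)
            for ds in items:
                for sid, responses in ds.subjects:
                    for order, word in enumerate(responses, start=1):
                        writer.writerow([ds.group_label, sid, order, word])
    elif fmt == "json":
        payload = {
            ds.group_label: {sid: responses for sid, responses in ds.subjects}
            for ds in items
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, ensure_ascii=False, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def build_response_matrix(ds: FluencyDataset) -> ResponseMatrix:
    """Binary incidence matrix over the group's full vocabulary.

    The vocabulary is the union of all tokens in the dataset, sorted
    lexicographically; cell (i, j) is 1 iff subject i produced word j at
    least once.  Production order does not affect the result.
    """
    if not ds.subjects:
        raise EmptyInputError(f"group {ds.group_label!r} has no subjects")
    vocab = ds.vocabulary()
    col = {w: j for j, w in enumerate(vocab)}
    cells = np.zeros((ds.n_subjects, len(vocab)), dtype=np.int8)
    for i, (_, responses) in enumerate(ds.subjects):
        for w in responses:
            cells[i, col[w]] = 1
    frame = pd.DataFrame(cells, index=ds.subject_ids, columns=vocab)
    return ResponseMatrix(group_label=ds.group_label, data=frame)


def select_wmcn_vocabulary(
    a: ResponseMatrix, b: ResponseMatrix, min_subjects: int = 2
) -> list[str]:
    """Common vocabulary for a word-matched network (WMCN).

    Returns the words produced by at least ``min_subjects`` subjects in BOTH
    groups, sorted lexicographically.  Symmetric in its two arguments.
    """
    counts_a = a.word_counts()
    counts_b = b.word_counts()
    common = [
        w
        for w in sorted(set(a.vocabulary) & set(b.vocabulary))
        if counts_a[w] >= min_subjects and counts_b[w] >= min_subjects
    ]
    if not common:
        raise EmptyVocabularyError(
            "no words reach the per-group threshold "
            f"(min_subjects={min_subjects}) in both groups"
        )
    return common


def restrict(m: ResponseMatrix, vocab: Sequence[str]) -> ResponseMatrix:
    """Column-subset of a response matrix; subject rows unchanged."""
    unknown = [w for w in vocab if w not in set(m.vocabulary)]
    if unknown:
        raise KeyError(f"words not in matrix vocabulary: {unknown[:5]}")
    return ResponseMatrix(group_label=m.group_label, data=m.data.loc[:, list(vocab)])
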