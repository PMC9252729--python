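"""Core data containers shared by every descriptor module.

Three objects travel through the whole pipeline:

* :class:`SequenceRecord` — one named protein/DNA/RNA sequence with an
  optional class label.
* :class:`SequenceSet` — an ordered collection of records of one molecule
  kind, with alphabet validation.
* :class:`FeatureMatrix` — the universal samples x features exchange table
  between extraction, analysis and plotting, backed by a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"
RNA_ALPHABET = "ACGU"

#: ambiguity characters tolerated (and dropped) under the permissive policy
AMBIGUOUS = {
    "protein": set("XBZUJO"),
    "dna": set("NRYSWKMBDHV"),
    "rna": set("NRYSWKMBDHV"),
}

ALPHABETS = {
    "protein": PROTEIN_ALPHABET,
    "dna": DNA_ALPHABET,
    "rna": RNA_ALPHABET,
}


def alphabet_for(kind: str) -> str:
    try:
        return ALPHABETS[kind]
    except KeyError:
        raise ValueError(f"unknown molecule kind {kind!r}") from None


@dataclass(frozen=True)
class SequenceRecord:
    """One named biological sequence.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within a :class:`SequenceSet`.
    kind:
        One of ``protein``, ``dna``, ``rna``.
    residues:
        Upper-case sequence over the canonical alphabet of *kind*.
    label:
        Optional category string (e.g. ``"1"`` / ``"0"`` for a binary
        training set).
    """

    id: str
    kind: str
    residues: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.kind not in ALPHABETS:
            raise ValueError(f"unknown molecule kind {self.kind!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


class SequenceSet:
    """Ordered, id-unique collection of :class:`SequenceRecord`.

    Characters outside the canonical alphabet raise by default; with
    ``permissive=True`` known ambiguity codes are removed instead (so
    composition denominators only count canonical residues).
    """

    def __init__(
        self,
        records: Iterable[SequenceRecord],
        kind: str,
        permissive: bool = False,
    ) -> None:
        alphabet_for(kind)
        self.kind = kind
        self.records: list[SequenceRecord] = []
        seen: set[str] = set()
        allowed = set(ALPHABETS[kind])
        ambiguous = AMBIGUOUS[kind]
        for rec in records:
            if rec.kind != kind:
                raise ValueError(
                    f"record {rec.id!r} has kind {rec.kind!r}, expected {kind!r}"
                )
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            residues = rec.residues
            bad = [
                (i, c) for i, c in enumerate(residues) if c not in allowed
            ]
            if bad:
                if permissive and all(c in ambiguous for _, c in bad):
                    residues = "".join(c for c in residues if c in allowed)
                    if not residues:
                        raise ValueError(
                            f"sequence {rec.id!r} contains no canonical residues"
                        )
                    rec = SequenceRecord(rec.id, kind, residues, rec.label)
                else:
                    i, c = bad[0]
                    raise ValueError(
                        f"sequence {rec.id!r}: character {c!r} at position "
                        f"{i + 1} is outside the {kind} alphabet"
                    )
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str] | None:
        labs = [r.label for r in self.records]
        if all(l is None for l in labs):
            return None
        return [l if l is not None else "" for l in labs]

    def equal_length(self) -> bool:
        lengths = {len(r) for r in self.records}
        return len(lengths) <= 1

    def min_length(self) -> int:
        return min(len(r) for r in self.records)


class FeatureMatrix:
    """Samples x named-features table with optional per-sample labels.

    Thin wrapper over a dense ``pandas.DataFrame`` that enforces unique,
    ordered sample ids and feature names and (by default) finite values.
    """

    def __init__(
        self,
        values: np.ndarray | pd.DataFrame,
        sample_ids: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
        labels: Sequence[str] | None = None,
        allow_nan: bool = False,
    ) -> None:
        if isinstance(values, pd.DataFrame):
            df = values.astype(float)
            if sample_ids is not None:
                df.index = list(sample_ids)
            if feature_names is not None:
                df.columns = list(feature_names)
        else:
            arr = np.asarray(values, dtype=float)
            if arr.ndim != 2:
                raise ValueError("feature matrix must be 2-D")
            if sample_ids is None:
                sample_ids = [f"s{i}" for i in range(arr.shape[0])]
            if feature_names is None:
                feature_names = [f"f{i}" for i in range(arr.shape[1])]
            df = pd.DataFrame(arr, index=list(sample_ids), columns=list(feature_names))
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate feature name {dup!r}")
        if not allow_nan and df.size and not np.isfinite(df.to_numpy()).all():
            raise ValueError("feature matrix contains non-finite values")
        self.df = df
        self.labels: list[str] | None
        if labels is None:
            self.labels = None
        else:
            labels = list(labels)
            if len(labels) != df.shape[0]:
                raise ValueError("labels length does not match sample count")
            self.labels = [str(l) for l in labels]

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.df.copy(),
            labels=None if self.labels is None else list(self.labels),
            allow_nan=True,
        )

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Same ids/names/labels, new value block."""
        return FeatureMatrix(
            np.asarray(values, dtype=float),
            sample_ids=self.sample_ids,
            feature_names=self.feature_names,
            labels=self.labels,
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n, m = self.shape
        return f"FeatureMatrix({n} samples x {m} features)"


def hstack(matrices: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Column-concatenate matrices sharing the same sample ids."""
    if not matrices:
        raise ValueError("nothing to stack")
    ids = matrices[0].sample_ids
    for m in matrices[1:]:
        if m.sample_ids != ids:
            raise ValueError("sample ids differ between matrices")
    df = pd.concat([m.df for m in matrices], axis=1)
    return FeatureMatrix(df, labels=matrices[0].labels)
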