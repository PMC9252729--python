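"""Readers, writers and the JSON run configuration.

FASTA input follows the ``>id|label`` header dialect (pipe-separated
optional label); feature matrices export to CSV, TSV, SVM-light and
ARFF.  :class:`RunConfig` validates the JSON configuration consumed by
the command-line front end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .records import FeatureMatrix, SequenceRecord, SequenceSet

EXPORT_FORMATS = ["csv", "tsv", "svm_light", "arff"]

SCHEMES = [
    "iProtein", "iDNA", "iRNA", "iStructure", "iLigand", "iAnalysis", "iPlot",
]


def read_fasta(
    path: str,
    kind: str,
    permissive: bool = False,
    transliterate: bool = True,
) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The header up to the first whitespace is the id; a ``|``-separated
    trailing token in the id carries an optional label.  Sequences are
    uppercased; with ``transliterate`` (default) T<->U is converted to
    match the declared kind.  An empty file yields an empty set.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        label: str | None = None
        if "|" in token:
            token, label = token.split("|", 1)
            label = label or None
        seq = str(rec.seq).upper()
        if transliterate:
            if kind == "rna":
                seq = seq.replace("T", "U")
            elif kind == "dna":
                seq = seq.replace("U", "T")
        records.append(SequenceRecord(token, kind, seq, label))
    return SequenceSet(records, kind, permissive=permissive)


def write_fasta(seqs: SequenceSet, path: str) -> None:
    with open(path, "w") as fh:
        for rec in seqs:
            header = rec.id if rec.label is None else f"{rec.id}|{rec.label}"
            fh.write(f">{header}\n{rec.residues}\n")


# --------------------------------------------------------------------------
# feature-matrix export
# --------------------------------------------------------------------------

def write_feature_matrix(
    matrix: FeatureMatrix, path: str, fmt: str = "csv"
) -> None:
    """Write a matrix as CSV, TSV, SVM-light or ARFF.

    SVM-light lines are ``label index:value`` with 1-based feature
    indices and zero values omitted; ARFF places the class attribute
    last and only when labels exist.
    """
    path = str(path)
    if fmt in {"csv", "tsv"}:
        df = matrix.df.copy()
        if matrix.labels is not None:
            df.insert(0, "label", matrix.labels)
        df.index.name = "sample"
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
    elif fmt == "svm_light":
        labels = matrix.labels or ["0"] * matrix.shape[0]
        with open(path, "w") as fh:
            for row, lab in zip(matrix.values, labels):
                pairs = " ".join(
                    f"{j + 1}:{v:g}" for j, v in enumerate(row) if v != 0
                )
                fh.write(f"{lab} {pairs}".rstrip() + "\n")
    elif fmt == "arff":
        relation = Path(path).stem
        with open(path, "w") as fh:
            fh.write(f"@RELATION {relation}\n\n")
            for name in matrix.feature_names:
                safe = name.replace(" ", "_")
                fh.write(f"@ATTRIBUTE {safe} NUMERIC\n")
            if matrix.labels is not None:
                classes = ",".join(sorted(set(matrix.labels)))
                fh.write(f"@ATTRIBUTE class {{{classes}}}\n")
            fh.write("\n@DATA\n")
            for i, row in enumerate(matrix.values):
                cells = [f"{v:g}" for v in row]
                if matrix.labels is not None:
                    cells.append(matrix.labels[i])
                fh.write(",".join(cells) + "\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_feature_matrix(path: str, fmt: str = "csv") -> FeatureMatrix:
    """Read back a CSV/TSV matrix written by :func:`write_feature_matrix`."""
    if fmt not in {"csv", "tsv"}:
        raise ValueError("only csv/tsv matrices can be read back")
    df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
    labels = None
    if "label" in df.columns[:1].tolist():
        labels = [str(v) for v in df["label"]]
        df = df.drop(columns=["label"])
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        labels,
    )


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_ALLOWED_KEYS = {
    "scheme", "input", "train_input", "kind", "descriptors", "parameters",
    "output", "format", "seed", "analysis", "plot", "permissive",
}


@dataclass
class RunConfig:
    """Validated JSON configuration for one CLI run."""

    scheme: str
    input: str | None = None
    train_input: str | None = None
    descriptors: list[str] = field(default_factory=list)
    parameters: dict[str, dict] = field(default_factory=dict)
    output: str = "features.csv"
    format: str = "csv"
    seed: int = 1
    analysis: list[dict] = field(default_factory=list)
    plot: dict | None = None
    permissive: bool = False

    @classmethod
    def from_json(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
        scheme = raw.get("scheme")
        if scheme not in SCHEMES:
            raise ValueError(
                f"scheme must be one of {SCHEMES}, got {scheme!r}"
            )
        fmt = raw.get("format", "csv")
        if fmt not in EXPORT_FORMATS:
            raise ValueError(f"format must be one of {EXPORT_FORMATS}")
        cfg = cls(
            scheme=scheme,
            input=raw.get("input"),
            train_input=raw.get("train_input"),
            descriptors=list(raw.get("descriptors", [])),
            parameters=dict(raw.get("parameters", {})),
            output=raw.get("output", "features.csv"),
            format=fmt,
            seed=int(raw.get("seed", 1)),
            analysis=list(raw.get("analysis", [])),
            plot=raw.get("plot"),
            permissive=bool(raw.get("permissive", False)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        from .registry import registry_list

        kind = {
            "iProtein": "protein", "iDNA": "dna", "iRNA": "rna",
            "iStructure": "structure", "iLigand": "ligand",
        }.get(self.scheme)
        if kind is not None:
            valid = {spec.name for spec in registry_list(kind)}
            for d in self.descriptors:
                if d not in valid:
                    raise ValueError(
                        f"descriptor {d!r} is not valid for scheme {self.scheme}"
                    )
            if not self.descriptors:
                raise ValueError(f"scheme {self.scheme} needs descriptors")
        if self.scheme in {"iAnalysis", "iPlot"} and self.input is None:
            raise ValueError(f"scheme {self.scheme} needs an input matrix")
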