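"""Sequence, label, and per-residue annotation IO.

Annotations follow the UniProt feature-table convention externally: 1-based
inclusive ``(start, end)`` intervals per (protein, type). Internally the
binary expansion is an ordinary 0-based vector; the interval <-> binary
round trip recovers intervals after overlap merging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import PROTEIN_ALPHABET

VALID_RESIDUES = frozenset(PROTEIN_ALPHABET + "X")

ANNOTATION_TYPES = frozenset(
    {"active_site", "binding_site", "transmembrane", "motif", "pattern", "custom"}
)

_FORMAT_VERSION = "1"


@dataclass
class SequenceRecord:
    """One protein: id, residue string, and its class labels."""

    id: str
    residues: str
    labels: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.residues != self.residues.upper():
            warnings.warn(f"record {self.id!r}: lowercase residues uppercased")
            self.residues = self.residues.upper()
        for pos, ch in enumerate(self.residues):
            if ch not in VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: illegal character {ch!r} at position "
                    f"{pos + 1} (1-based)"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AnnotationTrack:
    """Per-residue binary annotation as 1-based inclusive intervals."""

    protein_id: str
    annotation_type: str
    intervals: list[tuple[int, int]]
    length: int

    def __post_init__(self) -> None:
        if self.annotation_type not in ANNOTATION_TYPES:
            raise ValueError(f"unknown annotation type {self.annotation_type!r}")
        if self.length < 1:
            raise ValueError("length must be positive")
        for start, end in self.intervals:
            if not (1 <= start <= end <= self.length):
                raise ValueError(
                    f"{self.protein_id}: interval ({start}, {end}) violates "
                    f"1 <= start <= end <= length={self.length}"
                )

    def to_binary(self) -> np.ndarray:
        """Binary vector of length ``length``; intervals are unioned."""
        vec = np.zeros(self.length, dtype=np.int8)
        for start, end in self.intervals:
            vec[start - 1 : end] = 1  # 1-based inclusive -> 0-based half-open
        return vec

    @classmethod
    def from_binary(
        cls, protein_id: str, annotation_type: str, vector: np.ndarray
    ) -> "AnnotationTrack":
        """Inverse of :meth:`to_binary`; produces merged, sorted intervals."""
        vec = np.asarray(vector).astype(bool)
        if vec.ndim != 1 or vec.size == 0:
            raise ValueError("binary vector must be 1-D and non-empty")
        padded = np.concatenate(([False], vec, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[0::2], edges[1::2]
        intervals = [(int(s) + 1, int(e)) for s, e in zip(starts, ends)]
        return cls(protein_id, annotation_type, intervals, len(vec))


def to_binary(track: AnnotationTrack) -> np.ndarray:
    return track.to_binary()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read sequences; ids are the first whitespace token, must be unique."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.residues), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Annotation / label tables (TSV)
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    sequence_lengths: Mapping[str, int] | None = None,
) -> list[AnnotationTrack]:
    """Read a TSV of (protein_id, type, start, end), 1-based inclusive.

    Intervals are grouped per (protein, type). Lengths are taken from
    ``sequence_lengths`` when given (and validated against it); otherwise
    the per-protein maximum end coordinate is used as the length.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"protein_id", "type", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    tracks: list[AnnotationTrack] = []
    for (pid, ann_type), grp in df.groupby(["protein_id", "type"], sort=False):
        intervals = [(int(s), int(e)) for s, e in zip(grp["start"], grp["end"])]
        for start, end in intervals:
            if end < start:
                raise ValueError(f"{pid}: end {end} < start {start}")
            if start < 1:
                raise ValueError(f"{pid}: start {start} < 1 (coordinates are 1-based)")
        if sequence_lengths is not None:
            if pid not in sequence_lengths:
                raise ValueError(f"annotation for unknown protein {pid!r}")
            length = int(sequence_lengths[pid])
        else:
            length = max(e for _, e in intervals)
        tracks.append(AnnotationTrack(str(pid), str(ann_type), intervals, length))
    return tracks


def write_annotations(tracks: Iterable[AnnotationTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# headig annotation table v{_FORMAT_VERSION}\n")
        fh.write("protein_id\ttype\tstart\tend\n")
        for t in tracks:
            for start, end in t.intervals:
                fh.write(f"{t.protein_id}\t{t.annotation_type}\t{start}\t{end}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a TSV of (protein_id, label); one label per protein."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"protein_id", "label"}.issubset(df.columns):
        raise ValueError("label table must have columns protein_id, label")
    return {str(r.protein_id): str(r.label) for r in df.itertuples()}


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# headig label table v{_FORMAT_VERSION}\n")
        fh.write("protein_id\tlabel\n")
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{lab}\n")


def tracks_by_protein(
    tracks: Sequence[AnnotationTrack], annotation_type: str
) -> dict[str, AnnotationTrack]:
    return {t.protein_id: t for t in tracks if t.annotation_type == annotation_type}
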