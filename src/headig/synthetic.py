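"""Planted-motif synthetic datasets with exact per-residue ground truth.

Each class is defined by a short sequence motif planted exactly once into
an otherwise i.i.d. residue background; the motif span doubles as the
ground-truth annotation track. Because the motif fully determines the
label, a classifier that solves the task must use the motif residues, so
attribution methods can be validated against a known answer — the
desk-scale stand-in for proteins whose UniProt feature lines (transmembrane
regions, active sites, ...) mark the residues a real model should use.

Backgrounds are rejection-sampled so that no class motif occurs by chance,
and after planting, a sequence contains its own class motif exactly once
and no other class's motif at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import (
    AnnotationTrack,
    SequenceRecord,
    write_annotations,
    write_fasta,
    write_labels,
)
from .model import (
    PROTEIN_ALPHABET,
    ToyEncoderConfig,
    TrainResult,
    train_toy_model,
)

# Swiss-Prot-like background frequencies (order = PROTEIN_ALPHABET)
_EMPIRICAL_FREQS = np.array(
    [8.25, 1.38, 5.46, 6.72, 3.86, 7.07, 2.27, 5.91, 5.80, 9.65,
     2.41, 4.06, 4.74, 3.93, 5.53, 6.64, 5.35, 6.86, 1.10, 2.92]
)
_EMPIRICAL_FREQS = _EMPIRICAL_FREQS / _EMPIRICAL_FREQS.sum()

#: Default class motifs; pairwise Hamming distance >= half the length.
DEFAULT_MOTIFS: tuple[str, ...] = (
    "HWYKCE", "DGMPFN", "RQIVST", "ALHECW", "KDNYGM", "PFRVQI",
)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class MotifSpec:
    """Class-defining motifs and how they are planted."""

    motifs: tuple[str, ...] = DEFAULT_MOTIFS[:2]
    insertion: str = "uniform"  # "uniform" | "fixed"
    fixed_position: int = 0     # 0-based, used when insertion == "fixed"
    mutation_rate: float = 0.0  # per motif position

    def __post_init__(self) -> None:
        for m in self.motifs:
            if not (4 <= len(m) <= 10):
                raise ValueError(f"motif {m!r}: length must be in [4, 10]")
            if not set(m) <= set(PROTEIN_ALPHABET):
                raise ValueError(f"motif {m!r}: non-standard residue")
        for i, a in enumerate(self.motifs):
            for b in self.motifs[i + 1 :]:
                if len(a) == len(b) and _hamming(a, b) < len(a) / 2:
                    raise ValueError(
                        f"motifs {a!r} and {b!r} differ in fewer than half "
                        "their positions"
                    )
        if self.insertion not in ("uniform", "fixed"):
            raise ValueError(f"unknown insertion mode {self.insertion!r}")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")


@dataclass(frozen=True)
class DatasetSpec:
    """Size and composition of a generated dataset."""

    n_per_class: int = 100
    length_range: tuple[int, int] = (50, 100)
    background: str = "uniform"  # "uniform" | "empirical"
    n_classes: int = 2
    test_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not (0.0 < self.test_fraction < 1.0):
            raise ValueError("test_fraction must be in (0, 1)")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length range")


@dataclass
class SyntheticDataset:
    records: list[SequenceRecord]
    tracks: list[AnnotationTrack]
    labels: dict[str, int]                  # protein id -> class index
    class_names: list[str]
    train_ids: list[str]
    test_ids: list[str]
    spec: DatasetSpec
    motifs: MotifSpec
    seed: int

    def sequences_of(self, ids: list[str]) -> list[str]:
        by_id = {r.id: r.residues for r in self.records}
        return [by_id[i] for i in ids]

    def labels_of(self, ids: list[str]) -> list[int]:
        return [self.labels[i] for i in ids]

    def track_of(self, protein_id: str) -> AnnotationTrack:
        for t in self.tracks:
            if t.protein_id == protein_id:
                return t
        raise KeyError(protein_id)

    def write(self, outdir: str | Path) -> None:
        """Emit FASTA + annotation TSV + label TSV (deterministic bytes)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, outdir / "sequences.fasta")
        write_annotations(self.tracks, outdir / "annotations.tsv")
        write_labels(
            {pid: self.class_names[c] for pid, c in self.labels.items()},
            outdir / "labels.tsv",
        )
        split = {pid: ("train" if pid in set(self.train_ids) else "test")
                 for pid in self.labels}
        with open(outdir / "split.tsv", "w") as fh:
            fh.write("protein_id\tsplit\n")
            for pid, part in split.items():
                fh.write(f"{pid}\t{part}\n")


def generate(
    spec: DatasetSpec = DatasetSpec(),
    motifs: MotifSpec | None = None,
    seed: int = 0,
    max_retries: int = 1000,
) -> SyntheticDataset:
    """Generate a planted-motif dataset; reproducible from (spec, motifs, seed)."""
    if motifs is None:
        if spec.n_classes > len(DEFAULT_MOTIFS):
            raise ValueError(
                f"no default motifs for {spec.n_classes} classes; pass MotifSpec"
            )
        motifs = MotifSpec(motifs=DEFAULT_MOTIFS[: spec.n_classes])
    if len(motifs.motifs) != spec.n_classes:
        raise ValueError("one motif per class required")
    lo, hi = spec.length_range
    min_len = min(len(m) for m in motifs.motifs)
    if max(len(m) for m in motifs.motifs) >= lo:
        raise ValueError("motif length must be below the minimum sequence length")

    rng = np.random.default_rng(seed)
    alphabet = np.array(list(PROTEIN_ALPHABET))
    probs = None if spec.background == "uniform" else _EMPIRICAL_FREQS
    if spec.background not in ("uniform", "empirical"):
        raise ValueError(f"unknown background {spec.background!r}")

    records: list[SequenceRecord] = []
    tracks: list[AnnotationTrack] = []
    labels: dict[str, int] = {}
    seen_sequences: set[str] = set()
    all_motifs = motifs.motifs

    for c in range(spec.n_classes):
        motif = all_motifs[c]
        for i in range(spec.n_per_class):
            pid = f"C{c}_{i:04d}"
            for attempt in range(max_retries):
                L = int(rng.integers(lo, hi + 1))
                bg = "".join(rng.choice(alphabet, size=L, p=probs))
                if any(m in bg for m in all_motifs):
                    continue
                if motifs.insertion == "uniform":
                    pos = int(rng.integers(0, L - len(motif) + 1))
                else:
                    pos = motifs.fixed_position
                    if pos + len(motif) > L:
                        raise ValueError("fixed position exceeds sequence length")
                planted = motif
                if motifs.mutation_rate > 0:
                    chars = list(motif)
                    for j in range(len(chars)):
                        if rng.random() < motifs.mutation_rate:
                            chars[j] = str(rng.choice(alphabet))
                    planted = "".join(chars)
                seq = bg[:pos] + planted + bg[pos + len(motif):]
                if any(m in seq for m in all_motifs if m != motif):
                    continue
                if motifs.mutation_rate == 0 and seq.count(motif) != 1:
                    continue
                if seq in seen_sequences:
                    continue
                break
            else:
                raise RuntimeError(
                    f"rejection sampling exceeded {max_retries} retries for "
                    f"{pid}; consider longer or more distinctive motifs"
                )
            seen_sequences.add(seq)
            records.append(SequenceRecord(pid, seq))
            tracks.append(
                AnnotationTrack(pid, "motif", [(pos + 1, pos + len(motif))], L)
            )
            labels[pid] = c

    # stratified split with disjoint sequences (uniqueness enforced above)
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in range(spec.n_classes):
        ids = [r.id for r in records if labels[r.id] == c]
        perm = rng.permutation(len(ids))
        n_test = int(round(spec.test_fraction * len(ids)))
        test_ids += [ids[k] for k in perm[:n_test]]
        train_ids += [ids[k] for k in perm[n_test:]]

    class_names = [f"class{c}" for c in range(spec.n_classes)]
    return SyntheticDataset(records, tracks, labels, class_names,
                            sorted(train_ids), sorted(test_ids),
                            spec, motifs, seed)


@dataclass
class HeadwiseFixture:
    """End-to-end fixture: dataset + trained model + validity flag."""

    dataset: SyntheticDataset
    train_result: TrainResult
    accuracy_floor: float = 0.95

    @property
    def model(self):
        return self.train_result.model

    @property
    def valid(self) -> bool:
        return self.train_result.test_accuracy >= self.accuracy_floor

    @property
    def diagnostic(self) -> str:
        return (
            f"test accuracy {self.train_result.test_accuracy:.3f} "
            f"(floor {self.accuracy_floor}); "
            f"{'valid' if self.valid else 'INVALID'} fixture"
        )


def make_headwise_fixture(
    seed: int = 0,
    spec: DatasetSpec = DatasetSpec(),
    motifs: MotifSpec | None = None,
    config: ToyEncoderConfig | None = None,
    epochs: int = 40,
) -> HeadwiseFixture:
    """Generate the default dataset and train the toy encoder on it.

    The returned fixture is the harness for end-to-end recovery checks:
    embedding and head-level attributions of the trained model are expected
    to align with the planted-motif annotations, and at least one
    (layer, head) cell to be jointly significant in the combined
    correlation x positive-relevance analysis.
    """
    ds = generate(spec, motifs, seed=seed)
    config = config or ToyEncoderConfig(n_classes=ds.spec.n_classes, seed=seed)
    result = train_toy_model(
        ds.sequences_of(ds.train_ids), ds.labels_of(ds.train_ids),
        ds.sequences_of(ds.test_ids), ds.labels_of(ds.test_ids),
        config=config, seed=seed, epochs=epochs,
    )
    return HeadwiseFixture(ds, result)
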