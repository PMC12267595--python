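"""Peptide dataset ingestion, validation, curation and splitting.

Datasets are ordered collections of :class:`PeptideRecord`. Curation applies
the standard preparation rules for MHC-presented peptides: keep lengths in
[8, 25] and drop redundant sequences. Splitting produces a reproducible
held-out partition (default 80:20) for external validation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = "positive"
NEGATIVE = "negative"

DEFAULT_MIN_LEN = 8
DEFAULT_MAX_LEN = 25


class SequenceAlphabetError(ValueError):
    """Raised in strict mode when a sequence contains non-canonical residues."""


@dataclass(frozen=True)
class PeptideRecord:
    """A single peptide: identifier, uppercase sequence, optional class label.

    ``label`` is ``"positive"`` for an IL-2 inducer, ``"negative"`` for a
    non-inducer, or ``None`` when unlabeled.
    """

    id: str
    sequence: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.label not in (None, POSITIVE, NEGATIVE):
            raise ValueError(f"record {self.id!r}: bad label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """Ordered collection of peptide records with provenance text."""

    records: list[PeptideRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == POSITIVE)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == NEGATIVE)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def labels(self) -> np.ndarray:
        """0/1 label vector; raises if any record is unlabeled."""
        out = []
        for r in self.records:
            if r.label is None:
                raise ValueError(f"record {r.id!r} is unlabeled")
            out.append(1 if r.label == POSITIVE else 0)
        return np.asarray(out, dtype=int)

    def subset(self, labels: Iterable[str]) -> "PeptideDataset":
        wanted = set(labels)
        return PeptideDataset(
            [r for r in self.records if r.label in wanted],
            provenance=self.provenance,
        )

    def positives(self) -> "PeptideDataset":
        return self.subset([POSITIVE])

    def negatives(self) -> "PeptideDataset":
        return self.subset([NEGATIVE])


@dataclass(frozen=True)
class CurationReport:
    """Counts of records removed by each curation rule."""

    n_input: int
    n_length_removed: int
    n_duplicate_removed: int
    n_conflict_removed: int
    n_retained: int
    empty_result: bool = False


@dataclass(frozen=True)
class SplitResult:
    """Train/test partition with the parameters that produced it."""

    train: PeptideDataset
    test: PeptideDataset
    ratio: float
    seed: int


def _validate_sequence(seq: str, rec_id: str, strict: bool) -> Optional[str]:
    """Uppercase and validate; returns None when lenient mode drops a record."""
    seq = seq.upper()
    if not set(seq) <= _AA_SET:
        bad = sorted(set(seq) - _AA_SET)
        if strict:
            raise SequenceAlphabetError(
                f"record {rec_id!r}: non-canonical characters {bad}"
            )
        return None
    return seq


def read_fasta(
    path: str | Path,
    label: Optional[str] = None,
    strict: bool = True,
) -> PeptideDataset:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Record ids are the header token up to the first whitespace; sequences are
    uppercased. ``label`` tags every record with one class. In strict mode a
    non-canonical residue raises; in lenient mode the record is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[PeptideRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _validate_sequence(str(rec.seq), rec.id, strict)
        if seq is None:
            continue
        records.append(PeptideRecord(rec.id, seq, label))
    if not records:
        raise ValueError(f"{path}: no records")
    return PeptideDataset(records, provenance=f"fasta:{path.name}")


def read_paired_fasta(
    positive_path: str | Path,
    negative_path: str | Path,
    strict: bool = True,
) -> PeptideDataset:
    """Read a labeled dataset given as one FASTA per class."""
    pos = read_fasta(positive_path, label=POSITIVE, strict=strict)
    neg = read_fasta(negative_path, label=NEGATIVE, strict=strict)
    return PeptideDataset(
        pos.records + neg.records,
        provenance=f"{pos.provenance}+{neg.provenance}",
    )


def read_csv(path: str | Path, strict: bool = True) -> PeptideDataset:
    """Read the CSV dataset dialect: header ``id,sequence,label``, label in {1,0}.

    The label column may be absent for unlabeled prediction input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    records: list[PeptideRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sequence" not in reader.fieldnames:
            raise ValueError(f"{path}: expected header with 'sequence' column")
        for row in reader:
            seq = _validate_sequence(row["sequence"], row.get("id", "?"), strict)
            if seq is None:
                continue
            label = None
            if "label" in row and row["label"] not in (None, ""):
                label = POSITIVE if str(row["label"]).strip() == "1" else NEGATIVE
            records.append(PeptideRecord(row["id"], seq, label))
    if not records:
        raise ValueError(f"{path}: no records")
    return PeptideDataset(records, provenance=f"csv:{path.name}")


def write_fasta(dataset: PeptideDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in dataset:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_csv(dataset: PeptideDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "label"])
        for r in dataset:
            label = "" if r.label is None else ("1" if r.label == POSITIVE else "0")
            writer.writerow([r.id, r.sequence, label])


def curate(
    dataset: PeptideDataset,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[PeptideDataset, CurationReport]:
    """Apply the dataset preparation rules: length window and redundancy removal.

    Out-of-range sequences are removed first, then exact duplicates
    (case-insensitive, across both classes; first occurrence kept). A sequence
    labeled both positive and negative is contradictory evidence and is dropped
    entirely, counted separately as a conflict.
    """
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    in_range = [r for r in dataset if min_len <= len(r) <= max_len]
    n_length = len(dataset) - len(in_range)

    by_seq: dict[str, list[PeptideRecord]] = {}
    for r in in_range:
        by_seq.setdefault(r.sequence, []).append(r)

    conflicted = {
        seq
        for seq, group in by_seq.items()
        if len({g.label for g in group if g.label is not None}) > 1
    }
    n_conflict = sum(len(by_seq[s]) for s in conflicted)

    kept: list[PeptideRecord] = []
    seen: set[str] = set()
    n_dup = 0
    for r in in_range:
        if r.sequence in conflicted:
            continue
        if r.sequence in seen:
            n_dup += 1
            continue
        seen.add(r.sequence)
        kept.append(r)

    report = CurationReport(
        n_input=len(dataset),
        n_length_removed=n_length,
        n_duplicate_removed=n_dup,
        n_conflict_removed=n_conflict,
        n_retained=len(kept),
        empty_result=not kept,
    )
    out = PeptideDataset(kept, provenance=dataset.provenance + "|curated")
    return out, report


def write_curation_report(report: CurationReport, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rule", "count"])
        writer.writerow(["input", report.n_input])
        writer.writerow(["length_removed", report.n_length_removed])
        writer.writerow(["duplicate_removed", report.n_duplicate_removed])
        writer.writerow(["conflict_removed", report.n_conflict_removed])
        writer.writerow(["retained", report.n_retained])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def test_size(n: int, ratio: float) -> int:
    """Held-out size under the nearest-integer rule: round(ratio * n)."""
    return _round_half_up(ratio * n)


def split_dataset(
    dataset: PeptideDataset,
    ratio: float = 0.2,
    seed: int = 42,
    stratified: bool = True,
) -> SplitResult:
    """Randomly partition into train/test with ``|test| = round(ratio * N)``.

    Stratified splitting draws per-class test counts by largest-remainder
    apportionment so class proportions are preserved within rounding while the
    total still equals ``round(ratio * N)``. Reproducible under ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    n_test = test_size(n, ratio)
    rng = np.random.default_rng(seed)

    if stratified:
        groups: dict[Optional[str], list[int]] = {}
        for i, r in enumerate(dataset):
            if r.label is None:
                raise ValueError("stratified split requires a fully labeled dataset")
            groups.setdefault(r.label, []).append(i)
        keys = sorted(groups)
        exact = {k: ratio * len(groups[k]) for k in keys}
        take = {k: int(math.floor(exact[k])) for k in keys}
        shortfall = n_test - sum(take.values())
        by_frac = sorted(keys, key=lambda k: (-(exact[k] - take[k]), k))
        for k in by_frac[:shortfall]:
            take[k] += 1
        test_idx: set[int] = set()
        for k in keys:
            idx = np.array(groups[k])
            rng.shuffle(idx)
            test_idx.update(idx[: take[k]].tolist())
    else:
        idx = np.arange(n)
        rng.shuffle(idx)
        test_idx = set(idx[:n_test].tolist())

    train = PeptideDataset(
        [r for i, r in enumerate(dataset) if i not in test_idx],
        provenance=dataset.provenance + "|train",
    )
    test = PeptideDataset(
        [r for i, r in enumerate(dataset) if i in test_idx],
        provenance=dataset.provenance + "|test",
    )
    return SplitResult(train=train, test=test, ratio=ratio, seed=seed)
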