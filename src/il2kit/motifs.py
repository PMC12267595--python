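"""Discriminative motif discovery and scanning over residue-class alphabets.

A motif is an ordered list of symbols, each either a specific residue or the
name of a physicochemical group from a classification scheme. Mining finds
contiguous motifs frequent in the positive class (sequence-count semantics)
and present in at most ``fp`` negative-class sequences — the classic
discriminative-motif formulation used to contrast cytokine inducers against
non-inducers. Three schemes are provided:

- ``NONE`` — no grouping; motifs are plain substrings.
- ``BETTS-RUSSELL`` — polar / hydrophobic / small groups (overlapping).
- ``KOOLMAN`` — aliphatic, aromatic, sulfur, hydroxyl, basic, acidic+amide,
  imino groups.

Mixed residue/class symbols within one motif are permitted; group tables are
shipped as editable CSV resources.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import AMINO_ACIDS, PeptideDataset

NONE = "NONE"
BETTS_RUSSELL = "BETTS-RUSSELL"
KOOLMAN = "KOOLMAN"
SCHEME_NAMES = (NONE, BETTS_RUSSELL, KOOLMAN)


@dataclass(frozen=True)
class ClassificationScheme:
    """Named residue grouping: group symbol -> residue set (groups may overlap)."""

    name: str
    groups: dict[str, frozenset[str]]

    def symbol_set(self, symbol: str) -> frozenset[str]:
        """Residues matched by a symbol: the groups, or a literal residue."""
        if symbol in self.groups:
            return self.groups[symbol]
        if len(symbol) == 1 and symbol in AMINO_ACIDS:
            return frozenset(symbol)
        raise KeyError(f"unknown symbol {symbol!r} for scheme {self.name}")

    def alphabet(self) -> list[str]:
        """Mining alphabet: the 20 residues plus any non-singleton group symbols."""
        extra = [g for g in self.groups if len(g) > 1]
        return list(AMINO_ACIDS) + sorted(extra)


def _load_scheme(name: str, filename: str) -> ClassificationScheme:
    with resources.files("il2kit.data").joinpath(filename).open() as fh:
        tab = pd.read_csv(fh)
    groups = {
        row["group"]: frozenset(row["residues"]) for _, row in tab.iterrows()
    }
    return ClassificationScheme(name, groups)


_SCHEMES: dict[str, ClassificationScheme] = {
    NONE: ClassificationScheme(NONE, {a: frozenset(a) for a in AMINO_ACIDS}),
    BETTS_RUSSELL: _load_scheme(BETTS_RUSSELL, "scheme_betts_russell.csv"),
    KOOLMAN: _load_scheme(KOOLMAN, "scheme_koolman.csv"),
}


def get_scheme(name: str | ClassificationScheme) -> ClassificationScheme:
    if isinstance(name, ClassificationScheme):
        return name
    try:
        return _SCHEMES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown scheme {name!r}; choose from {SCHEME_NAMES}")


@dataclass(frozen=True)
class Motif:
    """An ordered symbol pattern with its class-wise sequence counts."""

    symbols: tuple[str, ...]
    scheme: str
    pos_count: int = 0
    neg_count: int = 0

    def __str__(self) -> str:
        return " ".join(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def parse(cls, text: str, scheme: str = NONE, **kw) -> "Motif":
        """Parse the space-separated form ("A L E G"); a bare word with no
        spaces is treated as a plain residue string ("ALEG")."""
        text = text.strip()
        symbols = tuple(text.split(" ")) if " " in text else None
        if symbols is None:
            sch = get_scheme(scheme)
            if text in sch.groups and len(text) > 1:
                symbols = (text,)
            else:
                symbols = tuple(text)
        return cls(symbols=symbols, scheme=get_scheme(scheme).name, **kw)


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence in one peptide, 0-based half-open coordinates."""

    peptide_id: str
    motif: Motif
    start: int
    end: int


def match_motif(sequence: str, motif: Motif) -> list[MotifHit]:
    """All contiguous occurrences of a motif in a sequence, leftmost first."""
    sch = get_scheme(motif.scheme)
    sets = [sch.symbol_set(s) for s in motif.symbols]
    m = len(sets)
    hits = []
    for start in range(len(sequence) - m + 1):
        if all(sequence[start + k] in sets[k] for k in range(m)):
            hits.append(MotifHit("", motif, start, start + m))
    return hits


def contains_motif(sequence: str, motif: Motif) -> bool:
    sch = get_scheme(motif.scheme)
    sets = [sch.symbol_set(s) for s in motif.symbols]
    m = len(sets)
    return any(
        all(sequence[start + k] in sets[k] for k in range(m))
        for start in range(len(sequence) - m + 1)
    )


def _sort_key(m: Motif):
    return (-m.pos_count, len(m.symbols), m.symbols)


def mine_motifs(
    pos: PeptideDataset,
    neg: PeptideDataset,
    scheme: str | ClassificationScheme = NONE,
    fp: int = 10,
    min_pos: Optional[int] = None,
    max_len: int = 7,
) -> list[Motif]:
    """Breadth-first discriminative motif search.

    Starting from single symbols, candidates are extended rightward one symbol
    per level. A candidate whose positive sequence count drops below
    ``min_pos`` is pruned (sequence-count support is anti-monotone under
    extension). Motifs are emitted when they occur in at least ``min_pos``
    positive sequences and at most ``fp`` negative sequences; counting is per
    sequence, not per occurrence. ``min_pos`` defaults to 2% of the positive
    set (minimum 1). Results are sorted by positive count descending, ties by
    shorter length then lexicographic symbols.
    """
    if fp < 0 or max_len < 1:
        raise ValueError("require fp >= 0 and max_len >= 1")
    pos_seqs = pos.sequences()
    neg_seqs = neg.sequences()
    if not pos_seqs:
        raise ValueError("empty positive set")
    if min_pos is None:
        min_pos = max(1, math.ceil(0.02 * len(pos_seqs)))
    if min_pos < 1:
        raise ValueError("min_pos must be >= 1")
    sch = get_scheme(scheme)
    alphabet = sch.alphabet()
    sets = {s: sch.symbol_set(s) for s in alphabet}

    def seq_count(occ: list[tuple[int, int]]) -> int:
        return len({i for i, _ in occ})

    # occurrence postings: (sequence index, start offset)
    results: list[Motif] = []
    frontier: list[tuple[tuple[str, ...], list, list]] = []
    for sym in alphabet:
        p_occ = [
            (i, j)
            for i, s in enumerate(pos_seqs)
            for j in range(len(s))
            if s[j] in sets[sym]
        ]
        if seq_count(p_occ) < min_pos:
            continue
        n_occ = [
            (i, j)
            for i, s in enumerate(neg_seqs)
            for j in range(len(s))
            if s[j] in sets[sym]
        ]
        frontier.append(((sym,), p_occ, n_occ))

    while frontier:
        next_frontier = []
        for symbols, p_occ, n_occ in frontier:
            nc = seq_count(n_occ)
            if nc <= fp:
                results.append(
                    Motif(symbols, sch.name, pos_count=seq_count(p_occ), neg_count=nc)
                )
            if len(symbols) >= max_len:
                continue
            k = len(symbols)
            for sym in alphabet:
                members = sets[sym]
                ext_p = [
                    (i, j)
                    for i, j in p_occ
                    if j + k < len(pos_seqs[i]) and pos_seqs[i][j + k] in members
                ]
                if seq_count(ext_p) < min_pos:
                    continue
                ext_n = [
                    (i, j)
                    for i, j in n_occ
                    if j + k < len(neg_seqs[i]) and neg_seqs[i][j + k] in members
                ]
                next_frontier.append((symbols + (sym,), ext_p, ext_n))
        frontier = next_frontier

    results.sort(key=_sort_key)
    return results


def motif_coverage(
    motifs: Iterable[Motif], dataset: PeptideDataset
) -> pd.DataFrame:
    """Per-motif counts of positive- and negative-labeled sequences matched."""
    rows = []
    for m in motifs:
        p = sum(
            1 for r in dataset if r.label == "positive" and contains_motif(r.sequence, m)
        )
        n = sum(
            1 for r in dataset if r.label == "negative" and contains_motif(r.sequence, m)
        )
        rows.append({"motif": str(m), "scheme": m.scheme, "positive": p, "negative": n})
    return pd.DataFrame(rows, columns=["motif", "scheme", "positive", "negative"])


def scan_sequence(
    record_id: str, sequence: str, motifs: Iterable[Motif]
) -> list[MotifHit]:
    """All hits of a motif list in one sequence, with the peptide id filled in."""
    hits = []
    for m in motifs:
        for h in match_motif(sequence, m):
            hits.append(MotifHit(record_id, m, h.start, h.end))
    hits.sort(key=lambda h: (h.start, h.end, h.motif.symbols))
    return hits


def write_motifs(motifs: Iterable[Motif], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["symbols", "scheme", "pos_count", "neg_count"])
        for m in motifs:
            writer.writerow([str(m), m.scheme, m.pos_count, m.neg_count])


def read_motifs(path) -> list[Motif]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Motif(
                    symbols=tuple(row["symbols"].split(" ")),
                    scheme=row["scheme"],
                    pos_count=int(row.get("pos_count", 0) or 0),
                    neg_count=int(row.get("neg_count", 0) or 0),
                )
            )
    return out
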