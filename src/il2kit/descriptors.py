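"""Sequence-derived numeric descriptors for peptide classification.

Implements the composition-style descriptor families used for model building:

- ``AAC`` — amino-acid composition, 20 percentages.
- ``DPC`` / ``DPC_LEN`` — dipeptide composition (400 percentages), optionally
  with the raw peptide length appended as a 401st feature.
- ``CTD`` — composition/transition/distribution over seven physicochemical
  properties, each splitting the alphabet into three groups (147 values).
- ``PCP`` — percentage composition over a fixed table of binary
  physicochemical residue classes.
- ``DDR`` — distance distribution of residues: summed gaps between successive
  occurrences of each residue, normalised by length.
- ``RRI`` — repetitive-residue information: squared run lengths per residue,
  normalised by length.
- ``AAB`` — terminal binary profile: one-hot encoding of the eight N-terminal
  and eight C-terminal positions (320 bits).

Group and class tables are shipped as editable CSV resources under
``il2kit/data`` and are versioned so they can be swapped wholesale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, PeptideDataset

FEATURE_SETS = ("AAC", "DPC", "DPC_LEN", "CTD", "PCP", "DDR", "RRI", "AAB")

_DIPEPTIDES = ["".join(p) for p in itertools.product(AMINO_ACIDS, repeat=2)]


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("il2kit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def ctd_property_groups() -> dict[str, list[tuple[str, frozenset[str]]]]:
    """The 7 physicochemical properties, each as 3 named residue groups."""
    tab = _load_table("ctd_groups.csv")
    out: dict[str, list[tuple[str, frozenset[str]]]] = {}
    for prop, sub in tab.groupby("property", sort=False):
        out[prop] = [
            (row["group"], frozenset(row["residues"])) for _, row in sub.iterrows()
        ]
    return out


def pcp_classes() -> list[tuple[str, frozenset[str]]]:
    """Ordered binary residue-class table used by the PCP descriptor."""
    tab = _load_table("pcp_classes.csv")
    return [(row["class"], frozenset(row["residues"])) for _, row in tab.iterrows()]


_CTD_GROUPS = ctd_property_groups()
_PCP_CLASSES = pcp_classes()


@dataclass
class FeatureMatrix:
    """A named descriptor table: one row per peptide, tagged by feature set."""

    feature_set: str
    frame: pd.DataFrame

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def column_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="id")

    @classmethod
    def from_csv(cls, path, feature_set: str) -> "FeatureMatrix":
        return cls(feature_set, pd.read_csv(path, index_col="id"))


def compute_aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: percent frequency of each residue; sums to 100."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.array([sequence.count(a) for a in AMINO_ACIDS], dtype=float)
    return 100.0 * counts / len(sequence)


def compute_dpc(sequence: str, append_length: bool = False) -> np.ndarray:
    """Dipeptide composition over the 400 ordered pairs; sums to 100.

    With ``append_length`` the raw residue count is appended as entry 401,
    giving the hybrid descriptor that pairs composition with peptide size.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("dipeptide composition requires length >= 2")
    counts: dict[str, int] = {}
    for i in range(n - 1):
        pair = sequence[i : i + 2]
        counts[pair] = counts.get(pair, 0) + 1
    vec = np.array([counts.get(d, 0) for d in _DIPEPTIDES], dtype=float)
    vec = 100.0 * vec / (n - 1)
    if append_length:
        vec = np.append(vec, float(n))
    return vec


def _group_index(sequence: str, groups: Sequence[tuple[str, frozenset[str]]]) -> np.ndarray:
    idx = np.empty(len(sequence), dtype=int)
    for i, ch in enumerate(sequence):
        for g, (_, members) in enumerate(groups):
            if ch in members:
                idx[i] = g
                break
        else:  # pragma: no cover - tables partition the alphabet
            raise ValueError(f"residue {ch!r} not covered by group table")
    return idx


def compute_ctd(sequence: str) -> np.ndarray:
    """Composition/transition/distribution descriptor (147 values).

    Per property: 3 group-composition percentages, 3 between-group transition
    percentages (of the L-1 adjacent pairs), and per group the positions of
    the first, 25%, 50%, 75% and last occurrence as percentages of L (0 when
    the group is absent).
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("CTD requires length >= 2")
    out: list[float] = []
    for prop, groups in _CTD_GROUPS.items():
        gi = _group_index(sequence, groups)
        for g in range(3):
            out.append(100.0 * float(np.sum(gi == g)) / n)
        pairs = list(zip(gi[:-1], gi[1:]))
        for a, b in ((0, 1), (0, 2), (1, 2)):
            t = sum(1 for x, y in pairs if {x, y} == {a, b})
            out.append(100.0 * t / (n - 1))
        for g in range(3):
            pos = np.flatnonzero(gi == g) + 1  # 1-based positions
            if len(pos) == 0:
                out.extend([0.0] * 5)
                continue
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                k = max(1, int(np.ceil(q * len(pos))))
                out.append(100.0 * pos[k - 1] / n)
    return np.asarray(out)


def ctd_column_names() -> list[str]:
    names: list[str] = []
    for prop, groups in _CTD_GROUPS.items():
        gnames = [g for g, _ in groups]
        names += [f"CTD_{prop}_C_{g}" for g in gnames]
        names += [
            f"CTD_{prop}_T_{gnames[a]}_{gnames[b]}" for a, b in ((0, 1), (0, 2), (1, 2))
        ]
        for g in gnames:
            names += [f"CTD_{prop}_D_{g}_{p}" for p in (0, 25, 50, 75, 100)]
    return names


def compute_pcp(sequence: str) -> np.ndarray:
    """Percent membership of each physicochemical residue class."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    return np.array(
        [100.0 * sum(1 for ch in sequence if ch in members) / n
         for _, members in _PCP_CLASSES]
    )


def compute_ddr(sequence: str) -> np.ndarray:
    """Distance distribution: summed gaps between successive occurrences.

    ``DDR_a = 100 * (sum of index gaps between consecutive a's) / L``; zero for
    residues occurring at most once.
    """
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    out = np.zeros(20)
    for j, a in enumerate(AMINO_ACIDS):
        pos = [i for i, ch in enumerate(sequence) if ch == a]
        if len(pos) > 1:
            out[j] = 100.0 * float(pos[-1] - pos[0]) / n
    return out


def compute_rri(sequence: str) -> np.ndarray:
    """Repetitive-residue information: sum of squared maximal run lengths / L."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    out = np.zeros(20)
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    i = 0
    while i < n:
        j = i
        while j < n and sequence[j] == sequence[i]:
            j += 1
        out[aa_index[sequence[i]]] += (j - i) ** 2
        i = j
    return out / n


def compute_terminal_binary(
    sequence: str, n_term: int = 8, c_term: int = 8
) -> np.ndarray:
    """One-hot terminal profile: N-terminal and C-terminal windows, 20 bits each.

    The N window covers the first ``n_term`` residues and the C window the
    last ``c_term``; for peptides shorter than their sum the windows overlap
    (the two-sample-logo convention), and positions beyond a short peptide's
    span are left all-zero rather than padded.
    """
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}
    vec = np.zeros(20 * (n_term + c_term))
    n = len(sequence)
    for i in range(min(n_term, n)):
        vec[20 * i + aa_index[sequence[i]]] = 1.0
    for j in range(c_term):
        src = n - c_term + j  # C window anchored at the C terminus
        if src >= 0:
            vec[20 * (n_term + j) + aa_index[sequence[src]]] = 1.0
    return vec


def aab_column_names(n_term: int = 8, c_term: int = 8) -> list[str]:
    names = []
    for i in range(n_term):
        names += [f"AAB_N{i + 1}_{a}" for a in AMINO_ACIDS]
    for j in range(c_term):
        names += [f"AAB_C{j + 1}_{a}" for a in AMINO_ACIDS]
    return names


_DISPATCH = {
    "AAC": (compute_aac, [f"AAC_{a}" for a in AMINO_ACIDS]),
    "DPC": (compute_dpc, [f"DPC_{d}" for d in _DIPEPTIDES]),
    "DPC_LEN": (
        lambda s: compute_dpc(s, append_length=True),
        [f"DPC_{d}" for d in _DIPEPTIDES] + ["LENGTH"],
    ),
    "CTD": (compute_ctd, ctd_column_names()),
    "PCP": (compute_pcp, [f"PCP_{c}" for c, _ in _PCP_CLASSES]),
    "DDR": (compute_ddr, [f"DDR_{a}" for a in AMINO_ACIDS]),
    "RRI": (compute_rri, [f"RRI_{a}" for a in AMINO_ACIDS]),
    "AAB": (compute_terminal_binary, aab_column_names()),
}


def compute_feature_set(dataset: PeptideDataset, feature_set: str) -> FeatureMatrix:
    """Compute one descriptor family for every peptide; rows follow input order."""
    if feature_set not in _DISPATCH:
        raise ValueError(
            f"unknown feature set {feature_set!r}; choose from {FEATURE_SETS}"
        )
    func, names = _DISPATCH[feature_set]
    rows = [func(r.sequence) for r in dataset]
    frame = pd.DataFrame(rows, index=[r.id for r in dataset], columns=names)
    if frame.isna().any().any():  # pragma: no cover - defensive
        raise ValueError("descriptor computation produced missing values")
    return FeatureMatrix(feature_set, frame)
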