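"""User-facing workflows: predict peptides, design mutants, scan proteins,
and locate motifs — the four operations an end user runs against a trained
model and mined motif lists.

All outputs are plain DataFrames (the CLI writes them as CSV). Coordinates
are 0-based half-open in machine-readable columns; 1-based inclusive
positions are emitted alongside for human readers.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import pandas as pd

from .hybrid import predict_dataset
from .io import (
    AMINO_ACIDS,
    DEFAULT_MAX_LEN,
    DEFAULT_MIN_LEN,
    PeptideDataset,
    PeptideRecord,
)
from .models import TrainedPredictor
from .motifs import Motif, scan_sequence


def predict(
    dataset: PeptideDataset,
    predictor: TrainedPredictor,
    pos_motifs: Sequence[Motif] = (),
    neg_motifs: Sequence[Motif] = (),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Hybrid-score every input peptide; one row per record, input order.

    Peptides outside the supported length window [8, 25] are still scored but
    flagged in the ``warning`` column.
    """
    if len(dataset) == 0:
        raise ValueError("empty input")
    records = predict_dataset(
        dataset, predictor, pos_motifs, neg_motifs, threshold=threshold
    )
    rows = []
    for r in records:
        L = len(r.sequence)
        warn = ""
        if not DEFAULT_MIN_LEN <= L <= DEFAULT_MAX_LEN:
            warn = f"length {L} outside supported range [{DEFAULT_MIN_LEN}, {DEFAULT_MAX_LEN}]"
        rows.append(
            {
                "id": r.id,
                "sequence": r.sequence,
                "base_prob": round(r.base_prob, 6),
                "pos_motif_hit": int(r.pos_motif_hit),
                "neg_motif_hit": int(r.neg_motif_hit),
                "final_score": round(r.final_score, 6),
                "call": r.call,
                "warning": warn,
            }
        )
    return pd.DataFrame(rows)


def design(
    peptide: str,
    predictor: TrainedPredictor,
    pos_motifs: Sequence[Motif] = (),
    neg_motifs: Sequence[Motif] = (),
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Exhaustive single-residue substitution scan, ranked by hybrid score.

    Emits the parent plus all 19*L single-point mutants, sorted by final
    score descending; ties are broken by (position, mutant residue) so output
    is reproducible. Ranks are dense, 1 = highest score.
    """
    peptide = peptide.upper()
    if not peptide or not set(peptide) <= set(AMINO_ACIDS):
        raise ValueError("peptide must be non-empty over the 20 canonical residues")
    variants: list[PeptideRecord] = [PeptideRecord("parent", peptide)]
    meta: dict[str, tuple[int, str, str]] = {"parent": (-1, "", "")}
    for pos in range(len(peptide)):
        wild = peptide[pos]
        for mut in AMINO_ACIDS:
            if mut == wild:
                continue
            vid = f"{wild}{pos + 1}{mut}"
            variants.append(
                PeptideRecord(vid, peptide[:pos] + mut + peptide[pos + 1:])
            )
            meta[vid] = (pos, wild, mut)
    dataset = PeptideDataset(variants, provenance="design")
    records = predict_dataset(
        dataset, predictor, pos_motifs, neg_motifs, threshold=threshold
    )
    rows = []
    for r in records:
        pos, wild, mut = meta[r.id]
        rows.append(
            {
                "mutant": r.id,
                "position": pos,
                "wild": wild,
                "mutated_to": mut,
                "sequence": r.sequence,
                "final_score": round(r.final_score, 6),
                "base_prob": round(r.base_prob, 6),
                "call": r.call,
            }
        )
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["final_score", "position", "mutated_to"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    frame["rank"] = frame["final_score"].rank(method="dense", ascending=False).astype(int)
    return frame


def scan(
    protein: str,
    predictor: TrainedPredictor,
    window: int = 15,
    step: int = 1,
    pos_motifs: Sequence[Motif] = (),
    neg_motifs: Sequence[Motif] = (),
    threshold: float = 0.5,
    per_residue: bool = False,
) -> pd.DataFrame:
    """Score overlapping fixed-length windows along a protein.

    Fragments start at offsets 0, step, 2*step, ... while they fit; the count
    is floor((L - window)/step) + 1. With ``per_residue`` an aggregate track
    (mean final score of all windows covering each residue) is returned
    instead, for region calling.
    """
    protein = protein.upper()
    if window > len(protein):
        raise ValueError("window longer than protein")
    if step < 1:
        raise ValueError("step must be >= 1")
    if not DEFAULT_MIN_LEN <= window <= DEFAULT_MAX_LEN:
        warnings.warn(
            f"window {window} outside the supported peptide range "
            f"[{DEFAULT_MIN_LEN}, {DEFAULT_MAX_LEN}]",
            UserWarning,
            stacklevel=2,
        )
    starts = list(range(0, len(protein) - window + 1, step))
    fragments = PeptideDataset(
        [
            PeptideRecord(f"frag_{s}", protein[s : s + window])
            for s in starts
        ],
        provenance="scan",
    )
    records = predict_dataset(
        fragments, predictor, pos_motifs, neg_motifs, threshold=threshold
    )
    frame = pd.DataFrame(
        {
            "start": starts,
            "end": [s + window for s in starts],
            "start_1based": [s + 1 for s in starts],
            "end_1based": [s + window for s in starts],
            "sequence": [r.sequence for r in records],
            "final_score": [round(r.final_score, 6) for r in records],
            "base_prob": [round(r.base_prob, 6) for r in records],
            "call": [r.call for r in records],
        }
    )
    if not per_residue:
        return frame
    totals = pd.Series(0.0, index=range(len(protein)))
    counts = pd.Series(0, index=range(len(protein)))
    for s, score in zip(starts, frame["final_score"]):
        totals[s : s + window] += score
        counts[s : s + window] += 1
    covered = counts > 0
    track = pd.DataFrame(
        {
            "position": totals.index[covered],
            "residue": [protein[i] for i in totals.index[covered]],
            "mean_score": (totals[covered] / counts[covered]).round(6),
        }
    )
    return track


def motif_scan(
    sequence: str,
    pos_motifs: Sequence[Motif],
    neg_motifs: Sequence[Motif] = (),
    record_id: str = "query",
) -> pd.DataFrame:
    """Locate every inducer/non-inducer motif occurrence in one sequence."""
    sequence = sequence.upper()
    rows = []
    for cls, motifs in (("inducer-motif", pos_motifs), ("non-inducer-motif", neg_motifs)):
        for h in scan_sequence(record_id, sequence, motifs):
            rows.append(
                {
                    "id": h.peptide_id,
                    "motif": str(h.motif),
                    "scheme": h.motif.scheme,
                    "class": cls,
                    "start": h.start,
                    "end": h.end,
                    "start_1based": h.start + 1,
                    "end_1based": h.end,
                    "matched": sequence[h.start : h.end],
                }
            )
    frame = pd.DataFrame(
        rows,
        columns=["id", "motif", "scheme", "class", "start", "end",
                 "start_1based", "end_1based", "matched"],
    )
    return frame.sort_values(
        by=["start", "end", "class", "motif"], kind="stable"
    ).reset_index(drop=True)
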