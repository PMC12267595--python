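"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the algorithms they check: motif enumeration scans
every candidate pattern generated directly from the positive sequences
(no support pruning, no breadth-first extension), and the metric oracles do
plain arithmetic / O(n^2) pair counting.
"""

import itertools
import math

import numpy as np

from il2kit.motifs import Motif, get_scheme


def _pattern_occurs(seq, sets):
    m = len(sets)
    return any(
        all(seq[j + k] in sets[k] for k in range(m))
        for j in range(len(seq) - m + 1)
    )


def brute_force_mine(pos_seqs, neg_seqs, scheme, fp, min_pos, max_len):
    """Enumerate every symbol pattern occurring in >= 1 positive sequence,
    count containing sequences exhaustively, and filter.

    Patterns absent from all positives have zero support, so generating
    candidates from positive-sequence windows loses nothing while staying a
    different algorithm from the miner under test.
    """
    sch = get_scheme(scheme)
    alphabet = sch.alphabet()
    sets = {s: sch.symbol_set(s) for s in alphabet}
    matching_symbols = {
        ch: [s for s in alphabet if ch in sets[s]] for ch in set("".join(pos_seqs))
    }
    candidates = set()
    for seq in pos_seqs:
        for L in range(1, max_len + 1):
            for j in range(len(seq) - L + 1):
                window = seq[j : j + L]
                for combo in itertools.product(
                    *(matching_symbols[ch] for ch in window)
                ):
                    candidates.add(combo)
    results = []
    for combo in candidates:
        csets = [sets[s] for s in combo]
        pc = sum(1 for s in pos_seqs if _pattern_occurs(s, csets))
        if pc < min_pos:
            continue
        nc = sum(1 for s in neg_seqs if _pattern_occurs(s, csets))
        if nc > fp:
            continue
        results.append(Motif(combo, sch.name, pos_count=pc, neg_count=nc))
    results.sort(key=lambda m: (-m.pos_count, len(m.symbols), m.symbols))
    return results


def pairwise_auc(scores, labels):
    """O(n^2) definition: fraction of (positive, negative) pairs where the
    positive outscores the negative, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def explicit_metrics(tp, fp, tn, fn):
    """Direct arithmetic for the four confusion-based metrics."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sens, spec, acc, mcc
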