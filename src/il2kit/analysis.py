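"""Dataset characterisation: length distributions, class-wise composition
comparison with multiplicity correction, and positional residue enrichment.

Per-sequence composition (not pooled residue counts) is the sampling unit
throughout, so peptides are treated as independent observations.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .descriptors import compute_feature_set
from .io import AMINO_ACIDS, PeptideDataset


def length_distribution(
    dataset: PeptideDataset,
    min_len: Optional[int] = None,
    max_len: Optional[int] = None,
) -> pd.DataFrame:
    """Per-class length histogram; rows are lengths, columns class counts."""
    lengths = [len(r) for r in dataset]
    lo = min(lengths) if min_len is None else min_len
    hi = max(lengths) if max_len is None else max_len
    idx = range(lo, hi + 1)
    pos = pd.Series(
        [len(r) for r in dataset if r.label == "positive"], dtype=int
    ).value_counts()
    neg = pd.Series(
        [len(r) for r in dataset if r.label == "negative"], dtype=int
    ).value_counts()
    return pd.DataFrame(
        {
            "length": list(idx),
            "positive": [int(pos.get(l, 0)) for l in idx],
            "negative": [int(neg.get(l, 0)) for l in idx],
        }
    ).set_index("length")


def _safe_p(p: float) -> float:
    return 1.0 if np.isnan(p) else float(p)


def composition_comparison(
    pos: PeptideDataset,
    neg: PeptideDataset,
    test: str = "mann-whitney",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare per-sequence residue composition between classes, residue by
    residue, with Benjamini-Hochberg correction over the 20 tests.

    Returns a 20-row table: mean composition per class, raw and adjusted
    p-value, and a significance flag at adjusted p < ``alpha``. Degenerate
    comparisons (identical constant columns) report p = 1.
    """
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both classes need at least 2 sequences")
    pos_aac = compute_feature_set(pos, "AAC").frame.to_numpy()
    neg_aac = compute_feature_set(neg, "AAC").frame.to_numpy()
    raw = []
    for j in range(20):
        a, b = pos_aac[:, j], neg_aac[:, j]
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
            raw.append(1.0)
            continue
        if test == "mann-whitney":
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        elif test == "t":
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        else:
            raise ValueError("test must be 'mann-whitney' or 't'")
        raw.append(_safe_p(p))
    reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    return pd.DataFrame(
        {
            "residue": list(AMINO_ACIDS),
            "mean_pos": pos_aac.mean(axis=0),
            "mean_neg": neg_aac.mean(axis=0),
            "p_raw": raw,
            "p_adjusted": adjusted,
            "significant": reject,
        }
    ).set_index("residue")


def positional_enrichment(
    pos: PeptideDataset,
    neg: PeptideDataset,
    n_term: int = 8,
    c_term: int = 8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Position-wise residue enrichment between classes (two-sample-logo style).

    For each of the N-terminal ``n_term`` and C-terminal ``c_term`` positions
    and each residue, the 0/1 residue indicators of the two classes are
    compared by a two-sample t-test. Sequences too short to reach a position
    are skipped for that position. Flags cells as enriched (higher indicator
    mean in positives) or depleted at p < ``alpha``.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty")

    def indicator(ds: PeptideDataset, position: str, k: int, aa: str) -> np.ndarray:
        vals = []
        for r in ds:
            if len(r) < k:
                continue
            ch = r.sequence[k - 1] if position == "N" else r.sequence[-k]
            vals.append(1.0 if ch == aa else 0.0)
        return np.asarray(vals)

    rows = []
    positions = [("N", k) for k in range(1, n_term + 1)] + [
        ("C", k) for k in range(1, c_term + 1)
    ]
    for side, k in positions:
        for aa in AMINO_ACIDS:
            a = indicator(pos, side, k, aa)
            b = indicator(neg, side, k, aa)
            if len(a) < 2 or len(b) < 2:
                continue
            diff = float(a.mean() - b.mean())
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                p = 1.0 if a.mean() == b.mean() else 0.0
            else:
                p = _safe_p(stats.ttest_ind(a, b, equal_var=False).pvalue)
            flag = ""
            if p < alpha:
                flag = "enriched" if diff > 0 else "depleted"
            rows.append(
                {
                    "position": f"{side}{k}",
                    "residue": aa,
                    "diff": diff,
                    "p": p,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows, columns=["position", "residue", "diff", "p", "flag"])


# ---------------------------------------------------------------------------
# optional rendering — the tables above are the contract, plots are cosmetic


def plot_length_distribution(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = table[["positive", "negative"]].plot.bar(figsize=(8, 4))
    ax.set_xlabel("peptide length")
    ax.set_ylabel("count")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)


def plot_composition(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ax = table[["mean_pos", "mean_neg"]].plot.bar(figsize=(9, 4))
    for i, (res, row) in enumerate(table.iterrows()):
        if row["significant"]:
            ax.annotate("*", (i, max(row["mean_pos"], row["mean_neg"])),
                        ha="center")
    ax.set_ylabel("mean composition (%)")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)


def plot_enrichment_heatmap(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = table.pivot(index="residue", columns="position", values="diff")
    fig, ax = plt.subplots(figsize=(10, 6))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(grid.columns)), grid.columns)
    ax.set_yticks(range(len(grid.index)), grid.index)
    fig.colorbar(im, label="indicator-frequency difference (pos - neg)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
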