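"""TPM quantification, presence/absence calls, expression bins, and
exclusive tissue intersections (the numbers behind an UpSet plot).

Presence follows the convention that a transcript with TPM < 1 is absent
from a tissue; expression bins are low [1, 10), medium [10, 50] and high
(50, inf), with the boundary cells assigned to medium so the bins
partition all present cells.
"""

from __future__ import annotations

import pandas as pd


def to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: TPM_g = 1e6 * (c_g/L_g) / sum_h (c_h/L_h).

    Every tissue column of the result sums to 1e6.  Raises if a tissue has
    no mapped reads at all (naming the tissue) or a gene lacks a length.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"genes without length: {list(missing[:5])}")
    L = lengths.loc[counts.index].astype(float)
    if (L <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(L, axis=0)
    colsum = rate.sum(axis=0)
    dead = colsum[colsum == 0]
    if len(dead):
        raise ValueError(f"tissue {dead.index[0]!r} has an all-zero count column")
    return rate.div(colsum, axis=1) * 1e6


def presence(expr: pd.DataFrame, threshold: float = 1.0) -> pd.DataFrame:
    """Boolean genes x tissues table: present iff TPM >= threshold."""
    if threshold <= 0:
        raise ValueError("presence threshold must be > 0")
    return expr >= threshold


def bin_levels(expr: pd.DataFrame, presence_threshold: float = 1.0,
               edges: tuple[float, float] = (10.0, 50.0)) -> pd.DataFrame:
    """Label each cell absent/low/medium/high.

    low is [threshold, edges[0]); medium is [edges[0], edges[1]] with both
    boundaries inclusive; high is (edges[1], inf).
    """
    lo, hi = edges
    out = pd.DataFrame("absent", index=expr.index, columns=expr.columns)
    out = out.mask((expr >= presence_threshold) & (expr < lo), "low")
    out = out.mask((expr >= lo) & (expr <= hi), "medium")
    out = out.mask(expr > hi, "high")
    return out


def exclusive_intersections(present: pd.DataFrame) -> dict[frozenset, int]:
    """Count genes per exact presence pattern (exclusive intersections).

    Each gene present somewhere is counted in exactly one tissue subset —
    its full presence pattern — so counts over all subsets sum to the
    number of present genes.
    """
    if present.shape[1] < 1:
        raise ValueError("need at least one tissue")
    out: dict[frozenset, int] = {}
    tissues = list(present.columns)
    arr = present.to_numpy(dtype=bool)
    for row in arr:
        if not row.any():
            continue
        key = frozenset(t for t, p in zip(tissues, row) if p)
        out[key] = out.get(key, 0) + 1
    return out


def unique_genes(present: pd.DataFrame, expr: pd.DataFrame,
                 top_n: int = 10) -> dict[str, list[tuple[str, float]]]:
    """Per tissue, the top-n most abundant genes present only in that tissue.

    Ranked by TPM in the tissue, descending; ties broken by gene id.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    n_present = present.sum(axis=1)
    out: dict[str, list[tuple[str, float]]] = {}
    for tissue in present.columns:
        only_here = present.index[(n_present == 1) & present[tissue]]
        ranked = sorted(((g, float(expr.at[g, tissue])) for g in only_here),
                        key=lambda gv: (-gv[1], gv[0]))
        out[tissue] = ranked[:top_n]
    return out


def plot_intersections(intersections: dict[frozenset, int], path,
                       top: int = 20) -> None:
    """Minimal UpSet-style bar chart of exclusive intersection sizes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    items = sorted(intersections.items(), key=lambda kv: -kv[1])[:top]
    labels = ["&".join(sorted(k)) for k, _ in items]
    fig, ax = plt.subplots(figsize=(max(6, len(items) * 0.5), 4))
    ax.bar(range(len(items)), [v for _, v in items], color="0.3")
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(labels, rotation=90, fontsize=7)
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
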