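"""The tissue-specificity index tau and its classification.

For a gene with expression x_i over n tissues,

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1),

computed on TPM after flooring every value at 2 to damp sampling noise in
tissues with no detected expression.  tau is 0 for perfectly uniform
expression and approaches 1 for expression confined to one tissue.  Genes
with tau < 0.3 are classed broadly expressed, tau > 0.8 highly
tissue-specific, the rest moderate; the broad regime is calibrated against
housekeeping genes with a two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def compute_tau(values, floor: float = 2.0) -> float:
    """Tissue-specificity index of one expression row (values floored first)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    x = np.maximum(x, floor)
    xhat = x / x.max()
    return float((1.0 - xhat).sum() / (x.size - 1))


def classify_tau(tau: float, broad: float = 0.3, high: float = 0.8) -> str:
    """broad if tau < broad; high if tau > high; moderate on [broad, high]."""
    if not broad < high:
        raise ValueError("cut-offs must be ordered")
    if tau < broad:
        return "broad"
    if tau > high:
        return "high"
    return "moderate"


def score_matrix(expr: pd.DataFrame, floor: float = 2.0, broad: float = 0.3,
                 high: float = 0.8, log2: bool = False) -> pd.DataFrame:
    """Score every gene of a TPM matrix: tau, maximal tissue, class.

    ``log2=True`` computes tau on log2(TPM + 1) after flooring (an
    alternative convention for heavy-tailed expression).  A gene whose row
    is entirely at/below the floor is flagged ``no_expression`` and gets
    tau 0.  Maximal-tissue ties go to the first tissue in column order and
    are flagged.  ``summed_log_expression`` is log10(sum_t TPM + 1).
    """
    arr = expr.to_numpy(dtype=float)
    floored = np.maximum(arr, floor)
    work = np.log2(floored + 1.0) if log2 else floored
    mx = work.max(axis=1)
    tau = (1.0 - work / mx[:, None]).sum(axis=1) / (work.shape[1] - 1)
    no_expr = (arr <= floor).all(axis=1)
    tau[no_expr] = 0.0
    argmax = work.argmax(axis=1)
    tie = (work == mx[:, None]).sum(axis=1) > 1
    return pd.DataFrame({
        "tau": tau,
        "max_tissue": [expr.columns[i] for i in argmax],
        "specificity_class": [classify_tau(t, broad, high) for t in tau],
        "summed_log_expression": np.log10(arr.sum(axis=1) + 1.0),
        "max_tie": tie,
        "no_expression": no_expr,
    }, index=expr.index)


def calibrate_cutoffs(tau_a, tau_b) -> tuple[float, float]:
    """Two-sample KS comparison of two tau distributions.

    Returns (D, asymptotic two-sided p); used to check that top unique
    genes and housekeeping genes occupy distinct tau regimes.
    """
    a = np.asarray(tau_a, dtype=float)
    b = np.asarray(tau_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both tau lists must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def tau_by_max_tissue(records: pd.DataFrame,
                      tissue_order: list[str] | None = None) -> pd.DataFrame:
    """Per-tissue summary of tau over genes maximally expressed there.

    Returns n_max, mean tau, and a normal-approximation 95% CI
    (mean +/- 1.96 * SE; degenerate at the mean when n_max = 1).
    """
    tissues = tissue_order or sorted(records["max_tissue"].unique())
    rows = []
    for tissue in tissues:
        grp = records.loc[records["max_tissue"] == tissue, "tau"]
        n = len(grp)
        mean = float(grp.mean()) if n else float("nan")
        se = float(grp.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append({"tissue": tissue, "n_max": n, "mean_tau": mean,
                     "ci_low": mean - 1.96 * se, "ci_high": mean + 1.96 * se})
    out = pd.DataFrame(rows).set_index("tissue")
    return out
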