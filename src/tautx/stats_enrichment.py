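"""GO overrepresentation and the comparative statistics of the pipeline:
Spearman correlation, seeded bootstrap group comparison, and one-way ANOVA
with Tukey's HSD.

Overrepresentation is one-sided (enrichment only): per GO term with at
least ``min_genes`` study genes annotated, the upper hypergeometric tail
P(X >= k) is computed and Benjamini-Hochberg FDR is applied across the
tested terms.  GO terms are treated as flat labels; any ontology
propagation must happen upstream.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def go_overrepresentation(study_genes, background_genes,
                          gene2terms: dict[str, set[str]],
                          min_genes: int = 3) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of GO terms in a study set.

    ``study_genes`` must be a subset of ``background_genes``.  Terms with
    fewer than ``min_genes`` study genes are not tested.  Returns a table
    sorted by q then p with columns term, k (study hits), n (study size),
    K (background hits), N (background size), p, q.
    """
    study = set(study_genes)
    background = set(background_genes)
    offenders = sorted(study - background)
    if offenders:
        raise ValueError(f"study genes absent from background: {offenders[:10]}")
    n, N = len(study), len(background)

    term_bg: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in gene2terms.get(gene, ()):  # unannotated genes still count in N
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    rows = []
    for term, k in sorted(term_study.items()):
        if k < min_genes:
            continue
        K = term_bg[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(out):
        _, q, _, _ = multipletests(out["p"], method="fdr_bh")
        out["q"] = q
        out = out.sort_values(["q", "p", "term"]).reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def spearman(x, y, method: str = "asymptotic", seed: int | None = None,
             n_perm: int = 10000) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    ``method="asymptotic"`` uses the t reference with n-2 df;
    ``method="permutation"`` permutes y with a seeded generator (exact
    enumeration of all n! permutations when n <= 8).  Constant input is an
    error: rho is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")

    def rho_of(ryy: np.ndarray) -> float:
        return float(np.corrcoef(rx, ryy)[0, 1])

    rho = rho_of(ry)
    n = x.size
    if method == "asymptotic":
        if abs(rho) >= 1.0:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
        return rho, min(p, 1.0)
    if method == "permutation":
        target = abs(rho) - 1e-12
        if n <= 8:
            hits = total = 0
            for perm in itertools.permutations(ry):
                total += 1
                hits += abs(rho_of(np.asarray(perm))) >= target
            return rho, hits / total
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            hits += abs(rho_of(rng.permutation(ry))) >= target
        return rho, (hits + 1) / (n_perm + 1)
    raise ValueError(f"unknown method {method!r}")


@dataclass
class BootstrapComparison:
    mean_a: float
    mean_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    diff: float
    ci_diff: tuple[float, float]
    p_value: float
    B: int
    seed: int


def bootstrap_compare(values_a, values_b, B: int = 10000,
                      seed: int = 0) -> BootstrapComparison:
    """Percentile bootstrap comparison of two group means.

    Each group is resampled with replacement B times; 2.5/97.5 percentile
    CIs are reported per group and for the difference of means, with the
    two-sided sign-crossing p-value floored at 2/B.  Bit-reproducible under
    a fixed seed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    boots_a = a[rng.integers(0, a.size, size=(B, a.size))].mean(axis=1)
    boots_b = b[rng.integers(0, b.size, size=(B, b.size))].mean(axis=1)
    diffs = boots_a - boots_b
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    p = min(max(p, 2.0 / B), 1.0)
    pct = lambda v: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
    return BootstrapComparison(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        ci_a=pct(boots_a), ci_b=pct(boots_b),
        diff=float(a.mean() - b.mean()), ci_diff=pct(diffs),
        p_value=p, B=B, seed=seed)


def anova_tukey(values, group_labels):
    """One-way ANOVA plus Tukey HSD over all group pairs.

    Returns (F, (df_between, df_within), p, tukey_table).  Requires at
    least two groups with at least two values each.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must align")
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f_stat, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = values.size - len(groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    tk = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    if math.isnan(f_stat):  # all groups identical constants
        f_stat, p = 0.0, 1.0
    return float(f_stat), (df1, df2), float(p), table
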