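"""Steroidogenic-pathway panel: per-tissue expression and specificity of
synthesis enzymes, conversion enzymes and steroid receptors, the stagewise
specificity trend, and hierarchical clustering of 17betaHSD isoforms by
tissue expression profile.

The default panel follows the sex-steroid cascade: synthesis (StAR,
P450scc, CYP17, 3bHSD1) -> conversion (SRD5A1, SRD5A2, AROM) -> receptors
(AR, ESR1, ESR2, GPER1), with the multi-functional 17bHSD isoforms handled
separately by clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from . import stats_enrichment

DEFAULT_STAGES: list[tuple[str, list[str]]] = [
    ("synthesis", ["StAR", "P450scc", "CYP17", "3bHSD1"]),
    ("conversion", ["SRD5A1", "SRD5A2", "AROM"]),
    ("receptor", ["AR", "ESR1", "ESR2", "GPER1"]),
]
DEFAULT_ISOFORMS = ["17bHSD1", "17bHSD2", "17bHSD4", "17bHSD7",
                    "17bHSD8", "17bHSD12", "17bHSD13"]
DEFAULT_SYNONYMS = {"AROM": "CYP19A1", "P450scc": "CYP11A1", "3bHSD1": "HSD3B1",
                    "StAR": "STAR", "CYP17": "CYP17A1"}


@dataclass
class PanelConfig:
    """Ordered pathway stages with their gene symbols, plus synonym map.

    Stage order is strict (synthesis before conversion before receptor
    binding); symbols must be unique across the panel.  Matching against
    expression indices is case-insensitive and consults ``synonyms`` in
    both directions.
    """

    stages: list[tuple[str, list[str]]] = field(
        default_factory=lambda: [(s, list(g)) for s, g in DEFAULT_STAGES])
    isoforms: list[str] = field(default_factory=lambda: list(DEFAULT_ISOFORMS))
    synonyms: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SYNONYMS))

    def __post_init__(self):
        symbols = [g for _, genes in self.stages for g in genes]
        if len(symbols) != len(set(symbols)):
            raise ValueError("duplicate gene symbols across panel stages")

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        stages = [(s["name"], list(s["genes"])) for s in data.get("stages", [])]
        if not stages:
            stages = [(s, list(g)) for s, g in DEFAULT_STAGES]
        return cls(stages=stages,
                   isoforms=list(data.get("isoforms", DEFAULT_ISOFORMS)),
                   synonyms=dict(data.get("synonyms", DEFAULT_SYNONYMS)))

    def candidates(self, symbol: str) -> set[str]:
        cands = {symbol}
        if symbol in self.synonyms:
            cands.add(self.synonyms[symbol])
        for k, v in self.synonyms.items():
            if v == symbol:
                cands.add(k)
        return {c.casefold() for c in cands}


@dataclass
class PanelReport:
    genes: pd.DataFrame        # per panel gene: stage, found, TPM, tau, ...
    stage_means: pd.DataFrame  # per stage: n found, mean tau


def _match(symbol: str, config: PanelConfig, index) -> str | None:
    folded = {str(g).casefold(): g for g in index}
    for cand in config.candidates(symbol):
        if cand in folded:
            return folded[cand]
    return None


def panel_profile(expr: pd.DataFrame, tau_records: pd.DataFrame,
                  config: PanelConfig | None = None) -> PanelReport:
    """Join expression and tau for every panel gene, stage by stage.

    Missing symbols are reported with ``found=False`` (never silently
    dropped); stage mean tau is computed over the genes actually found.
    """
    config = config or PanelConfig()
    rows = []
    for stage_idx, (stage, genes) in enumerate(config.stages):
        for symbol in genes:
            hit = _match(symbol, config, expr.index)
            row = {"stage": stage, "stage_index": stage_idx, "symbol": symbol,
                   "matched_id": hit, "found": hit is not None}
            if hit is not None:
                for tissue in expr.columns:
                    row[f"tpm_{tissue}"] = float(expr.at[hit, tissue])
                row["tau"] = float(tau_records.at[hit, "tau"])
                row["max_tissue"] = tau_records.at[hit, "max_tissue"]
            else:
                row["tau"] = np.nan
                row["max_tissue"] = ""
            rows.append(row)
    genes_df = pd.DataFrame(rows)
    stage_means = (genes_df[genes_df["found"]]
                   .groupby("stage", sort=False)
                   .agg(n_found=("symbol", "size"), mean_tau=("tau", "mean")))
    return PanelReport(genes=genes_df, stage_means=stage_means)


def stage_trend(report: PanelReport) -> tuple[float, float]:
    """Spearman correlation of pathway stage rank against per-gene tau.

    A negative rho means specificity decreases from synthesis toward
    receptor binding.  Propagates the constant-input error from
    :func:`tautx.stats_enrichment.spearman`.
    """
    found = report.genes[report.genes["found"]]
    if found["stage"].nunique() < 2:
        raise ValueError("need >= 2 stages with found genes")
    return stats_enrichment.spearman(found["stage_index"].to_numpy(dtype=float),
                                     found["tau"].to_numpy(dtype=float))


def cluster_isoforms(expr: pd.DataFrame, k: int = 2,
                     transform: str = "log2",
                     linkage_method: str = "complete",
                     ) -> tuple[dict[str, int], list[str]]:
    """Agglomerative clustering of isoform expression profiles.

    Euclidean distance on log2(TPM + 1) profiles (``transform="raw"`` uses
    TPM directly), complete linkage by default, cut into ``k`` clusters.
    Returns isoform -> cluster label (1-based) and the dendrogram leaf
    order.  Deterministic given the input row order.
    """
    if len(expr) < 2:
        raise ValueError("need at least 2 isoforms")
    if k > len(expr):
        raise ValueError(f"k={k} exceeds the {len(expr)} isoforms")
    mat = expr.to_numpy(dtype=float)
    if transform == "log2":
        mat = np.log2(mat + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    dists = pdist(mat, metric="euclidean")
    Z = linkage(dists, method=linkage_method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    order = [expr.index[i] for i in leaves_list(Z)]
    return dict(zip(expr.index, (int(c) for c in labels))), order
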