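"""Synthetic inputs with known ground truth.

Three generators cover everything the pipeline consumes:

* :func:`simulate_expression` — a 6-tissue count matrix with three gene
  classes (housekeeping, tissue-specific, intermediate) whose true
  tissue-specificity (tau) regime is known by construction;
* :func:`simulate_codon_alignment` — codon alignments evolved on a tagged
  tree under the four-class branch-site model, sharing the rate-matrix
  machinery of :mod:`tautx.selection`;
* :func:`simulate_blast_hits` — BLAST-like hit tables with bookkeeping of
  which hits pass an (identity, coverage, e-value) confidence filter.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PhyloTree, read_tree
from .selection import (CODONS, BranchSiteParams, CodonAlignment,
                        _Decomp, _role_scales, build_rate_matrix)

DEFAULT_TISSUES = ["brain", "blood", "ovary", "spleen", "liver", "muscle"]

#: symmetric 9-leaf fixture tree; the focal terminal branch carries the
#: foreground tag and is somewhat longer, as a focal lineage's often is.
FIXTURE_TREE_NEWICK = (
    "((((A#1:0.2,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.05,"
    "((E:0.1,F:0.1):0.05,(G:0.1,H:0.1):0.05):0.05):0.05,I:0.15);"
)


def fixture_tree() -> PhyloTree:
    return read_tree(FIXTURE_TREE_NEWICK)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimSpec:
    """Study conditions for the multi-tissue expression simulator.

    Class counts default to the 1,000-gene recovery experiment: 200
    housekeeping, 300 tissue-specific (50 per tissue), 500 intermediate.
    Expression locations are log-scale means of relative abundance;
    housekeeping genes sit higher than tissue-specific ones so that summed
    expression correlates negatively with specificity, as in real tissue
    panels.  ``dispersion`` is the negative-binomial alpha in
    var = mu + alpha * mu^2.
    """

    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    n_housekeeping: int = 200
    n_tissue_specific: int = 300
    n_intermediate: int = 500
    hk_log_loc: float = np.log(300.0)
    hk_log_scale: float = 0.6
    ts_log_loc: float = np.log(150.0)
    ts_log_scale: float = 0.9
    mid_log_loc: float = np.log(40.0)
    mid_log_scale: float = 0.8
    tissue_noise_sigma: float = 0.05
    dropout: float = 0.0
    #: off-target leak as an absolute relative abundance (same units as the
    #: class log-locations); ~0.2 TPM after per-tissue normalisation, i.e.
    #: well below the presence threshold of 1 TPM
    off_target_rel: float = 0.005
    dispersion: float = 0.01
    length_log_loc: float = np.log(1500.0)
    length_log_scale: float = 0.4
    library_size: int = 5_000_000
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_housekeeping + self.n_tissue_specific + self.n_intermediate <= 0:
            raise ValueError("zero total genes")
        if min(self.n_housekeeping, self.n_tissue_specific, self.n_intermediate) < 0:
            raise ValueError("class counts must be >= 0")
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError("dropout must be in [0, 1]")
        if min(self.hk_log_scale, self.ts_log_scale, self.mid_log_scale) <= 0:
            raise ValueError("log scales must be > 0")


@dataclass
class ExpressionSim:
    counts: pd.DataFrame
    lengths: pd.Series
    truth: pd.DataFrame
    true_tpm: pd.DataFrame


def simulate_expression(spec: ExpressionSimSpec) -> ExpressionSim:
    """Simulate counts, gene lengths, and a truth table.

    True TPM profiles are built per class (housekeeping near-uniform,
    tissue-specific one dominant tissue, intermediate a 2-4 tissue subset),
    each tissue column is normalised to sum to 1e6, and negative-binomial
    read counts are drawn proportional to TPM x length.  The truth table
    records class, target tissue and the true tau (floor 2) of the
    noise-free profile.
    """
    rng = np.random.default_rng(spec.rng_seed)
    tissues = list(spec.tissues)
    n_t = len(tissues)
    genes, classes, targets, rel_rows = [], [], [], []

    for g in range(spec.n_housekeeping):
        base = np.exp(rng.normal(spec.hk_log_loc, spec.hk_log_scale))
        row = base * np.exp(rng.normal(0.0, spec.tissue_noise_sigma, size=n_t))
        genes.append(f"hk_{g:04d}"); classes.append("housekeeping")
        targets.append(""); rel_rows.append(row)

    for g in range(spec.n_tissue_specific):
        target = g % n_t
        base = np.exp(rng.normal(spec.ts_log_loc, spec.ts_log_scale))
        row = np.full(n_t, spec.off_target_rel)
        drop = rng.random(n_t) < spec.dropout
        row[drop] = 0.0
        row[target] = base
        genes.append(f"ts_{g:04d}"); classes.append("tissue_specific")
        targets.append(tissues[target]); rel_rows.append(row)

    for g in range(spec.n_intermediate):
        k = rng.integers(2, min(4, n_t) + 1)
        on = rng.choice(n_t, size=k, replace=False)
        base = np.exp(rng.normal(spec.mid_log_loc, spec.mid_log_scale))
        row = np.full(n_t, spec.off_target_rel)
        row[on] = base * np.exp(rng.normal(0.0, 0.4, size=k))
        genes.append(f"mid_{g:04d}"); classes.append("intermediate")
        targets.append(tissues[int(on[0])]); rel_rows.append(row)

    rel = np.array(rel_rows)
    col = rel.sum(axis=0)
    if (col == 0).any():
        raise ValueError("a tissue column has zero total expression")
    true_tpm = rel / col * 1e6

    lengths = np.exp(rng.normal(spec.length_log_loc, spec.length_log_scale,
                                size=len(genes)))
    lengths = np.maximum(np.round(lengths), 300.0)

    # reads proportional to TPM x length, negative binomial around the mean
    weights = true_tpm * lengths[:, None]
    frac = weights / weights.sum(axis=0)
    mu = frac * spec.library_size
    if spec.dispersion > 0:
        size = 1.0 / spec.dispersion
        counts = rng.negative_binomial(size, size / (size + np.maximum(mu, 1e-12)))
    else:
        counts = rng.poisson(mu)

    from .specificity import compute_tau
    true_tau = np.array([compute_tau(row) for row in true_tpm])

    counts_df = pd.DataFrame(counts, index=genes, columns=tissues)
    truth = pd.DataFrame({
        "gene": genes, "gene_class": classes, "target_tissue": targets,
        "true_tau": true_tau,
        "expected_tpm_max": true_tpm.max(axis=1),
    }).set_index("gene")
    return ExpressionSim(
        counts=counts_df,
        lengths=pd.Series(lengths, index=genes, name="length"),
        truth=truth,
        true_tpm=pd.DataFrame(true_tpm, index=genes, columns=tissues),
    )


# ---------------------------------------------------------------------------
# codon alignments under the branch-site model
# ---------------------------------------------------------------------------

@dataclass
class CodonSimSpec:
    """Branch-site simulation conditions (see :class:`BranchSiteParams`)."""

    tree: PhyloTree
    kappa: float = 2.0
    omega0: float = 0.2
    omega2: float = 1.0
    p0: float = 0.45
    p1: float = 0.45
    pi: np.ndarray | None = None
    n_codons: int = 300
    rng_seed: int = 0

    def params(self) -> BranchSiteParams:
        pi = self.pi if self.pi is not None else default_codon_frequencies()
        return BranchSiteParams(kappa=self.kappa, omega0=self.omega0,
                                omega2=max(self.omega2, 1.0), p0=self.p0,
                                p1=self.p1, pi=pi)


def default_codon_frequencies(nt_freqs=(0.3, 0.2, 0.2, 0.3)) -> np.ndarray:
    """F1x4-style codon frequencies from nucleotide frequencies (A, C, G, T)."""
    f = dict(zip("ACGT", nt_freqs))
    pi = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in CODONS])
    return pi / pi.sum()


def simulate_codon_alignment(spec: CodonSimSpec) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve a gap-free codon alignment under the branch-site model.

    Per site a class is drawn from (p0, p1, p2a, p2b); the root codon comes
    from pi and each branch applies exp(Q t) with the branch's
    class-and-role-appropriate omega.  Matrices share the joint per-role
    scaling of the likelihood code, so simulated branch lengths mean what
    the inference assumes.  Returns the alignment and true site classes.
    """
    rng = np.random.default_rng(spec.rng_seed)
    params = spec.params()
    if (params.pi <= 0).any():
        raise ValueError("pi must be strictly positive for simulation")
    tree = spec.tree
    null = spec.omega2 <= 1.0
    # omega2 < 1 would silently change meaning; the spec of the model keeps
    # class-2 foreground omega >= 1
    omegas = params.class_omegas(null=False) if not null else params.class_omegas(null=True)
    s_bg, s_fg = _role_scales(params, null)
    distinct = sorted({w for pair in omegas for w in pair})
    decomps = {w: _Decomp(build_rate_matrix(params.kappa, w, params.pi), params.pi)
               for w in distinct}

    n = spec.n_codons
    site_class = rng.choice(4, size=n, p=params.proportions)
    states = np.empty((tree.n_nodes, n), dtype=np.int64)
    # root draw from pi
    states[tree.root] = rng.choice(61, size=n, p=params.pi)

    order = [i for i in reversed(tree.postorder()) if i != tree.root]
    for node in order:
        parent_states = states[tree.parent[node]]
        role_fg = tree.foreground[node]
        scale = s_fg if role_fg else s_bg
        t = tree.lengths[node] / scale
        child = np.empty(n, dtype=np.int64)
        for c in range(4):
            mask = site_class == c
            if not mask.any():
                continue
            w = omegas[c][1] if role_fg else omegas[c][0]
            p = decomps[w].transition(t)
            cum = p.cumsum(axis=1)
            u = rng.random(mask.sum())
            rows = cum[parent_states[mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[node] = np.clip(child, 0, 60)

    leaves = [i for i in range(tree.n_nodes) if tree.is_leaf(i)]
    ids = [tree.labels[i] for i in leaves]
    seqs = ["".join(CODONS[s] for s in states[i]) for i in leaves]
    return CodonAlignment(ids, seqs), site_class


# ---------------------------------------------------------------------------
# BLAST-like hit tables
# ---------------------------------------------------------------------------

def simulate_blast_hits(n_queries: int, rng_seed: int,
                        good_fraction: float = 0.6,
                        good_identity: tuple[float, float] = (88.0, 6.0),
                        poor_identity: tuple[float, float] = (55.0, 8.0),
                        good_coverage: tuple[float, float] = (8.0, 2.0),
                        poor_coverage: tuple[float, float] = (2.0, 4.0),
                        identity_min: float = 70.0,
                        coverage_min: float = 0.5,
                        evalue_max: float = 1e-10,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an outfmt-6-style hit table with filter-truth bookkeeping.

    ``good_fraction`` of queries get a confident best hit (normal identity,
    Beta coverage, tiny e-value); the rest get marginal hits.  The truth
    table records, per hit, identity/coverage/e-value and whether it passes
    the (identity_min, coverage_min, evalue_max) confidence filter, so the
    expected retained count under any threshold is recomputable.
    """
    rng = np.random.default_rng(rng_seed)
    rows, truth = [], []
    for q in range(n_queries):
        qid = f"tx_{q:05d}"
        good = rng.random() < good_fraction
        n_hits = int(rng.integers(1, 4))
        for h in range(n_hits):
            if good and h == 0:
                ident = float(np.clip(rng.normal(*good_identity), 0, 100))
                cov = float(np.clip(rng.beta(*good_coverage), 0, 1))
                evalue = float(10.0 ** rng.uniform(-180, -15))
            else:
                ident = float(np.clip(rng.normal(*poor_identity), 0, 100))
                cov = float(np.clip(rng.beta(*poor_coverage), 0, 1))
                evalue = float(10.0 ** rng.uniform(-12, -2))
            slen = int(rng.integers(150, 1200))
            alen = max(int(round(cov * slen)), 1)
            cov = alen / slen
            ident = round(ident, 2)  # table precision; truth must match it
            mism = int(round(alen * (1 - ident / 100)))
            sid = f"prot_{q:05d}_{h}"
            bits = max(30.0, 2.0 * alen * ident / 100.0)
            rows.append((qid, sid, ident, alen, mism, 0,
                         1, alen, 1, alen, evalue, round(bits, 1), slen,
                         f"GENE{q:05d}", alen / slen))
            truth.append((qid, sid, ident, cov, evalue,
                          (ident >= identity_min and cov >= coverage_min
                           and evalue < evalue_max)))
    from .io_formats import BLAST_COLUMNS
    hits = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    truth_df = pd.DataFrame(truth, columns=[
        "query_id", "subject_id", "identity", "coverage", "e_value", "passes"])
    return hits, truth_df
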