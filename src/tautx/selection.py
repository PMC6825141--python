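"""Orthology clustering and the branch-site positive-selection scan.

The substantive pieces live here:

* a Markov-cluster (MCL) implementation over all-vs-all similarity graphs,
  with the single-copy filter used to pick testable ortholog groups;
* GBlocks-style codon-column masking of alignments;
* a GY94-style codon substitution model with the four-class branch-site
  parameterisation (site classes 0, 1, 2a, 2b; one foreground branch whose
  class-2 sites evolve under a free omega2 >= 1), Felsenstein pruning over
  the 61 sense codons, and the likelihood-ratio test of omega2 > 1 against
  the null with omega2 pinned at 1.

Rate matrices q_ij are zero for multi-nucleotide changes and otherwise
pi_j, kappa*pi_j, omega*pi_j or omega*kappa*pi_j for synonymous
transversions/transitions and nonsynonymous transversions/transitions.
Per branch role (foreground or background) the class matrices are jointly
rescaled so the class-proportion-weighted mean substitution rate at
stationarity is one; branch lengths are therefore expected substitutions
per codon averaged over site classes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .io_formats import PhyloTree, SequenceSet

logger = logging.getLogger("tautx")

# ---------------------------------------------------------------------------
# genetic code
# ---------------------------------------------------------------------------

from Bio.Data import CodonTable as _CodonTable

_STANDARD = _CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))
#: the 61 sense codons of the standard genetic code, alphabetical
CODONS = tuple(sorted(c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
                      if c not in STOP_CODONS))
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO_ACIDS = tuple(_STANDARD.forward_table[c] for c in CODONS)

_PURINES = frozenset("AG")


def _single_nt_pairs():
    """(i, j, is_transition, is_synonymous) for codon pairs one change apart."""
    pairs = []
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            if i >= j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            x, y = diffs[0]
            is_ts = (x in _PURINES) == (y in _PURINES)
            pairs.append((i, j, is_ts, AMINO_ACIDS[i] == AMINO_ACIDS[j]))
    return pairs

_PAIRS = _single_nt_pairs()


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 instantaneous rate matrix over the 61 sense codons (unscaled).

    Rows sum to zero and the matrix is reversible with respect to ``pi``.
    """
    q = np.zeros((61, 61))
    for i, j, is_ts, is_syn in _PAIRS:
        rate = (kappa if is_ts else 1.0) * (1.0 if is_syn else omega)
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per unit time at stationarity."""
    return float(-(pi * np.diag(q)).sum())


class _Decomp:
    """Symmetric eigendecomposition of a reversible Q; P(t) = A e^{wt} B."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        d = np.sqrt(pi)
        s = (q * d[:, None]) / d[None, :]
        w, u = np.linalg.eigh((s + s.T) / 2.0)
        self.w = w
        self.a = u / d[:, None]
        self.b = u.T * d[None, :]

    def transition(self, t: float) -> np.ndarray:
        p = (self.a * np.exp(self.w * t)[None, :]) @ self.b
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

class CodonAlignment:
    """An in-frame codon alignment: equal-length rows, length divisible by 3.

    A codon containing a gap or ambiguity character is treated as missing
    data in the likelihood; internal stop codons in ungapped positions are
    rejected.
    """

    def __init__(self, ids: list[str], seqs: list[str]):
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate taxon ids in alignment")
        if not ids:
            raise ValueError("empty alignment")
        seqs = [s.upper() for s in seqs]
        length = len(seqs[0])
        if any(len(s) != length for s in seqs):
            raise ValueError("alignment rows differ in length")
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} not divisible by 3")
        for tid, s in zip(ids, seqs):
            for k in range(0, length, 3):
                codon = s[k:k + 3]
                if set(codon) <= set("ACGT") and codon in STOP_CODONS:
                    raise ValueError(
                        f"stop codon {codon} at codon position {k // 3 + 1} in {tid!r}")
        self.ids = list(ids)
        self.seqs = list(seqs)

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_sequence_set(cls, seqs: SequenceSet) -> "CodonAlignment":
        items = list(seqs)
        return cls([i for i, _ in items], [s for _, s in items])

    def to_sequence_set(self) -> SequenceSet:
        return SequenceSet(zip(self.ids, self.seqs), alphabet="nucleotide")

    def encode(self, taxon_order: list[str] | None = None) -> np.ndarray:
        """Codon-state matrix (taxa x sites); -1 marks missing data."""
        order = taxon_order if taxon_order is not None else self.ids
        lookup = {t: s for t, s in zip(self.ids, self.seqs)}
        out = np.full((len(order), self.n_codons), -1, dtype=np.int64)
        for r, taxon in enumerate(order):
            s = lookup[taxon]
            for k in range(self.n_codons):
                out[r, k] = CODON_INDEX.get(s[3 * k:3 * k + 3], -1)
        return out

    def gap_fraction_per_codon(self) -> np.ndarray:
        """Fraction of rows whose codon at each site contains a non-ACGT char."""
        arr = self.encode()
        return (arr < 0).mean(axis=0)


def mask_alignment(aln: CodonAlignment, max_gap_fraction: float = 0.0,
                   min_block_codons: int = 5) -> CodonAlignment:
    """Remove gap-ridden codon columns and short surviving blocks.

    A codon column is dropped when its gap fraction exceeds
    ``max_gap_fraction``; runs of surviving columns shorter than
    ``min_block_codons`` are then dropped too (GBlocks-style).
    """
    frac = aln.gap_fraction_per_codon()
    keep = frac <= max_gap_fraction
    # drop surviving runs shorter than the block minimum
    kept_cols: list[int] = []
    run: list[int] = []
    for k in range(aln.n_codons + 1):
        if k < aln.n_codons and keep[k]:
            run.append(k)
        else:
            if len(run) >= min_block_codons:
                kept_cols.extend(run)
            run = []
    if not kept_cols:
        raise ValueError("no columns survive masking")
    new_seqs = ["".join(s[3 * k:3 * k + 3] for k in kept_cols) for s in aln.seqs]
    return CodonAlignment(aln.ids, new_seqs)


# ---------------------------------------------------------------------------
# similarity graph, MCL, single-copy filter
# ---------------------------------------------------------------------------

#: cap on -log10(e-value) similarity weights (e-value 0 convention)
WEIGHT_CAP = 200.0


class SimilarityGraph:
    """Undirected weighted graph over (species, gene) nodes."""

    def __init__(self):
        self.nodes: set = set()
        self._edges: dict[tuple, float] = {}

    def add_node(self, node) -> None:
        self.nodes.add(node)

    def add_edge(self, u, v, weight: float) -> None:
        if u == v:
            raise ValueError("self-edges are not stored")
        if weight <= 0:
            raise ValueError("edge weights must be > 0")
        self.nodes.update((u, v))
        key = (u, v) if repr(u) <= repr(v) else (v, u)
        self._edges[key] = max(self._edges.get(key, 0.0), float(weight))

    def edges(self):
        return [(u, v, w) for (u, v), w in self._edges.items()]

    @classmethod
    def from_evalues(cls, triples, cap: float = WEIGHT_CAP) -> "SimilarityGraph":
        """Build from (node_a, node_b, e_value) triples; weight = -log10(e)."""
        g = cls()
        for u, v, e in triples:
            if u == v:
                continue
            w = cap if e <= 0 else min(cap, -math.log10(e))
            if w > 0:
                g.add_edge(u, v, w)
        return g


def mcl_cluster(graph: SimilarityGraph, inflation: float = 1.5,
                prune: float = 1e-5, max_iter: int = 100,
                tol: float = 1e-6) -> dict[int, list]:
    """Canonical Markov clustering on a weighted similarity graph.

    Self-loops are added with each node's maximum incident weight; the
    column-stochastic matrix is alternately squared (expansion) and raised
    elementwise to ``inflation`` (with pruning and renormalisation) until
    the maximum entry change falls below ``tol``.  Clusters are the node
    sets sharing attractors.  The result is invariant to node input order
    (nodes are sorted internally).
    """
    nodes = sorted(graph.nodes, key=repr)
    if not nodes:
        return {}
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = np.zeros((n, n))
    for u, v, w in graph.edges():
        m[idx[u], idx[v]] = w
        m[idx[v], idx[u]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    np.fill_diagonal(m, loop)
    m /= m.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0
        if dead.any():                 # revive emptied columns as self-loops
            m[np.where(dead)[0], np.where(dead)[0]] = 1.0
            colsum = m.sum(axis=0, keepdims=True)
        m /= colsum
        if np.abs(m - prev).max() < tol:
            break

    # attractors = rows with mass on the diagonal; merge overlapping supports
    attractors = np.where(np.diag(m) > 1e-8)[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for a in attractors:
        members = np.where(m[a] > 1e-8)[0]
        for b in members:
            union(a, b)
    groups: dict[int, list] = {}
    roots: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        gid = roots.setdefault(r, len(roots))
        groups.setdefault(gid, []).append(nodes[i])
    return groups


def single_copy_filter(groups: dict[int, list], required_species) -> dict[int, list]:
    """Keep groups with exactly one member per required species, no extras.

    Members are (species, gene) pairs.
    """
    required = list(required_species)
    if not required:
        raise ValueError("required species list is empty")
    req = set(required)
    kept = {}
    for gid, members in groups.items():
        species = [m[0] for m in members]
        if set(species) == req and len(species) == len(req):
            kept[gid] = members
    return kept


# ---------------------------------------------------------------------------
# branch-site model
# ---------------------------------------------------------------------------

@dataclass
class BranchSiteParams:
    """Parameters of the four-class branch-site model.

    ``p0``/``p1`` are the conserved and neutral class proportions; classes
    2a and 2b inherit the remainder split as p2a = (1-p0-p1)*p0/(p0+p1)
    and p2b likewise with p1.  ``omega2`` applies on the foreground branch
    for classes 2a/2b (fixed at 1 under the null).
    """

    kappa: float
    omega0: float
    omega2: float
    p0: float
    p1: float
    pi: np.ndarray

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if not 0 < self.omega0 <= 1:
            raise ValueError("omega0 must be in (0, 1]")
        if self.omega2 < 1:
            raise ValueError("omega2 must be >= 1")
        if self.p0 < 0 or self.p1 < 0 or self.p0 + self.p1 > 1 + 1e-12:
            raise ValueError("require p0, p1 >= 0 and p0 + p1 <= 1")
        if self.p0 + self.p1 <= 0:
            raise ValueError("p0 + p1 must be > 0")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (61,):
            raise ValueError("pi must have one entry per sense codon (61)")
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a distribution over the 61 sense codons")

    @property
    def proportions(self) -> np.ndarray:
        p2 = max(1.0 - self.p0 - self.p1, 0.0)  # guard float cancellation
        s = self.p0 + self.p1
        props = np.array([self.p0, self.p1, p2 * self.p0 / s, p2 * self.p1 / s])
        return props / props.sum()

    def class_omegas(self, null: bool) -> list[tuple[float, float]]:
        """(background, foreground) omega per site class 0, 1, 2a, 2b."""
        w2 = 1.0 if null else self.omega2
        return [(self.omega0, self.omega0), (1.0, 1.0),
                (self.omega0, w2), (1.0, w2)]


def _role_scales(params: BranchSiteParams, null: bool) -> tuple[float, float]:
    """Per-role joint scale: proportion-weighted mean rate at stationarity."""
    props = params.proportions
    rates = {}
    def rate(w):
        if w not in rates:
            rates[w] = stationary_rate(build_rate_matrix(params.kappa, w, params.pi), params.pi)
        return rates[w]
    omegas = params.class_omegas(null)
    s_bg = sum(p * rate(w_bg) for p, (w_bg, _) in zip(props, omegas))
    s_fg = sum(p * rate(w_fg) for p, (_, w_fg) in zip(props, omegas))
    return s_bg, s_fg


def estimate_codon_frequencies(aln: CodonAlignment, mode: str = "F1x4") -> np.ndarray:
    """Empirical codon frequencies: ``equal``, ``F1x4`` or ``F3x4``."""
    if mode == "equal":
        return np.full(61, 1.0 / 61)
    counts = np.zeros((3, 4)) + 0.5  # pseudocount keeps pi strictly positive
    nt_index = {c: i for i, c in enumerate("ACGT")}
    for s in aln.seqs:
        for k in range(0, len(s), 3):
            codon = s[k:k + 3]
            if set(codon) <= set("ACGT"):
                for pos, c in enumerate(codon):
                    counts[pos, nt_index[c]] += 1
    if mode == "F1x4":
        f = counts.sum(axis=0)
        f /= f.sum()
        pi = np.array([f[nt_index[c[0]]] * f[nt_index[c[1]]] * f[nt_index[c[2]]]
                       for c in CODONS])
    elif mode == "F3x4":
        f = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array([f[0, nt_index[c[0]]] * f[1, nt_index[c[1]]] * f[2, nt_index[c[2]]]
                       for c in CODONS])
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")
    return pi / pi.sum()


def _encode_patterns(aln: CodonAlignment, tree: PhyloTree):
    """Compress the alignment to unique site patterns in tree-leaf order."""
    leaf_nodes = [i for i in range(tree.n_nodes) if tree.is_leaf(i)]
    leaf_labels = [tree.labels[i] for i in leaf_nodes]
    if set(leaf_labels) != set(aln.ids):
        raise ValueError(
            f"taxon mismatch: tree has {sorted(leaf_labels)}, "
            f"alignment has {sorted(aln.ids)}")
    states = aln.encode(leaf_labels)
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return leaf_nodes, patterns, counts


def branch_site_lnL(aln: CodonAlignment, tree: PhyloTree,
                    params: BranchSiteParams, null: bool = False,
                    lengths_override: np.ndarray | None = None,
                    _patterns=None) -> float:
    """Log-likelihood of the alignment under the branch-site model.

    Felsenstein pruning over the 61 sense codons, run jointly over the four
    site classes (stacked matmuls) and mixed with the class proportions.
    Gapped/ambiguous codons contribute unit partial likelihoods (missing
    data).  ``_patterns`` lets a repeated caller reuse the compressed site
    patterns.
    """
    if tree.foreground_node() is None:
        raise ValueError("tree has no '#1' foreground branch")
    leaf_nodes, patterns, counts = (_patterns if _patterns is not None
                                    else _encode_patterns(aln, tree))
    npat = patterns.shape[1]
    leaf_pattern = {node: patterns[r] for r, node in enumerate(leaf_nodes)}

    lengths = np.asarray(lengths_override if lengths_override is not None
                         else tree.lengths, dtype=float)
    s_bg, s_fg = _role_scales(params, null)
    omegas = params.class_omegas(null)
    distinct = sorted({w for pair in omegas for w in pair})
    decomps = {w: _Decomp(build_rate_matrix(params.kappa, w, params.pi), params.pi)
               for w in distinct}

    pmats: dict[tuple[float, int], np.ndarray] = {}

    def pstack(child: int) -> np.ndarray:
        """(4, 61, 61) transition matrices for the branch above ``child``."""
        fg = tree.foreground[child]
        scale = s_fg if fg else s_bg
        mats = []
        for w_bg, w_fg in omegas:
            w = w_fg if fg else w_bg
            key = (w, child)
            if key not in pmats:
                pmats[key] = decomps[w].transition(lengths[child] / scale)
            mats.append(pmats[key])
        return np.stack(mats)

    partial: dict[int, np.ndarray] = {}   # node -> (4, 61, npat)
    logscale = np.zeros((4, npat))
    for node in tree.postorder():
        if tree.is_leaf(node):
            continue
        part = np.ones((4, 61, npat))
        for child in tree.children[node]:
            p = pstack(child)
            if tree.is_leaf(child):
                obs = leaf_pattern[child]
                contrib = np.ones((4, 61, npat))
                seen = obs >= 0
                contrib[:, :, seen] = p[:, :, obs[seen]]
            else:
                contrib = p @ partial.pop(child)
            part *= contrib
        m = part.max(axis=1)
        if not np.all(m > 0):
            bad = int(np.argmin(m.min(axis=0)))
            raise ValueError(f"vanishing likelihood at site pattern {bad}")
        part /= m[:, None, :]
        logscale += np.log(m)
        partial[node] = part

    site = np.einsum("j,cjp->cp", params.pi, partial[tree.root])
    class_logs = np.log(site) + logscale
    props = params.proportions
    mx = class_logs.max(axis=0)
    site_log = mx + np.log((props[:, None] * np.exp(class_logs - mx)).sum(axis=0))
    total = float((counts * site_log).sum())
    if not np.isfinite(total):
        bad = int(np.argmax(~np.isfinite(site_log)))
        raise ValueError(f"non-finite likelihood at site pattern {bad}")
    return total


# ---------------------------------------------------------------------------
# maximum likelihood fitting and the LRT
# ---------------------------------------------------------------------------

@dataclass
class OptimizerSettings:
    """Knobs for the branch-site maximum-likelihood fits.

    ``branch_mode`` ``"scale"`` optimises one multiplicative factor on the
    input branch lengths per hypothesis; ``"free"`` optimises every branch
    length.  ``p_reference`` ``"chi2"`` is the conservative chi-square(1)
    reference; ``"mixture"`` uses the half-and-half boundary mixture.
    """

    n_restarts: int = 3
    seed: int = 0
    branch_mode: str = "scale"
    freq_mode: str = "F1x4"
    p_reference: str = "chi2"
    maxiter: int = 200


@dataclass
class BranchSiteResult:
    gene_id: str
    lnl_null: float
    lnl_alt: float
    lrt: float
    p_value: float
    params_null: dict
    params_alt: dict
    converged: bool
    message: str = ""


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


class _Problem:
    """Packs/unpacks transformed parameters and evaluates -lnL."""

    def __init__(self, aln, tree, pi, null, settings):
        self.aln, self.tree, self.pi = aln, tree, pi
        self.null = null
        self.mode = settings.branch_mode
        self.base_lengths = np.asarray(tree.lengths, dtype=float)
        self.free_idx = [i for i in range(tree.n_nodes) if tree.parent[i] >= 0]
        self.maxiter = settings.maxiter
        self.patterns = _encode_patterns(aln, tree)

    # layout: [log kappa, logit w0, logit s, logit f, (log(w2-1)), branch...]
    def n_core(self) -> int:
        return 4 if self.null else 5

    def start(self) -> np.ndarray:
        core = [math.log(2.0), _logit(0.3), _logit(0.85), _logit(0.55)]
        if not self.null:
            core.append(0.0)  # omega2 = 2
        if self.mode == "scale":
            branch = [0.0]
        else:
            branch = list(np.log(np.maximum(self.base_lengths[self.free_idx], 1e-4)))
        return np.array(core + branch)

    def unpack(self, x: np.ndarray) -> tuple[BranchSiteParams, np.ndarray]:
        kappa = math.exp(x[0])
        omega0 = float(_sigmoid(x[1]))
        s = float(_sigmoid(x[2]))
        f = float(_sigmoid(x[3]))
        p0, p1 = s * f, s * (1 - f)
        omega2 = 1.0 if self.null else 1.0 + math.exp(np.clip(x[4], -30, 30))
        params = BranchSiteParams(kappa=kappa, omega0=omega0, omega2=omega2,
                                  p0=p0, p1=p1, pi=self.pi)
        lengths = self.base_lengths.copy()
        k = self.n_core()
        if self.mode == "scale":
            lengths = lengths * math.exp(x[k])
        else:
            lengths[self.free_idx] = np.exp(x[k:])
        return params, lengths

    def objective(self, x: np.ndarray) -> float:
        try:
            params, lengths = self.unpack(x)
            return -branch_site_lnL(self.aln, self.tree, params,
                                    null=self.null, lengths_override=lengths,
                                    _patterns=self.patterns)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    def bounds(self):
        k = self.n_core()
        nb = 1 if self.mode == "scale" else len(self.free_idx)
        core = [(-5, 5), (-12, 12), (-12, 12), (-12, 12)]
        if not self.null:
            core.append((-12.0, 6.0))
        return core + [(-8.0, 5.0)] * nb


def _fit(problem: _Problem, rng: np.random.Generator, n_restarts: int,
         warm: tuple[np.ndarray, np.ndarray] | None = None):
    """Minimise -lnL from several seeded starts; returns the best result.

    ``warm`` carries (core-4 block, branch block) from a previous fit of
    the other hypothesis and is tried in addition to the default starts.
    """
    starts = [problem.start()]
    if warm is not None:
        w = problem.start()
        core, branch = warm
        w[:4] = core
        w[problem.n_core():] = branch
        starts.insert(0, w)
    while len(starts) < n_restarts + (warm is not None):
        starts.append(problem.start() + rng.normal(0.0, 0.7, size=len(problem.start())))
    best = None
    for x0 in starts:
        res = minimize(problem.objective, x0, method="L-BFGS-B",
                       bounds=problem.bounds(),
                       options={"maxiter": problem.maxiter, "ftol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    return best


def branch_site_test(aln: CodonAlignment, tree: PhyloTree,
                     settings: OptimizerSettings | None = None,
                     gene_id: str = "") -> BranchSiteResult:
    """Likelihood-ratio test for positive selection on the foreground branch.

    Fits the alternative (omega2 free, >= 1) and the null (omega2 = 1) by
    bounded quasi-Newton optimisation on transformed parameters, with
    seeded restarts; LRT = 2 * (lnL_alt - lnL_null), clamped at zero, with
    the p-value from the configured reference distribution.
    """
    settings = settings or OptimizerSettings()
    rng = np.random.default_rng(settings.seed)
    pi = estimate_codon_frequencies(aln, settings.freq_mode)

    prob0 = _Problem(aln, tree, pi, True, settings)
    res0 = _fit(prob0, rng, settings.n_restarts)
    prob1 = _Problem(aln, tree, pi, False, settings)
    res1 = _fit(prob1, rng, settings.n_restarts,
                warm=(res0.x[:4], res0.x[prob0.n_core():]))

    lnl0, lnl1 = -res0.fun, -res1.fun
    lrt = 2.0 * (lnl1 - lnl0)
    converged = bool(res0.success and res1.success) and lrt > -1e-4
    lrt = max(lrt, 0.0)
    if settings.p_reference == "mixture":
        p = 1.0 if lrt <= 0 else 0.5 * float(chi2.sf(lrt, 1))
    else:
        p = float(chi2.sf(lrt, 1))

    def summarize(prob, res):
        params, lengths = prob.unpack(res.x)
        return {"kappa": params.kappa, "omega0": params.omega0,
                "omega2": params.omega2, "p0": params.p0, "p1": params.p1,
                "tree_length": float(lengths[np.asarray(prob.free_idx)].sum())}

    return BranchSiteResult(
        gene_id=gene_id, lnl_null=lnl0, lnl_alt=lnl1, lrt=lrt, p_value=p,
        params_null=summarize(prob0, res0), params_alt=summarize(prob1, res1),
        converged=converged,
        message="" if converged else "optimizer did not report convergence")


def selection_scan(alignments: dict[str, dict[str, CodonAlignment]],
                   trees: dict[str, PhyloTree],
                   settings: OptimizerSettings | None = None,
                   fdr: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Run the branch-site test per gene under each aligner variant.

    ``alignments`` maps variant name -> gene -> masked alignment; every
    gene needs an entry under every variant and a tagged tree, otherwise it
    is excluded (and logged).  Significance is assessed per variant after
    Benjamini-Hochberg correction; the final list is the intersection of
    the per-variant significant sets.
    """
    from statsmodels.stats.multitest import multipletests

    settings = settings or OptimizerSettings()
    variants = sorted(alignments)
    if not variants:
        return [], pd.DataFrame()
    genes = sorted(set.intersection(*(set(alignments[v]) for v in variants)) & set(trees))
    for v in variants:
        for g in sorted(set(alignments[v]) - set(genes)):
            logger.warning("gene %s excluded: missing an aligner variant or tree", g)

    rows = []
    for v in variants:
        results = [branch_site_test(alignments[v][g], trees[g], settings, gene_id=g)
                   for g in genes]
        pvals = [r.p_value for r in results]
        if pvals:
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        else:
            qvals = []
        for r, q in zip(results, qvals):
            rows.append({"gene": r.gene_id, "variant": v, "lnl_null": r.lnl_null,
                         "lnl_alt": r.lnl_alt, "lrt": r.lrt, "p": r.p_value,
                         "q": q, "omega2": r.params_alt["omega2"],
                         "converged": r.converged})
    table = pd.DataFrame(rows)
    sig_sets = [set(table[(table["variant"] == v) & (table["q"] < fdr)]["gene"])
                for v in variants]
    final = sorted(set.intersection(*sig_sets)) if sig_sets else []
    return final, table
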