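import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from tautx import read_tree
from tautx import selection as sel
from tautx.synthetic_data import (CodonSimSpec, default_codon_frequencies,
                                  simulate_codon_alignment)


# ---------------------------------------------------------------------------
# exhaustive likelihood oracle
# ---------------------------------------------------------------------------

def exhaustive_branch_site_lnl(aln, tree, params, null):
    """Independent oracle: marginalise the explicit joint distribution over
    all internal-node codon assignments (materialised as a full array),
    with transition matrices from scipy's expm."""
    pi = params.pi
    omegas = params.class_omegas(null)
    props = params.proportions
    s_bg, s_fg = sel._role_scales(params, null)
    leaves = [i for i in range(tree.n_nodes) if tree.is_leaf(i)]
    internals = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    axis = {n: k for k, n in enumerate(internals)}
    states = aln.encode([tree.labels[i] for i in leaves])

    total = 0.0
    for site in range(aln.n_codons):
        site_lik = 0.0
        for c, (w_bg, w_fg) in enumerate(omegas):
            P = {}
            for node in range(tree.n_nodes):
                if tree.parent[node] < 0:
                    continue
                w = w_fg if tree.foreground[node] else w_bg
                s = s_fg if tree.foreground[node] else s_bg
                q = sel.build_rate_matrix(params.kappa, w, pi)
                P[node] = expm(q * tree.lengths[node] / s)
            # joint over all internal assignments
            shape = [1] * len(internals)
            shape[axis[tree.root]] = 61
            joint = pi.reshape(shape).copy()
            joint = np.broadcast_to(joint, (61,) * len(internals)).copy()
            for node in range(tree.n_nodes):
                p = tree.parent[node]
                if p < 0:
                    continue
                if tree.is_leaf(node):
                    obs = states[leaves.index(node), site]
                    vec = np.ones(61) if obs < 0 else P[node][:, obs]
                    shape = [1] * len(internals)
                    shape[axis[p]] = 61
                    joint = joint * vec.reshape(shape)
                else:
                    mat_shape = [1] * len(internals)
                    mat_shape[axis[p]] = 61
                    mat_shape[axis[node]] = 61
                    mat = P[node]
                    if axis[p] > axis[node]:
                        mat = mat.T
                    joint = joint * mat.reshape(mat_shape)
            site_lik += props[c] * joint.sum()
        total += np.log(site_lik)
    return total


def _random_params(rng):
    return sel.BranchSiteParams(
        kappa=float(rng.uniform(1.0, 4.0)),
        omega0=float(rng.uniform(0.05, 0.9)),
        omega2=float(rng.uniform(1.0, 6.0)),
        p0=float(rng.uniform(0.2, 0.6)),
        p1=float(rng.uniform(0.1, 0.35)),
        pi=default_codon_frequencies(tuple(rng.dirichlet([10, 10, 10, 10]))))


def test_pruning_matches_exhaustive_enumeration(three_taxon_tree):
    """>= 20 random parameter draws on 3- and 4-taxon trees, <= 10 codons."""
    four_taxon = read_tree("((A#1:0.15,B:0.1):0.05,(C:0.2,D:0.1):0.08);")
    rng = np.random.default_rng(99)
    for draw in range(22):
        tree = three_taxon_tree if draw % 3 else four_taxon
        params = _random_params(rng)
        spec = CodonSimSpec(tree=tree, n_codons=int(rng.integers(3, 11)),
                            rng_seed=int(rng.integers(2 ** 31)),
                            kappa=params.kappa, omega0=params.omega0,
                            omega2=params.omega2, p0=params.p0, p1=params.p1,
                            pi=params.pi)
        aln, _ = simulate_codon_alignment(spec)
        for null in (True, False):
            got = sel.branch_site_lnL(aln, tree, params, null=null)
            want = exhaustive_branch_site_lnl(aln, tree, params, null)
            assert abs(got - want) < 1e-8


def test_missing_data_codons_are_marginalised(three_taxon_tree):
    aln = sel.CodonAlignment(["A", "B", "C"],
                             ["ATG---AAA", "ATGCCTAAA", "ATGCCT---"])
    params = _random_params(np.random.default_rng(1))
    got = sel.branch_site_lnL(aln, three_taxon_tree, params, null=False)
    want = exhaustive_branch_site_lnl(aln, three_taxon_tree, params, False)
    assert abs(got - want) < 1e-8


def test_zero_branch_lengths_identical_sequences_give_pi():
    """All branch lengths 0 with identical sequences: per-site likelihood is
    pi of the observed codon."""
    tree = read_tree("((A#1:0.0,B:0.0):0.0,C:0.0);")
    seq = "ATGAAACCT"
    aln = sel.CodonAlignment(["A", "B", "C"], [seq] * 3)
    params = _random_params(np.random.default_rng(2))
    lnl = sel.branch_site_lnL(aln, tree, params, null=False)
    codons = [seq[k:k + 3] for k in range(0, 9, 3)]
    expected = sum(np.log(params.pi[sel.CODON_INDEX[c]]) for c in codons)
    assert lnl == pytest.approx(expected, abs=1e-10)


def test_single_class_collapses_to_plain_omega_model(three_taxon_tree):
    """p0 -> 1: the mixture equals an independent single-matrix pruning."""
    pi = default_codon_frequencies()
    params = sel.BranchSiteParams(kappa=2.5, omega0=0.4, omega2=3.0,
                                  p0=1.0 - 1e-12, p1=1e-12, pi=pi)
    spec = CodonSimSpec(tree=three_taxon_tree, n_codons=30, rng_seed=7,
                        omega0=0.4)
    aln, _ = simulate_codon_alignment(spec)
    got = sel.branch_site_lnL(aln, three_taxon_tree, params, null=True)

    # independent single-omega implementation (explicit pruning, expm)
    q = sel.build_rate_matrix(2.5, 0.4, pi)
    q /= sel.stationary_rate(q, pi)
    tree = three_taxon_tree
    leaves = [i for i in range(tree.n_nodes) if tree.is_leaf(i)]
    states = aln.encode([tree.labels[i] for i in leaves])
    P = {n: expm(q * tree.lengths[n]) for n in range(tree.n_nodes)
         if tree.parent[n] >= 0}
    want = 0.0
    for site in range(aln.n_codons):
        part = {}
        for node in tree.postorder():
            if tree.is_leaf(node):
                part[node] = P[node][:, states[leaves.index(node), site]]
            else:
                vec = np.ones(61)
                for ch in tree.children[node]:
                    vec = vec * part[ch]
                part[node] = P[node] @ vec if tree.parent[node] >= 0 else vec
        want += np.log(pi @ part[tree.root])
    assert got == pytest.approx(want, abs=1e-8)


def test_taxon_mismatch_rejected(three_taxon_tree):
    aln = sel.CodonAlignment(["A", "B", "X"], ["ATG"] * 3)
    params = _random_params(np.random.default_rng(3))
    with pytest.raises(ValueError, match="mismatch"):
        sel.branch_site_lnL(aln, three_taxon_tree, params)


# ---------------------------------------------------------------------------
# rate-matrix invariants
# ---------------------------------------------------------------------------

def test_rate_matrix_detailed_balance_and_zero_rowsums():
    pi = default_codon_frequencies((0.35, 0.15, 0.2, 0.3))
    q = sel.build_rate_matrix(3.0, 0.7, pi)
    assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
    flux = pi[:, None] * q
    assert np.allclose(flux, flux.T, atol=1e-14)
    # multi-nucleotide changes have rate zero
    assert q[sel.CODON_INDEX["AAA"], sel.CODON_INDEX["ACC"]] == 0.0


def test_transition_probability_rows_sum_to_one():
    pi = default_codon_frequencies()
    q = sel.build_rate_matrix(2.0, 0.3, pi)
    d = sel._Decomp(q, pi)
    for t in (0.0, 0.01, 0.5, 5.0):
        p = d.transition(t)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)
        assert (p >= 0).all()


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def test_mask_gap_free_alignment_unchanged():
    aln = sel.CodonAlignment(["a", "b"], ["ATGAAACCTGGGTTT", "ATGAAACCTGGGTTC"])
    out = sel.mask_alignment(aln, max_gap_fraction=0.0, min_block_codons=2)
    assert out.seqs == aln.seqs


def test_mask_strict_removes_gapped_codon_column():
    aln = sel.CodonAlignment(
        ["a", "b"], ["ATGAAACCTGGGTTTAAA", "ATG---CCTGGGTTTAAA"])
    out = sel.mask_alignment(aln, max_gap_fraction=0.0, min_block_codons=1)
    assert out.n_codons == 5
    assert out.seqs[0] == "ATGCCTGGGTTTAAA"


def test_mask_short_blocks_removed_and_all_masked_error():
    #       col: 0    1    2    3    4    5
    a = "ATGAAA---GGGTTTAAA"
    b = "ATGAAACCT---TTTAAA"
    aln = sel.CodonAlignment(["a", "b"], [a, b])
    # surviving runs: [0,1] and [4,5]; min block 3 kills both
    with pytest.raises(ValueError, match="survive"):
        sel.mask_alignment(aln, 0.0, min_block_codons=3)
    out = sel.mask_alignment(aln, 0.0, min_block_codons=2)
    assert out.n_codons == 4


def test_mask_matches_brute_force_column_scan(nine_taxon_tree):
    rng = np.random.default_rng(12)
    spec = CodonSimSpec(tree=nine_taxon_tree, n_codons=60, rng_seed=3)
    aln, _ = simulate_codon_alignment(spec)
    # inject random gap codons
    seqs = [list(s) for s in aln.seqs]
    for _ in range(40):
        r, c = rng.integers(len(seqs)), rng.integers(60)
        seqs[r][3 * c:3 * c + 3] = "---"
    gappy = sel.CodonAlignment(aln.ids, ["".join(s) for s in seqs])
    out = sel.mask_alignment(gappy, max_gap_fraction=0.1, min_block_codons=1)
    keep = [c for c in range(60)
            if np.mean([s[3 * c:3 * c + 3] == list("---") for s in seqs]) <= 0.1]
    assert out.n_codons == len(keep)
    assert out.seqs[0] == "".join(gappy.seqs[0][3 * c:3 * c + 3] for c in keep)
    # never longer, gap fractions obey threshold
    assert out.n_codons <= gappy.n_codons
    assert (out.gap_fraction_per_codon() <= 0.1).all()


# ---------------------------------------------------------------------------
# MCL and the single-copy filter
# ---------------------------------------------------------------------------

def _triangle(graph, nodes, w=10.0):
    for i in range(3):
        graph.add_edge(nodes[i], nodes[(i + 1) % 3], w)


def test_mcl_disconnected_components_never_merge():
    g = sel.SimilarityGraph()
    _triangle(g, [("s1", "a"), ("s2", "b"), ("s3", "c")])
    _triangle(g, [("s1", "x"), ("s2", "y"), ("s3", "z")])
    groups = sel.mcl_cluster(g)
    assert len(groups) == 2
    sets = sorted(frozenset(m[1] for m in mem) for mem in groups.values())
    assert sets == sorted([frozenset("abc"), frozenset("xyz")])


def test_mcl_singleton():
    g = sel.SimilarityGraph()
    g.add_node(("s1", "lonely"))
    groups = sel.mcl_cluster(g)
    assert list(groups.values()) == [[("s1", "lonely")]]


def test_mcl_recovers_planted_two_block_graph():
    rng = np.random.default_rng(0)
    g = sel.SimilarityGraph()
    block1 = [("sp", f"a{i}") for i in range(8)]
    block2 = [("sp", f"b{i}") for i in range(8)]
    for block in (block1, block2):
        for i in range(8):
            for j in range(i + 1, 8):
                g.add_edge(block[i], block[j], 50.0)
    g.add_edge(block1[0], block2[0], 0.1)
    groups = sel.mcl_cluster(g, inflation=1.5)
    assert len(groups) == 2
    recovered = sorted(frozenset(m[1] for m in mem) for mem in groups.values())
    assert recovered == sorted([frozenset(m[1] for m in block1),
                                frozenset(m[1] for m in block2)])


def test_mcl_invariant_to_node_input_order():
    def build(order):
        g = sel.SimilarityGraph()
        edges = [(("s", "a"), ("s", "b"), 5.0), (("s", "b"), ("s", "c"), 5.0),
                 (("s", "x"), ("s", "y"), 7.0)]
        for u, v, w in (edges if order else edges[::-1]):
            g.add_edge(u, v, w)
        return sel.mcl_cluster(g)

    g1, g2 = build(True), build(False)
    assert sorted(map(sorted, g1.values())) == sorted(map(sorted, g2.values()))


def test_similarity_graph_weight_cap_and_validation():
    g = sel.SimilarityGraph.from_evalues([("a", "b", 0.0), ("a", "c", 1e-300)])
    weights = {frozenset((u, v)): w for u, v, w in g.edges()}
    assert weights[frozenset(("a", "b"))] == 200.0
    assert weights[frozenset(("a", "c"))] == 200.0
    with pytest.raises(ValueError):
        sel.SimilarityGraph().add_edge("a", "a", 1.0)


def test_single_copy_filter():
    species = [f"s{i}" for i in range(9)]
    groups = {
        0: [(s, f"g_{s}") for s in species],            # perfect single copy
        1: [(s, f"g_{s}") for s in species[:-1]],       # missing one species
        2: [(s, f"g_{s}") for s in species] + [("s0", "dup")],  # duplicate
    }
    kept = sel.single_copy_filter(groups, species)
    assert list(kept) == [0]
    with pytest.raises(ValueError):
        sel.single_copy_filter(groups, [])


# ---------------------------------------------------------------------------
# the LRT
# ---------------------------------------------------------------------------

def test_identical_sequences_lrt_zero(three_taxon_tree):
    aln = sel.CodonAlignment(["A", "B", "C"], ["ATGAAACCTGGG"] * 3)
    settings = sel.OptimizerSettings(n_restarts=1, seed=0)
    res = sel.branch_site_test(aln, three_taxon_tree, settings)
    assert res.lrt == pytest.approx(0.0, abs=1e-4)
    assert res.p_value > 0.99
    assert res.lnl_alt >= res.lnl_null - 1e-4


def test_alt_likelihood_dominates_null(three_taxon_tree):
    spec = CodonSimSpec(tree=three_taxon_tree, n_codons=120, rng_seed=4,
                        omega2=5.0, p0=0.3, p1=0.3)
    aln, _ = simulate_codon_alignment(spec)
    res = sel.branch_site_test(aln, three_taxon_tree,
                               sel.OptimizerSettings(n_restarts=1, seed=1))
    assert res.lnl_alt >= res.lnl_null - 1e-4
    assert 0.0 <= res.p_value <= 1.0
    assert res.params_alt["omega2"] >= 1.0


def test_mixture_reference_halves_p(three_taxon_tree):
    spec = CodonSimSpec(tree=three_taxon_tree, n_codons=90, rng_seed=6,
                        omega2=4.0, p0=0.3, p1=0.3)
    aln, _ = simulate_codon_alignment(spec)
    chi2_res = sel.branch_site_test(
        aln, three_taxon_tree, sel.OptimizerSettings(n_restarts=1, seed=2))
    mix_res = sel.branch_site_test(
        aln, three_taxon_tree,
        sel.OptimizerSettings(n_restarts=1, seed=2, p_reference="mixture"))
    if chi2_res.lrt > 0:
        assert mix_res.p_value == pytest.approx(chi2_res.p_value / 2, rel=1e-6)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def test_selection_scan_intersection_and_exclusions(nine_taxon_tree):
    settings = sel.OptimizerSettings(n_restarts=1, seed=3)
    genes = {}
    for i, w2 in enumerate([1.0, 8.0, 8.0]):
        spec = CodonSimSpec(tree=nine_taxon_tree, n_codons=200,
                            rng_seed=100 + i, omega2=w2, p0=0.3, p1=0.3)
        aln, _ = simulate_codon_alignment(spec)
        genes[f"g{i}"] = aln
    alignments = {"prank": dict(genes), "macse": dict(genes)}
    del alignments["macse"]["g1"]  # g1 lacks one aligner variant
    trees = {g: nine_taxon_tree for g in genes}
    final, table = sel.selection_scan(alignments, trees, settings, fdr=0.05)
    assert "g1" not in set(table["gene"])  # excluded, not tested
    assert set(final) <= {"g0", "g2"}
    assert set(table["variant"]) == {"prank", "macse"}
    # q-values present and within [0, 1]
    assert table["q"].between(0, 1).all()
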