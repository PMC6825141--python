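"""Annotation-confidence filtering, gene assignment, redundancy collapse,
and assembly summary statistics.

Transcript-to-protein hits are confidence-filtered (e-value, percent
identity, coverage of the full-length subject protein), each transcript is
assigned the gene symbol of its best surviving hit, and largely redundant
transcripts are collapsed by greedy length-sorted clustering in the style
of cd-hit-est.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import pandas as pd

from .io_formats import SequenceSet


def filter_hits(hits: pd.DataFrame, e_max: float = 1e-10,
                identity_min: float = 70.0,
                coverage_min: float = 0.5) -> pd.DataFrame:
    """Retain rows with e < e_max, identity >= identity_min, coverage >= coverage_min.

    Thresholds on identity and coverage are inclusive ("at least");
    the e-value bound is strict.  Idempotent; the retained set shrinks
    monotonically as any threshold tightens.
    """
    if not 0 <= identity_min <= 100:
        raise ValueError("identity_min must be in [0, 100]")
    if not 0 <= coverage_min <= 1:
        raise ValueError("coverage_min must be in [0, 1]")
    mask = ((hits["e_value"] < e_max)
            & (hits["percent_identity"] >= identity_min)
            & (hits["coverage"] >= coverage_min))
    return hits[mask].reset_index(drop=True)


def best_hit_per_transcript(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per query: lowest e-value, ties by highest bit score, then
    lexicographically smallest subject id (fully deterministic)."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["query_id", "e_value", "bit_score", "subject_id"],
        ascending=[True, True, False, True], kind="mergesort")
    best = ordered.drop_duplicates("query_id", keep="first").reset_index(drop=True)
    return best.rename(columns={"subject_gene": "gene_symbol"})


# ---------------------------------------------------------------------------
# redundancy collapse (cd-hit-est style greedy clustering)
# ---------------------------------------------------------------------------

def _canonical_kmers(seq: str, k: int) -> set[str]:
    comp = str.maketrans("ACGT", "TGCA")
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        rc = kmer.translate(comp)[::-1]
        out.add(min(kmer, rc))
    return out


def kmer_identity(seq: str, rep: str, k: int = 8,
                  kmers_rep: set[str] | None = None) -> float:
    """Estimated identity: containment of the query's canonical k-mers in
    the representative's.  Identical strings score exactly 1.0."""
    kq = _canonical_kmers(seq, k)
    if not kq:
        return 0.0
    kr = kmers_rep if kmers_rep is not None else _canonical_kmers(rep, k)
    return len(kq & kr) / len(kq)


def alignment_identity(a: str, b: str) -> float:
    """Exact verification: matched bases in a global alignment over the
    shorter sequence's length (match 1, mismatch/gap 0)."""
    from Bio import Align
    aligner = Align.PairwiseAligner(mode="global", match_score=1,
                                    mismatch_score=0, open_gap_score=0,
                                    extend_gap_score=0)
    return aligner.score(a, b) / min(len(a), len(b))


def collapse_redundancy(seqs: SequenceSet, identity_threshold: float = 0.95,
                        k: int = 8, verify: bool = False,
                        ) -> tuple[SequenceSet, dict[str, str]]:
    """Greedy incremental clustering, longest sequences first.

    Each sequence joins the first existing cluster whose representative
    (the cluster founder) shares estimated identity >= threshold, else it
    founds a new cluster.  ``verify=True`` additionally requires the exact
    aligned identity to clear the threshold.  Returns the representatives
    and a member -> representative map.
    """
    order = sorted(seqs.ids(), key=lambda i: (-len(seqs[i]), i))
    reps: list[tuple[str, set[str]]] = []
    membership: dict[str, str] = {}
    for sid in order:
        seq = seqs[sid]
        placed = False
        for rep_id, rep_kmers in reps:
            est = kmer_identity(seq, seqs[rep_id], k=k, kmers_rep=rep_kmers)
            if est >= identity_threshold:
                if verify and alignment_identity(seq, seqs[rep_id]) < identity_threshold:
                    continue
                membership[sid] = rep_id
                placed = True
                break
        if not placed:
            reps.append((sid, _canonical_kmers(seq, k)))
            membership[sid] = sid
    rep_set = SequenceSet([(r, seqs[r]) for r, _ in reps], alphabet=seqs.alphabet)
    return rep_set, membership


# ---------------------------------------------------------------------------
# assembly statistics
# ---------------------------------------------------------------------------

@dataclass
class AssemblyStats:
    n: int
    total_bases: int
    mean_length: float
    median_length: float
    n50: int
    gc_percent: float


def assembly_stats(seqs: SequenceSet) -> AssemblyStats:
    """N50, length summaries and GC% (over A/C/G/T only) of an assembly.

    N50 is the largest length L such that contigs of length >= L cover at
    least half the total assembled bases.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    lengths = sorted((len(s) for _, s in seqs), reverse=True)
    total = sum(lengths)
    cum = 0
    n50 = lengths[-1]
    for L in lengths:
        cum += L
        if cum * 2 >= total:
            n50 = L
            break
    gc = at = 0
    for _, s in seqs:
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    gc_percent = 100.0 * gc / (gc + at) if gc + at else float("nan")
    return AssemblyStats(
        n=len(seqs), total_bases=total, mean_length=total / len(seqs),
        median_length=float(statistics.median(lengths)), n50=n50,
        gc_percent=gc_percent)
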