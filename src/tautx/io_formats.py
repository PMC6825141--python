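"""Readers/writers for every external format the pipeline touches.

Formats handled here: FASTA (via Biopython), Newick trees with the PAML-style
``#1`` foreground-branch tag (via dendropy), TSV expression/count tables,
BLAST tabular hit files (outfmt-6 style, optionally extended with subject
length and subject gene columns), two-column gene->GO maps, and the YAML run
configuration.  All coordinates and lengths are 1-based residue counts;
decimal points only (locale-independent parsing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("tautx")

# IUPAC alphabets (upper case); '-' allowed so aligned FASTA round-trips.
NUCLEOTIDE_CHARS = set("ACGTURYSWKMBDHVN-")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")

#: canonical column order of a parsed BLAST tabular file
BLAST_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score", "subject_length", "subject_gene", "coverage",
]


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a plain-text stream handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# sequence sets
# ---------------------------------------------------------------------------

class SequenceSet:
    """An ordered id -> sequence mapping with alphabet validation.

    Parameters
    ----------
    records
        Iterable of ``(id, sequence)`` pairs.  Ids must be unique and
        sequences non-empty; sequences are upper-cased.
    alphabet
        ``"nucleotide"``, ``"protein"`` or ``None`` (no validation).
    """

    def __init__(self, records, alphabet: str | None = "nucleotide"):
        self.alphabet = alphabet
        self.records: dict[str, str] = {}
        allowed = None
        if alphabet == "nucleotide":
            allowed = NUCLEOTIDE_CHARS
        elif alphabet == "protein":
            allowed = PROTEIN_CHARS
        elif alphabet is not None:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        for seq_id, seq in records:
            if seq_id in self.records:
                raise ValueError(f"duplicate sequence id {seq_id!r}")
            seq = "".join(str(seq).split()).upper()
            if not seq:
                raise ValueError(f"empty sequence for id {seq_id!r}")
            if allowed is not None:
                bad = set(seq) - allowed
                if bad:
                    raise ValueError(
                        f"sequence {seq_id!r} contains characters {sorted(bad)} "
                        f"outside the {alphabet} alphabet")
            self.records[seq_id] = seq

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> str:
        return self.records[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records

    def __iter__(self):
        return iter(self.records.items())

    def ids(self) -> list[str]:
        return list(self.records)

    def lengths(self) -> dict[str, int]:
        return {i: len(s) for i, s in self.records.items()}


def read_fasta(path, alphabet: str | None = "nucleotide") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Raises on duplicate ids (naming the offender) and on empty files.
    """
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(records, alphabet=alphabet)


def write_fasta(seqs: SequenceSet, path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# expression / count tables
# ---------------------------------------------------------------------------

def read_expression_table(path, tissue_order: list[str]) -> pd.DataFrame:
    """Read a genes x tissues TSV and reorder columns to ``tissue_order``.

    The header row holds tissue names; the first column holds gene ids.
    Values must be non-negative reals with no missing cells.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [c for c in df.columns if c not in tissue_order]
    if unknown:
        raise ValueError(f"unknown tissues in header: {unknown}; expected {tissue_order}")
    missing = [t for t in tissue_order if t not in df.columns]
    if missing:
        raise ValueError(f"tissues missing from table: {missing}")
    df = df[tissue_order]
    if df.isna().any().any():
        r, c = next(zip(*df.isna().to_numpy().nonzero()))
        raise ValueError(f"missing value at gene {df.index[r]!r}, tissue {df.columns[c]!r}")
    df = df.astype(float)
    if (df.to_numpy() < 0).any():
        r, c = next(zip(*(df.to_numpy() < 0).nonzero()))
        raise ValueError(
            f"negative value at gene {df.index[r]!r}, tissue {df.columns[c]!r}")
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_lengths(path) -> pd.Series:
    """Read a two-column ``gene<TAB>length`` TSV (header required)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.iloc[:, 0].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    return lengths


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene")


def read_gene2go(path) -> dict[str, set[str]]:
    """Read a two-column ``gene<TAB>term`` TSV (no header) into a mapping."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"line {lineno}: expected gene<TAB>term")
            mapping.setdefault(parts[0], set()).add(parts[1])
    return mapping


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

def read_blast_tab(path) -> pd.DataFrame:
    """Parse an outfmt-6-style BLAST tabular file.

    Expects the 12 standard columns; column 13 (subject length, needed to
    derive coverage) and column 14 (subject gene symbol) are optional.
    Coverage is ``alignment_length / subject_length`` when not supplied;
    NaN when the subject length is unknown.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"line {lineno}: expected >=12 tab-separated fields, got {len(parts)}")
            try:
                pident = float(parts[2])
                alen = int(float(parts[3]))
                evalue = float(parts[10])
                bits = float(parts[11])
                slen = float(parts[12]) if len(parts) > 12 and parts[12] != "" else math.nan
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if not 0.0 <= pident <= 100.0:
                raise ValueError(f"line {lineno}: percent identity {pident} outside [0, 100]")
            if evalue < 0:
                raise ValueError(f"line {lineno}: negative e-value {evalue}")
            sgene = parts[13] if len(parts) > 13 and parts[13] != "" else parts[1]
            rows.append((parts[0], parts[1], pident, alen,
                         int(float(parts[4])), int(float(parts[5])),
                         int(float(parts[6])), int(float(parts[7])),
                         int(float(parts[8])), int(float(parts[9])),
                         evalue, bits, slen, sgene,
                         alen / slen if slen and not math.isnan(slen) else math.nan))
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


def write_blast_tab(hits: pd.DataFrame, path) -> None:
    """Write the 14-column tabular form read back by :func:`read_blast_tab`."""
    cols = BLAST_COLUMNS[:-1]  # coverage is derived, not stored
    hits[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Newick trees with "#1" foreground tags
# ---------------------------------------------------------------------------

class PhyloTree:
    """A rooted tree with branch lengths and at most one foreground branch.

    Nodes are stored in postorder; ``parent[i]`` indexes into the node list
    (root parent is ``-1``).  ``foreground`` flags the branch above a node.
    """

    def __init__(self, parent, lengths, labels, foreground):
        self.parent = list(parent)
        self.lengths = list(lengths)
        self.labels = list(labels)
        self.foreground = list(foreground)
        n = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        self.root = self.parent.index(-1)
        if sum(self.foreground) > 1:
            raise ValueError("more than one foreground branch")

    # -- structure helpers -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in range(self.n_nodes) if self.is_leaf(i)]

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        return order[::-1]

    def foreground_node(self) -> int | None:
        for i, f in enumerate(self.foreground):
            if f:
                return i
        return None

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def render(i: int) -> str:
            tag = "#1" if self.foreground[i] else ""
            if self.is_leaf(i):
                body = f"{self.labels[i]}{tag}"
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")" + tag
            if self.parent[i] == -1:
                return body
            return f"{body}:{self.lengths[i]:.10g}"
        return render(self.root) + ";"


def read_tree(path_or_string, default_branch_length: float | None = None) -> PhyloTree:
    """Parse a Newick tree, honouring the PAML ``#1`` foreground suffix.

    At most one node (leaf or internal) may carry the tag.  Branch lengths
    are required on non-root branches unless ``default_branch_length`` is
    given explicitly.
    """
    text = str(path_or_string)
    if "(" not in text:
        with open(text) as fh:
            text = fh.read()
    import dendropy
    tree = dendropy.Tree.get(data=text, schema="newick",
                             suppress_internal_node_taxa=True)

    parent, lengths, labels, fg = [], [], [], []
    index: dict[int, int] = {}

    def label_and_tag(nd) -> tuple[str | None, bool]:
        raw = nd.taxon.label if nd.taxon is not None else nd.label
        if raw is None:
            return None, False
        raw = str(raw)
        if raw.endswith("#1"):
            return (raw[:-2] or None), True
        return raw, False

    n_tags = 0
    for nd in tree.preorder_node_iter():
        lab, tagged = label_and_tag(nd)
        n_tags += tagged
        if n_tags > 1:
            raise ValueError("more than one '#1' foreground tag in tree")
        is_root = nd.parent_node is None
        length = nd.edge.length
        if length is None:
            if is_root:
                length = 0.0
            elif default_branch_length is not None:
                length = default_branch_length
            else:
                raise ValueError(
                    f"missing branch length above node {lab!r}; pass "
                    "default_branch_length to fill in a default")
        if length < 0:
            raise ValueError(f"negative branch length {length} above node {lab!r}")
        index[id(nd)] = len(parent)
        parent.append(-1 if is_root else index[id(nd.parent_node)])
        lengths.append(float(length))
        labels.append(lab)
        fg.append(tagged)
    out = PhyloTree(parent, lengths, labels, fg)
    leaf_labels = out.leaf_labels()
    if len(set(leaf_labels)) != len(leaf_labels):
        raise ValueError("duplicate leaf labels in tree")
    return out


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Effective run configuration; every CLI flag overrides a key here."""

    tissue_order: list[str] = field(default_factory=lambda: [
        "brain", "blood", "ovary", "spleen", "liver", "muscle"])
    presence_tpm: float = 1.0
    tau_floor: float = 2.0
    tau_broad_cutoff: float = 0.3
    tau_high_cutoff: float = 0.8
    identity_min: float = 70.0
    coverage_min: float = 0.5
    evalue_max: float = 1e-10
    bin_edges: tuple[float, float] = (10.0, 50.0)
    rng_seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.presence_tpm < 0:
            raise ValueError("presence_tpm must be >= 0")
        if self.tau_floor <= 0:
            raise ValueError("tau_floor must be > 0")
        if not 0 < self.tau_broad_cutoff < self.tau_high_cutoff < 1:
            raise ValueError("require 0 < tau_broad_cutoff < tau_high_cutoff < 1")
        if not isinstance(self.rng_seed, int):
            raise ValueError("rng_seed must be an integer")
        self.bin_edges = tuple(float(e) for e in self.bin_edges)
        if len(self.bin_edges) != 2 or self.bin_edges[0] >= self.bin_edges[1]:
            raise ValueError("bin_edges must be two increasing values")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        data = asdict(self)
        data["bin_edges"] = list(self.bin_edges)
        return yaml.safe_dump(data, sort_keys=True)

    def log_effective(self) -> None:
        """Log the effective configuration verbatim at run start."""
        logger.info("effective configuration:\n%s", self.to_yaml().rstrip())
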