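"""Trees, codon alignments and candidate edge runs.

Trees are rooted phylogenies with branch lengths in dS units (expected
synonymous substitutions per synonymous site).  An *internal* edge is an
edge both of whose endpoints are internal nodes, i.e. a tree segment
ancestral to more than one extant species.  Candidate edge runs are single
short internal edges, or paths of consecutive internal edges whose combined
length stays below a dS cap.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import GAP_CODON, NUCLEOTIDES, STOP_CODONS


class TreeError(ValueError):
    """Raised for malformed or unsupported tree input."""


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


class PhyloTree:
    """Rooted phylogeny with per-edge lengths in dS units.

    Nodes are integer ids in preorder (root = 0).  Every non-root node
    identifies the edge above it; edges are referred to by the child node id
    or, externally, by the child node's label.
    """

    def __init__(self, parent: list[int | None], children: list[list[int]],
                 lengths: list[float | None], labels: list[str]):
        self.parent = parent
        self.children = children
        self.lengths = lengths          # branch length above each node (root: None)
        self.labels = labels
        self._label_to_node = {lab: i for i, lab in enumerate(labels)}
        if len(self._label_to_node) != len(labels):
            raise TreeError("duplicate node labels in tree")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        """Parse a rooted Newick string with branch lengths.

        Raises :class:`TreeError` for malformed input, missing branch
        lengths, or an explicitly unrooted tree (``[&U]``).
        """
        if "[&U]" in text.upper().replace(" ", ""):
            raise TreeError("tree is annotated as unrooted ([&U]); a rooted "
                            "tree is required for ancestral reconstruction")
        try:
            dtree = dendropy.Tree.get(data=text, schema="newick",
                                      suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise TreeError(f"malformed Newick: {exc}") from exc
        if len(dtree.seed_node._child_nodes) == 0:
            raise TreeError("tree has no edges")

        parent: list[int | None] = []
        children: list[list[int]] = []
        lengths: list[float | None] = []
        labels: list[str] = []

        def walk(node, parent_id: int | None) -> int:
            nid = len(parent)
            parent.append(parent_id)
            children.append([])
            if parent_id is None:
                lengths.append(None)
            else:
                if node.edge.length is None:
                    raise TreeError("branch length missing on an edge; all "
                                    "edges must carry dS lengths")
                if node.edge.length < 0:
                    raise TreeError(f"negative branch length {node.edge.length}")
                lengths.append(float(node.edge.length))
                children[parent_id].append(nid)
            kids = node._child_nodes
            if kids:
                labels.append(node.label or f"node{nid}")
            else:
                if node.taxon is None or not node.taxon.label:
                    raise TreeError("leaf without a taxon name")
                labels.append(node.taxon.label)
            for kid in kids:
                walk(kid, nid)
            return nid

        walk(dtree.seed_node, None)
        return cls(parent, children, lengths, labels)

    def to_newick(self) -> str:
        """Serialize to Newick; internal node labels and lengths preserved."""

        def render(node: int) -> str:
            if not self.children[node]:
                s = self.labels[node]
            else:
                inner = ",".join(render(c) for c in self.children[node])
                s = f"({inner}){self.labels[node]}"
            if self.parent[node] is not None:
                s += f":{self.lengths[node]:.10g}"
            return s

        return render(0) + ";"

    # -- topology queries --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    def is_leaf(self, node: int) -> bool:
        return not self.children[node]

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_names(self) -> list[str]:
        return [self.labels[i] for i in self.leaves]

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.is_leaf(i)]

    @property
    def edges(self) -> list[int]:
        """All edges, identified by child node id (preorder)."""
        return [i for i in range(1, self.n_nodes)]

    def is_internal_edge(self, child: int) -> bool:
        """True if both endpoints of the edge above ``child`` are internal
        nodes (the edge is ancestral to more than one species)."""
        return not self.is_leaf(child)

    @property
    def internal_edges(self) -> list[int]:
        return [i for i in self.edges if self.is_internal_edge(i)]

    def edge_length(self, child: int) -> float:
        length = self.lengths[child]
        if length is None:
            raise TreeError("root has no edge above it")
        return length

    def node(self, label: str) -> int:
        try:
            return self._label_to_node[label]
        except KeyError:
            raise TreeError(f"no node labelled {label!r}") from None

    def postorder(self) -> Iterator[int]:
        def walk(node: int) -> Iterator[int]:
            for c in self.children[node]:
                yield from walk(c)
            yield node

        return walk(0)

    def preorder(self) -> Iterator[int]:
        def walk(node: int) -> Iterator[int]:
            yield node
            for c in self.children[node]:
                yield from walk(c)

        return walk(0)

    def descendants(self, node: int) -> list[int]:
        out: list[int] = []
        stack = list(self.children[node])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    def leaf_set(self, node: int) -> set[str]:
        """Labels of the leaves descending from ``node`` (itself if a leaf)."""
        if self.is_leaf(node):
            return {self.labels[node]}
        return {self.labels[d] for d in self.descendants(node) if self.is_leaf(d)}


@dataclass(frozen=True)
class EdgeRun:
    """One or more consecutive internal edges, each the parent of the next.

    ``edges`` are child-node ids in root-to-tip order; ``length`` is the sum
    of the member dS lengths.
    """

    edges: tuple[int, ...]
    length: float
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def label(self) -> str:
        return "+".join(self.labels)


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string with branch lengths into a PhyloTree."""
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def enumerate_edge_runs(tree: PhyloTree, max_ds: float,
                        max_run_edges: int = 2) -> list[EdgeRun]:
    """Enumerate candidate edge runs: every internal edge shorter than
    ``max_ds`` and every path of up to ``max_run_edges`` consecutive internal
    edges with combined length below ``max_ds`` (strict comparison).

    Runs are returned in deterministic order: by preorder position of the
    starting edge, then by run length.
    """
    if max_ds <= 0:
        raise ValueError("max_ds must be positive")
    if max_run_edges < 1:
        raise ValueError("max_run_edges must be >= 1")

    runs: list[EdgeRun] = []
    preorder_pos = {n: i for i, n in enumerate(tree.preorder())}

    def extend(path: list[int], total: float) -> None:
        if len(path) >= max_run_edges:
            return
        tip = path[-1]
        for child in tree.children[tip]:
            if not tree.is_internal_edge(child):
                continue
            new_total = total + tree.edge_length(child)
            if new_total < max_ds:
                runs.append(EdgeRun(tuple(path) + (child,), new_total,
                                    tuple(tree.labels[e] for e in path)
                                    + (tree.labels[child],)))
                extend(path + [child], new_total)

    for edge in sorted(tree.internal_edges, key=preorder_pos.get):
        length = tree.edge_length(edge)
        if length < max_ds:
            runs.append(EdgeRun((edge,), length, (tree.labels[edge],)))
            extend([edge], length)

    runs.sort(key=lambda r: (preorder_pos[r.edges[0]], len(r)))
    return runs


_VALID_CHARS = frozenset(NUCLEOTIDES) | {"-"}


class CodonAlignment:
    """A per-gene codon-aligned set of nucleotide sequences.

    All sequences have equal length divisible by 3.  A codon column is a
    *gap column* if any sequence carries a non-ACGT character (gap or
    ambiguity code) within that triplet; burst statistics use only gapless
    columns.
    """

    def __init__(self, gene_id: str, sequences: Mapping[str, str],
                 stop_policy: str = "error"):
        if not sequences:
            raise AlignmentError("alignment with no sequences")
        if stop_policy not in ("error", "mask"):
            raise ValueError(f"unknown stop_policy {stop_policy!r}")
        self.gene_id = gene_id
        self.sequences: dict[str, str] = {t: s.upper() for t, s in sequences.items()}
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"{gene_id}: ragged alignment, lengths {sorted(lengths)}")
        (self.length,) = lengths
        if self.length == 0:
            raise AlignmentError(f"{gene_id}: empty sequences")
        if self.length % 3:
            raise AlignmentError(
                f"{gene_id}: length {self.length} not divisible by 3")
        self.n_codons = self.length // 3
        self.taxa = sorted(self.sequences)

        self._masked: set[tuple[str, int]] = set()
        gap_cols: set[int] = set()
        for taxon, seq in self.sequences.items():
            for col in range(self.n_codons):
                codon = seq[3 * col:3 * col + 3]
                if any(ch not in NUCLEOTIDES for ch in codon):
                    gap_cols.add(col)
                elif codon in STOP_CODONS:
                    if stop_policy == "error":
                        raise AlignmentError(
                            f"{gene_id}: internal stop codon {codon} in "
                            f"{taxon} at codon column {col + 1}")
                    self._masked.add((taxon, col))
                    gap_cols.add(col)
        self.gap_columns: frozenset[int] = frozenset(gap_cols)

    @property
    def gapless_columns(self) -> list[int]:
        return [c for c in range(self.n_codons) if c not in self.gap_columns]

    @property
    def gap_fraction(self) -> float:
        return len(self.gap_columns) / self.n_codons

    def codon(self, taxon: str, column: int) -> str:
        if (taxon, column) in self._masked:
            return GAP_CODON
        return self.sequences[taxon][3 * column:3 * column + 3]

    def __repr__(self) -> str:
        return (f"CodonAlignment({self.gene_id!r}, {len(self.taxa)} taxa, "
                f"{self.n_codons} codons, {len(self.gap_columns)} gap columns)")


def parse_codon_fasta(path: str | os.PathLike, gene_id: str | None = None,
                      stop_policy: str = "error") -> CodonAlignment:
    """Read one gene's codon alignment from a FASTA file.

    ``stop_policy`` controls internal stop codons in ungapped sequence:
    ``"error"`` rejects the file, ``"mask"`` treats the codon as missing.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    seqs = {}
    for rec in records:
        if rec.id in seqs:
            raise AlignmentError(f"{path}: duplicate taxon {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    return CodonAlignment(gene_id or path.stem, seqs, stop_policy=stop_policy)


def write_codon_fasta(alignment: CodonAlignment, path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(alignment.sequences[t]), id=t, description="")
               for t in alignment.taxa]
    SeqIO.write(records, str(path), "fasta")


def read_manifest(path: str | os.PathLike) -> dict[str, Path]:
    """Read a two-column TSV manifest mapping gene id -> alignment path
    (relative paths resolved against the manifest's directory)."""
    path = Path(path)
    out: dict[str, Path] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise AlignmentError(f"{path}: manifest line is not 2 columns: {line!r}")
        gene, p = fields
        out[gene] = (path.parent / p) if not os.path.isabs(p) else Path(p)
    return out


def write_manifest(entries: Mapping[str, str | os.PathLike],
                   path: str | os.PathLike) -> None:
    lines = [f"{gene}\t{p}" for gene, p in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")
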