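"""Marginal ancestral codon reconstruction and substitution mapping.

Likelihoods are computed with the pruning (post-order conditional
likelihood) recursion; marginal posteriors at every internal node come from
a standard up-down (inside-outside) pass.  Substitutions are mapped onto an
edge as the sites where the MAP codons of the edge's two endpoints differ;
sites where either endpoint's MAP posterior falls below a cutoff are dropped
from the events *and* from the site counts used downstream, because an
uncertain ancestral state cannot place a substitution on a specific edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .codon import CODON_INDEX, SENSE_CODONS, classify_path
from .io import CodonAlignment, PhyloTree
from .model import N_CODONS, CodonModel


@dataclass
class AncestralReconstruction:
    """Per internal node × per codon column: MAP codon and its posterior.

    ``map_state[r, c]`` is the index (into the 61 sense codons) of the MAP
    codon of internal node ``internal_nodes[r]`` at codon column ``c``;
    ``map_posterior`` the corresponding posterior probability.  Full
    posterior distributions are retained only when requested.
    """

    tree: PhyloTree
    internal_nodes: list[int]
    map_state: np.ndarray          # (n_internal, n_columns) int16
    map_posterior: np.ndarray      # (n_internal, n_columns) float
    all_gap_columns: frozenset[int]
    posteriors: np.ndarray | None = None  # (n_internal, n_columns, 61)
    _row: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._row = {n: i for i, n in enumerate(self.internal_nodes)}

    def map_codon(self, node: int, column: int) -> str:
        return SENSE_CODONS[self.map_state[self._row[node], column]]

    def posterior_of_map(self, node: int, column: int) -> float:
        return float(self.map_posterior[self._row[node], column])

    def to_frame(self):
        """Long-format table (node, column, MAP codon, posterior); columns
        are 1-based in the output."""
        import pandas as pd

        rows = []
        for r, node in enumerate(self.internal_nodes):
            for c in range(self.map_state.shape[1]):
                rows.append((self.tree.labels[node], c + 1,
                             SENSE_CODONS[self.map_state[r, c]],
                             float(self.map_posterior[r, c])))
        return pd.DataFrame(rows, columns=["node", "column", "map_codon",
                                           "posterior"])


def _leaf_partials(alignment: CodonAlignment, tree: PhyloTree) -> dict[int, np.ndarray]:
    """One-hot partial likelihoods per leaf, (n_columns, 61); gap/ambiguous/
    masked codons get a flat row (missing data)."""
    n_cols = alignment.n_codons
    partials: dict[int, np.ndarray] = {}
    for leaf in tree.leaves:
        taxon = tree.labels[leaf]
        if taxon not in alignment.sequences:
            raise ValueError(f"taxon {taxon!r} in tree but not in alignment "
                             f"{alignment.gene_id!r}")
        arr = np.zeros((n_cols, N_CODONS))
        for c in range(n_cols):
            codon = alignment.codon(taxon, c)
            idx = CODON_INDEX.get(codon)
            if idx is None:
                arr[c, :] = 1.0
            else:
                arr[c, idx] = 1.0
        partials[leaf] = arr
    extra = set(alignment.sequences) - set(tree.leaf_names)
    if extra:
        raise ValueError(f"alignment taxa not in tree: {sorted(extra)}")
    return partials


def _edge_matrices(tree: PhyloTree, model: CodonModel) -> dict[int, np.ndarray]:
    mats: dict[int, np.ndarray] = {}
    for child in tree.edges:
        t = model.ds_to_subs_per_codon(tree.edge_length(child))
        mats[child] = model.transition_matrix(t)
    return mats


def _upward(tree: PhyloTree, leaf_partials: Mapping[int, np.ndarray],
            mats: Mapping[int, np.ndarray]):
    """Post-order pass.  Returns (below, msg, logscale) where ``msg[c]`` is
    the message from child c to its parent and ``below[v]`` the scaled
    partial likelihood of the data below v; ``logscale[v]`` accumulates the
    log of the scaling constants below v."""
    below: dict[int, np.ndarray] = {}
    msg: dict[int, np.ndarray] = {}
    logscale: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if tree.is_leaf(node):
            below[node] = leaf_partials[node]
            logscale[node] = np.zeros(leaf_partials[node].shape[0])
        else:
            prod = None
            ls = np.zeros(next(iter(leaf_partials.values())).shape[0])
            for child in tree.children[node]:
                m = below[child] @ mats[child].T
                msg[child] = m
                prod = m if prod is None else prod * m
                ls = ls + logscale[child]
            scale = prod.max(axis=1)
            scale[scale == 0] = 1.0
            below[node] = prod / scale[:, None]
            logscale[node] = ls + np.log(scale)
    return below, msg, logscale


def prune_likelihood(tree: PhyloTree, site: Mapping[str, str],
                     model: CodonModel) -> float:
    """Likelihood of a single codon column under the model.

    ``site`` maps each leaf taxon to its codon; gaps/ambiguity codes are
    missing data (flat partial likelihood).
    """
    if set(site) != set(tree.leaf_names):
        raise ValueError("site must provide a codon for every leaf taxon")
    partials: dict[int, np.ndarray] = {}
    for leaf in tree.leaves:
        codon = site[tree.labels[leaf]].upper()
        arr = np.zeros((1, N_CODONS))
        idx = CODON_INDEX.get(codon)
        if idx is None:
            arr[0, :] = 1.0
        else:
            arr[0, idx] = 1.0
        partials[leaf] = arr
    mats = _edge_matrices(tree, model)
    below, _, logscale = _upward(tree, partials, mats)
    like = float((below[0] @ model.freqs)[0])
    return like * float(np.exp(logscale[0][0]))


def site_log_likelihoods(tree: PhyloTree, alignment: CodonAlignment,
                         model: CodonModel) -> np.ndarray:
    """Per-codon-column log-likelihoods for a whole alignment."""
    partials = _leaf_partials(alignment, tree)
    mats = _edge_matrices(tree, model)
    below, _, logscale = _upward(tree, partials, mats)
    return np.log(below[0] @ model.freqs) + logscale[0]


def marginal_posteriors(tree: PhyloTree, alignment: CodonAlignment,
                        model: CodonModel,
                        keep_posteriors: bool = False) -> AncestralReconstruction:
    """Marginal posterior codon distributions at every internal node.

    For each internal node the posterior is proportional to the partial
    likelihood of the data below the node times the outside contribution of
    the rest of the tree, normalised per column.  The MAP codon is the
    argmax; ties break to the lexicographically smallest codon.  Columns
    that are entirely gaps get a stationary-distribution posterior and are
    reported in ``all_gap_columns``.
    """
    partials = _leaf_partials(alignment, tree)
    mats = _edge_matrices(tree, model)
    below, msg, _ = _upward(tree, partials, mats)
    n_cols = alignment.n_codons

    all_gap = frozenset(
        c for c in range(n_cols)
        if all(CODON_INDEX.get(alignment.codon(t, c)) is None
               for t in alignment.taxa))

    above: dict[int, np.ndarray] = {0: np.broadcast_to(model.freqs,
                                                       (n_cols, N_CODONS)).copy()}
    for node in tree.preorder():
        kids = tree.children[node]
        for child in kids:
            out = above[node].copy()
            for sib in kids:
                if sib is not child:
                    out *= msg[sib]
            out = out @ mats[child]
            scale = out.max(axis=1)
            scale[scale == 0] = 1.0
            above[child] = out / scale[:, None]

    internal = tree.internal_nodes
    map_state = np.zeros((len(internal), n_cols), dtype=np.int16)
    map_post = np.zeros((len(internal), n_cols))
    full = np.zeros((len(internal), n_cols, N_CODONS)) if keep_posteriors else None
    for r, node in enumerate(internal):
        post = below[node] * above[node]
        post /= post.sum(axis=1, keepdims=True)
        map_state[r] = np.argmax(post, axis=1)  # first max = smallest codon
        map_post[r] = post[np.arange(n_cols), map_state[r]]
        if full is not None:
            full[r] = post
    return AncestralReconstruction(tree, internal, map_state, map_post,
                                   all_gap, posteriors=full)


@dataclass(frozen=True)
class SubstitutionEvent:
    """A single mapped codon substitution on an edge."""

    gene_id: str
    edge: int                 # child node id identifying the edge
    column: int               # 0-based codon column
    parent_codon: str
    child_codon: str
    nd: float
    sd: float
    min_posterior: float


@dataclass
class EdgeMapping:
    """Mapped substitutions on one edge plus the columns excluded because an
    endpoint's MAP posterior fell below the cutoff."""

    edge: int
    events: list[SubstitutionEvent]
    excluded_columns: frozenset[int]

    @property
    def nd(self) -> float:
        return sum(e.nd for e in self.events)

    @property
    def sd(self) -> float:
        return sum(e.sd for e in self.events)


def map_substitutions(reconstruction: AncestralReconstruction,
                      alignment: CodonAlignment, edge: int,
                      min_posterior: float = 0.8,
                      columns: Sequence[int] | None = None) -> EdgeMapping:
    """Map substitutions onto one edge from endpoint MAP codons.

    Only the given columns (default: the alignment's gapless columns) are
    considered.  A leaf endpoint uses its observed codon with posterior 1.
    Columns whose minimum endpoint posterior is below ``min_posterior`` are
    excluded from the events and must also be excluded from the site counts
    of any statistic recomputed for this edge.
    """
    if not 0.0 <= min_posterior <= 1.0:
        raise ValueError("min_posterior must be in [0, 1]")
    tree = reconstruction.tree
    parent = tree.parent[edge]
    if parent is None:
        raise ValueError("root identifies no edge")
    if columns is None:
        columns = alignment.gapless_columns

    events: list[SubstitutionEvent] = []
    excluded: set[int] = set()
    child_is_leaf = tree.is_leaf(edge)
    child_taxon = tree.labels[edge] if child_is_leaf else None
    for c in columns:
        p_codon = reconstruction.map_codon(parent, c)
        p_post = reconstruction.posterior_of_map(parent, c)
        if child_is_leaf:
            c_codon = alignment.codon(child_taxon, c)
            c_post = 1.0
            if c_codon not in CODON_INDEX:
                excluded.add(c)
                continue
        else:
            c_codon = reconstruction.map_codon(edge, c)
            c_post = reconstruction.posterior_of_map(edge, c)
        mp = min(p_post, c_post)
        if mp < min_posterior:
            excluded.add(c)
            continue
        if p_codon != c_codon:
            sub = classify_path(p_codon, c_codon)
            events.append(SubstitutionEvent(alignment.gene_id, edge, c,
                                            p_codon, c_codon, sub.Nd, sub.Sd, mp))
    return EdgeMapping(edge, events, frozenset(excluded))
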