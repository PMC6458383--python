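"""Synthetic codon-evolution datasets with ground-truth substitution events.

The generator emulates the shape of the study inputs — many genes of a few
hundred codons evolving neutrally (dN = dS unless ω is changed) along a
clade-like tree containing very short internal edges — and can inject
bursts of k non-synonymous substitutions on a chosen edge.  Every simulated
substitution is recorded, so recovery of events, edge dS and injected
bursts can be tested exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codon import CODON_INDEX, SENSE_CODONS, STOP_CODONS, is_synonymous
from .io import CodonAlignment, PhyloTree, write_codon_fasta, write_manifest
from .model import N_CODONS, CodonModel

#: Clade-like tree for the amphipod-style preset: 10 closely related taxa,
#: six internal edges shorter than 0.005 dS (several consecutive).  No
#: candidate edge is a child of the root: a substitution on a root-adjacent
#: edge cannot be told apart from one on the root's other child edge, so the
#: posterior filter would discard it (see the methods note).
GAMMARID_LIKE_NEWICK = (
    "(((((T1:0.012,T2:0.014)n9:0.0008,T3:0.013)n3:0.0007,"
    "(T4:0.012,T5:0.015)n4:0.0024)n2:0.0040,"
    "((T6:0.013,T7:0.012)n6:0.0010,T8:0.014)n5:0.0030)n1:0.018,"
    "(T9:0.020,T10:0.022)n8:0.018)root;"
)

#: Primate-style preset: 11 taxa, exactly three internal edges < 0.005 dS.
PRIMATE_LIKE_NEWICK = (
    "(((P1:0.020,P2:0.022)n2:0.0043,(P3:0.025,P4:0.021)n3:0.008)n1:0.012,"
    "(((P5:0.024,P6:0.026)n6:0.0025,P7:0.023)n5:0.0030,"
    "((P8:0.020,P9:0.027)n8:0.018,(P10:0.020,P11:0.030)n9:0.009)n7:0.015)"
    "n4:0.010)root;"
)

PRESETS = ("gammarid-like", "primate-like", "custom")


@dataclass(frozen=True)
class BurstSpec:
    """An injected burst: k extra non-synonymous substitutions of one gene
    on one edge (edge named by its child-node label)."""

    gene: str
    edge_label: str
    k: int


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic dataset.

    Defaults are desk-scale versions of the study inputs: 200 genes of
    150–350 codons on a 10-taxon clade tree, neutral baseline (ω = 1),
    κ = 2, uniform codon frequencies, no alignment gaps.
    """

    tree: PhyloTree
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (150, 350)
    omega: float = 1.0
    kappa: float = 2.0
    freqs: np.ndarray | None = None
    bursts: tuple[BurstSpec, ...] = ()
    gap_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducible simulation")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene length range")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")
        self.bursts = tuple(self.bursts)
        for b in self.bursts:
            node = self.tree.node(b.edge_label)  # raises if absent
            if self.tree.parent[node] is None:
                raise ValueError(f"burst edge {b.edge_label!r} is the root")
            if b.k < 1:
                raise ValueError("burst k must be >= 1")
            if b.k > 3 * hi:
                raise ValueError(f"burst k={b.k} exceeds 3 x gene length")


@dataclass(frozen=True)
class SimEvent:
    """One simulated substitution (ground truth)."""

    gene_id: str
    edge: int            # child node id
    edge_label: str
    column: int          # 0-based codon column
    from_codon: str
    to_codon: str
    synonymous: bool
    injected: bool = False

    @property
    def nucleotide_change(self) -> tuple[str, str]:
        for p in range(3):
            if self.from_codon[p] != self.to_codon[p]:
                return self.from_codon[p], self.to_codon[p]
        raise ValueError("event with identical codons")


@dataclass
class GeneSimulation:
    """One gene: node sequences (codon indices), its alignment, events."""

    gene_id: str
    node_states: dict[int, np.ndarray]
    events: list[SimEvent]
    gapped: set[tuple[str, int]] = field(default_factory=set)

    def leaf_sequence(self, tree: PhyloTree, taxon: str) -> str:
        """Ungapped nucleotide sequence of a leaf (pre gap-injection)."""
        leaf = tree.node(taxon)
        return "".join(SENSE_CODONS[i] for i in self.node_states[leaf])

    def alignment(self, tree: PhyloTree) -> CodonAlignment:
        seqs = {}
        for leaf in tree.leaves:
            taxon = tree.labels[leaf]
            codons = [SENSE_CODONS[i] for i in self.node_states[leaf]]
            for (t, col) in self.gapped:
                if t == taxon:
                    codons[col] = "---"
            seqs[taxon] = "".join(codons)
        return CodonAlignment(self.gene_id, seqs)


@dataclass
class SimulationTruth:
    """All simulated events plus per-edge synonymous tallies."""

    events: list[SimEvent]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.gene_id, e.edge_label, e.column + 1, e.from_codon, e.to_codon,
              "S" if e.synonymous else "N", int(e.injected))
             for e in self.events],
            columns=["gene", "edge", "column", "from", "to", "class",
                     "injected"])

    def syn_events_on_edge(self, edge_label: str) -> int:
        return sum(1 for e in self.events
                   if e.edge_label == edge_label and e.synonymous)

    def nonsyn_events_on_edge(self, edge_label: str,
                              gene_id: str | None = None) -> int:
        return sum(1 for e in self.events
                   if e.edge_label == edge_label and not e.synonymous
                   and (gene_id is None or e.gene_id == gene_id))

    def injected_events(self) -> list[SimEvent]:
        return [e for e in self.events if e.injected]


@dataclass
class SimulationResult:
    tree: PhyloTree
    model: CodonModel
    config: GeneratorConfig
    genes: dict[str, GeneSimulation]

    @property
    def truth(self) -> SimulationTruth:
        return SimulationTruth([e for g in self.genes.values() for e in g.events])

    def alignments(self) -> dict[str, CodonAlignment]:
        return {gid: g.alignment(self.tree) for gid, g in self.genes.items()}


def _evolve_branch(state: np.ndarray, t: float, model: CodonModel,
                   rng: np.random.Generator) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Gillespie evolution of a codon-index vector along one branch of
    length ``t`` expected substitutions per codon site.  Returns the derived
    state and the (column, from, to) jumps in per-site time order."""
    cur = state.copy()
    events: list[tuple[int, int, int]] = []
    if t <= 0:
        return cur, events
    with np.errstate(divide="ignore"):  # zero exit rate => infinite wait
        wait = rng.exponential(1.0, size=cur.shape[0]) / model.exit_rates[cur]
    exit_rate = model.exit_rates
    for col in np.nonzero(wait < t)[0]:
        tau = wait[col]
        while tau < t:
            i = int(cur[col])
            u = rng.random()
            j = int(np.searchsorted(model.jump_cumulative[i], u, side="right"))
            if j == i or j >= N_CODONS:  # guard against boundary round-off
                tau += rng.exponential(1.0) / exit_rate[i]
                continue
            events.append((int(col), i, j))
            cur[col] = j
            if exit_rate[j] <= 0:
                break  # absorbing under this model (e.g. omega = 0)
            tau += rng.exponential(1.0) / exit_rate[j]
    return cur, events


def simulate_gene(tree: PhyloTree, model: CodonModel, length: int,
                  rng: np.random.Generator, gene_id: str) -> GeneSimulation:
    """Simulate one gene along the tree: root drawn from the stationary
    codon frequencies, then Gillespie event sampling per branch (branch dS
    lengths converted to per-codon-site expected substitutions)."""
    node_states: dict[int, np.ndarray] = {}
    events: list[SimEvent] = []
    node_states[tree.root] = rng.choice(N_CODONS, size=length, p=model.freqs)
    for node in tree.preorder():
        if node == tree.root:
            continue
        t = model.ds_to_subs_per_codon(tree.edge_length(node))
        derived, jumps = _evolve_branch(node_states[tree.parent[node]], t,
                                        model, rng)
        node_states[node] = derived
        label = tree.labels[node]
        for col, i, j in jumps:
            ci, cj = SENSE_CODONS[i], SENSE_CODONS[j]
            events.append(SimEvent(gene_id, node, label, col, ci, cj,
                                   synonymous=is_synonymous(ci, cj)))
    return GeneSimulation(gene_id, node_states, events)


def _nonsyn_neighbours(codon_idx: int) -> list[int]:
    ci = SENSE_CODONS[codon_idx]
    out = []
    for p in range(3):
        for alt in "ACGT":
            if alt == ci[p]:
                continue
            cj = ci[:p] + alt + ci[p + 1:]
            if cj in STOP_CODONS:
                continue
            if not is_synonymous(ci, cj):
                out.append(CODON_INDEX[cj])
    return out


_NONSYN_NEIGHBOURS: list[list[int]] = [_nonsyn_neighbours(i) for i in range(N_CODONS)]


def inject_burst(gene: GeneSimulation, tree: PhyloTree, edge_label: str,
                 k: int, rng: np.random.Generator | int) -> GeneSimulation:
    """Inject k extra non-synonymous single-nucleotide substitutions on an
    edge, at k distinct uniformly chosen codon columns.

    Columns already hit by an event on the edge or anywhere below it are
    avoided so that every descendant of the edge carries the derived allele
    and no other species does; the gene's state vectors at the edge's child
    and all its descendants are updated consistently.  Modifies ``gene`` in
    place and returns it.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    edge = tree.node(edge_label)
    if tree.parent[edge] is None:
        raise ValueError("cannot inject on the root")
    below = [edge] + tree.descendants(edge)
    length = gene.node_states[edge].shape[0]
    touched = {e.column for e in gene.events if e.edge in below}
    candidates = np.array(sorted(set(range(length)) - touched))
    if len(candidates) < k:
        raise ValueError(f"only {len(candidates)} untouched columns available "
                         f"for a burst of k={k}")
    cols = rng.choice(candidates, size=k, replace=False)
    for col in sorted(int(c) for c in cols):
        i = int(gene.node_states[edge][col])
        nbrs = _NONSYN_NEIGHBOURS[i]
        j = int(nbrs[rng.integers(len(nbrs))])
        for node in below:
            gene.node_states[node][col] = j
        gene.events.append(SimEvent(gene.gene_id, edge, edge_label, col,
                                    SENSE_CODONS[i], SENSE_CODONS[j],
                                    synonymous=False, injected=True))
    return gene


def simulate_dataset(config: GeneratorConfig) -> SimulationResult:
    """Simulate a full dataset.  Deterministic for a given config+seed:
    per-gene random substreams are spawned from the master seed."""
    model = CodonModel(kappa=config.kappa, omega=config.omega,
                       freqs=config.freqs)
    master = np.random.SeedSequence(config.seed)
    substreams = master.spawn(config.n_genes)
    lo, hi = config.gene_length_range
    bursts_by_gene: dict[str, list[BurstSpec]] = {}
    for b in config.bursts:
        bursts_by_gene.setdefault(b.gene, []).append(b)

    genes: dict[str, GeneSimulation] = {}
    for gi in range(config.n_genes):
        rng = np.random.default_rng(substreams[gi])
        gene_id = f"g{gi + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        gene = simulate_gene(config.tree, model, length, rng, gene_id)
        for b in bursts_by_gene.get(gene_id, []):
            inject_burst(gene, config.tree, b.edge_label, b.k, rng)
        if config.gap_rate > 0:
            taxa = config.tree.leaf_names
            for col in range(length):
                if rng.random() < config.gap_rate:
                    gene.gapped.add((taxa[rng.integers(len(taxa))], col))
        genes[gene_id] = gene
    unknown = set(bursts_by_gene) - set(genes)
    if unknown:
        raise ValueError(f"burst specs reference unknown genes: {sorted(unknown)}")
    return SimulationResult(config.tree, model, config, genes)


def preset_config(preset: str, seed: int, **overrides) -> GeneratorConfig:
    """Build a GeneratorConfig for a named preset ('gammarid-like',
    'primate-like' or 'custom', the last requiring an explicit tree)."""
    if preset == "gammarid-like":
        tree = PhyloTree.from_newick(GAMMARID_LIKE_NEWICK)
    elif preset == "primate-like":
        tree = PhyloTree.from_newick(PRIMATE_LIKE_NEWICK)
    elif preset == "custom":
        if "tree" not in overrides:
            raise ValueError("custom preset requires a tree")
        tree = overrides.pop("tree")
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    return GeneratorConfig(tree=tree, seed=seed, **overrides)


def make_dataset(preset: str, seed: int, out_dir: str | Path,
                 **overrides) -> SimulationResult:
    """Simulate a preset dataset and write it to disk in the layout the
    detector consumes: per-gene FASTA files, Newick tree, TSV manifest,
    ground-truth event TSV and a config echo."""
    config = preset_config(preset, seed, **overrides)
    result = simulate_dataset(config)
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    manifest = {}
    for gid, gene in result.genes.items():
        p = out / "genes" / f"{gid}.fasta"
        write_codon_fasta(gene.alignment(result.tree), p)
        manifest[gid] = f"genes/{gid}.fasta"
    (out / "tree.nwk").write_text(result.tree.to_newick() + "\n")
    write_manifest(manifest, out / "manifest.tsv")
    result.truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    echo = {
        "preset": preset,
        "seed": seed,
        "n_genes": config.n_genes,
        "gene_length_range": list(config.gene_length_range),
        "omega": config.omega,
        "kappa": config.kappa,
        "gap_rate": config.gap_rate,
        "bursts": [[b.gene, b.edge_label, b.k] for b in config.bursts],
    }
    (out / "config.json").write_text(json.dumps(echo, indent=2) + "\n")
    (out / "README.md").write_text(
        "# Synthetic codon-evolution dataset\n\n"
        f"Preset `{preset}`, seed {seed}: {config.n_genes} genes of "
        f"{config.gene_length_range[0]}-{config.gene_length_range[1]} codons "
        "evolved along `tree.nwk` (branch lengths in dS units) under a "
        f"61-state codon model (kappa={config.kappa}, omega={config.omega}).\n\n"
        "- `genes/*.fasta` - per-gene codon alignments (leaves only)\n"
        "- `manifest.tsv` - gene id -> alignment path\n"
        "- `truth.tsv` - every simulated substitution event (1-based codon "
        "columns; `injected` marks burst events)\n"
        "- `config.json` - generator configuration echo\n")
    return result
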