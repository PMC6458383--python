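"""Burst detection: Poisson test of non-synonymous substitution counts on
short internal edge runs, with BH correction and the filtering pipeline.

The statistic: for a gene with N non-synonymous sites and an edge run of
combined length dS (estimated from the synonymous substitutions of *all*
genes, because a single gene carries almost no synonymous information on a
short edge), the number of non-synonymous substitutions k of that gene on
the run is compared with Poisson(λ = dS × N) under the neutral null
(dN = dS); the p-value is the upper tail P(X ≥ k).  P-values of all
(gene × run) tests in a scan form one Benjamini–Hochberg family.  An
identical scan on synonymous counts (λ = dS × S) serves both as a negative
control and as the paralogue/pseudogene consistency filter: a gene whose
own synonymous count on the run is significantly above the all-gene
expectation is flagged rather than reported as a burst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special
from statsmodels.stats.multitest import multipletests

from .ancestry import marginal_posteriors
from .codon import (CODON_INDEX, SENSE_CODONS, SiteCounts,
                    SubstitutionCounts, classify_path, codon_sites,
                    gene_dnds, jukes_cantor)
from .io import CodonAlignment, EdgeRun, PhyloTree, enumerate_edge_runs
from .model import N_CODONS, CodonModel

# ---------------------------------------------------------------------------
# elementary statistics


def poisson_tail(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(lam),
    via the regularized lower incomplete gamma function (stable for tails
    well below 1e-30)."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k < 0 or k != int(k):
        raise ValueError("k must be a non-negative integer")
    if k == 0:
        return 1.0
    return float(special.gammainc(k, lam))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def estimate_edge_ds(sd_total: float, s_total: float) -> float:
    """Edge length in dS units from pooled synonymous counts of all genes:
    Jukes–Cantor-corrected (Σ Sd) / (Σ S)."""
    if s_total <= 0:
        raise ValueError("zero synonymous sites; cannot estimate dS")
    if sd_total < 0:
        raise ValueError("negative synonymous count")
    return jukes_cantor(sd_total / s_total)


def ds_consistency_test(gene_sd_on_run: float, gene_s: float,
                        run_ds_global: float,
                        alpha: float = 0.001) -> tuple[float, bool]:
    """Test whether a gene's own synonymous count on a run exceeds the
    all-gene expectation (possible paralogue/pseudogene signal).

    Returns (upper-tail Poisson p, passes) where ``passes`` is False when
    p <= alpha.  Within a scan the p entering this rule is BH-adjusted.
    """
    if gene_s <= 0:
        raise ValueError("gene_s must be positive")
    k = math.floor(gene_sd_on_run)
    lam = run_ds_global * gene_s
    p = poisson_tail(k, lam) if lam > 0 else 1.0
    return p, p > alpha


def filter_gap_alignments(alignments: Mapping[str, CodonAlignment],
                          max_gap_fraction: float = 0.5
                          ) -> tuple[dict[str, CodonAlignment], list[str]]:
    """Drop alignments with strictly more than ``max_gap_fraction`` gap
    columns.  Returns (retained, excluded gene ids)."""
    keep, dropped = {}, []
    for gid, aln in alignments.items():
        if aln.gap_fraction > max_gap_fraction:
            dropped.append(gid)
        else:
            keep[gid] = aln
    return keep, dropped


# ---------------------------------------------------------------------------
# configuration / result containers


_ROUNDERS = {"floor": math.floor, "round": round, "ceil": math.ceil}


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds of the scan (defaults are the study's settings)."""

    max_edge_ds: float = 0.005
    min_posterior: float = 0.8
    max_gap_fraction: float = 0.5
    alpha: float = 0.05
    ds_consistency_alpha: float = 0.001
    max_run_edges: int = 2
    rounding: str = "floor"
    kappa: float = 2.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.max_edge_ds <= 0:
            raise ValueError("max_edge_ds must be positive")
        if not 0.0 <= self.min_posterior <= 1.0:
            raise ValueError("min_posterior must be in [0, 1]")
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction must be in [0, 1]")
        for a in (self.alpha, self.ds_consistency_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("significance levels must be in (0, 1)")
        if self.max_run_edges < 1:
            raise ValueError("max_run_edges must be >= 1")
        if self.rounding not in _ROUNDERS:
            raise ValueError(f"rounding must be one of {sorted(_ROUNDERS)}")


@dataclass
class BurstCandidate:
    """One (gene × edge run) test with its filter verdicts."""

    gene_id: str
    run: EdgeRun
    k: int                      # rounded non-synonymous count
    nd_raw: float               # fractional count before rounding
    k_syn: int
    sd_raw: float
    n_sites: float              # gene N after gap + posterior exclusions
    s_sites: float
    lam: float                  # run dS x N
    lam_syn: float
    p_raw: float
    p_adj: float = math.nan
    p_syn_raw: float = math.nan
    p_syn_adj: float = math.nan
    ds_consistency_pass: bool = True
    no_rate_signal: bool = False
    posterior_columns_excluded: int = 0
    significant: bool = False
    gene_dnds_excluding_run: float = math.nan


@dataclass
class ScanResult:
    candidates: list[BurstCandidate]
    syn_candidates: list[BurstCandidate]
    edge_ds: dict[str, float]
    excluded_genes: list[str]
    runs: list[EdgeRun]
    config: ScanConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def significant(self) -> list[BurstCandidate]:
        return [c for c in self.candidates if c.significant]

    def to_frame(self) -> pd.DataFrame:
        rows = [(c.gene_id, c.run.label, c.run.length, c.k, c.nd_raw,
                 c.k_syn, c.sd_raw, c.n_sites, c.s_sites, c.lam, c.p_raw,
                 c.p_adj, c.p_syn_adj, c.ds_consistency_pass,
                 c.significant) for c in self.candidates]
        return pd.DataFrame(rows, columns=[
            "gene", "edge_run", "run_ds", "k_nonsyn", "nd_raw", "k_syn",
            "sd_raw", "n_sites", "s_sites", "lambda", "p_raw", "p_adj",
            "p_syn_adj", "ds_consistency_pass", "significant"])

    def table1(self) -> pd.DataFrame:
        """Per-burst report shaped like the study's summary table: edge run,
        run dS, gene, substitution counts, overall gene dN/dS excluding the
        burst run, adjusted p."""
        rows = [(c.run.label, c.run.length, c.gene_id, c.nd_raw, c.sd_raw,
                 c.gene_dnds_excluding_run, c.p_adj)
                for c in self.significant]
        return pd.DataFrame(rows, columns=[
            "edge_run", "edge_ds", "gene", "nonsyn_substitutions",
            "syn_substitutions", "gene_dnds_excluding_burst", "adjusted_p"])


# ---------------------------------------------------------------------------
# the scan

_ND_PAIR = np.zeros((N_CODONS, N_CODONS))
_SD_PAIR = np.zeros((N_CODONS, N_CODONS))
for _i in range(N_CODONS):
    for _j in range(_i + 1, N_CODONS):
        _sub = classify_path(SENSE_CODONS[_i], SENSE_CODONS[_j])
        _ND_PAIR[_i, _j] = _ND_PAIR[_j, _i] = _sub.Nd
        _SD_PAIR[_i, _j] = _SD_PAIR[_j, _i] = _sub.Sd

_N_BY_CODON = np.array([codon_sites(c).N for c in SENSE_CODONS])
_S_BY_CODON = np.array([codon_sites(c).S for c in SENSE_CODONS])


class _GeneScan:
    """Vectorised per-gene quantities: endpoint states/posteriors for every
    edge over the gapless columns, per-column site counts, per-edge Nd/Sd
    and posterior-excluded columns."""

    def __init__(self, tree: PhyloTree, aln: CodonAlignment,
                 model: CodonModel, min_posterior: float):
        self.tree = tree
        self.aln = aln
        cols = np.array(aln.gapless_columns, dtype=int)
        self.columns = cols
        rec = marginal_posteriors(tree, aln, model)
        n_nodes = tree.n_nodes
        ncol = len(cols)

        state = np.zeros((n_nodes, ncol), dtype=np.int16)
        post = np.ones((n_nodes, ncol))
        for r, node in enumerate(rec.internal_nodes):
            state[node] = rec.map_state[r, cols]
            post[node] = rec.map_posterior[r, cols]
        for leaf in tree.leaves:
            taxon = tree.labels[leaf]
            state[leaf] = [CODON_INDEX[aln.codon(taxon, c)] for c in cols]

        # per-column NG86 site counts averaged over extant taxa
        leaf_ids = tree.leaves
        leaf_states = state[leaf_ids]
        self.n_col = _N_BY_CODON[leaf_states].mean(axis=0)
        self.s_col = _S_BY_CODON[leaf_states].mean(axis=0)

        self.diff: dict[int, np.ndarray] = {}
        self.nd_col: dict[int, np.ndarray] = {}
        self.sd_col: dict[int, np.ndarray] = {}
        self.excluded: dict[int, np.ndarray] = {}
        for edge in tree.edges:
            parent = tree.parent[edge]
            sp, sc = state[parent], state[edge]
            minpost = np.minimum(post[parent], post[edge])
            excl = minpost < min_posterior
            diff = (sp != sc) & ~excl
            self.diff[edge] = diff
            self.nd_col[edge] = np.where(diff, _ND_PAIR[sp, sc], 0.0)
            self.sd_col[edge] = np.where(diff, _SD_PAIR[sp, sc], 0.0)
            self.excluded[edge] = excl

    def run_exclusion(self, run: EdgeRun) -> np.ndarray:
        excl = np.zeros(len(self.columns), dtype=bool)
        for e in run.edges:
            excl |= self.excluded[e]
        return excl

    def run_counts(self, run: EdgeRun) -> tuple[float, float, float, float, int]:
        """(Nd, Sd, N sites, S sites, n excluded columns) on a run, with the
        union of member-edge posterior exclusions applied to both the events
        and the site counts (the 'recalculated statistic')."""
        excl = self.run_exclusion(run)
        keep = ~excl
        nd = sd = 0.0
        for e in run.edges:
            nd += float(self.nd_col[e][keep].sum())
            sd += float(self.sd_col[e][keep].sum())
        n_sites = float(self.n_col[keep].sum())
        s_sites = float(self.s_col[keep].sum())
        return nd, sd, n_sites, s_sites, int(excl.sum())

    def edge_syn_counts(self, edge: int) -> tuple[float, float]:
        """(Sd, S) on one edge after that edge's own posterior exclusion —
        a gene's contribution to the all-gene edge dS estimate."""
        keep = ~self.excluded[edge]
        return float(self.sd_col[edge][keep].sum()), float(self.s_col[keep].sum())

    def totals_excluding(self, exclude_edges: frozenset[int]
                         ) -> SubstitutionCounts:
        nd = sd = 0.0
        for e in self.tree.edges:
            if e in exclude_edges:
                continue
            nd += float(self.nd_col[e].sum())
            sd += float(self.sd_col[e].sum())
        return SubstitutionCounts(nd, sd)


def scan_bursts(tree: PhyloTree, alignments: Mapping[str, CodonAlignment],
                config: ScanConfig = ScanConfig(),
                model: CodonModel | None = None) -> ScanResult:
    """Run the full burst scan.

    Pipeline: gap filter → marginal ancestral reconstruction → substitution
    mapping with posterior-based site exclusion → all-gene edge dS
    estimation → per (gene × run) Poisson tests → BH adjustment over the
    scan → dS-consistency filter → candidates sorted by adjusted p.  The
    synonymous control scan runs identically on synonymous counts and is
    reported separately; any significant synonymous burst raises a
    dataset-level warning.
    """
    if model is None:
        model = CodonModel(kappa=config.kappa, omega=config.omega)
    warnings: list[str] = []

    runs = enumerate_edge_runs(tree, config.max_edge_ds, config.max_run_edges)
    retained, dropped = filter_gap_alignments(alignments,
                                              config.max_gap_fraction)
    if dropped:
        warnings.append(f"{len(dropped)} alignments excluded by the gap filter")
    if not runs or not retained:
        if not runs:
            warnings.append("no internal edge runs below the dS cap")
        return ScanResult([], [], {}, dropped, runs, config, warnings)

    rounder = _ROUNDERS[config.rounding]
    genes = {gid: _GeneScan(tree, aln, model, config.min_posterior)
             for gid, aln in sorted(retained.items())}

    # all-gene dS per member edge, then per run
    member_edges = sorted({e for r in runs for e in r.edges})
    edge_ds: dict[int, float] = {}
    for edge in member_edges:
        sd_tot = s_tot = 0.0
        for g in genes.values():
            sd, s = g.edge_syn_counts(edge)
            sd_tot += sd
            s_tot += s
        edge_ds[edge] = estimate_edge_ds(sd_tot, s_tot)
    edge_ds_labels = {tree.labels[e]: v for e, v in edge_ds.items()}

    candidates: list[BurstCandidate] = []
    syn_candidates: list[BurstCandidate] = []
    for gid, g in genes.items():
        for run in runs:
            nd, sd, n_sites, s_sites, n_excl = g.run_counts(run)
            run_ds = sum(edge_ds[e] for e in run.edges)
            lam = run_ds * n_sites
            lam_syn = run_ds * s_sites
            k = rounder(nd)
            k_syn = rounder(sd)
            no_signal = lam <= 0
            p = 1.0 if no_signal else poisson_tail(k, lam)
            p_syn = 1.0 if lam_syn <= 0 else poisson_tail(k_syn, lam_syn)
            cand = BurstCandidate(gid, run, k, nd, k_syn, sd, n_sites,
                                  s_sites, lam, lam_syn, p, p_syn_raw=p_syn,
                                  no_rate_signal=no_signal,
                                  posterior_columns_excluded=n_excl)
            candidates.append(cand)

    adj = bh_adjust([c.p_raw for c in candidates])
    adj_syn = bh_adjust([c.p_syn_raw for c in candidates])
    for c, a, a_s in zip(candidates, adj, adj_syn):
        c.p_adj = float(a)
        c.p_syn_adj = float(a_s)
        c.ds_consistency_pass = c.p_syn_adj > config.ds_consistency_alpha
        c.significant = (c.p_adj < config.alpha and c.ds_consistency_pass
                         and not c.no_rate_signal)
        if c.p_syn_adj < config.alpha:
            syn_candidates.append(c)
    if syn_candidates:
        warnings.append(
            f"synonymous control: {len(syn_candidates)} significant "
            "synonymous bursts detected (expected none under the null; "
            "possible paralogy or rate heterogeneity)")

    for c in candidates:
        if c.significant:
            g = genes[c.gene_id]
            subs = g.totals_excluding(frozenset(c.run.edges))
            sites = SiteCounts(N=float(g.n_col.sum()), S=float(g.s_col.sum()))
            c.gene_dnds_excluding_run = gene_dnds(subs, sites)

    candidates.sort(key=lambda c: (c.p_adj, c.p_raw, c.gene_id, c.run.label))
    return ScanResult(candidates, syn_candidates, edge_ds_labels, dropped,
                      runs, config, warnings)
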