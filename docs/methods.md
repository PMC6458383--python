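# Methods

This note documents the model and procedure implemented by `burstscan`,
the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## The burst statistic

A *burst* is an excess of non-synonymous (amino-acid-changing)
substitutions of one gene concentrated on a short internal edge of a
phylogeny, or on a run of up to two consecutive internal edges, relative
to a neutral expectation.  The test works edge-run by edge-run and gene by
gene:

1. **Candidate edge runs.**  Only internal edges qualify (both endpoints
   internal nodes, so the derived state is shared by at least two species
   and single-sample sequencing or alignment artefacts cannot create a
   candidate).  A run is a single internal edge of length `< max_edge_ds`
   (default 0.005 dS, strict comparison) or up to `max_run_edges`
   (default 2) consecutive internal edges whose combined length is below
   the cap.  Runs of more than two edges are supported but off by
   default, since two is the longest composite burst the statistic is
   designed around.

2. **Edge length in dS units.**  A single gene of a few hundred codons
   expects ~1 synonymous substitution on a 0.005 dS edge, so per-gene dS
   on a short edge is essentially noise.  The edge's length is therefore
   estimated from all genes jointly:
   `dS = JC( Σ_genes Sd(edge) / Σ_genes S(gene) )`,
   where Sd are mapped synonymous substitutions, S are Nei–Gojobori
   synonymous sites, and JC is the Jukes–Cantor correction
   `−(3/4)·ln(1 − 4p/3)`.  A run's length is the sum of its member
   edges' estimates.

3. **Counting.**  Sites (N, S) follow the unweighted Nei–Gojobori
   convention: each codon position contributes the fraction of its
   single-nucleotide changes that are synonymous to S and the remainder
   to N; changes through stop codons are removed from the denominator, so
   every sense codon contributes exactly 3 sites.  A gene's N and S are
   averaged over its extant taxa and restricted to gapless codon columns.
   Multi-nucleotide codon differences are resolved by averaging syn /
   non-syn step counts over all orderings of the single steps, excluding
   orderings through stops; this produces fractional counts (e.g. 1.5
   non-synonymous + 0.5 synonymous for a two-step difference whose two
   orderings disagree), which are carried as reals end to end.

4. **The test.**  For gene g and run r,
   `λ = dS(r) × N(g)` and `p = P(X ≥ k)` with `X ~ Poisson(λ)` and k the
   gene's mapped non-synonymous count on the run.  Fractional k is
   **floored** before the tail test (configurable floor/round/ceil;
   flooring never overstates significance).  The tail is computed via the
   regularised incomplete gamma function and is accurate far below 1e-30.

5. **Multiplicity.**  All (gene × run) tests of one scan form a single
   Benjamini–Hochberg family.  Scans of different clades are separate
   families (each clade is searched separately).  Whether the original
   analysis adjusted over genes only or genes × edges is not stated
   anywhere we could rely on; genes × runs is the more conservative
   choice and is declared here rather than inferred.

6. **Filters.**
   - Alignments with strictly more than 50% gap codon columns are
     excluded; surviving alignments contribute only gapless columns.
   - Sites whose reconstruction posterior (minimum over the run's
     endpoint nodes) is below 0.8 are removed from the events **and**
     from the site counts, and λ and k are recomputed from the surviving
     sites.  Whether N was recomputed before or after this exclusion in
     the original analysis is unstated; recomputing after is the
     self-consistent reading of "recalculated the statistics".
   - dS consistency: the gene's *own* synonymous count on the run is
     tested against `λ_S = dS(r) × S(g)`; a candidate whose BH-adjusted
     synonymous p is ≤ 0.001 is flagged as a possible anciently diverged
     paralogue or pseudogene (its apparent "burst" being misalignment of
     a fast lineage) and not reported as significant.
   - The same synonymous scan over all genes is the negative control; any
     significant synonymous burst raises a dataset-level warning.

   Filters that require raw reads or genome annotations (read-mapping
   consistency of pre-/post-burst sequences, repeated-domain exclusion,
   genomic-position conservation, manual curation) are **not
   implemented**; the detector lists them as such in its run metadata so
   downstream users know the report is pre-curation.

Degenerate inputs: an edge with zero pooled synonymous substitutions gets
dS = 0, hence λ = 0; rather than calling k > 0 infinitely significant on a
zero-length edge, the candidate is assigned p = 1 and flagged
`no_rate_signal`.  A gene with zero synonymous substitutions outside the
run has undefined dN/dS and reports NaN.

## Ancestral reconstruction

The observed count k requires ancestral states at the run's endpoints.
Reconstruction is marginal, per codon column, under a 61-state codon
model, replacing the external ML reconstruction step a practitioner would
otherwise run:

- **Model.**  HKY-style nucleotide exchangeability with
  transition/transversion ratio κ (default 2), an ω multiplier on
  non-synonymous changes (default ω = 1, the same neutral null the test
  assumes), and stationary codon frequencies (uniform by default,
  configurable).  The matrix is reversible and normalised to one expected
  substitution per codon site per unit time.  The statistic consumes only
  event counts and dS lengths, so reconstruction quality — not fine model
  realism — is what matters; κ and frequency defaults are declared
  choices, not values inferred from any dataset.
- **Units.**  Trees arrive in dS units; per-branch lengths are converted
  to expected substitutions per codon site by the pure function
  `t = dS × S̄ / f_S`, where S̄ is the stationary-expected Nei–Gojobori
  synonymous sites per codon and f_S the synonymous fraction of the
  model's substitution flow.  With this convention the expected mapped
  synonymous substitutions per synonymous site on a branch equal its dS
  length exactly, which is what makes the all-gene dS estimator
  self-consistent (verified by simulation).
- **Numerics.**  Pruning (post-order conditional likelihoods) with
  per-branch transition matrices from a single eigendecomposition of the
  symmetrised rate matrix; per-node rescaling with log-scale accumulators
  guards against underflow; rows of exp(Qt) are clipped at 0 and
  renormalised against round-off.  Posteriors come from a standard
  up-down pass.  MAP ties break to the lexicographically smallest codon
  (deterministic).  Correctness is pinned to an independent oracle:
  direct summation of the joint probability over all internal-node state
  assignments on every ≤5-leaf topology, agreeing to < 1e-10 relative.
- **Gaps.**  Gap or ambiguous codons are missing data (flat partial
  likelihood); reconstruction uses them, but burst statistics use gapless
  columns only.  Leaf endpoints of an edge use their observed codon with
  posterior 1.

## Detectability envelope

The statistic's power has a sharp envelope worth stating explicitly.  A
burst of k substitutions survives BH over m ≈ 10³ tests only if
`P(X ≥ k | λ) ≲ α/m ≈ 5×10⁻⁵`.  For k = 8 this requires **λ ≲ 1**, i.e.
`edge dS × N ≲ 1`.  A 300-codon gene has N ≈ 670, so 8 substitutions are
detectable on edges up to roughly 0.0015 dS — not on every edge below the
0.005 cap (on a 0.004 dS edge, k = 8 gives a raw p around 7×10⁻³, hopeless
after correction; such an edge needs k ≳ 11).  The detectability test
suite therefore evaluates the "k ≥ 8 in ≤ 300 codons" recovery claim on
the preset's sub-0.0015 dS edge runs, the regime where the claim is
mathematically attainable; larger bursts (k ≥ 10–12) are detectable across
the full edge range, as the power tests with k = 10 on a 0.004 dS edge
show.

A second structural blind spot: an edge whose parent is the clade root.
Under a reversible model a substitution there cannot be distinguished from
one on the root's other child edge — the root posterior splits roughly in
proportion to the two edge lengths (e.g. 0.79 / 0.21 for a 0.004 dS edge
against a 0.015 dS sister), so the 0.8-posterior filter removes exactly
the event sites.  This is correct behaviour, not a bug: the method cannot
place such events, and real analyses need outgroup signal for the same
reason.  The synthetic presets keep candidate edges away from the root.

## The synthetic generator

`burstscan.simulate` emulates the *shape* of the study inputs at desk
scale so every pipeline stage is testable without any download:

- a 10-taxon clade-like tree (preset `gammarid-like`) with six internal
  edges of 0.0007–0.004 dS, several consecutive, echoing the edge lengths
  on which real composite bursts sit, and an 11-taxon `primate-like` tree
  with exactly three short internal edges;
- 200 genes (default) of 150–350 codons — a desk-scale stand-in for
  thousands of orthologue clusters; null behaviour at this family size
  transfers to larger families because BH thresholds scale as rank/m;
- neutral evolution (ω = 1) by Gillespie event sampling per branch, root
  sequences from the stationary distribution, branch dS lengths converted
  exactly as in reconstruction;
- optional injected bursts: k extra non-synonymous single-nucleotide
  events at distinct uniformly chosen codon columns of one edge, applied
  consistently to all descendant sequences (columns already hit on or
  below the edge are avoided, so every descendant carries the derived
  allele and no other taxon does);
- a full truth record of every event; replaying truth from the root
  reproduces every leaf sequence exactly, and a single master seed with
  per-gene spawned substreams makes datasets byte-reproducible.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: incomplete lineage sorting and
other sources of gene-tree discordance (the posterior filter is exercised
only mildly), gene conversion and GC-biased fixation, indel processes
(gaps are injected at random rather than evolved), rate variation across
sites and lineages (overdispersed clocks inflate the real false-positive
risk; the test's p-values share this caveat with the original statistic),
codon usage bias (uniform frequencies by default), and alignment error.
Type-I results here validate the machinery under its own null, not the
adequacy of that null for transcriptome data.

## Problem sizes used by the shipped checks

The test suite runs 50 null scans of 200 genes (type-I), 50 burst
replicates of 100 genes (power), a 100-gene dataset for edge-dS recovery,
and a 30-gene dataset for reconstruction accuracy and counting
identities; the acceptance script uses 10 null scans, 20 power
replicates and one 100-gene recovery dataset.  These sizes give
Monte-Carlo error comfortably inside the asserted bounds (e.g. edge-dS
recovery is checked against 3 standard errors of the realised Poisson
counts) while keeping a full run in minutes on one CPU.

## Known limitations

- The Poisson null ignores overdispersion of the molecular clock;
  p-values on real data should be read as outlier scores, as in the
  original analysis.
- Site counting is unweighted NG86; no ML ω estimation is provided or
  intended.
- Marginal (not joint) reconstruction; no branch-length re-estimation,
  no among-site rate variation.
- The dS-consistency filter reuses the synonymous-control scan, so its
  family-wise adjustment is tied to the scan's BH family.
- One-significant-figure rounding (`round_sig`) is how all
  "approximately" figures in prose and reports are produced.
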