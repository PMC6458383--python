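# burstscan

Detection of **bursts of amino acid replacements** — episodes in which a
single protein accumulates many non-synonymous substitutions within a very
short interval of evolutionary time — from codon alignments and a dated
phylogeny.

The package is aimed at molecular evolution researchers who have a set of
orthologous protein-coding gene alignments for a clade of closely related
species (e.g. transcriptome-derived orthologue clusters, or genome-browser
multiple alignments) together with a phylogeny whose branch lengths are in
dS units, and who want to ask: *did any gene undergo a statistically
extreme burst of protein evolution on one of the tree's very short internal
edges?*

## The statistic

Only **internal** edges are used (both endpoints ancestral to more than one
species, so derived alleles are shared and sequencing artefacts cannot
mimic a burst), and only edges — or runs of up to two consecutive edges —
shorter than 0.005 dS.

For a gene with *N* non-synonymous sites (Nei–Gojobori counting) and an
edge run of length *t* dS, the expected number of non-synonymous
substitutions under the neutral null hypothesis (dN = dS) is

    λ = t · N

The edge length *t* is estimated from the pooled synonymous substitutions
of **all** genes on that edge (a single gene carries almost no synonymous
information on a short edge: a 200-codon gene expects only ~1 synonymous
substitution on a 0.005 dS edge).  The observed non-synonymous count *k*
of the gene on the run — obtained by marginal ancestral reconstruction
under a 61-state codon model and mapping of MAP-state differences onto the
edge — gives the p-value

    p = P(X ≥ k),   X ~ Poisson(λ)

All (gene × run) tests in a scan form one Benjamini–Hochberg family.
Candidates then pass through the filters: alignments with >50% gap columns
are excluded; sites whose reconstruction posterior is below 0.8 are removed
and the statistic recalculated; and genes whose *own* synonymous count on
the run significantly exceeds the all-gene expectation (BH-adjusted
p ≤ 0.001) are flagged as possible paralogues rather than reported.  An
identical scan of synonymous counts serves as a negative control.

Because no real transcriptome data ship with the package, a synthetic
codon-evolution generator (`burstscan.simulate`) produces clade-like
datasets — neutral evolution along a tree with short internal edges, with
optional injected bursts — with a full ground-truth record of every
substitution, so the whole pipeline is testable end to end.

## Worked example

Simulate a 40-gene clade-like dataset with a burst of 10 non-synonymous
substitutions injected into gene `g0007` on internal edge `n3`
(0.0007 dS), then scan it:

```sh
$ burstscan simulate --preset gammarid-like --seed 11 --out demo \
      --n-genes 40 --burst g0007:n3:10
wrote 40 genes to demo (5555 true events)

$ burstscan detect --tree demo/tree.nwk --genes demo/manifest.tsv --out demo_scan
360 tests, 3 significant bursts -> demo_scan.table1.tsv
```

`demo_scan.table1.tsv` (the per-burst report):

```
edge_run  edge_ds  gene   nonsyn_substitutions  syn_substitutions  gene_dnds_excluding_burst  adjusted_p
n3        0.0007   g0007  11.0                  0.0                0.646                      2.09e-10
n3+n9     0.0015   g0007  12.0                  1.0                0.653                      1.95e-05
n2+n3     0.0047   g0007  14.0                  0.0                0.627                      9.80e-05
```

The injected burst is recovered on the correct edge (`n3`) with 11 mapped
non-synonymous substitutions (10 injected + 1 neutral background event) and
an adjusted p of 2×10⁻¹⁰; the two overlapping two-edge runs that contain
`n3` flag the same signal.  The gene's overall dN/dS *excluding* the burst
run stays near its neutral background, showing that the burst, not the
gene's baseline rate, drives the detection.  No other gene is significant,
and the synonymous control scan is clean.

The interpretation arithmetic is available as a calculator:

```sh
$ burstscan popgen --enrich 3 5 0.14
fixation probability / generation (4 Ne mu s)  4e-05   (~4e-05)
generations on a 0.004 dS edge                 400000  (~400000)
generations per substitution (k=39)            10256.4 (~10000)
burst rate / protein / dS                      0.00977231 (~0.01)
enrichment P(X>=3), n=5, p0=0.14               0.0220003  (~0.02)
```

i.e. a 0.004 dS edge at μ = 10⁻⁸ spans ≈400 000 generations — ≈10 000 per
substitution for a 39-substitution burst; an advantageous mutation with
s = 0.01 at Nₑ = 10⁵ appears and fixes with probability 4Nₑμs = 4×10⁻⁵ per
generation; 5 bursts among 3411 proteins over 0.15 dS of qualifying edges
give a burst rate of ≈0.01 per protein per dS; and 3 mitochondrial genes
among 5 against a 14% background is a p = 0.022 enrichment.

All of this is equally available as a library — see `burstscan.scan_bursts`,
`burstscan.simulate_dataset`, `burstscan.marginal_posteriors`,
`burstscan.ng86_sites` and friends.

## What is deliberately out of scope

Transcriptome assembly, orthology clustering and tree inference (inputs are
taken as given); maximum-likelihood ω estimation; and the filters that need
raw reads or genome annotations (read-mapping paralogue checks,
repeated-domain exclusion, genomic-position conservation, manual curation)
— the detector lists these as unimplemented filters in its run metadata.

See `docs/methods.md` for the model, its assumptions, the numerical
choices, and known limitations (including the detectability envelope of
the statistic and the root-adjacent-edge blind spot).
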