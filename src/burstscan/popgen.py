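"""Population-genetic back-of-envelope calculators.

Small, pure functions for the arithmetic used to interpret bursts: the
per-generation fixation probability of a recurrent advantageous mutation,
conversion of edge lengths (dS) into generations, the per-protein per-dS
burst rate, and the binomial enrichment test for functional categories of
burst genes.  'Approximately' figures for prose are produced by rounding
to one significant figure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class PopGenParams:
    """Population parameters: census size N, effective size N_e,
    per-nucleotide per-generation mutation rate mu, selection coefficient s.
    """

    N: float
    N_e: float
    mu: float
    s: float

    def __post_init__(self) -> None:
        for name in ("N", "N_e", "mu", "s"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.N_e > self.N > 0:
            warnings.warn("N_e exceeds census size N; check parameters")


def round_sig(x: float, figures: int = 1) -> float:
    """Round to the given number of significant figures (for prose)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, figures - 1 - exp)


def fixation_probability(params: PopGenParams) -> float:
    """Per-generation probability that an advantageous mutation at a given
    site appears and eventually fixes: 2Nμ new copies per generation, each
    fixing with probability 2sN_e/N, i.e. 4 N_e μ s."""
    if params.N_e <= 0 or params.mu <= 0:
        raise ValueError("N_e and mu must be positive")
    if params.s < 0:
        raise ValueError("s must be non-negative")
    return 4.0 * params.N_e * params.mu * params.s


def edge_generations(ds: float, mu: float) -> float:
    """Number of generations an edge of the given dS length corresponds to,
    assuming synonymous sites evolve at the neutral rate μ per generation:
    generations = dS / μ."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    if ds < 0:
        raise ValueError("ds must be non-negative")
    return ds / mu


def per_substitution(generations: float, k: int) -> float:
    """Generations available per substitution when k substitutions occur
    without overlaps within the given number of generations."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return generations / k


def burst_rate(n_bursts: int, n_proteins: int, total_ds: float) -> float:
    """Bursts per protein per unit of dS: the probability that a protein
    undergoes a detectable burst during the time needed for one synonymous
    substitution per site."""
    if n_proteins <= 0 or total_ds <= 0:
        raise ValueError("n_proteins and total_ds must be positive")
    if n_bursts < 0:
        raise ValueError("n_bursts must be non-negative")
    return n_bursts / (n_proteins * total_ds)


def enrichment_binomial(k: int, n: int, p0: float) -> float:
    """Upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0):
    enrichment of a category observed k times among n draws against a
    background frequency p0."""
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))
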