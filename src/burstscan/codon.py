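"""Genetic-code machinery: Nei–Gojobori (NG86) site counting and
substitution classification.

The NG86 method partitions each codon position into synonymous and
non-synonymous "site" fractions by enumerating the three possible
single-nucleotide changes at that position, and classifies observed codon
differences by averaging synonymous / non-synonymous step counts over all
orderings of the single-nucleotide steps connecting the two codons.
Changes through stop codons are excluded before averaging.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"

_standard = CodonTable.unambiguous_dna_by_id[1]

#: stop codons of the standard nuclear code
STOP_CODONS = frozenset(_standard.stop_codons)

#: the 61 sense codons, lexicographic order (A < C < G < T)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
           if c not in STOP_CODONS)
)

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: codon -> single-letter amino acid
TRANSLATION: dict[str, str] = {c: _standard.forward_table[c] for c in SENSE_CODONS}

_PURINES = frozenset("AG")
_WEAK = frozenset("AT")  # A:T pairs (weak); G:C pairs are strong


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a -> b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def is_synonymous(codon_a: str, codon_b: str) -> bool:
    """Synonymy of two *sense* codons (amino acid unchanged)."""
    return TRANSLATION[codon_a] == TRANSLATION[codon_b]


@dataclass(frozen=True)
class SiteCounts:
    """Numbers of non-synonymous (N) and synonymous (S) sites."""

    N: float
    S: float

    def __add__(self, other: "SiteCounts") -> "SiteCounts":
        return SiteCounts(self.N + other.N, self.S + other.S)


@dataclass(frozen=True)
class SubstitutionCounts:
    """Numbers of non-synonymous (Nd) and synonymous (Sd) substitutions.

    Fractional values arise from NG86 path averaging when codons differ at
    more than one position.
    """

    Nd: float
    Sd: float

    def __add__(self, other: "SubstitutionCounts") -> "SubstitutionCounts":
        return SubstitutionCounts(self.Nd + other.Nd, self.Sd + other.Sd)


def _codon_site_counts(codon: str) -> SiteCounts:
    """NG86 site counts of a single sense codon.

    At each position the three single-nucleotide changes are enumerated;
    changes producing a stop codon are excluded from the denominator, so the
    position's one site is redistributed among the remaining changes and the
    codon always contributes exactly 3 sites.
    """
    s = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            neighbour = codon[:pos] + alt + codon[pos + 1:]
            if is_stop(neighbour):
                continue
            counted += 1
            if is_synonymous(codon, neighbour):
                syn += 1
        if counted:
            s += syn / counted
        # counted == 0 cannot occur in the standard code; the position would
        # then contribute a full non-synonymous site.
    return SiteCounts(N=3.0 - s, S=s)


_SITE_COUNT_CACHE: dict[str, SiteCounts] = {c: _codon_site_counts(c) for c in SENSE_CODONS}


def codon_sites(codon: str) -> SiteCounts:
    """NG86 (N, S) site counts for one sense codon."""
    try:
        return _SITE_COUNT_CACHE[codon]
    except KeyError:
        raise ValueError(f"not a sense codon: {codon!r}") from None


def ng86_sites(sequence: str | Sequence[str]) -> SiteCounts:
    """NG86 site counts of a codon sequence.

    Parameters
    ----------
    sequence
        Either a nucleotide string whose length is divisible by 3 or an
        iterable of codons.  Gap codons and stop codons are skipped.

    Raises
    ------
    ValueError
        If the sequence is empty or its length is not divisible by 3.
    """
    if isinstance(sequence, str):
        if len(sequence) == 0:
            raise ValueError("empty sequence")
        if len(sequence) % 3:
            raise ValueError(f"sequence length {len(sequence)} not divisible by 3")
        codons: Iterable[str] = (sequence[i:i + 3] for i in range(0, len(sequence), 3))
    else:
        codons = sequence
        if not codons:
            raise ValueError("empty sequence")

    n = s = 0.0
    counted = 0
    for codon in codons:
        codon = codon.upper()
        if codon in _SITE_COUNT_CACHE:
            sc = _SITE_COUNT_CACHE[codon]
            n += sc.N
            s += sc.S
            counted += 1
        # codons containing gaps / ambiguity codes and stop codons are skipped
    if counted == 0:
        import warnings

        warnings.warn("no countable codons in sequence; zero site counts")
    return SiteCounts(N=n, S=s)


def classify_path(codon_from: str, codon_to: str) -> SubstitutionCounts:
    """Classify the change between two sense codons into (Nd, Sd).

    Codons differing at d positions are connected by d single-nucleotide
    steps; syn / non-syn step counts are averaged with equal weight over all
    d! orderings, excluding orderings that pass through a stop codon.  The
    result is symmetric in its arguments.
    """
    codon_from = codon_from.upper()
    codon_to = codon_to.upper()
    for c in (codon_from, codon_to):
        if c not in CODON_INDEX:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if codon_from[i] != codon_to[i]]
    if not diff:
        return SubstitutionCounts(0.0, 0.0)

    paths: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = codon_from
        nd = sd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_to[pos] + cur[pos + 1:]
            if is_stop(nxt):
                ok = False
                break
            if is_synonymous(cur, nxt):
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:
        # every ordering passes through a stop; fall back to counting the
        # steps without stop exclusion (rare corner, documented)
        for order in itertools.permutations(diff):
            cur = codon_from
            nd = sd = 0.0
            for pos in order:
                nxt = cur[:pos] + codon_to[pos] + cur[pos + 1:]
                if not is_stop(nxt) and is_synonymous(cur, nxt):
                    sd += 1.0
                else:
                    nd += 1.0
                cur = nxt
            paths.append((nd, sd))
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return SubstitutionCounts(Nd=nd, Sd=sd)


SPECTRUM_CATEGORIES = ("AT>GC", "GC>AT", "AT>AT", "GC>GC")


def substitution_spectrum(events: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Count single-nucleotide changes by weak/strong category.

    A and T are 'weak' (AT); G and C are 'strong' (GC).  Every event falls
    in exactly one of ``AT>GC``, ``GC>AT``, ``AT>AT``, ``GC>GC``.
    """
    counts = dict.fromkeys(SPECTRUM_CATEGORIES, 0)
    for frm, to in events:
        frm, to = frm.upper(), to.upper()
        if frm == to:
            raise ValueError(f"event with identical states: {frm}->{to}")
        if frm not in NUCLEOTIDES or to not in NUCLEOTIDES:
            raise ValueError(f"not nucleotides: {frm}->{to}")
        key = ("AT" if frm in _WEAK else "GC") + ">" + ("AT" if to in _WEAK else "GC")
        counts[key] += 1
    return counts


def jukes_cantor(p: float) -> float:
    """Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) of a proportion of
    observed substitutions per site."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p == 0:
        return 0.0
    if p >= 0.75:
        raise ValueError(f"proportion {p} too large for Jukes-Cantor correction")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def gene_dnds(substitutions: SubstitutionCounts, sites: SiteCounts) -> float:
    """dN/dS of a gene by counting (NG86 with Jukes–Cantor correction).

    ``substitutions`` are the summed (Nd, Sd) over the edges of interest
    (typically all edges except a burst-carrying run) and ``sites`` the
    gene's NG86 site counts.  Returns NaN when the ratio is undefined
    (zero synonymous substitutions or zero sites).
    """
    if sites.N <= 0 or sites.S <= 0:
        return math.nan
    if substitutions.Sd == 0:
        return math.nan
    dn = jukes_cantor(substitutions.Nd / sites.N)
    ds = jukes_cantor(substitutions.Sd / sites.S)
    if ds == 0:
        return math.nan
    return dn / ds
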