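"""A 61-state codon substitution model.

HKY-style nucleotide exchangeability (transition/transversion ratio κ) with
an ω multiplier on non-synonymous changes and arbitrary stationary codon
frequencies (uniform by default).  The rate matrix is normalised so that
branch lengths are expected substitutions per codon site; a pure conversion
maps dS branch lengths (synonymous substitutions per synonymous site, the
unit trees arrive in) to per-codon-site lengths via the model's synonymous
flow fraction and its expected NG86 synonymous site count.
"""

from __future__ import annotations

import numpy as np

from .codon import (CODON_INDEX, SENSE_CODONS, codon_sites, is_synonymous,
                    is_transition)

N_CODONS = len(SENSE_CODONS)


class CodonModel:
    """Reversible 61-state codon model.

    Parameters
    ----------
    kappa
        Transition/transversion rate ratio (> 0).
    omega
        Non-synonymous/synonymous rate ratio (>= 0); ω = 1 is the neutral
        null used by the burst test.
    freqs
        Stationary codon frequencies over the 61 sense codons in
        lexicographic order; uniform if omitted.
    """

    def __init__(self, kappa: float = 2.0, omega: float = 1.0,
                 freqs: np.ndarray | None = None):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        if omega < 0:
            raise ValueError("omega must be non-negative")
        if freqs is None:
            freqs = np.full(N_CODONS, 1.0 / N_CODONS)
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != (N_CODONS,):
            raise ValueError(f"freqs must have shape ({N_CODONS},)")
        if np.any(freqs <= 0):
            raise ValueError("codon frequencies must be positive")
        if abs(freqs.sum() - 1.0) > 1e-8:
            raise ValueError("codon frequencies must sum to 1")
        freqs = freqs / freqs.sum()

        self.kappa = float(kappa)
        self.omega = float(omega)
        self.freqs = freqs

        q = np.zeros((N_CODONS, N_CODONS))
        syn_mask = np.zeros((N_CODONS, N_CODONS), dtype=bool)
        for i, ci in enumerate(SENSE_CODONS):
            for j, cj in enumerate(SENSE_CODONS):
                if i == j:
                    continue
                diff = [p for p in range(3) if ci[p] != cj[p]]
                if len(diff) != 1:
                    continue
                p = diff[0]
                rate = freqs[j]
                if is_transition(ci[p], cj[p]):
                    rate *= kappa
                if is_synonymous(ci, cj):
                    syn_mask[i, j] = True
                else:
                    rate *= omega
                q[i, j] = rate
        np.fill_diagonal(q, -q.sum(axis=1))

        # normalise: one expected substitution per codon site per unit time
        total_flow = -float(freqs @ np.diag(q))
        if total_flow <= 0:
            raise ValueError("degenerate rate matrix (zero total flow)")
        q /= total_flow
        self.Q = q
        self.syn_mask = syn_mask

        off = q.copy()
        np.fill_diagonal(off, 0.0)
        #: fraction of the substitution flow that is synonymous
        self.syn_flow_fraction = float(freqs @ (off * syn_mask).sum(axis=1))

        #: expected NG86 synonymous sites per codon under the stationary
        #: distribution (stop-exclusion convention as in codon counting)
        self.mean_syn_sites = float(sum(freqs[i] * codon_sites(c).S
                                        for i, c in enumerate(SENSE_CODONS)))
        self.mean_nonsyn_sites = 3.0 - self.mean_syn_sites

        # eigendecomposition of the symmetrised reversible Q, reused for all
        # transition matrices: Q = D^{-1/2} (V Λ V') D^{1/2}
        sqrt_pi = np.sqrt(freqs)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        sym = 0.5 * (sym + sym.T)  # clean tiny asymmetries
        eigval, eigvec = np.linalg.eigh(sym)
        self._eigval = eigval
        self._left = eigvec.T * sqrt_pi[None, :]         # V' D^{1/2}
        self._right = (1.0 / sqrt_pi)[:, None] * eigvec  # D^{-1/2} V

        # per-codon exit rates and jump distributions for simulation
        self.exit_rates = -np.diag(q).copy()
        with np.errstate(invalid="ignore"):
            jump = off / self.exit_rates[:, None]
        self.jump_cumulative = np.cumsum(jump, axis=1)

    # -- branch-length units ----------------------------------------------

    def ds_to_subs_per_codon(self, ds: float) -> float:
        """Convert a branch length in dS units to expected substitutions per
        codon site under this model (at the model's own ω)."""
        if ds < 0:
            raise ValueError("branch length must be non-negative")
        return ds * self.mean_syn_sites / self.syn_flow_fraction

    def subs_per_codon_to_ds(self, t: float) -> float:
        return t * self.syn_flow_fraction / self.mean_syn_sites

    # -- transition probabilities ------------------------------------------

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t) for a branch of length ``t`` expected
        substitutions per codon site."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        # clip tiny negative round-off and renormalise rows
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def __repr__(self) -> str:
        return (f"CodonModel(kappa={self.kappa}, omega={self.omega}, "
                f"freqs={'uniform' if np.allclose(self.freqs, self.freqs[0]) else 'custom'})")
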