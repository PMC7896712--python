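"""True (expected) rate of inbreeding depression of a simulated population.

The inbreeding load B is the expected decline in the trait mean per unit
increase in the inbreeding coefficient F.  For a biallelic QTL with
genotypic values 0 / ah / a and mutant-allele frequency q, inbreeding by F
shifts 2pq*F heterozygotes to homozygotes, changing the mean by -2dpq*F with
d = a(h - 1/2).  Summed over segregating QTLs this gives B = sum 2dpq; with
deleterious (a < 0), partially recessive (h < 1/2) mutations every d > 0,
i.e. dominance is directional and the load is positive.

The same quantity is also computed "experimentally" by forcing every
individual to complete homozygosity (F = 1) and taking the drop in the mean,
which serves as an internal consistency check of the formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simcore import PopulationState

__all__ = ["TrueID", "true_id_2dpq", "true_id_forced_homozygosity",
           "true_id"]


@dataclass(frozen=True)
class TrueID:
    """Inbreeding load of one population, by formula and by forcing F=1."""

    B_2dpq: float
    B_forced: float
    n_qtl: int


def true_id_2dpq(pop: PopulationState) -> float:
    """Inbreeding load B = sum over segregating QTLs of 2 d p q.

    d = a(h - 1/2), p the wild-type and q the mutant allele frequency in the
    current generation.
    """
    qcols = np.flatnonzero(pop.is_qtl)
    if qcols.size == 0:
        return 0.0
    q = pop.haplotypes[:, qcols].mean(axis=0)
    p = 1.0 - q
    d = pop.a[qcols] * (pop.h[qcols] - 0.5)
    return float(np.sum(2.0 * d * p * q))


def true_id_forced_homozygosity(pop: PopulationState) -> float:
    """Load measured by making every individual fully homozygous.

    Each heterozygous QTL genotype (value ah) is replaced by the expected
    value of the two homozygotes it can resolve into, (0 + a)/2; the change
    per heterozygous locus is a/2 - ah = -d.  The decline in the population
    mean is returned as a per-unit-F rate, taking the baseline mean F of the
    population as ~0 (its actual value, about -1/2N, is negligible).
    """
    qcols = np.flatnonzero(pop.is_qtl)
    if qcols.size == 0:
        return 0.0
    g = pop.genotypes(qcols)
    d = pop.a[qcols] * (pop.h[qcols] - 0.5)
    per_ind_drop = (g == 1) @ d  # decline of each individual when forced
    return float(per_ind_drop.mean())


def true_id(pop: PopulationState) -> TrueID:
    """Both load computations plus the segregating QTL count."""
    return TrueID(B_2dpq=true_id_2dpq(pop),
                  B_forced=true_id_forced_homozygosity(pop),
                  n_qtl=int(pop.is_qtl.sum()))
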