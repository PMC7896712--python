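"""SNP-by-SNP genomic inbreeding coefficients.

Four per-individual measures of inbreeding computed from a dense panel of
biallelic SNPs with minor-allele dosages x in {0, 1, 2} and allele
frequencies p (the analysed panel's own frequencies by default):

* ``f_I``   - diagonal of the VanRaden genomic relationship matrix minus 1
              ("VanRaden2", GCTA Fhat1).
* ``f_II``  - excess homozygosity scaled per SNP (GCTA Fhat2).
* ``f_III`` - correlation between uniting gametes (GCTA Fhat3, also known
              as F_UNI / F_GRM / F_alt), which weights homozygotes by the
              inverse of their allele frequency and so emphasises rare
              alleles.
* ``f_hom`` - observed-vs-expected heterozygote count (PLINK --het).

With the panel's own frequencies all four have the same expectation, the
Hardy-Weinberg deviation of a panmictic population (about -1/2N); computed
with the frequencies of an earlier reference generation they instead
estimate identity by descent accumulated since that generation,
1 - (1 - 1/2N)^t under pure drift.
"""

from __future__ import annotations

import numpy as np

from .markers_io import MarkerPanel

__all__ = ["f_I", "f_II", "f_III", "f_III_delta", "f_hom",
           "compute_f_estimates", "estimates_table"]


def _genotypes_and_freqs(panel, ref_freqs):
    if isinstance(panel, MarkerPanel):
        x = panel.genotypes
        p = panel.p if ref_freqs is None else ref_freqs
    else:
        x = np.asarray(panel)
        if ref_freqs is None:
            p = x.mean(axis=0) / 2.0
        else:
            p = ref_freqs
    x = x.astype(np.float64)
    p = np.asarray(p, dtype=np.float64)
    if ((x < 0) | (x > 2)).any():
        raise ValueError("genotype dosages must be complete and in {0,1,2}")
    if ((p <= 0.0) | (p >= 1.0)).any():
        raise ValueError("allele frequencies must lie strictly in (0, 1); "
                         "monomorphic sites cannot enter the estimators")
    return x, p


def f_I(panel, ref_freqs: np.ndarray | None = None) -> np.ndarray:
    """F^I_i = (1/S) sum_k (x_ik - 2 p_k)^2 / (2 p_k (1 - p_k)) - 1."""
    x, p = _genotypes_and_freqs(panel, ref_freqs)
    w = 2.0 * p * (1.0 - p)
    return ((x - 2.0 * p) ** 2 / w).mean(axis=1) - 1.0


def f_II(panel, ref_freqs: np.ndarray | None = None) -> np.ndarray:
    """F^II_i = 1 - (1/S) sum_k x_ik (2 - x_ik) / (2 p_k (1 - p_k))."""
    x, p = _genotypes_and_freqs(panel, ref_freqs)
    w = 2.0 * p * (1.0 - p)
    return 1.0 - (x * (2.0 - x) / w).mean(axis=1)


def f_III(panel, ref_freqs: np.ndarray | None = None) -> np.ndarray:
    """F^III_i = (1/S) sum_k [x^2 - (1+2p) x + 2p^2] / (2 p (1 - p))."""
    x, p = _genotypes_and_freqs(panel, ref_freqs)
    w = 2.0 * p * (1.0 - p)
    num = x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p
    return (num / w).mean(axis=1)


def f_III_delta(panel) -> np.ndarray:
    """F^III by its homozygote-weight reformulation (cross-check only).

    Per SNP, delta = 1/p for minor-allele homozygotes, 1/(1-p) for
    major-allele homozygotes and 0 for heterozygotes; the estimator is the
    opposite sign of 1 - (sum delta)/S, i.e. (sum delta)/S - 1.  Must agree
    with :func:`f_III` to numerical precision; it exists to make the heavy
    weighting of rare-allele homozygotes explicit and to cross-check the
    quadratic form.
    """
    x, p = _genotypes_and_freqs(panel, None)
    delta = np.where(x == 2, 1.0 / p, 0.0) + np.where(x == 0,
                                                      1.0 / (1.0 - p), 0.0)
    return delta.mean(axis=1) - 1.0


def f_hom(panel, ref_freqs: np.ndarray | None = None) -> np.ndarray:
    """F_HOM,i = 1 - sum_k x(2-x) / sum_k 2 p (1 - p)  (PLINK --het)."""
    x, p = _genotypes_and_freqs(panel, ref_freqs)
    expected_het = np.sum(2.0 * p * (1.0 - p))
    observed_het = (x * (2.0 - x)).sum(axis=1)
    return 1.0 - observed_het / expected_het


def compute_f_estimates(panel, ref_freqs: np.ndarray | None = None) -> dict:
    """All four SNP-by-SNP estimators as a name -> vector mapping."""
    return {
        "F_I": f_I(panel, ref_freqs),
        "F_II": f_II(panel, ref_freqs),
        "F_III": f_III(panel, ref_freqs),
        "F_HOM": f_hom(panel, ref_freqs),
    }


def estimates_table(panel, ref_freqs: np.ndarray | None = None):
    """Per-individual estimator table (one row per individual).

    Returns a pandas DataFrame indexed by individual id with the four
    estimator columns; write with ``.to_csv(path, sep="\\t")`` for a
    delimited-text export.
    """
    import pandas as pd

    values = compute_f_estimates(panel, ref_freqs)
    n = len(next(iter(values.values())))
    return pd.DataFrame(values,
                        index=pd.Index([f"IND{i + 1}" for i in range(n)],
                                       name="individual"))
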