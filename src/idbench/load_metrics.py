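"""Homozygous mutation load (HML) per individual.

The load counts loci at which an individual carries two copies of the
mutant (derived) allele — a common proxy for the burden of recessive
deleterious variation.  Three flavours:

* ``HML``      - over all neutral SNPs;
* ``HML_MAF``  - over neutral SNPs with minor-allele frequency <= 0.05,
                 where derived and minor alleles almost always coincide;
* ``HML_QTL``  - over the (pleiotropic) QTLs themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers_io import MarkerPanel
from .simcore import PopulationState

__all__ = ["HMLValues", "hml_counts", "hml_from_population",
           "MAF_THRESHOLD"]

MAF_THRESHOLD = 0.05


@dataclass
class HMLValues:
    """Per-individual homozygous mutation loads (integer counts)."""

    HML: np.ndarray
    HML_MAF: np.ndarray
    HML_QTL: np.ndarray

    def as_dict(self) -> dict:
        return {"HML": self.HML, "HML_MAF": self.HML_MAF,
                "HML_QTL": self.HML_QTL}


def hml_counts(panel: MarkerPanel, qtl_genotypes: np.ndarray,
               maf_threshold: float = MAF_THRESHOLD) -> HMLValues:
    """Count derived-allele homozygotes per individual.

    ``panel`` must carry the derived-allele orientation
    (``derived_is_minor``); ``qtl_genotypes`` is the (N, n_qtl) derived
    dosage at QTLs from the same population.  The MAF filter is inclusive
    (<= ``maf_threshold``) and applies to the minor allele frequency.
    """
    if panel.derived_is_minor is None:
        raise ValueError("panel lacks derived-allele orientation; "
                         "HML needs a panel extracted from a population")
    derived_hom = np.where(panel.derived_is_minor, panel.genotypes == 2,
                           panel.genotypes == 0)
    hml = derived_hom.sum(axis=1)
    rare = panel.p <= maf_threshold
    hml_maf = derived_hom[:, rare].sum(axis=1)
    qtl_genotypes = np.atleast_2d(qtl_genotypes)
    hml_qtl = (qtl_genotypes == 2).sum(axis=1)
    return HMLValues(HML=hml, HML_MAF=hml_maf, HML_QTL=hml_qtl)


def hml_from_population(pop: PopulationState, panel: MarkerPanel,
                        maf_threshold: float = MAF_THRESHOLD) -> HMLValues:
    """Convenience wrapper pulling the QTL genotypes out of ``pop``."""
    qtl_g = pop.genotypes(np.flatnonzero(pop.is_qtl))
    return hml_counts(panel, qtl_g, maf_threshold)
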