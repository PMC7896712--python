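"""Neutral-SNP marker panels and PLINK PED/MAP text I/O.

The marker panel is what the downstream estimators see: every individual of
the population typed at every segregating *neutral* SNP (QTLs are removed,
no MAF pruning), with genotypes recoded to minor-allele dosage using the
current-generation frequencies.  Panels round-trip through the PLINK text
formats (a single chromosome; alleles coded 1/2 with 2 = minor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simcore import PopulationState

__all__ = ["MarkerPanel", "PanelError", "extract_marker_panel",
           "write_ped_map", "read_ped_map"]

MISSING_ALLELE = "0"


class PanelError(ValueError):
    """Panel construction or file parsing failed."""


@dataclass
class MarkerPanel:
    """Individuals x neutral-SNP genotype matrix in minor-allele dosage.

    Attributes
    ----------
    genotypes : (N, S) int8 matrix of minor-allele counts in {0, 1, 2}.
    positions : (S,) int64 base-pair positions (0-based), sorted ascending.
    p : (S,) minor-allele frequencies, in (0, 0.5].
    derived_is_minor : (S,) bool, or None when the orientation of the
        mutant allele is unknown (e.g. after reading from PED/MAP, which
        does not encode it).
    """

    genotypes: np.ndarray
    positions: np.ndarray
    p: np.ndarray
    derived_is_minor: np.ndarray | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def het(self) -> np.ndarray:
        """(N, S) boolean heterozygosity matrix (dosage == 1)."""
        return self.genotypes == 1

    def subset(self, cols: np.ndarray) -> "MarkerPanel":
        """Panel restricted to the given SNP columns."""
        return MarkerPanel(
            genotypes=self.genotypes[:, cols],
            positions=self.positions[cols],
            p=self.p[cols],
            derived_is_minor=None if self.derived_is_minor is None
            else self.derived_is_minor[cols],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, MarkerPanel):
            return NotImplemented
        same = (np.array_equal(self.genotypes, other.genotypes)
                and np.array_equal(self.positions, other.positions)
                and np.allclose(self.p, other.p))
        if self.derived_is_minor is not None \
                and other.derived_is_minor is not None:
            same = same and np.array_equal(self.derived_is_minor,
                                           other.derived_is_minor)
        return same


def extract_marker_panel(pop: PopulationState) -> MarkerPanel:
    """Neutral-SNP panel of the whole population, recoded to minor alleles.

    The derived allele becomes the counted allele when its frequency is
    <= 0.5 (ties at exactly 0.5 count the derived allele); otherwise dosage
    is flipped to count the ancestral allele.  Deterministic given the
    population.
    """
    ncols = np.flatnonzero(~pop.is_qtl)
    if ncols.size == 0:
        raise PanelError("population segregates no neutral SNPs")
    x = pop.genotypes(ncols)  # derived dosage
    q = pop.haplotypes[:, ncols].mean(axis=0)  # derived frequency
    derived_is_minor = q <= 0.5
    x = np.where(derived_is_minor, x, 2 - x).astype(np.int8)
    p = np.where(derived_is_minor, q, 1.0 - q)
    return MarkerPanel(genotypes=x, positions=pop.positions[ncols].copy(),
                       p=p, derived_is_minor=derived_is_minor)


def _require_complete(panel: MarkerPanel) -> None:
    if ((panel.genotypes < 0) | (panel.genotypes > 2)).any():
        raise PanelError("panel contains missing or invalid genotypes; "
                         "estimators require complete data")


def write_ped_map(panel: MarkerPanel, prefix: str,
                  cm_per_bp: float = 1e-6) -> tuple[str, str]:
    """Write ``prefix.ped`` and ``prefix.map`` (PLINK text, one chromosome).

    MAP columns: chromosome (1), SNP id, genetic position in cM
    (bp * cm_per_bp, i.e. bp * c * 100), 1-based bp.  PED alleles are coded
    1/2 per SNP with 2 = the minor allele.  Returns the two file paths.
    """
    if panel.n_snps == 0:
        raise PanelError("refusing to write an empty panel")
    _require_complete(panel)
    ped_path, map_path = f"{prefix}.ped", f"{prefix}.map"
    with open(map_path, "w") as fh:
        for k in range(panel.n_snps):
            bp = int(panel.positions[k]) + 1
            fh.write(f"1\tsnp{k}\t{panel.positions[k] * cm_per_bp:.8g}"
                     f"\t{bp}\n")
    allele_pairs = {0: "1 1", 1: "1 2", 2: "2 2"}
    with open(ped_path, "w") as fh:
        for i in range(panel.n_individuals):
            cols = [f"FAM1 IND{i + 1} 0 0 0 -9"]
            cols.extend(allele_pairs[int(g)] for g in panel.genotypes[i])
            fh.write(" ".join(cols) + "\n")
    return ped_path, map_path


def read_ped_map(prefix: str) -> MarkerPanel:
    """Read ``prefix.ped``/``prefix.map`` back into a MarkerPanel.

    Minor-allele frequencies are recomputed from the genotypes; the
    derived-allele orientation is not representable in PED/MAP and comes
    back as None.  Missing genotypes (allele code 0) are rejected because
    every downstream estimator assumes complete data.
    """
    positions = []
    with open(f"{prefix}.map") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) != 4:
                raise PanelError(f"{prefix}.map line {lineno}: expected 4 "
                                 f"columns, got {len(fields)}")
            positions.append(int(fields[3]) - 1)
    positions = np.asarray(positions, dtype=np.int64)
    n_snps = positions.size

    rows = []
    with open(f"{prefix}.ped") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if len(fields) != 6 + 2 * n_snps:
                raise PanelError(
                    f"{prefix}.ped line {lineno}: expected "
                    f"{6 + 2 * n_snps} columns, got {len(fields)}")
            alleles = fields[6:]
            dosage = np.empty(n_snps, dtype=np.int8)
            for k in range(n_snps):
                a1, a2 = alleles[2 * k], alleles[2 * k + 1]
                if MISSING_ALLELE in (a1, a2):
                    raise PanelError(f"{prefix}.ped line {lineno}: missing "
                                     f"genotype at SNP {k}; estimators "
                                     f"require complete data")
                if a1 not in ("1", "2") or a2 not in ("1", "2"):
                    raise PanelError(f"{prefix}.ped line {lineno}: "
                                     f"inconsistent allele code at SNP {k}")
                dosage[k] = (a1 == "2") + (a2 == "2")
            rows.append(dosage)
    genotypes = np.vstack(rows)
    p = genotypes.mean(axis=0) / 2.0
    return MarkerPanel(genotypes=genotypes, positions=positions, p=p)
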