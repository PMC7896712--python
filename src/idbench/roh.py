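"""Runs of homozygosity: LD pruning, window-based calling, and F_ROH.

The caller mirrors the PLINK 1.9 ``--homozyg`` defaults: a 50-SNP scanning
window may contain at most 1 heterozygote to count as homozygous; a SNP is
eligible when at least 5% of the windows covering it are homozygous; maximal
runs of eligible SNPs are split at >1 Mb inter-SNP gaps and kept when they
contain >= 100 SNPs, span at least ``min_length_mb`` and average at most
50 kb per SNP.  F_ROH is the fraction of the genome inside kept segments,
evaluated at 0.1 / 1 / 5 Mb minimum lengths.  Before calling, SNP pairs in
high linkage disequilibrium (r^2 > 0.9 in sliding 50-SNP windows stepped by
5) are thinned, as is standard practice before ROH scans.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .markers_io import MarkerPanel

__all__ = ["ROHParams", "ROHSegment", "ld_prune", "call_roh", "f_roh",
           "compute_f_roh", "segments_table", "DEFAULT_MIN_LENGTHS_MB"]

DEFAULT_MIN_LENGTHS_MB = (0.1, 1.0, 5.0)


@dataclass(frozen=True)
class ROHParams:
    """PLINK-style ROH caller parameters (defaults = PLINK 1.9 defaults,
    except the minimum segment length which is scanned at 0.1/1/5 Mb)."""

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5   # kept for format compatibility; no missing data
    window_threshold: float = 0.05
    min_snp: int = 100
    min_density_kb_per_snp: float = 50.0
    max_gap_kb: float = 1000.0
    min_length_mb: float = 0.1

    def __post_init__(self) -> None:
        if min(self.window_snp, self.window_het + 1, self.min_snp) <= 0 or \
                min(self.window_threshold, self.min_density_kb_per_snp,
                    self.max_gap_kb, self.min_length_mb) <= 0:
            raise ValueError("all ROH parameters must be positive")
        if self.min_snp < self.window_snp:
            raise ValueError("min_snp must be >= window_snp")

    def scaled(self, factor: float) -> "ROHParams":
        """Length thresholds scaled by ``factor`` (e.g. 1e-3 for a short
        test genome, keeping the SNP-count parameters unchanged)."""
        return ROHParams(
            window_snp=self.window_snp, window_het=self.window_het,
            window_missing=self.window_missing,
            window_threshold=self.window_threshold, min_snp=self.min_snp,
            min_density_kb_per_snp=self.min_density_kb_per_snp * factor,
            max_gap_kb=self.max_gap_kb * factor,
            min_length_mb=self.min_length_mb * factor)


@dataclass(frozen=True)
class ROHSegment:
    """One run of homozygosity (bp span = first to last SNP)."""

    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(panel: MarkerPanel, window: int = 50, step: int = 5,
             r2_max: float = 0.9) -> MarkerPanel:
    """Thin SNPs in high LD (PLINK ``--indep-pairwise window step r2``).

    Windows of ``window`` SNPs advance by ``step``; while any retained pair
    within the window has squared dosage correlation above ``r2_max``, the
    pair member with the smaller minor-allele frequency is removed (ties
    remove the downstream SNP).  Deterministic.
    """
    S = panel.n_snps
    keep = np.ones(S, dtype=bool)
    if S < 2:
        return panel
    x = panel.genotypes.astype(np.float64)
    maf = panel.p
    for start in range(0, S, step):
        idx = np.flatnonzero(keep[start:start + window]) + start
        if idx.size < 2:
            if start + window >= S:
                break
            continue
        sub = x[:, idx]
        sub = sub - sub.mean(axis=0)
        cov = sub.T @ sub
        var = np.diag(cov).copy()
        var[var == 0.0] = np.nan  # monomorphic in sample: undefined r
        with np.errstate(invalid="ignore"):
            r2 = cov * cov / np.outer(var, var)
        alive = np.ones(idx.size, dtype=bool)
        while True:
            hit = None
            for ii in range(idx.size):
                if not alive[ii]:
                    continue
                for jj in range(ii + 1, idx.size):
                    if alive[jj] and r2[ii, jj] > r2_max:
                        hit = (ii, jj)
                        break
                if hit:
                    break
            if hit is None:
                break
            ii, jj = hit
            drop = jj if maf[idx[ii]] >= maf[idx[jj]] else ii
            alive[drop] = False
            keep[idx[drop]] = False
        if start + window >= S:
            break
    return panel.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# ROH calling
# ---------------------------------------------------------------------------

def _eligible_snps(het: np.ndarray, params: ROHParams) -> np.ndarray:
    """Boolean (n_ind, S) eligibility from the scanning-window hit rate."""
    n_ind, S = het.shape
    w = params.window_snp
    n_win = S - w + 1
    cs = np.zeros((n_ind, S + 1), dtype=np.int32)
    np.cumsum(het, axis=1, out=cs[:, 1:])
    win_het = cs[:, w:] - cs[:, :-w]              # (n_ind, n_win)
    hom_win = (win_het <= params.window_het).astype(np.int32)
    hw = np.zeros((n_ind, n_win + 1), dtype=np.int32)
    np.cumsum(hom_win, axis=1, out=hw[:, 1:])
    k = np.arange(S)
    lo = np.maximum(0, k - w + 1)
    hi = np.minimum(k, n_win - 1)
    hits = hw[:, hi + 1] - hw[:, lo]
    n_cover = hi - lo + 1
    return hits / n_cover >= params.window_threshold


def _segments_from_runs(eligible: np.ndarray, positions: np.ndarray,
                        params: ROHParams) -> list[ROHSegment]:
    """Maximal eligible runs -> gap split -> SNP/length/density filters."""
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return []
    max_gap_bp = params.max_gap_kb * 1000.0
    pos = positions[idx]
    # break a run where eligibility is interrupted or the bp gap is too wide
    brk = np.flatnonzero((np.diff(idx) > 1) |
                         (np.diff(pos) > max_gap_bp)) + 1
    segments = []
    for chunk in np.split(idx, brk):
        n = chunk.size
        if n < params.min_snp:
            continue
        start, end = int(positions[chunk[0]]), int(positions[chunk[-1]])
        length = end - start
        if length < params.min_length_mb * 1e6:
            continue
        if length / n > params.min_density_kb_per_snp * 1000.0:
            continue
        segments.append(ROHSegment(start, end, n))
    return segments


def call_roh(genotypes: np.ndarray, positions: np.ndarray,
             params: ROHParams = ROHParams()) -> list[list[ROHSegment]]:
    """ROH segments per individual from a (pruned) genotype matrix.

    ``genotypes`` is (n_individuals, S) dosage (any allele orientation:
    only heterozygosity matters), ``positions`` the matching bp coordinates
    sorted ascending.  Returns one (possibly empty) sorted, non-overlapping
    segment list per individual.
    """
    genotypes = np.atleast_2d(genotypes)
    positions = np.asarray(positions)
    if genotypes.shape[1] < params.window_snp:
        warnings.warn("fewer SNPs than the scanning window; no ROH called",
                      stacklevel=2)
        return [[] for _ in range(genotypes.shape[0])]
    eligible = _eligible_snps((genotypes == 1).astype(np.int8), params)
    return [_segments_from_runs(eligible[i], positions, params)
            for i in range(genotypes.shape[0])]


def segments_table(seg_lists: list[list[ROHSegment]]):
    """Per-individual segment table (individual id, start/end bp, SNPs).

    Returns a pandas DataFrame with one row per called segment; write with
    ``.to_csv(path, sep="\\t")`` for a delimited-text export.
    """
    import pandas as pd

    rows = [(f"IND{i + 1}", seg.start_bp, seg.end_bp, seg.n_snps)
            for i, segs in enumerate(seg_lists) for seg in segs]
    return pd.DataFrame(rows, columns=["individual", "start_bp", "end_bp",
                                       "n_snps"])


def f_roh(segments: list[ROHSegment], min_length_mb: float,
          genome_length: float) -> float:
    """Genome fraction inside segments at least ``min_length_mb`` long."""
    total = sum(seg.length_bp for seg in segments
                if seg.length_bp >= min_length_mb * 1e6)
    return total / genome_length


def compute_f_roh(panel: MarkerPanel, genome_length: float,
                  params: ROHParams = ROHParams(),
                  min_lengths_mb: tuple = DEFAULT_MIN_LENGTHS_MB,
                  prune: bool = True) -> dict:
    """LD-prune, call ROH once, and evaluate F_ROH at several length cuts.

    The caller's own ``min_length_mb`` is set to the smallest cut; longer
    cuts are obtained by filtering, which is exact because the minimum
    length enters the caller only as a final filter.  Returns a mapping
    like ``{"F_ROH_1": (n_individuals,) array, ...}`` keyed by the Mb cut.
    """
    work = ld_prune(panel) if prune else panel
    base = dataclasses.replace(params, min_length_mb=min(min_lengths_mb))
    seg_lists = call_roh(work.genotypes, work.positions, base)
    out = {}
    for cut in min_lengths_mb:
        key = f"F_ROH_{cut:g}"
        out[key] = np.array([f_roh(segs, cut, genome_length)
                             for segs in seg_lists])
    return out
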