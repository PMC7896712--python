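"""Numba kernels for the inner loops of the forward simulator.

The genotype state is a dense (2N, S) uint8 haplotype matrix, but derived
alleles are sparse (the site-frequency spectrum is dominated by rare
variants), so the per-generation work iterates a CSR-style index of the
derived alleles of each haplotype row instead of scanning the matrix:
a counting pass decides which sites survive, and an assembly pass writes
each recombinant gamete's derived alleles straight into the compacted,
position-sorted column layout of the next generation.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def fill_row_nonzero(haps, offsets, idx):
    """CSR index of derived alleles: row r's set columns land in
    ``idx[offsets[r]:offsets[r+1]]`` (ascending).

    ``idx`` needs one slot of slack (branchless: every column is stored,
    the cursor only advances on derived alleles).
    """
    n_rows, n_sites = haps.shape
    for r in range(n_rows):
        k = offsets[r]
        for j in range(n_sites):
            idx[k] = j
            k += haps[r, j]


@njit(cache=True, inline="always")
def _lower_bound(arr, lo, hi, val):
    while lo < hi:
        mid = (lo + hi) >> 1
        if arr[mid] < val:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def count_alleles(nz_idx, nz_off, hap_row_a, hap_row_b, start_strand,
                  cut_sites, cut_offsets, colsum):
    """Accumulate the derived-allele count each gamete will contribute.

    Gamete g copies from row ``hap_row_a[g]`` when the current strand is 0
    and ``hap_row_b[g]`` when it is 1, starting at ``start_strand[g]`` and
    flipping at every breakpoint in
    ``cut_sites[cut_offsets[g]:cut_offsets[g+1]]`` (site indices, sorted).
    """
    n_gam = hap_row_a.shape[0]
    n_sites = colsum.shape[0]
    for g in range(n_gam):
        cur = start_strand[g]
        prev = 0
        for k in range(cut_offsets[g], cut_offsets[g + 1] + 1):
            cut = cut_sites[k] if k < cut_offsets[g + 1] else n_sites
            r = hap_row_a[g] if cur == 0 else hap_row_b[g]
            i = _lower_bound(nz_idx, nz_off[r], nz_off[r + 1], prev)
            while i < nz_off[r + 1] and nz_idx[i] < cut:
                colsum[nz_idx[i]] += 1
                i += 1
            cur = 1 - cur
            prev = cut


@njit(cache=True)
def assemble_compact(nz_idx, nz_off, hap_row_a, hap_row_b, start_strand,
                     cut_sites, cut_offsets, colmap, out):
    """Write recombinant gametes straight into the compacted layout.

    ``colmap[j]`` is the destination column of parental site j, or -1 when
    the site does not survive.  ``out`` must be zero-initialised; only
    derived alleles are stored.
    """
    n_gam = hap_row_a.shape[0]
    n_sites = colmap.shape[0]
    for g in range(n_gam):
        cur = start_strand[g]
        prev = 0
        for k in range(cut_offsets[g], cut_offsets[g + 1] + 1):
            cut = cut_sites[k] if k < cut_offsets[g + 1] else n_sites
            r = hap_row_a[g] if cur == 0 else hap_row_b[g]
            i = _lower_bound(nz_idx, nz_off[r], nz_off[r + 1], prev)
            while i < nz_off[r + 1] and nz_idx[i] < cut:
                dest = colmap[nz_idx[i]]
                if dest >= 0:
                    out[g, dest] = 1
                i += 1
            cur = 1 - cur
            prev = cut
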