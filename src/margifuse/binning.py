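"""Genome binning and sparse binned count matrices.

A :class:`GenomeBinning` partitions every chromosome into fixed-width bins
and assigns each bin a global index in chromosome order, so a genome-wide
interaction matrix is a single sparse 2D array.  Positions arriving from
.pairs files are 1-based; BED intervals are 0-based half-open; conversion
happens at the call boundary, never inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


class GenomeBinning:
    """Fixed-width genome binning with global, chromosome-ordered bin indices.

    Bin of a 1-based position: ``floor((pos - 1) / bin_size_bp)`` within its
    chromosome, offset by the cumulative bin count of preceding chromosomes.
    """

    def __init__(self, bin_size_bp: int, chrom_sizes: dict[str, int]):
        if bin_size_bp <= 0:
            raise ValueError("bin_size_bp must be positive")
        if not chrom_sizes:
            raise ValueError("chrom_sizes is empty")
        self.bin_size_bp = int(bin_size_bp)
        self.chrom_sizes = dict(chrom_sizes)
        self._n_bins = {
            c: int(np.ceil(size / bin_size_bp)) for c, size in self.chrom_sizes.items()
        }
        self._offsets = {}
        off = 0
        for c in self.chrom_sizes:
            self._offsets[c] = off
            off += self._n_bins[c]
        self.n_bins = off

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenomeBinning)
            and self.bin_size_bp == other.bin_size_bp
            and self.chrom_sizes == other.chrom_sizes
        )

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._offsets

    def bin_of(self, chrom: str, pos_1based: int) -> int:
        """Global bin index of a 1-based genomic position."""
        return self._offsets[chrom] + (int(pos_1based) - 1) // self.bin_size_bp

    def bins_of(self, chroms: np.ndarray, pos_1based: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`bin_of`; raises KeyError on unknown chromosome."""
        offsets = np.array([self._offsets[c] for c in chroms], dtype=np.int64)
        return offsets + (np.asarray(pos_1based, dtype=np.int64) - 1) // self.bin_size_bp

    def chrom_of_bin(self, global_bin: int) -> str:
        for c in self.chrom_sizes:
            off = self._offsets[c]
            if off <= global_bin < off + self._n_bins[c]:
                return c
        raise IndexError(f"bin {global_bin} out of range")

    def chrom_bin_range(self, chrom: str) -> tuple[int, int]:
        """Half-open global bin index range [start, stop) of a chromosome."""
        off = self._offsets[chrom]
        return off, off + self._n_bins[chrom]

    def to_dict(self) -> dict:
        return {"bin_size_bp": self.bin_size_bp, "chrom_sizes": self.chrom_sizes}

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeBinning":
        return cls(d["bin_size_bp"], d["chrom_sizes"])


@dataclass
class BinnedMatrix:
    """Sparse binned count matrix (rows = RNA end / gene A, cols = DNA end / gene B)."""

    binning: GenomeBinning
    counts: sp.csr_matrix
    normalization: str = "raw"  # {"raw", "row-normalized"}

    @classmethod
    def empty(cls, binning: GenomeBinning) -> "BinnedMatrix":
        n = binning.n_bins
        return cls(binning, sp.csr_matrix((n, n)))

    @classmethod
    def from_bin_pairs(
        cls, binning: GenomeBinning, rows: np.ndarray, cols: np.ndarray
    ) -> "BinnedMatrix":
        n = binning.n_bins
        data = np.ones(len(rows), dtype=np.int64)
        m = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        return cls(binning, m)

    def total(self) -> float:
        return float(self.counts.sum())

    def to_triplets(self) -> pd.DataFrame:
        """Nonzero entries as a (row_bin, col_bin, count) table."""
        coo = self.counts.tocoo()
        df = pd.DataFrame({"row_bin": coo.row, "col_bin": coo.col, "count": coo.data})
        return df.sort_values(["row_bin", "col_bin"]).reset_index(drop=True)


def row_normalize(matrix: BinnedMatrix) -> BinnedMatrix:
    """Divide each nonzero row by its sum; zero rows pass through unchanged."""
    if matrix.normalization != "raw":
        raise ValueError("matrix is already row-normalized")
    m = matrix.counts.tocsr().astype(float)
    row_sums = np.asarray(m.sum(axis=1)).ravel()
    scale = np.ones_like(row_sums)
    nz = row_sums > 0
    scale[nz] = 1.0 / row_sums[nz]
    normed = sp.diags(scale) @ m
    return BinnedMatrix(matrix.binning, normed.tocsr(), normalization="row-normalized")
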