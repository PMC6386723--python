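"""Binned interaction maps, distance decay, gene-pair rankings and attachment profiles."""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .binning import BinnedMatrix, GenomeBinning, row_normalize  # noqa: F401 (re-export)
from .coloc import OverlapRule, interacting_gene_pairs


def _known_mask(binning: GenomeBinning, chroms: np.ndarray) -> np.ndarray:
    return np.array([binning.has_chrom(c) for c in chroms], dtype=bool)


def bin_interactions(
    pairs: pd.DataFrame, binning: GenomeBinning, on_unknown_chrom: str = "error"
) -> BinnedMatrix:
    """Count read pairs into (RNA-end bin, DNA-end bin) cells.

    Raw mode conserves the total: the matrix sum equals the number of
    contributing pairs.  ``on_unknown_chrom``: ``"error"`` raises on a pair
    mapped to a chromosome absent from the binning, ``"skip"`` drops it.
    """
    if on_unknown_chrom not in ("error", "skip"):
        raise ValueError("on_unknown_chrom must be 'error' or 'skip'")
    if len(pairs) == 0:
        return BinnedMatrix.empty(binning)
    rchrom = pairs["rna_chrom"].to_numpy()
    dchrom = pairs["dna_chrom"].to_numpy()
    ok = _known_mask(binning, rchrom) & _known_mask(binning, dchrom)
    if not ok.all():
        if on_unknown_chrom == "error":
            bad = set(rchrom[~ok]) | set(dchrom[~ok])
            raise KeyError(f"pairs on chromosomes outside the binning: {sorted(bad - set(binning.chrom_sizes))}")
        pairs = pairs[ok]
        rchrom, dchrom = rchrom[ok], dchrom[ok]
    rows = binning.bins_of(rchrom, pairs["rna_pos"].to_numpy())
    cols = binning.bins_of(dchrom, pairs["dna_pos"].to_numpy())
    return BinnedMatrix.from_bin_pairs(binning, rows, cols)


def distance_decay(
    pairs: pd.DataFrame,
    binning: GenomeBinning,
    min_count: int = 10,
) -> pd.DataFrame:
    """Number of populated bin pairs per genomic separation.

    Only intrachromosomal pairs contribute (proximal pairs are expected to
    have been removed upstream).  For each separation ``s`` (|RNA bin − DNA
    bin| within a chromosome, reported in bp as ``s * bin_size``) the value
    is the count of ordered (RNA bin, DNA bin) cells whose read count is at
    least ``min_count``.

    Returns a DataFrame with columns ``separation_bp`` and ``n_bin_pairs``
    covering every separation up to the longest chromosome.
    """
    intra = pairs[pairs["rna_chrom"].to_numpy() == pairs["dna_chrom"].to_numpy()]
    max_bins = max(
        int(np.ceil(size / binning.bin_size_bp)) for size in binning.chrom_sizes.values()
    )
    seps = np.arange(max_bins, dtype=np.int64)
    values = np.zeros(max_bins, dtype=np.int64)
    if len(intra):
        matrix = bin_interactions(intra, binning, on_unknown_chrom="error")
        coo = matrix.counts.tocoo()
        keep = coo.data >= min_count
        sep = np.abs(coo.row[keep] - coo.col[keep])
        np.add.at(values, sep, 1)
    return pd.DataFrame(
        {"separation_bp": seps * binning.bin_size_bp, "n_bin_pairs": values}
    )


def gene_pair_counts(
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    rule: OverlapRule = OverlapRule(),
    exclude_genes: Iterable[str] = (),
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Read-pair counts for every interacting gene pair, ranked descending.

    Genes in ``exclude_genes`` (e.g. extremely abundant noncoding RNAs such
    as XIST or MALAT1, which blanket the genome with contacts) are removed
    before ranking.  Ties rank by canonical gene-pair order.
    """
    excluded = set(exclude_genes)
    kept = annotation[~annotation["gene_id"].isin(excluded)]
    if len(kept) == 0:
        return pd.DataFrame(columns=["gene_a", "gene_b", "n_read_pairs"])
    counts = interacting_gene_pairs(pairs, kept, rule, chrom_sizes)
    rows = [(a, b, n) for (a, b), n in counts.items()]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_read_pairs"])
    return df.sort_values(
        ["n_read_pairs", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


def attachment_level(pairs: pd.DataFrame, binning: GenomeBinning) -> np.ndarray:
    """Per-bin RNA attachment level: DNA-end read count in each genomic bin.

    The conventional bin size for cross-dataset comparison is 100 kb.
    Returns a dense vector over all global bins; its sum equals the number
    of input pairs on chromosomes covered by the binning.
    """
    profile = np.zeros(binning.n_bins, dtype=np.int64)
    if len(pairs) == 0:
        return profile
    chroms = pairs["dna_chrom"].to_numpy()
    ok = _known_mask(binning, chroms)
    bins = binning.bins_of(chroms[ok], pairs["dna_pos"].to_numpy()[ok])
    np.add.at(profile, bins, 1)
    return profile


def profile_correlation(p1: np.ndarray, p2: np.ndarray) -> float:
    """Pearson correlation of two attachment profiles on the same binning.

    NaN when either profile has zero variance (the correlation is undefined).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("profiles have different binnings")
    if p1.std() == 0 or p2.std() == 0:
        return math.nan
    return float(np.corrcoef(p1, p2)[0, 1])


def fusion_map(
    futra_pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    binning: GenomeBinning,
    on_unknown_gene: str = "skip",
) -> BinnedMatrix:
    """Symmetric genome × genome map of Futra-pair counts.

    Each gene is located at its body midpoint (a single bin even when the
    body straddles a bin boundary).  Every pair increments (bin_a, bin_b)
    and its transpose; pairs whose genes share a bin are counted once on
    the diagonal.  The conventional bin size is 10 Mb.
    """
    genes = annotation.set_index("gene_id")
    rows, cols = [], []
    for rec in futra_pairs.itertuples(index=False):
        try:
            ga, gb = genes.loc[rec.gene_a], genes.loc[rec.gene_b]
        except KeyError:
            if on_unknown_gene == "error":
                raise
            continue
        mid_a = int((ga["start"] + ga["end"]) // 2)
        mid_b = int((gb["start"] + gb["end"]) // 2)
        ba = binning.bin_of(ga["chrom"], mid_a + 1)
        bb = binning.bin_of(gb["chrom"], mid_b + 1)
        rows.append(ba)
        cols.append(bb)
        if ba != bb:
            rows.append(bb)
            cols.append(ba)
    return BinnedMatrix.from_bin_pairs(
        binning, np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64)
    )
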