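"""Readers and writers for the text formats the pipeline speaks.

* mapped read pairs — 4DN ``.pairs`` text (1-based positions, ``#columns:``
  header; side 1 = RNA end, side 2 = DNA end);
* gene annotation — BED6 (0-based half-open; the BED name field is the
  gene id);
* chromosome sizes — 2-column TSV;
* fusion calls — TSV with STAR-Fusion-compatible column mapping;
* Futra catalogs — TSV and BEDPE;
* binned matrices — triplet TSV plus a binning sidecar JSON;
* FISH images — single-channel TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .binning import BinnedMatrix, GenomeBinning
from .pairs import PAIR_COLUMNS, RawReadPair

PAIRS_HEADER = "## pairs format v1.0"
_PAIRS_COLUMN_LINE = "#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2"

#: STAR-Fusion column names -> internal names.
STARFUSION_COLUMNS = {
    "#FusionName": "fusion_name",
    "JunctionReadCount": "junction_read_count",
    "SpanningFragCount": "spanning_frag_count",
    "LeftGene": "gene_a",
    "RightGene": "gene_b",
}


def write_pairs(pairs: pd.DataFrame, path: str | Path,
                chrom_sizes: Mapping[str, int] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(PAIRS_HEADER + "\n")
        if chrom_sizes:
            for c, size in chrom_sizes.items():
                fh.write(f"#chromsize: {c} {size}\n")
        fh.write(_PAIRS_COLUMN_LINE + "\n")
        layout = ["read_id", "rna_chrom", "rna_pos", "dna_chrom", "dna_pos",
                  "rna_strand", "dna_strand"]  # 4DN column order
        pairs[layout].to_csv(fh, sep="\t", header=False, index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    """Read a 4DN .pairs text file into the canonical pair table."""
    path = Path(path)
    names = None
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            if line.startswith("#columns:"):
                names = line.split(":", 1)[1].split()
    df = pd.read_csv(path, sep="\t", skiprows=skip, header=None)
    if names and len(names) == df.shape[1]:
        rename = {
            "readID": "read_id",
            "chrom1": "rna_chrom", "pos1": "rna_pos", "strand1": "rna_strand",
            "chrom2": "dna_chrom", "pos2": "dna_pos", "strand2": "dna_strand",
        }
        df.columns = [rename.get(n, n) for n in names]
    else:
        df.columns = PAIR_COLUMNS[: df.shape[1]]
    return df[PAIR_COLUMNS]


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    pd.Series(chrom_sizes).to_csv(path, sep="\t", header=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_bed6(annotation: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["start"],
            "end": annotation["end"],
            "name": annotation["gene_id"],
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"].astype(int),
            "end": bed["end"].astype(int),
            "strand": bed["strand"],
        }
    )


def write_fusion_calls(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_fusion_calls(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a fusion-call TSV; ``column_map`` renames foreign headers.

    Pass ``STARFUSION_COLUMNS`` for raw STAR-Fusion output (the sample id
    must then be supplied in a ``sample_id`` column by the caller's
    preprocessing, as STAR-Fusion emits one file per sample).
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return df


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_catalog_bedpe(
    catalog: pd.DataFrame, annotation: pd.DataFrame, path: str | Path
) -> None:
    """Catalog as BEDPE: the two gene-body intervals plus pair metadata."""
    genes = annotation.set_index("gene_id")
    rows = []
    for rec in catalog.itertuples(index=False):
        ga, gb = genes.loc[rec.gene_a], genes.loc[rec.gene_b]
        rows.append(
            (
                ga["chrom"], ga["start"], ga["end"],
                gb["chrom"], gb["start"], gb["end"],
                f"{rec.gene_a}--{rec.gene_b}", rec.recurrence,
                ga["strand"], gb["strand"], rec.pair_class,
                "" if pd.isna(rec.distance_bp) else int(rec.distance_bp),
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_matrix(matrix: BinnedMatrix, path_prefix: str | Path) -> None:
    """Write a binned matrix as ``<prefix>.tsv`` plus ``<prefix>.binning.json``."""
    prefix = Path(path_prefix)
    matrix.to_triplets().to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
    sidecar = {"normalization": matrix.normalization, **matrix.binning.to_dict()}
    prefix.with_suffix(".binning.json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path_prefix: str | Path) -> BinnedMatrix:
    import scipy.sparse as sp

    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".binning.json").read_text())
    binning = GenomeBinning(meta["bin_size_bp"], meta["chrom_sizes"])
    trip = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    n = binning.n_bins
    m = sp.coo_matrix(
        (trip["count"], (trip["row_bin"], trip["col_bin"])), shape=(n, n)
    ).tocsr()
    return BinnedMatrix(binning, m, normalization=meta.get("normalization", "raw"))


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path) -> Iterator[RawReadPair]:
    """Iterate raw read pairs from two mate FASTQ files (R1 = RNA end)."""
    from Bio import SeqIO

    for rec1, rec2 in zip(SeqIO.parse(str(r1_path), "fastq"),
                          SeqIO.parse(str(r2_path), "fastq")):
        yield RawReadPair(rec1.id, str(rec1.seq), str(rec2.seq))


def write_image_tiff(image: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(str(path)))
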