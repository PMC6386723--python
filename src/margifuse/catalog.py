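"""Building the catalog of fusion-transcript-contributing gene pairs.

Per-sample fusion-transcript calls (STAR-Fusion-style tables carrying
junction-read and spanning-fragment support counts) are reduced to the set
of unique unordered gene pairs — *Futra pairs* — with their recurrence
across samples, intra/interchromosomal class and genomic distance.

Two filters shape the catalog:

* the call-level support filter: junction reads > 0, spanning fragments > 0
  and their sum > 2;
* the neighbour-pair filter: intrachromosomal pairs whose gene bodies lie
  within 200 kb of each other are removed, since read-through transcription
  between adjacent genes mimics fusion transcripts.

Gene-pair distance is the gap between gene bodies (0 when the bodies
overlap), not a TSS-to-TSS distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CALL_COLUMNS = ["sample_id", "gene_a", "gene_b", "junction_read_count", "spanning_frag_count"]
ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]

#: Default neighbour-removal distance in bp.
MIN_FUTRA_DISTANCE_BP = 200_000

INTRA = "intrachromosomal"
INTER = "interchromosomal"


def canonical_pair(gene_a: str, gene_b: str) -> tuple[str, str]:
    """Order-free representation of a gene pair (lexicographic)."""
    return (gene_a, gene_b) if gene_a <= gene_b else (gene_b, gene_a)


def filter_fusion_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Apply the call-support filter.

    A call is kept iff ``junction_read_count > 0`` and
    ``spanning_frag_count > 0`` and their sum is > 2.  Records with missing
    counts raise, naming the offending sample/pair.
    """
    j = calls["junction_read_count"]
    s = calls["spanning_frag_count"]
    missing = j.isna() | s.isna()
    if missing.any():
        bad = calls.loc[missing, ["sample_id", "gene_a", "gene_b"]].astype(str)
        ids = "; ".join("/".join(row) for row in bad.itertuples(index=False, name=None))
        raise ValueError(f"fusion calls with missing support counts: {ids}")
    keep = (j > 0) & (s > 0) & ((j + s) > 2)
    return calls[keep].reset_index(drop=True)


def gene_pair_distance(g1: pd.Series, g2: pd.Series) -> float:
    """Genomic distance between two gene bodies.

    Returns the gap ``max(0, max(starts) - min(ends))`` for same-chromosome
    genes (0 when bodies overlap or touch), and ``inf`` as the
    interchromosomal marker.
    """
    if g1["chrom"] != g2["chrom"]:
        return math.inf
    return float(max(0, max(g1["start"], g2["start"]) - min(g1["end"], g2["end"])))


def _annotation_index(annotation: pd.DataFrame) -> pd.DataFrame:
    idx = annotation.set_index("gene_id", verify_integrity=True)
    return idx


def build_futra_pairs(
    calls: pd.DataFrame,
    annotation: pd.DataFrame,
    min_distance_bp: int = MIN_FUTRA_DISTANCE_BP,
    on_unknown_gene: str = "error",
) -> pd.DataFrame:
    """Reduce filtered fusion calls to the unique Futra-pair catalog.

    Parameters
    ----------
    calls
        Fusion-call table (already passed through :func:`filter_fusion_calls`).
    annotation
        Gene table with columns ``gene_id, chrom, start, end, strand``
        (0-based half-open coordinates).
    min_distance_bp
        Intrachromosomal pairs with body gap <= this value are removed.
    on_unknown_gene
        ``"error"`` raises on a call naming an unannotated gene; ``"skip"``
        drops the call.

    Returns
    -------
    DataFrame with one row per retained unique pair: ``gene_a, gene_b``
    (canonical lexicographic order), ``recurrence`` (number of distinct
    samples), ``pair_class`` and ``distance_bp`` (NaN for interchromosomal).
    """
    if on_unknown_gene not in ("error", "skip"):
        raise ValueError("on_unknown_gene must be 'error' or 'skip'")
    genes = _annotation_index(annotation)
    known = set(genes.index)

    rows: dict[tuple[str, str], set[str]] = {}
    for rec in calls.itertuples(index=False):
        a, b = rec.gene_a, rec.gene_b
        if a not in known or b not in known:
            if on_unknown_gene == "error":
                missing = a if a not in known else b
                raise KeyError(f"fusion call names unannotated gene {missing!r}")
            continue
        rows.setdefault(canonical_pair(a, b), set()).add(rec.sample_id)

    out = []
    for (a, b), samples in rows.items():
        d = gene_pair_distance(genes.loc[a], genes.loc[b])
        if math.isinf(d):
            pair_class, dist = INTER, math.nan
        else:
            if d <= min_distance_bp:
                continue  # neighbouring genes: likely read-through, not fusion
            pair_class, dist = INTRA, d
        out.append((a, b, len(samples), pair_class, dist))

    cat = pd.DataFrame(out, columns=["gene_a", "gene_b", "recurrence", "pair_class", "distance_bp"])
    return cat.sort_values(["gene_a", "gene_b"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class RecurrenceSummary:
    """Recurrence histogram of a Futra-pair catalog."""

    histogram: dict[int, int]
    n_pairs: int
    singleton_fraction: float


def recurrence_summary(futra_pairs: pd.DataFrame) -> RecurrenceSummary:
    """Histogram of recurrence values and the fraction of single-sample pairs."""
    if len(futra_pairs) == 0:
        return RecurrenceSummary({}, 0, math.nan)
    counts = futra_pairs["recurrence"].value_counts().sort_index()
    hist = {int(k): int(v) for k, v in counts.items()}
    n = int(len(futra_pairs))
    singles = hist.get(1, 0)
    return RecurrenceSummary(hist, n, singles / n)
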