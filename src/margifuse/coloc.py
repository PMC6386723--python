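"""Colocalization of Futra pairs with RNA–DNA interactions, and enrichment tests.

The overlap rule: an iMARGI read pair overlaps a gene pair (A, B) when its
RNA end maps strand-specifically inside the body of one gene and its DNA end
maps inside the other gene's body extended by a flanking window (±100 kb by
default), in either orientation.  The DNA-end strand is never tested; the
RNA-end strand test is configurable (``sense`` by default: the mapped strand
must equal the gene's annotated strand).

Enrichment of interactions on Futra pairs relative to a background universe
of same-class gene pairs is scored on a 2×2 contingency table with the odds
ratio and a χ² test (Yates-corrected by default, matching R's convention for
2×2 tables).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import chi2 as chi2_dist

from .catalog import INTER, INTRA, canonical_pair


@dataclass(frozen=True)
class OverlapRule:
    """Parameters of the read-pair / gene-pair overlap rule.

    ``strand_mode``: ``sense`` requires the RNA-end strand to equal the
    gene's strand, ``antisense`` the opposite, ``ignore`` skips the test.
    """

    flank_bp: int = 100_000
    strand_mode: str = "sense"

    def __post_init__(self):
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if self.strand_mode not in ("sense", "antisense", "ignore"):
            raise ValueError("strand_mode must be sense, antisense or ignore")

    def strand_ok(self, read_strand: str, gene_strand: str) -> bool:
        if self.strand_mode == "ignore":
            return True
        if self.strand_mode == "sense":
            return read_strand == gene_strand
        return read_strand != gene_strand


class GeneIndex:
    """Interval index over gene bodies and flank-extended bodies, per chromosome.

    Built once per (annotation, rule); queries return gene ids whose body
    (RNA-end query, with strand test) or flanked body (DNA-end query)
    contains a 1-based position.
    """

    def __init__(self, annotation: pd.DataFrame, rule: OverlapRule,
                 chrom_sizes: Optional[Mapping[str, int]] = None):
        self.rule = rule
        self.genes = annotation.set_index("gene_id", verify_integrity=True)
        self._body: dict[str, IntervalTree] = {}
        self._flank: dict[str, IntervalTree] = {}
        flank = rule.flank_bp
        for rec in annotation.itertuples(index=False):
            body = self._body.setdefault(rec.chrom, IntervalTree())
            body[rec.start:rec.end] = (rec.gene_id, rec.strand)
            lo = max(0, rec.start - flank)
            hi = rec.end + flank
            if chrom_sizes is not None and rec.chrom in chrom_sizes:
                hi = min(hi, chrom_sizes[rec.chrom])
            fl = self._flank.setdefault(rec.chrom, IntervalTree())
            fl[lo:hi] = rec.gene_id

    def rna_genes(self, chrom: str, pos_1based: int, strand: str) -> list[str]:
        """Genes whose body contains the RNA end, passing the strand test."""
        tree = self._body.get(chrom)
        if tree is None:
            return []
        p0 = int(pos_1based) - 1
        return [gid for iv in tree[p0] for gid, gstrand in [iv.data]
                if self.rule.strand_ok(strand, gstrand)]

    def dna_genes(self, chrom: str, pos_1based: int) -> list[str]:
        """Genes whose flank-extended body contains the DNA end."""
        tree = self._flank.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree[int(pos_1based) - 1]]


def _in_body(pos_1based: int, chrom: str, gene: pd.Series) -> bool:
    return chrom == gene["chrom"] and gene["start"] <= pos_1based - 1 < gene["end"]


def _in_flank(pos_1based: int, chrom: str, gene: pd.Series, flank_bp: int) -> bool:
    lo = max(0, gene["start"] - flank_bp)
    return chrom == gene["chrom"] and lo <= pos_1based - 1 < gene["end"] + flank_bp


def pair_overlaps_futra(
    pair,
    gene_a: str,
    gene_b: str,
    annotation: pd.DataFrame,
    rule: OverlapRule = OverlapRule(),
) -> bool:
    """Does one read pair overlap one gene pair under the rule?

    ``pair`` is any mapping/namespace with rna_chrom, rna_pos, rna_strand,
    dna_chrom, dna_pos fields.  True iff the RNA end lies in one gene's body
    (strand test per rule) and the DNA end lies within the other gene's
    flank-extended body, in either gene order.
    """
    genes = annotation if annotation.index.name == "gene_id" else annotation.set_index("gene_id")
    try:
        ga, gb = genes.loc[gene_a], genes.loc[gene_b]
    except KeyError as e:
        raise KeyError(f"gene not in annotation: {e.args[0]!r}") from e
    p = pair._asdict() if hasattr(pair, "_asdict") else pair  # namedtuple / Series / dict
    for rna_gene, dna_gene in ((ga, gb), (gb, ga)):
        if (
            _in_body(p["rna_pos"], p["rna_chrom"], rna_gene)
            and rule.strand_ok(p["rna_strand"], rna_gene["strand"])
            and _in_flank(p["dna_pos"], p["dna_chrom"], dna_gene, rule.flank_bp)
        ):
            return True
    return False


def interacting_gene_pairs(
    pairs: pd.DataFrame,
    annotation: pd.DataFrame,
    rule: OverlapRule = OverlapRule(),
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> dict[tuple[str, str], int]:
    """Count supporting read pairs for every interacting unordered gene pair.

    A read pair supports (A, B) when the overlap rule holds in either
    orientation; each read pair contributes at most once per gene pair.
    Returns a dict keyed by canonical gene-pair tuples.
    """
    index = GeneIndex(annotation, rule, chrom_sizes)
    counts: dict[tuple[str, str], int] = {}
    for rec in pairs.itertuples(index=False):
        rna_hits = index.rna_genes(rec.rna_chrom, rec.rna_pos, rec.rna_strand)
        if not rna_hits:
            continue
        dna_hits = index.dna_genes(rec.dna_chrom, rec.dna_pos)
        seen: set[tuple[str, str]] = set()
        for r in rna_hits:
            for d in dna_hits:
                if r != d:
                    seen.add(canonical_pair(r, d))
        for key in seen:
            counts[key] = counts.get(key, 0) + 1
    return counts


def colocalization_report(
    futra_pairs: pd.DataFrame,
    pairs_by_dataset: Mapping[str, pd.DataFrame] | pd.DataFrame,
    annotation: pd.DataFrame,
    rule: OverlapRule = OverlapRule(),
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Flag each Futra pair as overlapped by RNA–DNA interactions.

    ``pairs_by_dataset`` maps dataset names (e.g. cell types) to read-pair
    tables; a bare DataFrame is treated as one dataset named ``"pairs"``.
    The output carries one boolean column per dataset plus ``any_dataset``
    (union) and ``all_datasets`` (intersection), mirroring "either / both"
    comparisons across cell types.
    """
    if isinstance(pairs_by_dataset, pd.DataFrame):
        pairs_by_dataset = {"pairs": pairs_by_dataset}
    out = futra_pairs.copy()
    flag_cols = []
    for name, pairs in pairs_by_dataset.items():
        hits = interacting_gene_pairs(pairs, annotation, rule, chrom_sizes)
        col = f"overlap_{name}"
        out[col] = [
            canonical_pair(a, b) in hits
            for a, b in zip(out["gene_a"], out["gene_b"])
        ]
        flag_cols.append(col)
    out["any_dataset"] = out[flag_cols].any(axis=1)
    out["all_datasets"] = out[flag_cols].all(axis=1)
    return out


def colocalization_fractions(report: pd.DataFrame, flag_col: str = "any_dataset") -> dict[str, float]:
    """Overlapped fraction per pair class (NaN for an absent class)."""
    out = {}
    for cls in (INTRA, INTER):
        sub = report[report["pair_class"] == cls]
        out[cls] = float(sub[flag_col].mean()) if len(sub) else math.nan
    return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 enrichment table.

    a = Futra pairs with interaction, b = without; c = background gene pairs
    with interaction, d = without.  The odds ratio is (a·d)/(b·c); the χ²
    statistic (1 df, optional Yates continuity correction) gives the p-value.
    ``log_or_ci95`` is the Woolf (log-odds ± 1.96·SE) interval, infinite when
    any cell is 0.
    """

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    chi2: float
    p_value: float
    yates: bool
    log_or_ci95: tuple[float, float]
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "odds_ratio": self.odds_ratio, "chi2": self.chi2,
            "p_value": self.p_value, "yates": self.yates,
            "log_or_ci95_low": self.log_or_ci95[0],
            "log_or_ci95_high": self.log_or_ci95[1],
            "note": self.note,
        }


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = True) -> tuple[float, float]:
    """χ² statistic and p-value (1 df) for a 2×2 table.

    Uses the margin form χ² = n(|ad − bc| − corr)² / (r1·r2·c1·c2) with
    corr = n/2 under Yates, 0 otherwise.  Returns (nan, nan) when a margin
    is zero (the test is undefined).
    """
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return math.nan, math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff * diff / (r1 * r2 * c1 * c2)
    p = float(chi2_dist.sf(stat, df=1))
    return float(stat), p


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a·d)/(b·c); inf when b·c = 0 and a·d > 0, NaN when both products are 0."""
    num, den = a * d, b * c
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def enrichment_test(
    n_futra_with: int,
    n_futra_without: int,
    n_background_with: int,
    n_background_without: int,
    yates: bool = True,
) -> ContingencyTable2x2:
    """Score interaction enrichment on Futra pairs vs a background universe."""
    a, b, c, d = (int(n_futra_with), int(n_futra_without),
                  int(n_background_with), int(n_background_without))
    orr = odds_ratio(a, b, c, d)
    stat, p = chi2_2x2(a, b, c, d, yates=yates)
    note = "" if not math.isnan(stat) else "chi2 undefined: zero margin"
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo, hi = math.log(orr) - 1.96 * se, math.log(orr) + 1.96 * se
    else:
        lo, hi = -math.inf, math.inf
    return ContingencyTable2x2(a, b, c, d, orr, stat, p, yates, (lo, hi), note)


def background_gene_pairs(
    annotation: pd.DataFrame,
    pair_class: str,
    exclude: Iterable[tuple[str, str]] = (),
    min_distance_bp: int = 200_000,
) -> list[tuple[str, str]]:
    """Background universe: all annotated unordered gene pairs of one class.

    ``intrachromosomal`` pairs must have a body gap > ``min_distance_bp``
    (matching the catalog's neighbour removal); ``interchromosomal`` pairs
    have no distance constraint.  Pairs in ``exclude`` (e.g. the Futra set)
    are removed.
    """
    if pair_class not in (INTRA, INTER):
        raise ValueError(f"unknown pair_class {pair_class!r}")
    excluded = {canonical_pair(*p) for p in exclude}
    srt = annotation.sort_values("gene_id")
    out: list[tuple[str, str]] = []
    if pair_class == INTRA:
        for _, sub in srt.groupby("chrom", sort=False):
            ids = sub["gene_id"].to_numpy()
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            gap = np.maximum(
                0, np.maximum.outer(starts, starts) - np.minimum.outer(ends, ends)
            )
            ii, jj = np.where(np.triu(gap > min_distance_bp, k=1))
            out.extend(
                key for key in zip(ids[ii], ids[jj]) if key not in excluded
            )
    else:
        groups = [sub["gene_id"].to_numpy() for _, sub in srt.groupby("chrom", sort=False)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        key = canonical_pair(a, b)
                        if key not in excluded:
                            out.append(key)
    return sorted(out)


def class_enrichment(
    report: pd.DataFrame,
    annotation: pd.DataFrame,
    interaction_counts: dict[tuple[str, str], int],
    pair_class: str,
    flag_col: str = "any_dataset",
    min_distance_bp: int = 200_000,
    yates: bool = True,
) -> ContingencyTable2x2:
    """Enrichment test for one pair class against the all-gene-pairs background."""
    sub = report[report["pair_class"] == pair_class]
    futra_keys = [canonical_pair(a, b) for a, b in zip(sub["gene_a"], sub["gene_b"])]
    a = int(sub[flag_col].sum())
    b = len(sub) - a
    bg = background_gene_pairs(annotation, pair_class, exclude=futra_keys,
                               min_distance_bp=min_distance_bp)
    c = sum(1 for key in bg if key in interaction_counts)
    d = len(bg) - c
    return enrichment_test(a, b, c, d, yates=yates)


def detected_in_dataset(futra_pairs: pd.DataFrame, fusion_calls: pd.DataFrame) -> pd.Series:
    """Flag catalog pairs that appear among a sample's (filtered) fusion calls.

    Matching is unordered on gene ids; the calls are expected to have passed
    the support filter already.
    """
    call_keys = {
        canonical_pair(a, b)
        for a, b in zip(fusion_calls["gene_a"], fusion_calls["gene_b"])
    }
    flags = [
        canonical_pair(a, b) in call_keys
        for a, b in zip(futra_pairs["gene_a"], futra_pairs["gene_b"])
    ]
    return pd.Series(flags, index=futra_pairs.index, name="detected")
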