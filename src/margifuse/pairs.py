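"""Cleaning, deduplication and classification of iMARGI read pairs.

An iMARGI read pair joins a chromatin-associated RNA fragment (the RNA end,
Read 1) to the genomic locus it was ligated to (the DNA end, Read 2).  The
library chemistry leaves two diagnostic marks on every genuine pair: the DNA
end must begin with ``CT`` (the AluI cut overhang) and the first two bases of
the RNA end are random fill-in nucleotides that carry no information.

Mapped pairs fall into three classes relative to a distance threshold
(200 kb by default):

* ``proximal`` — same chromosome, end-to-end distance <= threshold;
* ``distal`` — same chromosome, distance > threshold;
* ``interchromosomal`` — ends on different chromosomes.

Proximal pairs mostly reflect nascent transcripts hybridising near their own
locus and are dropped before any interaction analysis; the union of distal
and interchromosomal pairs is referred to as the *remote* set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Canonical column order of a mapped-pair table (positions are 1-based,
#: following the 4DN .pairs convention; side 1 is the RNA end).
PAIR_COLUMNS = [
    "read_id",
    "rna_chrom",
    "rna_pos",
    "rna_strand",
    "dna_chrom",
    "dna_pos",
    "dna_strand",
]

#: Key identifying a unique molecule for deduplication.
DEDUP_KEY = ["rna_chrom", "rna_pos", "rna_strand", "dna_chrom", "dna_pos", "dna_strand"]

#: Default proximal/distal boundary in bp ("within 200 kb" is inclusive).
PROXIMAL_THRESHOLD_BP = 200_000

CLASS_LABELS = ("proximal", "distal", "interchromosomal")

REJECT_TOO_SHORT = "too_short"
REJECT_NOT_CT = "dna_end_not_ct"


@dataclass(frozen=True)
class RawReadPair:
    """An unmapped read pair: Read 1 is the RNA end, Read 2 the DNA end."""

    read_id: str
    read1_seq: str
    read2_seq: str


@dataclass(frozen=True)
class CleanResult:
    """Outcome of :func:`clean_raw_pair` for one raw read pair."""

    accepted: bool
    pair: Optional[RawReadPair]
    reason: Optional[str] = None


def clean_raw_pair(raw: RawReadPair) -> CleanResult:
    """Apply the iMARGI sequence-level filter to one raw read pair.

    A pair is accepted iff its DNA end (Read 2) starts with ``CT``; on
    acceptance the first two (random) bases of the RNA end (Read 1) are
    trimmed off and the DNA end is left untouched.  Reads too short to
    survive the trim (< 3 nt) are rejected with a distinct reason code.
    """
    if len(raw.read1_seq) < 3 or len(raw.read2_seq) < 3:
        return CleanResult(False, None, REJECT_TOO_SHORT)
    if not raw.read2_seq.startswith("CT"):
        return CleanResult(False, None, REJECT_NOT_CT)
    cleaned = RawReadPair(raw.read_id, raw.read1_seq[2:], raw.read2_seq)
    return CleanResult(True, cleaned)


def clean_raw_pairs(raws: Iterable[RawReadPair]) -> tuple[list[RawReadPair], pd.DataFrame]:
    """Clean a stream of raw pairs; return accepted pairs and a rejection log."""
    accepted: list[RawReadPair] = []
    rejected: list[tuple[str, str]] = []
    for raw in raws:
        res = clean_raw_pair(raw)
        if res.accepted:
            accepted.append(res.pair)  # type: ignore[arg-type]
        else:
            rejected.append((raw.read_id, res.reason or "unknown"))
    log = pd.DataFrame(rejected, columns=["read_id", "reason"])
    return accepted, log


def deduplicate(pairs: pd.DataFrame) -> pd.DataFrame:
    """Drop PCR/optical duplicates: exact six-tuple position/strand matches.

    The first occurrence of each key is kept and input order is preserved,
    so the operation is idempotent.  No positional tolerance is applied.
    """
    return pairs.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)


def classify_pair(
    rna_chrom: str,
    rna_pos: int,
    dna_chrom: str,
    dna_pos: int,
    threshold_bp: int = PROXIMAL_THRESHOLD_BP,
) -> str:
    """Classify a single pair as proximal, distal or interchromosomal.

    The boundary is inclusive: a distance of exactly ``threshold_bp`` is
    proximal.
    """
    if rna_chrom != dna_chrom:
        return "interchromosomal"
    if abs(int(rna_pos) - int(dna_pos)) <= threshold_bp:
        return "proximal"
    return "distal"


def classify(pairs: pd.DataFrame, threshold_bp: int = PROXIMAL_THRESHOLD_BP) -> pd.DataFrame:
    """Vectorised classification; returns a copy with a ``pair_class`` column."""
    out = pairs.copy()
    inter = (out["rna_chrom"].to_numpy() != out["dna_chrom"].to_numpy())
    dist = np.abs(out["rna_pos"].to_numpy(dtype=np.int64) - out["dna_pos"].to_numpy(dtype=np.int64))
    labels = np.where(inter, "interchromosomal", np.where(dist <= threshold_bp, "proximal", "distal"))
    out["pair_class"] = labels
    return out


def filter_remote(pairs: pd.DataFrame, threshold_bp: int = PROXIMAL_THRESHOLD_BP) -> pd.DataFrame:
    """Drop proximal pairs, keeping distal + interchromosomal in input order."""
    if "pair_class" not in pairs.columns:
        pairs = classify(pairs, threshold_bp)
    return pairs[pairs["pair_class"] != "proximal"].reset_index(drop=True)


@dataclass(frozen=True)
class PairsSummary:
    """QC summary of a classified pair set.

    ``remote_inter_to_intra_ratio`` is the interchromosomal:distal count
    ratio after proximal removal (NaN when no remote pairs exist).
    """

    n_valid: int
    n_per_class: dict[str, int]
    class_fractions: dict[str, float]
    remote_inter_to_intra_ratio: float

    def to_dict(self) -> dict:
        return {
            "n_valid": self.n_valid,
            **{f"n_{k}": v for k, v in self.n_per_class.items()},
            **{f"frac_{k}": v for k, v in self.class_fractions.items()},
            "remote_inter_to_intra_ratio": self.remote_inter_to_intra_ratio,
        }


def summarize(pairs: pd.DataFrame, threshold_bp: int = PROXIMAL_THRESHOLD_BP) -> PairsSummary:
    """Count pairs per class and derive fractions and the remote ratio."""
    if "pair_class" not in pairs.columns:
        pairs = classify(pairs, threshold_bp)
    counts = {label: 0 for label in CLASS_LABELS}
    counts.update(pairs["pair_class"].value_counts().to_dict())
    n = int(len(pairs))
    fractions = {label: (counts[label] / n if n else math.nan) for label in CLASS_LABELS}
    n_distal = counts["distal"]
    n_inter = counts["interchromosomal"]
    if n_distal > 0:
        ratio = n_inter / n_distal
    elif n_inter > 0:
        ratio = math.inf
    else:
        ratio = math.nan
    return PairsSummary(n, counts, fractions, ratio)
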