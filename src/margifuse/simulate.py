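"""Synthetic genomes, iMARGI read pairs, fusion catalogs and FISH images.

Every downstream stage of the pipeline is exercised against data with
planted, recoverable parameters:

* a genome of non-overlapping genes on equal-length chromosomes;
* iMARGI read pairs with configurable proximal/distal/interchromosomal
  fractions, a power-law intrachromosomal distance decay beyond the
  proximal threshold, and a set of *fusion-susceptible* gene pairs whose
  read-pair rate is multiplied by an enrichment factor;
* a per-sample fusion-call catalog drawn preferentially from the
  susceptible pairs, with mostly-singleton recurrence across samples;
* two-channel FISH fields with Gaussian spots and a planted colocalized
  fraction.

All generators are bit-reproducible for a fixed seed.  Default parameter
values mirror the empirical regime the pipeline targets: remote-heavy class
fractions (~35% proximal, 10% distal, 55% interchromosomal), a decaying
intrachromosomal contact law, and a fusion catalog in which the large
majority of unique gene pairs occur in a single sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catalog import canonical_pair
from .pairs import PROXIMAL_THRESHOLD_BP


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    ``proximal_fraction`` and ``distal_fraction`` set the read-pair class
    mix (interchromosomal takes the remainder).  ``decay_exponent`` is the
    power-law exponent of the intrachromosomal distance density beyond the
    proximal threshold.  ``gene_assign_fraction`` is the share of remote
    read pairs emitted from annotated gene pairs rather than background
    positions; within that share a susceptible pair is drawn with
    ``enrichment_factor`` times the weight of an ordinary gene pair.
    ``filter_fail_fraction`` of fusion calls are drawn with support counts
    that fail the call filter, so the filter itself is testable.
    """

    n_chromosomes: int = 4
    chrom_length: int = 20_000_000
    n_genes: int = 200
    gene_length_bp: tuple[int, int] = (5_000, 50_000)
    n_read_pairs: int = 100_000
    proximal_fraction: float = 0.35
    distal_fraction: float = 0.10
    decay_exponent: float = 1.5
    n_susceptible_pairs: int = 20
    enrichment_factor: float = 20.0
    gene_assign_fraction: float = 0.1
    n_samples: int = 500
    fusion_rate_susceptible: float = 0.004
    fusion_rate_background: float = 5e-6
    filter_fail_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.proximal_fraction <= 1 and 0 <= self.distal_fraction <= 1):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.proximal_fraction + self.distal_fraction > 1 + 1e-12:
            raise ValueError("proximal_fraction + distal_fraction must be <= 1")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.fusion_rate_background > self.fusion_rate_susceptible:
            raise ValueError("fusion_rate_background must be <= fusion_rate_susceptible")
        if not (0 <= self.gene_assign_fraction <= 1):
            raise ValueError("gene_assign_fraction must lie in [0, 1]")
        if not (0 <= self.filter_fail_fraction <= 1):
            raise ValueError("filter_fail_fraction must lie in [0, 1]")
        if self.n_chromosomes < 1 or self.chrom_length < 1 or self.n_genes < 0:
            raise ValueError("genome dimensions must be positive")

    @property
    def interchromosomal_fraction(self) -> float:
        return 1.0 - self.proximal_fraction - self.distal_fraction

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # one independent stream per generator, all derived from the single seed
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _gene_lengths(config: SimConfig, k: int, rng: np.random.Generator) -> np.ndarray:
    gl = config.gene_length_bp
    if isinstance(gl, int):
        return np.full(k, gl, dtype=np.int64)
    lo, hi = gl
    return rng.integers(lo, hi + 1, size=k)


def make_genome(config: SimConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    """Place non-overlapping genes on equal-length chromosomes.

    Genes are distributed round-robin over chromosomes; within a chromosome
    their positions are drawn uniformly subject to non-overlap (a sorted
    uniform-spacing construction).  Returns a BED-like annotation
    (0-based half-open) and a chromosome-size mapping.

    Raises ValueError when the requested genes cannot fit on a chromosome.
    """
    rng = _rng(config, 1)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_sizes = {c: config.chrom_length for c in chrom_names}
    per_chrom: dict[str, int] = {c: 0 for c in chrom_names}
    for i in range(config.n_genes):
        per_chrom[chrom_names[i % config.n_chromosomes]] += 1

    records = []
    gene_idx = 0
    for chrom in chrom_names:
        k = per_chrom[chrom]
        if k == 0:
            continue
        lengths = _gene_lengths(config, k, rng)
        total = int(lengths.sum())
        free = config.chrom_length - total
        if free < 0:
            raise ValueError(
                f"cannot place {k} genes totalling {total} bp on a "
                f"{config.chrom_length} bp chromosome"
            )
        gaps = np.sort(rng.uniform(0, free, size=k)).astype(np.int64)
        start = gaps + np.concatenate(([0], np.cumsum(lengths[:-1])))
        strands = rng.choice(["+", "-"], size=k)
        for j in range(k):
            records.append(
                (f"G{gene_idx:05d}", chrom, int(start[j]), int(start[j] + lengths[j]), strands[j])
            )
            gene_idx += 1
    annotation = pd.DataFrame(records, columns=["gene_id", "chrom", "start", "end", "strand"])
    return annotation, chrom_sizes


def _eligible_pairs(annotation: pd.DataFrame, threshold_bp: int) -> tuple[list, list]:
    """All unordered gene pairs usable as remote interactions, split by class.

    Intrachromosomal pairs qualify only when their body gap exceeds the
    proximal threshold, so any read pair emitted from their bodies is
    guaranteed distal.
    """
    intra: list[tuple[str, str]] = []
    inter: list[tuple[str, str]] = []
    groups = {c: sub for c, sub in annotation.groupby("chrom", sort=False)}
    chrom_names = list(groups)
    for c, sub in groups.items():
        ids = sub["gene_id"].to_numpy()
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        gap = np.maximum(
            0, np.maximum.outer(starts, starts) - np.minimum.outer(ends, ends)
        )
        ii, jj = np.where(np.triu(gap > threshold_bp, k=1))
        intra.extend(zip(ids[ii], ids[jj]))
    for i, ca in enumerate(chrom_names):
        for cb in chrom_names[i + 1:]:
            for a in groups[ca]["gene_id"]:
                for b in groups[cb]["gene_id"]:
                    inter.append((a, b))
    return intra, inter


def choose_susceptible_pairs(annotation: pd.DataFrame, config: SimConfig) -> list[tuple[str, str]]:
    """Draw the planted fusion-susceptible gene pairs (remote-eligible only).

    Deterministic for a fixed seed; independent of the read-pair draw.
    """
    rng = _rng(config, 2)
    intra, inter = _eligible_pairs(annotation, PROXIMAL_THRESHOLD_BP)
    pool = intra + inter
    if config.n_susceptible_pairs > len(pool):
        raise ValueError("not enough remote-eligible gene pairs for the requested susceptible set")
    idx = rng.choice(len(pool), size=config.n_susceptible_pairs, replace=False)
    return [pool[i] for i in sorted(idx)]


def _power_law_distances(
    rng: np.random.Generator, n: int, d_min: float, d_max: float, alpha: float
) -> np.ndarray:
    """Inverse-CDF sample of a truncated power law with density ∝ d^(−alpha)."""
    u = rng.uniform(size=n)
    if abs(alpha - 1.0) < 1e-12:
        d = d_min * (d_max / d_min) ** u
    else:
        e = 1.0 - alpha
        d = (d_min**e + u * (d_max**e - d_min**e)) ** (1.0 / e)
    return np.minimum(np.maximum(d.astype(np.int64), int(d_min) + 1), int(d_max))


def simulate_imargi(
    annotation: pd.DataFrame,
    chrom_sizes: dict[str, int],
    config: SimConfig,
    susceptible_pairs: list[tuple[str, str]] | None = None,
    threshold_bp: int = PROXIMAL_THRESHOLD_BP,
) -> pd.DataFrame:
    """Emit a mapped read-pair table with planted class mix and enrichment.

    Per read pair, a class is drawn from the configured fractions.  Proximal
    pairs land uniformly within the threshold of a uniform anchor.  Remote
    pairs are either *background* (distal: power-law distance beyond the
    threshold; interchromosomal: independent uniform positions on two
    chromosomes) or *gene-assigned* with probability
    ``gene_assign_fraction``: an eligible gene pair of the matching class is
    drawn with weight ``enrichment_factor`` for susceptible pairs and 1
    otherwise, the RNA end falls uniformly in one gene body (on that gene's
    strand) and the DNA end uniformly in the other body.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    if config.interchromosomal_fraction > 1e-12 and len(chrom_sizes) < 2:
        raise ValueError("interchromosomal pairs need at least two chromosomes")
    if config.distal_fraction > 1e-12 and min(chrom_sizes.values()) <= threshold_bp + 1:
        raise ValueError("distal pairs need chromosomes longer than the proximal threshold")
    rng = _rng(config, 3)
    if susceptible_pairs is None:
        susceptible_pairs = (
            choose_susceptible_pairs(annotation, config) if config.n_susceptible_pairs else []
        )
    susceptible = {canonical_pair(*p) for p in susceptible_pairs}

    chroms = np.array(list(chrom_sizes))
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    chrom_p = lengths / lengths.sum()
    genes = annotation.set_index("gene_id")
    g_chrom = genes["chrom"].to_dict()
    g_start = genes["start"].to_dict()
    g_end = genes["end"].to_dict()
    g_strand = genes["strand"].to_dict()

    intra_pool, inter_pool = _eligible_pairs(annotation, threshold_bp)
    pools = {1: intra_pool, 2: inter_pool}
    weights = {}
    for cls, pool in pools.items():
        w = np.array(
            [config.enrichment_factor if canonical_pair(*p) in susceptible else 1.0 for p in pool]
        )
        weights[cls] = w / w.sum() if len(pool) else None

    n = config.n_read_pairs
    probs = [config.proximal_fraction, config.distal_fraction, config.interchromosomal_fraction]
    cls_draw = rng.choice(3, size=n, p=probs)  # 0 proximal, 1 distal, 2 inter
    gene_assigned = rng.uniform(size=n) < config.gene_assign_fraction

    rna_chrom = np.empty(n, dtype=object)
    dna_chrom = np.empty(n, dtype=object)
    rna_pos = np.zeros(n, dtype=np.int64)
    dna_pos = np.zeros(n, dtype=np.int64)
    rna_strand = rng.choice(np.array(["+", "-"]), size=n)
    dna_strand = rng.choice(np.array(["+", "-"]), size=n)

    # proximal: uniform anchor, signed uniform offset within the threshold
    prox = np.flatnonzero(cls_draw == 0)
    if len(prox):
        ci = rng.choice(len(chroms), size=len(prox), p=chrom_p)
        L = lengths[ci]
        p1 = rng.integers(1, L + 1)
        delta = rng.integers(0, threshold_bp + 1, size=len(prox))
        sign = np.where(rng.uniform(size=len(prox)) < 0.5, 1, -1)
        p2 = np.clip(p1 + sign * delta, 1, L)
        rna_chrom[prox] = chroms[ci]
        dna_chrom[prox] = chroms[ci]
        rna_pos[prox], dna_pos[prox] = p1, p2

    # remote gene-assigned reads: weighted eligible gene pair of the class
    for cls in (1, 2):
        idx = np.flatnonzero((cls_draw == cls) & gene_assigned)
        pool = pools[cls]
        rest = np.flatnonzero((cls_draw == cls) & ~gene_assigned)
        if len(idx) and pool:
            picks = rng.choice(len(pool), size=len(idx), p=weights[cls])
            flip = rng.uniform(size=len(idx)) < 0.5
            pair_a = np.array([p[0] for p in pool], dtype=object)
            pair_b = np.array([p[1] for p in pool], dtype=object)
            a_ids = np.where(flip, pair_b[picks], pair_a[picks])
            b_ids = np.where(flip, pair_a[picks], pair_b[picks])
            a_start = np.array([g_start[g] for g in a_ids], dtype=np.int64)
            a_end = np.array([g_end[g] for g in a_ids], dtype=np.int64)
            b_start = np.array([g_start[g] for g in b_ids], dtype=np.int64)
            b_end = np.array([g_end[g] for g in b_ids], dtype=np.int64)
            rna_chrom[idx] = [g_chrom[g] for g in a_ids]
            dna_chrom[idx] = [g_chrom[g] for g in b_ids]
            rna_pos[idx] = rng.integers(a_start + 1, a_end + 1)
            dna_pos[idx] = rng.integers(b_start + 1, b_end + 1)
            rna_strand[idx] = [g_strand[g] for g in a_ids]
        elif len(idx):
            rest = np.sort(np.concatenate([rest, idx]))  # no eligible pairs: background

        if cls == 1 and len(rest):  # distal background: power-law distance
            ci = rng.choice(len(chroms), size=len(rest), p=chrom_p)
            L = lengths[ci]
            d = _power_law_distances(
                rng, len(rest), threshold_bp, int(lengths.max()) - 1, config.decay_exponent
            )
            d = np.minimum(d, L - 1)
            p1 = rng.integers(1, L - d + 1)
            p2 = p1 + d
            swap = rng.uniform(size=len(rest)) < 0.5
            p1s = np.where(swap, p2, p1)
            p2s = np.where(swap, p1, p2)
            rna_chrom[rest] = chroms[ci]
            dna_chrom[rest] = chroms[ci]
            rna_pos[rest], dna_pos[rest] = p1s, p2s
        elif cls == 2 and len(rest):  # interchromosomal background
            ci = rng.choice(len(chroms), size=len(rest), p=chrom_p)
            cj = rng.choice(len(chroms), size=len(rest), p=chrom_p)
            clash = np.flatnonzero(ci == cj)
            while len(clash):
                cj[clash] = rng.choice(len(chroms), size=len(clash), p=chrom_p)
                clash = clash[ci[clash] == cj[clash]]
            rna_chrom[rest] = chroms[ci]
            dna_chrom[rest] = chroms[cj]
            rna_pos[rest] = rng.integers(1, lengths[ci] + 1)
            dna_pos[rest] = rng.integers(1, lengths[cj] + 1)

    return pd.DataFrame(
        {
            "read_id": [f"sim{i:08d}" for i in range(n)],
            "rna_chrom": rna_chrom,
            "rna_pos": rna_pos,
            "rna_strand": rna_strand,
            "dna_chrom": dna_chrom,
            "dna_pos": dna_pos,
            "dna_strand": dna_strand,
        }
    )


def simulate_fusion_catalog(
    annotation: pd.DataFrame,
    susceptible_pairs: list[tuple[str, str]],
    config: SimConfig,
) -> pd.DataFrame:
    """Per-sample fusion-call table with planted susceptible enrichment.

    In each simulated tumor every susceptible pair yields a call with
    probability ``fusion_rate_susceptible`` and every other gene pair with
    probability ``fusion_rate_background``.  Support counts are drawn so
    that about ``filter_fail_fraction`` of calls fail the call filter
    (zero junction or spanning support, or total support <= 2); the rest
    pass it.  Gene order within a call is randomised.
    """
    rng = _rng(config, 4)
    genes = list(annotation["gene_id"])
    susceptible = [canonical_pair(*p) for p in susceptible_pairs]
    sus_set = set(susceptible)
    n_genes = len(genes)
    n_all_pairs = n_genes * (n_genes - 1) // 2
    n_bg_pairs = n_all_pairs - len(sus_set)

    # background pairs are indexed lazily through the (i, j) triangle to
    # avoid materialising every gene pair per sample
    tri_i, tri_j = np.triu_indices(n_genes, k=1)

    records = []
    for s in range(config.n_samples):
        sample = f"S{s:04d}"
        hit = rng.uniform(size=len(susceptible)) < config.fusion_rate_susceptible
        emitted = [susceptible[k] for k in np.flatnonzero(hit)]
        n_bg = rng.binomial(n_bg_pairs, config.fusion_rate_background)
        taken: set[tuple[str, str]] = set()
        while len(taken) < n_bg:
            k = int(rng.integers(0, n_all_pairs))
            pair = canonical_pair(genes[tri_i[k]], genes[tri_j[k]])
            if pair not in sus_set:
                taken.add(pair)
        emitted.extend(sorted(taken))
        for a, b in emitted:
            if rng.uniform() < 0.5:
                a, b = b, a
            j, sp = _support_counts(rng, config.filter_fail_fraction)
            records.append((sample, a, b, j, sp))
    return pd.DataFrame(
        records,
        columns=["sample_id", "gene_a", "gene_b", "junction_read_count", "spanning_frag_count"],
    )


def _support_counts(rng: np.random.Generator, fail_fraction: float) -> tuple[int, int]:
    if rng.uniform() < fail_fraction:
        mode = rng.integers(0, 3)
        if mode == 0:
            return int(1 + rng.poisson(2)), 0
        if mode == 1:
            return 0, int(1 + rng.poisson(2))
        return 1, 1  # both positive but sum not > 2
    j = int(1 + rng.poisson(2.0))
    s = int(1 + rng.poisson(1.0))
    if j + s < 3:
        j += 1
    return j, s


# ---------------------------------------------------------------------------
# FISH image synthesis


def simulate_fish_image(
    spot_centers: np.ndarray,
    spot_sigma: float = 1.5,
    amplitude: float = 100.0,
    noise_sd: float = 5.0,
    image_shape: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> np.ndarray:
    """Render Gaussian spots on a noisy background.

    ``spot_centers`` is an (n, 2) array of (x, y) sub-pixel coordinates
    (x = column, y = row).  Noise is zero-mean Gaussian clipped at 0 so
    intensities stay non-negative.  Centers outside the image raise.
    """
    centers = np.asarray(spot_centers, dtype=float).reshape(-1, 2)
    h, w = image_shape
    if len(centers) and (
        (centers[:, 0] < 0).any() or (centers[:, 0] > w - 1).any()
        or (centers[:, 1] < 0).any() or (centers[:, 1] > h - 1).any()
    ):
        raise ValueError("spot centers outside image bounds")
    rng = np.random.default_rng(seed)
    img = np.zeros((h, w), dtype=float)
    if noise_sd > 0:
        img += np.clip(rng.normal(0.0, noise_sd, size=(h, w)), 0.0, None)
    yy, xx = np.mgrid[0:h, 0:w]
    for cx, cy in centers:
        img += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spot_sigma**2))
    return img


def simulate_fish_field(
    n_spots_a: int,
    n_spots_b: int,
    colocalized_fraction: float,
    image_shape: tuple[int, int] = (192, 192),
    spot_sigma: float = 1.5,
    amplitude: float = 100.0,
    noise_sd: float = 5.0,
    min_separation: float = 12.0,
    coloc_jitter: float = 0.5,
    seed: int = 0,
) -> dict:
    """Two-channel field with a planted colocalized spot fraction.

    ``colocalized_fraction`` of channel-A spots share (jittered) centers
    with channel-B spots; remaining spots in each channel are independent.
    All centers keep a minimum mutual separation so detection is unambiguous.
    Returns the two images and the ground-truth center lists.
    """
    if not 0 <= colocalized_fraction <= 1:
        raise ValueError("colocalized_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    n_coloc = int(round(colocalized_fraction * min(n_spots_a, n_spots_b)))
    n_total = n_spots_a + n_spots_b - n_coloc

    margin = 4 * spot_sigma
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_total:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("cannot place spots with the requested separation")
        cand = (rng.uniform(margin, w - 1 - margin), rng.uniform(margin, h - 1 - margin))
        if all(math.hypot(cand[0] - x, cand[1] - y) >= min_separation for x, y in centers):
            centers.append(cand)
    centers_arr = np.array(centers)
    shared = centers_arr[:n_coloc]
    only_a = centers_arr[n_coloc:n_spots_a]
    only_b = centers_arr[n_spots_a:]

    jitter = rng.normal(0.0, coloc_jitter, size=shared.shape) if len(shared) else shared
    centers_a = np.vstack([shared, only_a]) if n_spots_a else np.empty((0, 2))
    centers_b = np.vstack([shared + jitter, only_b]) if n_spots_b else np.empty((0, 2))

    seed_a, seed_b = int(rng.integers(0, 2**31 - 1)), int(rng.integers(0, 2**31 - 1))
    img_a = simulate_fish_image(centers_a, spot_sigma, amplitude, noise_sd, image_shape, seed_a)
    img_b = simulate_fish_image(centers_b, spot_sigma, amplitude, noise_sd, image_shape, seed_b)
    return {
        "image_a": img_a,
        "image_b": img_b,
        "centers_a": centers_a,
        "centers_b": centers_b,
        "n_colocalized": n_coloc,
    }
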