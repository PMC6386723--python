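"""End-to-end synthetic study: simulate, process, and score one replicate.

Chains the full analysis on generated data: genome → iMARGI read pairs →
cleaning-stage classification → remote filtering → fusion catalog →
Futra-pair catalog → colocalization report → enrichment test.  Used by the
replicate-level calibration checks and the reproduction script; real-data
analyses call the underlying modules directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import catalog as cat
from . import coloc as cl
from . import pairs as pr
from . import simulate as sim


@dataclass
class StudyResult:
    """Everything one synthetic replicate produces."""

    annotation: pd.DataFrame
    chrom_sizes: dict[str, int]
    susceptible_pairs: list[tuple[str, str]]
    read_pairs: pd.DataFrame
    remote_pairs: pd.DataFrame
    summary: pr.PairsSummary
    fusion_calls: pd.DataFrame
    futra_catalog: pd.DataFrame
    recurrence: cat.RecurrenceSummary
    report: pd.DataFrame
    interaction_counts: dict[tuple[str, str], int]
    enrichment: cl.ContingencyTable2x2


def run_synthetic_study(
    config: sim.SimConfig,
    rule: cl.OverlapRule = cl.OverlapRule(),
    yates: bool = True,
) -> StudyResult:
    """Run the whole pipeline on one synthetic replicate.

    The enrichment table pools intra- and interchromosomal Futra pairs
    against the pooled background universe of remote-eligible gene pairs;
    per-class tables can be recomputed from the returned report and
    interaction counts via :func:`margifuse.coloc.class_enrichment`.
    """
    annotation, chrom_sizes = sim.make_genome(config)
    susceptible = sim.choose_susceptible_pairs(annotation, config)
    read_pairs = sim.simulate_imargi(annotation, chrom_sizes, config, susceptible)
    classified = pr.classify(read_pairs)
    summary = pr.summarize(classified)
    remote = pr.filter_remote(classified)

    calls = sim.simulate_fusion_catalog(annotation, susceptible, config)
    filtered = cat.filter_fusion_calls(calls)
    futra = cat.build_futra_pairs(filtered, annotation)
    recurrence = cat.recurrence_summary(futra)

    hits = cl.interacting_gene_pairs(remote, annotation, rule, chrom_sizes)
    report = cl.colocalization_report(futra, {"sim": remote}, annotation, rule, chrom_sizes)

    futra_keys = [
        cat.canonical_pair(a, b) for a, b in zip(futra["gene_a"], futra["gene_b"])
    ]
    a = sum(1 for k in futra_keys if k in hits)
    b = len(futra_keys) - a
    background = cl.background_gene_pairs(
        annotation, cat.INTRA, exclude=futra_keys
    ) + cl.background_gene_pairs(annotation, cat.INTER, exclude=futra_keys)
    c = sum(1 for k in background if k in hits)
    d = len(background) - c
    enrichment = cl.enrichment_test(a, b, c, d, yates=yates)

    return StudyResult(
        annotation=annotation,
        chrom_sizes=chrom_sizes,
        susceptible_pairs=susceptible,
        read_pairs=read_pairs,
        remote_pairs=remote,
        summary=summary,
        fusion_calls=calls,
        futra_catalog=futra,
        recurrence=recurrence,
        report=report,
        interaction_counts=hits,
        enrichment=enrichment,
    )
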