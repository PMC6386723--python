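# margifuse

Tools for asking whether the places where chromatin-associated RNA touches
the genome are the same places where cancer fusion transcripts are born.

iMARGI (in situ mapping of RNA–genome interactions) produces chimeric read
pairs whose Read 1 comes from a chromatin-associated RNA (the *RNA end*)
and whose Read 2 comes from the genomic locus it was ligated to (the *DNA
end*). Fusion-transcript callers such as STAR-Fusion, run over tumor
RNA-seq cohorts, produce per-sample gene pairs joined in a fusion
transcript — *Futra pairs* (fusion-transcript-contributing RNA pairs).
`margifuse` implements the full analysis connecting the two:

* **`margifuse.pairs`** — sequence-level cleaning of raw read pairs (the
  DNA end must start with `CT`, the AluI cut signature; the RNA end's
  first two random bases are trimmed), exact-position deduplication, and
  classification into proximal / distal / interchromosomal at a 200-kb
  threshold (inclusive). Proximal pairs are discarded; *remote* = distal +
  interchromosomal.
* **`margifuse.catalog`** — the Futra-pair catalog: STAR-Fusion-style
  support filtering (junction reads > 0, spanning fragments > 0, sum > 2),
  unordered gene-pair deduplication, per-sample recurrence, and removal of
  intrachromosomal pairs whose gene bodies lie within 200 kb (read-through
  artifacts).
* **`margifuse.binning` / `margifuse.maps`** — sparse genome-wide binned
  matrices of read pairs (RNA-end bin × DNA-end bin) and Futra pairs,
  row normalization, distance-decay curves (bin pairs with ≥ *k* read
  pairs per genomic separation), per-gene-pair read counts and rankings,
  and per-bin "RNA attachment level" profiles with Pearson correlation
  between libraries.
* **`margifuse.coloc`** — the colocalization rule: a read pair overlaps a
  gene pair (A, B) when its RNA end maps strand-specifically inside one
  gene's body and its DNA end maps within the other gene's body ± 100 kb,
  in either orientation. Enrichment of interactions on Futra pairs over a
  background universe of same-class gene pairs is scored on a 2×2 table
  with the odds ratio OR = (a·d)/(b·c) and a χ² test (1 df, Yates-corrected
  by default).
* **`margifuse.fish`** — single-molecule FISH spot detection by a
  robust-threshold plateau scan (the working threshold sits in the longest
  run of candidate thresholds giving an unchanged spot count) and
  two-channel fusion calling by mutual-nearest-neighbour center matching
  within a radius.
* **`margifuse.simulate`** — synthetic genomes, iMARGI libraries with
  planted class fractions, power-law distance decay and enriched
  *fusion-susceptible* gene pairs, per-sample fusion catalogs, and
  two-channel FISH fields — all bit-reproducible, so every stage has a
  planted-parameter recovery test.

## Worked example

Run one fully synthetic study — genome, 100,000 read pairs with class mix
(0.35, 0.10, 0.55), 20 susceptible gene pairs at 20× enrichment, and a
500-sample fusion cohort — and test whether Futra pairs are enriched for
RNA–DNA interactions:

```python
from margifuse import pipeline, simulate

study = pipeline.run_synthetic_study(simulate.SimConfig(seed=1))

s = study.summary
print({k: round(v, 4) for k, v in s.class_fractions.items()})
print(round(s.remote_inter_to_intra_ratio, 3))
print(round(study.recurrence.singleton_fraction, 3))
t = study.enrichment
print(f"OR = {t.odds_ratio:.2f}, chi2 = {t.chi2:.1f}, p = {t.p_value:.2g}")
```

prints

```
{'proximal': 0.3506, 'distal': 0.0993, 'interchromosomal': 0.5501}
5.538
0.806
OR = 2.16, chi2 = 8.6, p = 0.0034
```

Reading this: the simulator recovered the configured class mix to within
binomial noise; remote pairs are ~5.5:1 inter- to intrachromosomal; ~81%
of the unique Futra pairs occurred in a single sample; and Futra pairs are
significantly more likely than background gene pairs of the same class to
carry an RNA–DNA interaction (odds ratio 2.16 on a pooled 2×2 of 19,810
gene pairs) — the planted susceptible-pair signal is detected.

The same stages are exposed as a CLI:

```bash
margifuse sim pairs  --seed 1 --out demo/        # genome + .pairs + ground truth
margifuse sim fusions --seed 1 --out demo/
margifuse futra build --calls demo/fusion_calls.tsv --genes demo/genes.bed \
    --out demo/catalog.tsv
margifuse coloc report --pairs sim demo/imargi.pairs --catalog demo/catalog.tsv \
    --genes demo/genes.bed --out demo/report.tsv
```

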