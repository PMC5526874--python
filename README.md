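# cresig

Pipeline for extracting transcription-factor **core gene signatures** from
stimulated-transcriptome data, built around the CREB/CRE use case:

1. **Differential expression** — two-group contrasts with empirical-Bayes
   moderated t-statistics (method-of-moments variance prior), BH or raw
   p-value DEG calling, probe-to-gene collapse by max |t|.
2. **TRAP quartile filtration** — first-quartile construction from a
   cell-type abundance (TRAP-style) list, DEG partition into Q1/REST,
   ranked-transcriptome 250-gene bin profiles, symbol mapping, multi-subtype
   profile averaging.
3. **CRE-motif enrichment** — PWM scanning of promoter windows (best site
   over both strands, min-max normalized log-odds), one-sample z-test
   over-representation per rank bin and per partition (all/Q1/REST/UP/DOWN).
4. **Pre-ranked GSEA** — weighted running-sum enrichment score, gene-set
   permutation null, sign-matched NES, add-one nominal p.
5. **GO enrichment** — two-sided hypergeometric test, Bonferroni correction,
   term-selection filters (min genes, min %), Cohen's-kappa term grouping.
6. **Core signature** — multi-condition intersection (significant-in-all →
   UP-in-all → registry cross-reference), average-fold-change ranking,
   Venn/Pearson overlap statistics, cross-cell-type comparison.

A **synthetic study generator** (`cresig.simulate`) produces the complete
input set — three stimulus expression matrices with replicate noise,
promoters with planted CRE sites, a TRAP list enriched for the planted
regulon, a target registry, GO-like sets and a ranked "in vivo" list — with
a known truth table, so every stage has a recoverable ground truth.

## CLI

All stages are exposed as `cresig` subcommands; each writes its outputs plus
a JSON summary (config, seeds, input digests) into `--out-dir`.

```sh
cresig simulate --seed 1 --out-dir study/            # synthetic study
cresig de --expr study/expr_FSK.tsv --conditions study/conditions_FSK.tsv \
          --contrast FSK:CT --out-dir de_FSK/
cresig filter --deg de_FSK/degs.tsv --trap study/trap.tsv --out-dir filt/
cresig profile --deg de_FSK/stats_all.tsv --trap study/trap.tsv --out-dir prof/
cresig scanmotif --fasta study/promoters.fasta --pwm study/cre_motif.pfm \
          --deg de_FSK/stats_all.tsv --trap study/trap.tsv --out-dir motif/
cresig gsea --rnk study/invivo.rnk --gmt study/go_sets.gmt --seed 1 --out-dir gsea/
cresig go --deg de_FSK/degs.tsv --gmt study/go_sets.gmt \
          --universe study/universe.txt --out-dir go/
cresig core --deg FSK de_FSK/degs.tsv --deg NE de_NE/degs.tsv \
          --deg VP16 de_VP16/degs.tsv --trap study/trap.tsv \
          --registry study/registry.txt --out-dir core/
cresig compare --sig-a core_a/core_signature.tsv --sig-b core_b/core_signature.tsv \
          --out-dir cmp/
```

Formats: TSV (expression, DEG/TRAP/mapping tables), GMT (gene sets),
JASPAR pfm / TRANSFAC blocks (PWMs), FASTA (promoters keyed by gene
symbol), RNK (ranked lists), JSON (summaries). Randomized stages require an
explicit `--seed`; reruns with the same seed are byte-identical.

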