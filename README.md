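# breakgene

Genes recurrently hit by copy-number-aberration (CNA)–associated
chromosomal breakpoints are a clinically relevant but under-studied class
of structural variation in cancer. `breakgene` implements, as a tested and
reusable Python library, the full analysis chain for discovering such
genes from segmented array-CGH copy-number profiles and for using them —
together with gene point mutations — to stratify patients into prognostic
subtypes:

1. **Breakpoint extraction** — a breakpoint is the genomic start of a DNA
   copy-number segment; the first segment of each chromosome and
   transitions between two copy-number-neutral segments are excluded.
   Breakpoints are localized only to the gap between flanking probes
   (~17 kb on the emulated platform) and mapped to genes by overlapping
   this uncertainty interval with gene spans. Genes sharing
   breakpoint-supporting probes are merged into pools (named `GENE*`).
2. **Recurrence statistics** — for gene *g* and profile *s* a logistic
   regression estimates the baseline probability *p₍gs₎* of a random
   breakpoint in the gene, from log(probes in *g* + 1), log(span of *g*)
   and log(breakpoints in *s* + 1). The test statistic *T₍g₎* = number of
   profiles with ≥ 1 breakpoint in *g* has the Poisson-binomial null
   *T₍g₎* ~ Σₛ Bernoulli(*p₍gs₎*), whose exact tail is computed by
   dynamic-programming convolution. Because every gene has its own
   discrete null, multiple testing uses a Benjamini–Hochberg-type step-up
   over each gene's attainable p-value distribution
   (FDR̂(t) = Σ₍g₎ P₀(P₍g₎ ≤ t) / #{p₍g₎ ≤ t}); it reduces exactly to
   standard BH when the nulls coincide, which is why the probe-level test
   (uniform breakpoint probability across probes) uses plain BH.
   FDR < 0.1 is called significant.
3. **Network-based stratification** — prevalent recurrent breakpoint genes
   (> 3% of samples) are merged with a mutation panel into one binary
   event matrix, smoothed over a protein-interaction network by
   random-walk-with-restart, and consensus-clustered (k = 4) with
   graph-regularized NMF over subsampled iterations. Per-sample gene
   aberration scores *R₍s₎* = (1/C₍s₎) Σᵢ (WᵢHᵢ)₍s₎ are averaged over
   iterations and tested per subtype by Mann–Whitney U.
4. **Clinical association** — Kaplan–Meier / log-rank survival comparisons,
   Cox hazard ratios, a Bonferroni-corrected per-gene survival screen, and
   Fisher exact enrichment of mutations, breakpoints and MSI status.

A synthetic cohort generator (`breakgene.synthetic_cohort`) emulates the
structure of a segmented array-CGH cohort with exact planted ground truth
(recurrent genes, subtypes, survival), so the whole chain is testable
without any data download.

## Worked example

```bash
python examples/02_recurrence_test.py
```

prints, for a 100-sample synthetic cohort with 20 planted recurrent genes:

```
cohort: 100 samples, 4908 breakpoints
recurrent breakpoint genes at FDR < 0.1: 10 (10 contain a planted gene)

top 5 by p-value:
         t_obs  prevalence       p_value       q_value
gene
REC19       12        0.12  1.204748e-10  5.750201e-08
REC07       11        0.11  1.905403e-09  5.278544e-07
G00803*      9        0.09  3.448325e-07  6.889466e-05
REC08        9        0.09  3.448325e-07  6.889466e-05
G01456*     12        0.12  7.323981e-07  7.636819e-05
```

`t_obs` is the number of samples carrying a breakpoint in the gene,
`p_value` the exact Poisson-binomial tail under the fitted null and
`q_value` its discrete-FDR adjustment; all ten discoveries contain a
planted gene (pools such as `G00803*` merged a planted gene with a
neighbour sharing its breakpoint probes). The other examples cover
breakpoint extraction on a hand-built profile, network-based
stratification (ARI 0.934 against planted subtypes), and survival /
enrichment analysis (HR 2.25 for the planted poor-prognosis subtype, MSI
odds ratio 16).

The same stages are scriptable from the shell:

```bash
breakgene simulate --scenario planted --seed 7 --out-dir sim/
breakgene recurrence --segments sim/segments.tsv --probes sim/probes.tsv \
    --genes sim/genes.bed --out recurrence.tsv
```

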