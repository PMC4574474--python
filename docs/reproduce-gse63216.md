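# Reproducing the real-cohort analysis (GEO GSE63216)

The synthetic generator emulates the structure of a deposited array-CGH
cohort of 352 primary colorectal cancers (GEO accession
[GSE63216](https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc=GSE63216)).
Running the pipeline on the real data reproduces the cohort-scale results
(hundreds of recurrent breakpoint genes; the most prevalent gene broken
in ~41% of samples; ~170 genes above 3% prevalence). This requires a
download and two upstream R steps that are deliberately outside this
package's scope (it consumes segmented, state-called profiles).

## 1. Download

```bash
# series matrix + supplementary files (log2 ratios per probe)
wget -r -np 'ftp://ftp.ncbi.nlm.nih.gov/geo/series/GSE63nnn/GSE63216/'
```

The platform annotation gives probe ids and hg18 genomic positions.
Exclude the ~4.5k probes added for Cancer Census gene enrichment, leaving
the 168 823 evenly spaced (~17 kb) genome-wide probes, and write
`probes.tsv` (columns `probe_id`, `chromosome`, `position`).

## 2. Segment and call states (upstream, R)

Segment each tumor/normal log2-ratio profile with Bioconductor `DNAcopy`
(CBS) and call states with `CGHcall`, matching the versions noted in the
deposit (DNAcopy 1.36.0, CGHcall 2.17.6 were used originally; current
versions give near-identical segments):

```r
library(DNAcopy); library(CGHcall)
# ... segment, call, then export one row per segment:
# sample, chromosome, start_probe, end_probe, mean_log2, call
```

Start/end probe indices must be 0-based within-chromosome indices into
`probes.tsv`, covering every probe exactly once per chromosome
(`breakgene.profiles_io.read_segments` validates this and names the
offending sample/chromosome otherwise).

## 3. Gene annotation

Export hg18/Ensembl54 gene spans as BED4 (`genes.bed`). Any mirror of
Ensembl release 54 (e.g. BioMart archive) works; coordinates must match
the probe build (NCBI36/hg18).

## 4. Run the pipeline

```bash
breakgene breakpoints --segments segments.tsv --probes probes.tsv \
    --genes genes.bed --out-dir breakpoints/
breakgene recurrence --segments segments.tsv --probes probes.tsv \
    --genes genes.bed --alpha 0.1 --out recurrence.tsv
```

`recurrence.tsv` lists every tested gene/pool with prevalence, exact
Poisson-binomial p-value and discrete-FDR q-value; rows with
`significant == True` are the recurrent breakpoint genes. The probe-level
table comes from `breakgene.recurrence.probe_recurrence_test` on the
probe matrix written by the `breakpoints` command.

## 5. Stratification and survival (optional)

With a mutation matrix for the 8-gene panel (APC, TP53, KRAS, PIK3CA,
FBXW7, SMAD4, BRAF, NRAS), a STRING-derived edge list, and a clinical
table (`sample`, `os_days`, `event`, `msi_status`):

```bash
breakgene stratify --breakpoints breakpoints/gene_matrix.tsv \
    --mutations mutations.tsv --network string_edges.tsv \
    --k 4 --n-iter 1000 --seed 7 --out-dir nbs/
breakgene associate --subtypes nbs/subtypes.tsv --clinical clinical.tsv \
    --gene-matrix breakpoints/gene_matrix.tsv --out-dir clinical_out/
```

Mutation calls and the clinical table are not part of the GEO deposit;
they must be obtained from the original study's supplementary tables.
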