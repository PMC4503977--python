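# cnvmir

Comparative analysis of how genes inside copy-number-variable (CNV) regions
are regulated, relative to non-CNV genes, across eight species (chicken,
dog, cow, rat, mouse, macaque, chimpanzee, human). The package is built
around a model system: genes whose longest mRNA carries a 3'UTR shorter
than 8 nt, which are presumed to lose canonical (3'UTR-mediated) miRNA
repression. It asks where miRNA binding sites and SNPs go when the 3'UTR
is effectively absent, and whether human CNV genes behave differently from
everyone else's.

The pipeline:

1. **Gene model** — one longest transcript per gene; 5'UTR/CDS/3'UTR
   lengths from the mRNA CDS coordinates (`utr3_len = mrna_length −
   cds_end`); genes classed *long* (3'UTR ≥ 8 nt) or *short*.
2. **CNV atlas** — genes are *CNV* iff their genomic span shares ≥ 1 bp
   with a CNV interval; human status propagates to the other species
   through a homolog table; mature miRNAs overlapping CNV gene
   coordinates become *CNV-miRNAs*.
3. **Binding sites** — two independent scanners per gene region: a
   canonical seed matcher (6mer / 7mer-A1 / 7mer-m8 / 8mer sites at
   occurrences of the reverse complement of miRNA positions 2–7) and a
   longest-consecutive-complementarity scanner anchored at miRNA position
   1 or 2 (`walk-k`, k ≥ 7); only sites called by both survive the
   consensus filter.
4. **SNP profile** — SNPs per region and pooled density (SNPs/kb) by
   transcript-size bin.
5. **Statistics** — Fisher's exact test (two-sided, minimum-likelihood
   rule, exact integer enumeration) with Holm or Benjamini–Hochberg
   correction for overrepresentation; one-way ANOVA omnibus followed by
   pairwise Wilcoxon rank-sum tests (exact null enumeration for small
   tie-free samples) for species and DER comparisons.

Because the original gene, CNV, miRNA, SNP and pathway censuses came from
specific database releases, the package ships a synthetic-fixture
generator (`cnvmir.synthetic`) that emulates all inputs with planted,
parameterized effects — CNV fractions, short-UTR fractions, a 2× 5'UTR
site rate in human CNV short-UTR genes, a 2× human:mouse SNP rate, an
overrepresented pathway, a DER shift — so every stage can be validated
against ground truth.

## Worked example

```sh
cnvmir simulate --seed 11 --n-genes 500 --outdir results/fixture
cnvmir run-all --bundle results/fixture --outdir results/pipeline
```

or, as a library (numbers from the seed-11 fixture):

```python
>>> from cnvmir.pipeline import RunConfig, run_full
>>> rep = run_full(RunConfig("results/fixture", "results/pipeline"))
>>> rep.short_utr_counts
  species  CNV  nonCNV  total
0     bta   42      71    113
...
3     hsa   34      12     46
```

Human has the fewest short-3'UTR genes (46 vs 82 for the next-lowest
species) and is the only species where they are majority-CNV (34 vs 12) —
the qualitative pattern the generator plants. The 5'UTR enrichment
contrast on those genes recovers the planted 2× site rate:

```
short-UTR contrast: OR=2.02, Holm-adjusted p=4.64e-03
human:mouse pooled SNP density ratio per region: 1.91 / 2.06 / 1.82
```

The numbered drivers under `analysis/` (`01_simulate.py` …
`06_compare.py`) run these stages in sequence and write their tables
under `results/`.

## Layout

```
src/cnvmir/      genemodel, cnv_atlas, sitescan, snpmap, enrich, compare,
                 synthetic, experiments, pipeline, cli
analysis/        numbered narrative drivers over the library
tests/           unit, property and end-to-end suites
docs/methods.md  models, parameters, calibration and limitations
```
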