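# Methods

## Gene model and 3'UTR classification

A gene is represented by its single longest mRNA (ties broken by the
lexicographically smallest transcript id, so deduplication is
deterministic and order-free). Region lengths come from the CDS
coordinates as printed in transcript tables (1-based inclusive on the
mRNA): `utr5 = cds_start − 1`, `cds = cds_end − cds_start + 1`,
`utr3 = mrna_length − cds_end`; the three always sum to the mRNA length.

A gene is *long* when its 3'UTR is at least 8 nt and *short* otherwise.
The boundary deserves a note: short genes are often described loosely as
having 3'UTRs "shorter than 7 nt", which leaves 7 nt ambiguous; this
package applies the ≥ 8 = long rule, so a 7-nt 3'UTR is short. The
threshold is a parameter (`long_threshold`, default 8). The rationale for
a threshold this small is mechanistic: below ~8 nt no seed match fits in
the 3'UTR at all, so canonical miRNA repression is structurally
impossible rather than merely weakened.

Genomic coordinates are 0-based half-open internally (BED convention);
transcript-table genomic columns are 1-based inclusive and converted at
the reader boundary. Sequences are stored uppercase with U folded to T.

## CNV atlas

A gene is **CNV** iff its genomic span shares at least one base pair with
any CNV interval — the most permissive deterministic rule; no minimum
overlap fraction is imposed, and strand is ignored. Because CNV maps
effectively exist for human only, CNV status is computed for human genes
and propagated to the other species through a homolog table; species
genes without a homolog are excluded from both classes and counted in the
run log. A species gene homologous to both a CNV and a non-CNV human gene
takes the CNV label (dominant), with a warning.

Mature miRNAs are classed the same way: **CNV-miRNA** iff their genomic
location overlaps the coordinates of CNV genes. The interval set is an
argument, so scanning against CNV regions themselves (rather than CNV
gene spans) is a one-line change; CNV gene coordinates are the default.

## Binding-site scanners

The analysis needs two independent predictors and an intersection filter;
both scanners are deliberately transparent, rule-based and fast, so that
background rates are analytically computable and every call is
reproducible. Watson–Crick pairs only by default (`allow_wobble` adds G:U
at a documented cost in specificity); all occurrences are reported,
including overlapping and nested ones — no greedy masking.

**Seed scanner.** Every occurrence on the target of the reverse
complement of miRNA positions 2–7 is a site. The occurrence is upgraded
by two independent features: pairing extends to position 8 (7mer-m8), an
adenosine faces miRNA position 1 (7mer-A1), or both (8mer). On i.i.d.
uniform sequence the expected 6mer-core count is (L−5)·4⁻⁶ per miRNA —
the calibration the tests check to 3 SE.

**Walk scanner.** For each target position, the longest run of
consecutive pairs anchored at miRNA position 1 or position 2 is computed;
maximal runs of at least `min_len` (default 7, minimum 6) are reported as
`walk-k`. A position-2 run whose position-1 pair also matches is part of
the corresponding position-1 run and is not reported twice. Background
expectation on uniform sequence: ≈ (L−6)·4⁻⁷·(1 + 3/4) — one term per
anchor, the second discounted by the ¾ chance the position-1 pair fails.

**Consensus.** A seed site is retained iff a walk site for the same
miRNA/gene/region overlaps it by ≥ 1 nt; each overlapping pair yields one
consensus site at the seed coordinates. Every planted exact 8mer is found
by both scanners (the 2–8 pairing is a ≥ 7 run anchored at position 2),
so consensus recovery of planted sites is 100% by construction.

Counting unit: individual binding sites. A distinct-miRNAs-per-gene
column is emitted alongside, since both statistics are of interest.

## SNP density

SNPs arrive pre-assigned to a gene region, the form in which
region-restricted database queries export them; no coordinate lifting is
performed. Counts are zero-filled over all annotated genes. Density is
pooled within a group — Σ SNPs / Σ region kb — rather than a mean of
per-gene densities, which is unstable when regions are a few nt long.
Transcript-size bins are half-open `[lo, hi)` at 1-kb steps up to 10 kb
plus an open top bin (configurable); binning conserves the total SNP
count by construction, and zero-length groups are flagged, not dropped.

## Statistics

**Fisher's exact test** is two-sided by the minimum-likelihood rule: with
margins fixed, sum the hypergeometric probabilities of every table whose
probability does not exceed the observed one. Implementations differ in
this rule, so it is pinned down with exact integer binomial weights
(ties compare exactly; p is the correctly rounded float of an exact
rational). The odds ratio is the sample ad/bc, ∞ when bc = 0 < ad.

**Multiplicity.** Both Holm (step-down FWER) and Benjamini–Hochberg
(step-up FDR) are available, via statsmodels. Defaults: Holm for
binding-site contrasts, BH for pathway enrichment — the two families the
analysis runs. The source protocol is ambiguous between the two methods
(its wording conflates them), hence both are first-class and the choice
is a parameter.

**Site-enrichment 2×2.** For a contrast of gene categories A vs B in
region R: a = A-sites in R, b = A-sites elsewhere, c/d likewise for B.
The table builder is exposed separately so alternative layouts are
testable. Correction applies across all contrasts of a run.

**Wilcoxon rank-sum** is two-sided; exact when n_x + n_y ≤ 12 with no
ties (the full rank-sum null distribution via subset-sum dynamic
programming; p = 2·min(lower, upper) tail, capped at 1), otherwise a
normal approximation with midranks, tie-corrected variance and a 0.5
continuity correction. **ANOVA** (scipy) runs first as the omnibus over
species; pairwise reference-vs-other Wilcoxon p values are reported raw
by default (an optional Holm flag covers the pairwise family), matching
the usual practice of quoting per-pair p values. An all-values-identical
input reports "no difference" (p = 1) instead of a 0/0 F statistic.
Comparisons run on raw counts by default; a `log1p` flag is provided.

**DER comparison.** For each miRNA class, the differential-expression
ratios of its CNV-gene targets and its non-CNV-gene targets are compared
by Wilcoxon; groups below 2 values are skipped with a warning.

## Synthetic fixtures

The generator emulates the statistical structure of the real inputs, not
their content:

* **Geometry.** Genes are laid out intron-free on 5 chromosomes with
  1-kb gaps. CNV status is assigned per human gene (Bernoulli) and then
  realised by writing a CNV interval inside each chosen gene's span, so
  interval classification recovers the assignment exactly; other species
  inherit status through the homolog table (default coverage 0.92).
* **Study conditions** (`default_config`, 500 genes/species): human has
  the lowest short-UTR fraction (0.10, others 0.14–0.30) and is the only
  species whose short-UTR genes are majority-CNV (0.65 vs the 0.30
  background CNV fraction) — the qualitative cross-species pattern the
  pipeline is meant to expose. Mean region lengths 200/900/500 nt
  (5'UTR/CDS/3'UTR, normal with CV 0.2); short-gene 3'UTRs are uniform on
  0–7 nt. 30 miRNAs of 22 nt; 25% placed inside CNV gene spans.
* **Planted sites.** Exact 8mers for randomly chosen miRNAs are embedded
  in every 5'UTR on a non-overlapping 8-nt lattice at a baseline 25
  sites/kb; human CNV short-UTR genes get 2× that rate. The lattice
  guarantees placement capacity ≈ L/8, so the realized counts are
  untruncated Poisson. The baseline was calibrated once so the planted
  2× contrast is recovered at ≈ 0.90 power (measured over independent
  seed blocks) and then frozen.
* **SNPs.** Poisson per region at per-kb rates; defaults make every
  human rate exactly twice the mouse rate (8/6/10 vs 4/3/5 per kb for
  5'UTR/CDS/3'UTR), with rat and chicken lower still.
* **Pathways.** 20 pathways of 40 genes per species; one (`pw01`) drawn
  with 8× weight on human short-UTR genes (calibrated to ≈ 0.97 BH
  recovery power, then frozen).
* **DER.** Human genes draw N(0.30, 0.12) clipped at 0, plus +0.10 for
  CNV genes.
* Background sequence is i.i.d. uniform ACGT (optional GC bias), which
  makes scanner background rates exact; one RNG stream per file type,
  all spawned from the master seed, so regeneration is stable and a
  fixed seed yields byte-identical bundles.

`null_config` zeroes every planted effect — no embedded sites at all, no
DER shift, flat pathway weights — and equalizes per-species parameters,
for type-I-error suites.

What the generator does **not** emulate: introns and genome-to-transcript
coordinate lifting, isoform/alternative-polyadenylation structure,
repeat content and realistic base composition, conservation, and
thermodynamic binding. Passing tests therefore demonstrate that the
pipeline's logic recovers effects of the planted kind at the stated
sizes — not that the scanners match experimentally validated target sets
on real transcriptomes.

## Operating characteristics and problem sizes

The heavy simulations run at the study conditions (500 genes/species,
human-only where only human cells enter the contrast): 200 replicates for
planted-effect power, 1,200 for the null rejection fraction (tighter SE
for a quantity asserted to sit inside [0.03, 0.07]), 500 × 1-kb targets
for scanner calibration, and exhaustive enumeration for the statistical
primitives (all 135,750 tables with total ≤ 40; all rank splits with
n ≤ 10). The planted-contrast simulations use the seed scanner: the
planted effect is defined in seed-site units, and the single-predictor
route isolates the enrichment machinery from consensus-filter attrition.

## Known limitations

* The pooled-count Fisher contrast treats sites as independent draws;
  per-gene site counts are clustered (lengths vary between genes), so
  even under the no-planting null its rejection rate sits slightly above
  nominal (measured ≈ 0.057 at α = 0.05). A gene-level resampling test
  would be calibrated but is not what the analysis protocol specifies.
  With baseline planting left on under a unit multiplier, the extra
  mixed-Poisson overdispersion pushes the same test to ≈ 0.08 — one
  reason the null fixture zeroes planting entirely.
* Homolog propagation assumes the human CNV map is the reference for all
  species; species-specific CNVs are out of scope, as is CNV calling.
* The walk scanner's parameterization (minimum run 7, anchor at position
  1 or 2) follows the common description of complementarity-walk
  predictors; the exact historical parameter sets of the published tools
  it stands in for are not reproduced.
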