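# Methods

`phasetally` re-implements, as a reusable and tested pipeline, the computational
analyses used to characterize miRNA-induced secondary siRNA populations in
plant small RNA-seq data: anchoring reads to RISC cleavage sites, a 21-register
phasing statistic, trim/tail classification at the 5'-cleavage-fragment
extremity, cleavage-site-centered density metaplots, simplified
negative-binomial differential testing with miRNA-target enrichment, and
logistic/mixed models linking miRNA expression and seed affinity to siRNA
production. This note records the models, the parameters that matter, and the
numerical choices made where the design was genuinely open.

## Coordinates and cleavage-site anchoring

Transcripts are strand-aware exon chains. Internal coordinates are 0-based
half-open; GFF3 I/O converts from the 1-based closed convention at the
boundary. On the minus strand, transcript coordinate 0 is the genomically
rightmost exonic base, so transcript order always runs 5'→3' biologically.

A cleavage site `cs` indexes the **first nucleotide of the 3' cleavage
fragment**: the 5' fragment is `[0, cs)`, the 3' fragment `[cs, length)`, and
the signed distance of a position is simply `position − cs` (the last
nucleotide of the 5' fragment is −1). Published cleavage-site tables give a
1-bp genomic position without stating which side of the scissile bond it
denotes; the loader fixes the first-nucleotide-of-3'-CF convention and offers
`convention="last_5cf"` for the alternative, which shifts `cs` by one.

Alignments are projected onto transcripts through spliced coordinates:
an alignment anchors to a transcript only if all its aligned bases are exonic
there and form one contiguous spliced run. Partially exonic alignments are
dropped with a count. A read's anchor for distance plots is its 5' end in
transcript orientation; both ends are retained for phasing and trim/tail.

## Phasing registers

Single-round RDR6/DCL4 amplification dices dsRNA from the cleavage-site
terminus, so 21-nt siRNAs stack in 21-nt registers. The nucleotide adjacent to
the site is fragment-local position 1 **on both fragments** (numbering runs
away from the site on each side, mirroring dicing that proceeds from the
cleaved end; the direction is configurable in principle but fixed here). Each
fragment is split into intervals 1–21, 22–42, 43–63, …; a read whose
site-proximal boundary sits at fragment-local position `l` has register
`((l − 1) mod 21) + 1`.

Qualifying reads are perfect 21-nt matches (CIGAR 21M, zero mismatches,
no clips) lying wholly within one fragment; reads straddling the site are
rejected and counted — whether the original analyses kept them is unstated, so
the stricter rule is used and reported. The 2-nt displacement of minus-strand
dicer products is deliberately **not** corrected, so a tightly phased
double-stranded population splits between neighboring registers by strand
(the TAS1c-like signature, reproducible with
`SimConfig(antisense_duplex_offset=2)`).

A population is called *phased* iff register 1 holds a strict majority of
qualifying reads; an exact 50% tie is unphased ("majority" read strictly), and
zero qualifying reads yield "undetermined".

## Trimming and tailing

Reads deriving from the 3' extremity of the 5' cleavage fragment are selected
by an exact match to a 10-nt reference anchor occupying fragment-local
positions 11–20 — i.e. the anchor's site-proximal edge is offset 10 nt from
the fragment end, leaving the terminal decile (where trimming and tailing
live) free to vary. Anchor length is a parameter (`anchor_len`); matching is
exact, and whether the original analysis tolerated mismatches ("approximately
10 nt") is unknowable from the text, so exactness is the documented default.

For each selected sense read, `n_trimmed` is the number of reference
nucleotides between its last templated base and the annotated fragment
terminus (floored at 0), and `n_tailed` the number of 3' soft-clipped bases —
non-templated by the aligner's own account — with the tail sequence reported
in RNA alphabet. Aligned-but-mismatching bases beyond the fragment end are not
re-examined: the classifier trusts the clip structure, which is also exactly
how the generator encodes tails, so the recovered joint distribution is
directly comparable to the configured one. A read whose templated alignment
runs past the fragment end is flagged as readthrough and excluded from the
dot-plot table. Antisense reads are excluded throughout (the fragment
extremity is a property of the sense strand).

## Metaplots

Densities are per-base coverage (each read contributes to every templated
position it covers), normalized to reads per ten million mapped (RP10M),
averaged over replicate libraries, and re-indexed to signed distance from the
cleavage site; `mode="5prime"` counts read 5' ends instead for spike-style
per-target panels. The default window is ±1000 nt (the source figures do not
state one); windows clipped by transcript ends are flagged as truncated.
Aggregation over a target set is the unweighted per-distance mean and is
permutation-invariant. Strands are kept separate so sense coverage can be
plotted upward and antisense downward; lengths 21–24 are kept as classes.

## Counting and differential testing

Counting follows featureCounts defaults in spirit: a primary alignment counts
toward a gene when its span overlaps exactly one feature; overlaps of two or
more features are ambiguous and tallied as unassigned (conservation: assigned
+ unassigned = total). `multimap={primary, fractional, all}` offers 1/NH
weighting or all-records counting. Intergenic gaps become explicit bin
features so every position is annotated.

Size factors are DESeq-style median-of-ratios over genes nonzero in all
libraries, with an optional pseudocount escape hatch when no such gene exists.

The differential test is a deliberate simplification of DESeq2 with no
empirical-Bayes machinery: per-gene NB GLM with log link and size-factor
offsets, a Wald z on the mutant-vs-WT contrast, two-sided normal p, BH
adjustment, padj < 0.05 default significance. With a two-group design the GLM
decomposes into independent per-group mean fits, solved exactly by vectorized
Newton iterations; at dispersion → 0 the p-values agree with a Poisson GLM to
< 1e-3. Genotypes with fewer than two replicates are refused for testing (they
can still be inspected descriptively), and all-zero genes are excluded and
flagged.

**Dispersion.** Two method-of-moments estimators are provided, both floored at
1e-8. The default `"per-gene"` estimator matches the documented simplification
but carries almost no information at typical replication (4 residual df), and
Wald tests built on it are strongly anticonservative (measured type-I ≈ 0.14
at the nominal 0.05 in a 3-vs-3 null). The `"pooled"` estimator computes one
common dispersion from moment sums pooled over genes and groups, with the
denominator debiased by `m² − v/n` (the sample mean squared overestimates μ²
by the variance of the mean); under a homogeneous-dispersion null it measures
type-I ≈ 0.054 and is the estimator used wherever calibration matters. Neither
is empirical-Bayes shrinkage; when dispersions are truly gene-specific the
pooled estimator trades some robustness for calibration, which is the right
trade for the simulated designs and a documented caveat for real data.

Enrichment of miRNA targets among differentially-siRNA-producing genes (and
set-overlap tests) is the exact Fisher test on the 2×2 membership table;
it agrees with brute-force hypergeometric summation to 1e-9 on every table
with universe ≤ 20.

Row z-scores for target-by-genotype heatmaps use the population
(n-denominator) standard deviation — the source does not say which convention
was used, so one is fixed and documented; constant rows get zeros and a flag.

## Seed affinity and producer models

The seed is miRNA nucleotides 2–9. Its duplex with the 8 target nucleotides in
antiparallel register is scored by nearest-neighbor summation at 37 °C using
the Turner 2004 RNA free-energy set (Watson–Crick stacks from Xia et al. 1998,
G:U stacks from Mathews et al. 1999) at the 0.01 kcal/mol resolution of
community parameter distributions: duplex initiation +4.10 kcal/mol and
+0.50 kcal/mol per helix end closed by A:U or G:U, converted to kJ/mol
(×4.184). Hand-summation with this table reproduces ViennaRNA duplex folding
on fully complementary duplexes to the printed digit (kept as an oracle test).
Internal mismatches interrupt the helix: flanking stacks contribute nothing. A
mismatch at a terminal seed position routes to the fallback scorer — the
maximal contiguous Watson–Crick/G:U core, scored the same way — and sets a
flag, mirroring the original analysis's use of a second tool for
terminal-mismatch pairs. No target secondary structure, 3'-supplementary
pairing, or AGO-conformation correction is attempted; as in the original
analysis, these errors are assumed similar across pairs so *relative*
affinities are meaningful.

miRNA isoforms sharing a seed are grouped and their RPM summed, giving one
record per (seed group, target). Expression enters the models as the natural
log of mean RPM; zero-RPM pairs are excluded with a warning.

Four logistic formulas are available: `expression_only`
(producer ~ log RPM), `saturated` (main effects + interaction with −ΔG),
`covariate` (intercept + the single product term log RPM × (−ΔG), the reduced
model), and `covariate_main` (two main effects) — the published description is
ambiguous between the last two, so both exist. Binding energy enters as −ΔG
so positive coefficients mean stronger binding → higher producer probability.
Each fit reports AIC, Tjur's R² (mean fitted probability in producers minus
non-producers), a likelihood-ratio test against intercept-only, and a
Kolmogorov–Smirnov test of randomized-quantile residuals against
Uniform(0, 1) — the published validation does not say what the KS test was
applied to, and PIT residuals are the natural choice for a binary response.
Perfect separation falls back to a ridge-penalized fit with a flag.

Family keys strip isoform suffixes from miRBase-style names, with miR156 and
miR157 merged; only families containing both producers and non-producers are
informative for the within-family contrast. The mixed model is
ΔG ~ producer + (1 | family), ML (not REML, so log-likelihoods are comparable),
with the fixed effect tested by χ² LRT (df = 1) against the no-fixed-effect
nested model. A boundary (zero family variance) or non-converged fit is
flagged singular and falls back to the OLS comparison, its degenerate limit.

## The synthetic-data generator

The generator emulates the features the pipeline assumes about real
inflorescence libraries, with study-shaped defaults:

* **Transcripts** — six genes laid along one chromosome, alternating strands,
  three exons (800/400/900 nt, 100-nt introns), gene types cycling through
  miRNA target / protein coding / transposable element, 500-nt intergenic
  gaps; each miRNA target carries one cleavage site (default transcript
  position 1000, strictly exonic). Random seed-reproducible sequences.
* **Reads** — 21–24 nt (default mix 0.70/0.10/0.10/0.10, 21 dominant as for
  mRNA-derived siRNAs), both strands (sense probability 0.5), spread over both
  cleavage fragments with a gentle per-nucleotide geometric decay (0.99) away
  from the site and a 5'-fragment share of 0.65, reflecting the observed
  5'-sided asymmetry. Neither the decay nor the split is a literature claim —
  no quantitative spreading model exists — they are artifact choices fixed
  once. A 21-nt read starts exactly on the site-anchored grid with probability
  `phase_fidelity`; otherwise its offset is uniform over the 21 possibilities,
  making the register-1 fraction exactly `f + (1−f)/21`. Sense reads abutting
  the 5'-fragment terminus receive `(n_trimmed, n_tailed)` noise from
  `trimtail_model` (default mass concentrated on ≤3-nt trims and ≤2-nt tails,
  40% unmodified), with tails drawn uniformly from the alphabet. Reads are
  emitted already aligned (mapping is out of scope) and written as SAM with
  tails as 3' soft clips; `simulate_terminal_reads` produces the
  fragment-terminal population directly for trim/tail calibration.
* **Counts** — NB per gene with configurable genotype/replicate structure
  (default 3 vs 3), mean 100 and dispersion 0.1, plus per-genotype log2
  fold changes.
* **Pair tables** — log RPM ~ Normal(2, 1.5), ΔG ~ Normal(−30, 8) kJ/mol,
  producer ~ Bernoulli(logistic(β0 + β1·logRPM [+ β2·(−ΔG)])); default table
  size 153, the size of a reduced unique-seed set. A separate family table
  generator draws family intercepts (sd 2 kJ/mol) and a producer effect
  (−3 kJ/mol) for mixed-model recovery.

What the generator does **not** emulate: sequencing error, multimapping
ambiguity, rRNA/tRNA contamination, isoform mixtures, gene-specific dispersion
heterogeneity, or correlated miRNA families in the logistic table. Passing
tests therefore demonstrate that the statistics recover the structure they are
built for — not that real libraries satisfy that structure.

## Problem sizes and tolerances

Calibration checks use 21 000 reads per phasing library, 10 000 terminal reads
for trim/tail, 2 000 genes at 3-vs-3 for the NB null, 5 000 pairs for
coefficient recovery, and 25–30 permutations for null-uniformity KS checks —
sizes at which binomial/χ² tolerances are tight while everything runs in
seconds. Binomial comparisons use the 99% two-sided band; GOF and KS
uniformity use α = 0.01. Newton fits run a fixed 60 damped iterations
(step clip ±2 on the log scale); dispersions are floored at 1e-8; BH
propagates NaNs without letting them enter the ranking.

## Known limitations

* The NB Wald test with per-gene moment dispersions is anticonservative at
  low replication — by design it reproduces a simplification, and the pooled
  mode exists for calibrated use.
* ΔG values assume an unstructured, naked target site; absolute values are
  not comparable to experiments, only differences between pairs.
* Trim/tail calls trust aligner soft clips; a mismatching templated extension
  aligned as M is counted as templated.
* One designated isoform anchors each cleavage site; alternative isoform
  quantification is out of scope.
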