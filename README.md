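# phasetally

Cleavage-site-anchored analysis of miRNA-induced secondary siRNAs in plant
small RNA-seq data.

When an Argonaute-loaded miRNA (RISC) slices a target mRNA, the transcript is
split into a 5' and a 3' cleavage fragment (CF), and — normally only for a
select few targets — RNA-dependent RNA polymerase amplification converts the
target into double-stranded RNA that DICER-LIKE enzymes dice into *secondary
siRNAs*. In mutants of RNA-decay machinery (cytoplasmic and nuclear exosome
cofactors, ribosome-rescue factors), many ordinary miRNA targets illicitly
spawn such siRNAs. `phasetally` provides the computational toolkit for
characterizing these populations, for researchers analyzing plant small
RNA-seq libraries against a table of known miRNA cleavage sites:

* **coordinates** — strand-aware genomic↔transcript mapping, cleavage-site
  anchoring (`distance = position − cs`, with `cs` the first nucleotide of the
  3' CF), and projection of SAM/BAM alignments into transcript space.
* **phasing** — the 21-register statistic: fragment-local position 1 is the
  nucleotide adjacent to the cleavage site on *both* fragments; a perfect
  21-nt read at fragment-local position ℓ occupies register
  `((ℓ − 1) mod 21) + 1`, and a population is *phased* iff register 1 holds a
  strict majority. Phasing diagnoses single-round dicing from the cleaved end.
* **trimtail** — selects reads covering the 3' extremity of the 5' CF (exact
  10-nt anchor, 10 nt back from the fragment end) and classifies each as
  `(n_trimmed, n_tailed)`: nucleotides nibbled from, or non-templated
  nucleotides added to, the fragment terminus.
* **metaplot** — cleavage-site-centered per-base read densities (RP10M),
  by strand and read-length class, averaged over replicates and over targets.
* **quantify** — per-gene siRNA counting, RPM/RP10M normalization,
  median-of-ratios size factors, a simplified negative-binomial Wald test for
  mutant-vs-WT differential siRNA production (s_j = size factor,
  log μ_gj = log s_j + β₀_g + β₁_g·mutant_j, H₀: β₁ = 0), Benjamini–Hochberg
  adjustment, exact Fisher enrichment of miRNA targets, size-class profiles
  and z-score heatmap matrices.
* **affinity** — seed (miRNA nt 2–9) : target duplex ΔG by nearest-neighbor
  summation (Turner 2004 parameters at 37 °C, kJ/mol), seed-grouped expression
  sums, and the statistical models of siRNA triggering: binomial logistic
  regressions of producer status on log miRNA RPM and −ΔG (with AIC, Tjur R²,
  LRT, KS validation) and a linear mixed model ΔG ~ producer + (1 | miRNA
  family).
* **synthetic_data** — a first-class generator producing GFF3/FASTA/SAM/TSV
  fixtures with the exact statistical structure above (tunable phase fidelity,
  trim/tail model, NB counts, logistic pair tables), so the whole pipeline is
  testable offline.

## Worked example

```python
import phasetally as pt

cfg = pt.SimConfig(seed=0, phase_fidelity=0.7)
tome = pt.simulate_transcriptome(cfg)
reads = pt.simulate_sirna_reads(cfg, tome, n_reads=20_000)
site = tome.sites[0]
own = [r for r in reads if r.transcript_id == site.transcript_id]

table = pt.phase_distribution(own, site)
print(f"qualifying 21-nt reads: {table.total}, rejected: {table.rejected}")
print(f"register-1 fraction: {table.register_fraction(1):.3f}  call: {pt.call_phased(table)}")

dg, fb = pt.seed_delta_g("UGACAGAAGAGAGUGAGCAC", "GUGCUCACUCUCUUCUGUCA")
print(f"seed dG = {dg:.2f} kJ/mol (fallback={fb})")

pairs = pt.simulate_pair_table(pt.SimConfig(seed=0, logit_coefs=(-2.0, 1.2)), 153)
fit = pt.fit_logit(pairs, "expression_only")
print(f"logit: slope={fit.coefficients['log_rpm']:.2f} AIC={fit.aic:.1f} "
      f"TjurR2={fit.tjur_r2:.2f} LRT p={fit.lrt_p:.2e}")
```

prints

```
qualifying 21-nt reads: 6834, rejected: 3166
register-1 fraction: 0.705  call: phased
seed dG = -42.26 kJ/mol (fallback=False)
logit: slope=0.99 AIC=161.4 TjurR2=0.28 LRT p=8.73e-12
```

Reading this: with phase fidelity 0.7, 70% of perfect 21-nt reads start
exactly on the cleavage-site-anchored grid and the rest land uniformly, so the
register-1 fraction sits near 0.7 + 0.3/21 ≈ 0.714 and the population is
called phased (strict majority). Reads that are not perfect 21-nt matches
(other size classes, trimmed/tailed terminal reads) are rejected from the
phasing denominator and counted. The seed:target duplex of a fully
complementary 8-bp seed scores −42.3 kJ/mol. In the 153-pair table drawn from
a known logistic model, the refit slope on log expression (0.99 vs the
generative 1.2 at this small n) is strongly significant: more abundant miRNAs
are more likely to trigger siRNA production.

The same stages are scriptable from the shell:

```bash
phasetally simulate --out sim/ --seed 1
phasetally phasing  --gff sim/annotation.gff3 --sam sim/reads.sam \
                    --sites sites.tsv --out phase.tsv
phasetally de       --counts sim/counts.tsv --contrast mutant:wt \
                    --genotypes wt_1:wt,wt_2:wt,wt_3:wt,mutant_1:mutant,mutant_2:mutant,mutant_3:mutant \
                    --out de.tsv
```

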