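# strpurity

Selective constraint and interruption density at short tandem repeats.

Short tandem repeats (STRs) mutate orders of magnitude faster than unique
sequence because of replication slippage. "Interruptions" — bases that
break the pure repeat — stabilize a locus: slippage rates scale roughly
with the longest remaining stretch of pure repeat, so an interruption acts
as a cis-linked anti-mutator in perfect linkage with the mutations whose
rate it suppresses. Whether interruptions accumulate or are purged at a
locus should therefore depend on what selection cares about there: where
expansions and contractions are deleterious (e.g. coding repeats in
constrained genes), interruptions that cause no amino-acid change are
indirectly favored; where the *purity* of the repeat is itself functional
(e.g. STRs in gene regulatory elements that modulate DNA-binding-protein
occupancy), interruptions are directly deleterious.

`strpurity` is a toolkit for testing these hypotheses on population-scale
STR genotype tables, for users in population genetics and variant
analysis. It provides:

* **Purity metrics** (`strpurity.repeats`) — minimum Levenshtein distance
  of an observed allele to a pure repeat under a fitting alignment (free
  template end gaps, minimized over motif rotations), longest pure stretch,
  and the fraction-interrupted exclusion rule (> 25%).
* **Coding audits** (`strpurity.coding`) — inference of a hypothetical pure
  ancestral allele minimizing amino-acid changes (nonsense excluded),
  per-codon silent/missense classification, and mutational-space exposures
  so that silent and missense interruption counts are comparable: for an
  allele of `n` codons, the silent exposure is `n` and the missense
  exposure is `n · Σ(missense subs)/Σ(silent subs)` over ancestral codons.
* **Genotype filters** (`strpurity.filters`) — missingness (> 25%),
  Hardy-Weinberg (chi-square with pooling, P < 10⁻⁶), segmental-duplication
  overlap, and major-allele extraction.
* **Annotation joins** (`strpurity.annotate`) — BED interval intersection,
  the sequential 25-state chromatin collapse (transcribed → promoter →
  strong/weak enhancer → other → heterochromatin), element-level minimum
  LOEUF, per-locus selection-score classes, and SNV-based interruption
  counting.
* **Non-B DNA prediction** (`strpurity.nonb`) — pattern-level detectors for
  slipped-strand, triple-helix, cruciform, bent-DNA, Z-DNA and
  G-quadruplex structures over the allele plus 150 bp margins, with the
  ≥ 1 bp repeat-overlap binning rule.
* **Regression layer** (`strpurity.glm`) — Poisson GLMs with log link and
  log-exposure offsets (`log λ = Xβ + offset`), logistic purity models,
  interaction terms, AIC comparison and Bonferroni correction, declared as
  model specifications.
* **Synthetic data and forward simulation** (`strpurity.simulate`,
  `strpurity.wright_fisher`) — generators for every input format with
  planted, recoverable effects, and a haploid Wright-Fisher simulator of
  the anti-mutator dynamics.
* **Pipeline and CLI** (`strpurity.pipeline`, `strpurity` console script) —
  end-to-end `run-coding` / `run-noncoding` orchestration with manifests,
  plus `simulate`, `filter`, `purity`, `coding-audit`, `annotate`, `nonb`
  and `fit` subcommands.

## Worked example

Generate a synthetic cohort with a planted enhancer-purity effect and run
the noncoding analysis:

```sh
strpurity simulate --out bundle/ --seed 7 --n-loci 2000 --enhancer-effect -0.3
strpurity run-noncoding --bundle bundle/ --out results/
```

The run prints one line per fitted model (headline term, Wald p, AIC):

```
enhancer_vs_heterochromatin: B[enhancer]=-0.5859 p=0.0182 AIC=1925.1 n=1684
purity_logistic: B[enhancer]=+0.7058 p=0.0142 AIC=1654.5 n=1684
strong_vs_weak_enhancer: B[strong]=-20.5057 p=0.999 AIC=94.5 n=119
enhancer_atac: B[atac_peak]=-0.0123 p=0.982 AIC=98.0 n=119
longest_pure: B[enhancer]=+0.0128 p=0.355 AIC=11477.5 n=1684
longest_pure_given_purity: B[edit_distance]=-0.2923 p=1.75e-297 AIC=9973.0 n=1684
sistr_snv: B[constrained]=-0.5835 p=4.76e-22 AIC=3701.3 n=1743
```

Reading the output: the bundle planted a −0.3 log-scale coefficient on the
enhancer indicator for interruption counts; the fitted
`enhancer_vs_heterochromatin` Poisson model recovers B = −0.59 ± 0.25
(enhancer STRs are purer than heterochromatic ones per bp of allele, with
only ~120 enhancer loci at this cohort size), and the logistic model shows
the complementary enrichment of fully pure alleles. The
strong-vs-weak contrast separates (B = −20.5, eight strong-enhancer loci
with no interruptions at all) — the model battery reports it with a
converged-but-degenerate coefficient rather than failing the run.
Conditioning on purity dominates the longest-pure-stretch model, and the
constrained-locus SNV model recovers the planted depletion of interrupting
SNVs at constrained loci (the generator's neutral:constrained SNV rate
ratio is 0.9:0.5, i.e. a true effect of log(0.5/0.9) = −0.59).

The coding side runs the codon audit and the consequence-specific models:

```sh
strpurity run-coding --bundle bundle/ --out results_coding/
```

```
silent_vs_loeuf: B[loeuf]=-0.2517 p=0.000214 AIC=4471.5 n=2000
missense_vs_loeuf: B[loeuf]=+0.0825 p=0.0151 AIC=6623.1 n=2000
joint_interaction: B[is_missense:loeuf]=+0.3307 p=1.38e-05 AIC=11169.6 n=4000
```

The coding generator plants β = −0.25 (silent) and +0.1 (missense) on
LOEUF; the audits and fits recover −0.25 and +0.08. Lower LOEUF means
stronger constraint, so the negative silent coefficient says constrained
genes carry *more* silent interruptions per unit of mutational
opportunity, while missense interruptions show the opposite trend; the
joint model's interaction term captures the difference between the two
slopes.

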