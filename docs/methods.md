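# Methods

`strpurity` implements an analysis of how selective constraint shapes the
density of interruptions at short tandem repeats (STRs), together with the
synthetic data and forward simulation needed to exercise and validate every
stage without external data. This note records the models, the numerical
conventions, and the design choices that were genuinely open.

## Purity metrics

An STR allele's impurity is the minimum Levenshtein distance between the
observed allele and a hypothetical pure allele built by tiling the locus
motif. The alignment is a *fitting* alignment: the observed allele aligns
end-to-end against a pure template with free leading and trailing gaps on
the template side only, so insertions and deletions relative to the pure
repeat are charged unit cost but the template's phase and length are not.
The template has length `L + 2|m|` (allele length plus two motif copies);
free end gaps make any longer template redundant, a property the test suite
verifies against a brute-force dynamic program that minimizes a global edit
distance over every motif rotation and every template prefix up to `2L +
2|m|`. The distance is additionally minimized over motif rotations; because
a sufficiently long pure template contains every rotation as a substring
this minimization is a no-op for the distance, but it determines the
reported aligned phase (ties break to the lexicographically smallest
rotation). The reverse complement is *not* considered: callers report
alleles on the reference strand.

The **longest pure stretch** is the longest substring whose period equals
the motif length and whose repeating unit is a rotation of the motif.
Partial trailing motif copies count toward the length — slippage rates
scale per base of uninterrupted repeat, not per complete copy — and the
metric is invariant under which rotation of the motif is supplied. Motifs
are canonicalized to their smallest period on construction (`ATAT` → `AT`);
homopolymers are rejected. The implementation decomposes the allele into
maximal period-p agreement runs; an O(n³) substring scan serves as the test
oracle.

**Fraction interrupted** is edit distance over allele length in bp. Alleles
with strictly more than 25% of bases classified as interruptions are
flagged for exclusion (boundary values are retained); such alleles are
likely mis-genotyped or compound repeats.

## Coding STR audits

Coding loci carry 3- or 6-bp motifs fully contained in one exon. The
hypothetical pure ancestor of an observed major allele is the motif
rotation, tiled to the allele length, that minimizes the number of
amino-acid differences from the observed allele, discarding any candidate
whose comparison implies a nonsense change in either direction; if all
candidates are discarded the locus is flagged unusable rather than raising.
Codons are read in transcript frame (`frame_offset` gives the phase of the
allele's first base); codons straddling the allele boundary are skipped;
minus-strand alleles are reverse-complemented first. Each audited codon is
pure, silent (sequences differ, translations agree) or missense.

**Mutational space.** Each sense codon partitions its 9 possible
single-base substitutions into silent/missense/nonsense counts under the
standard genetic code. Because silent opportunities are scarcer than
missense ones, raw counts of silent and missense interruptions are not
comparable. The package computes per-class exposures: the silent exposure
is the codon count and the missense exposure is the codon count multiplied
by the ratio of total missense to total silent substitution opportunities
over the ancestral codons. Under uniform mutagenesis with nonsense
rejected, both classes then show equal interruption rates per unit
exposure — a property the suite verifies on 10,000 codons. The opposite
orientation of the ratio (silent:missense), which would make missense
interruptions appear ~49-fold enriched under neutrality for CAG repeats, is
available via `exposure ratio orientation` for sensitivity analysis; the
neutrality-preserving orientation is the default because the reweighting's
stated purpose is to correct for the neutral mutational process. Loci whose
ancestral codons offer no silent opportunity at all (e.g. tryptophan runs)
are excluded from the joint model.

## Genotype filters

Loci are dropped when missing genotypes for more than 25% of individuals,
when failing Hardy-Weinberg equilibrium at P < 1e-6, or when overlapping a
segmental duplication; only the major allele (ties broken
lexicographically) is analyzed, with frequencies recalculated after
sample-level exclusions (excluded samples are treated as missing calls).
HWE for multiallelic STRs uses a chi-square goodness of fit on the full
diploid genotype table, pooling classes with expected count below 5;
degrees of freedom are `classes − 1 − (alleles − 1)`, floored at 1.
Monomorphic loci return P = 1 by convention. Exact tests are impractical at
STR allele counts; the chi-square choice is recorded in the filter report.
An alternative allele-vs-rest collapsing (each allele tested biallelically
at 1 df, minimum p Bonferroni-corrected by the allele count) is available
for very sparse tables via ``hwe_test(..., mode="allele_vs_rest")``.

## Annotations

All coordinates are 0-based half-open (BED convention); VCF positions are
converted on read, and readers normalize `chr`-prefixed and bare
chromosome names. The 25-state chromatin segmentation collapses to six
classes by fixed sequential precedence: transcribed (states 1, 5–9), then
promoter (2–4), strong enhancer (13–15), weak enhancer (10–12, 16–18),
"other" (19, 20, 22, 23), else heterochromatin. States 21, 24 and 25 are
not named by any rule and deliberately fall through to heterochromatin. A
locus overlapping several segmentation intervals contributes the union of
their states before classification. Element-level constraint is the
minimum LOEUF over an element's linked genes (unscored genes skipped);
enhancer-catalog joins honor the element- and link-level "elite" evidence
flags, restricting to elite links by default.
Locus-level constraint uses per-locus selection coefficients against
one-motif length changes: loci are neutral (median s = 0) or constrained
(s > 0), and only 2–4-bp-motif noncoding loci with a 95% CI narrower than
0.3 are scored. Interruption counts on recent timescales are nonsingleton,
filter-passing SNVs inside the reference-allele footprint.

## Non-B DNA structure prediction

Six structure classes are predicted by pattern matching over the major
allele padded with up to 150 bp of flanking sequence per side. Default
thresholds (one config block, all overridable): direct repeats with
identical arms ≥ 10 bp and spacer ≤ 10 bp (slipped strand); mirror repeats
with arms ≥ 10 bp, spacer ≤ 8 bp in ≥ 90% purine- or pyrimidine-skewed
spans (triple helix) — maximal mirror arms are trimmed down before the skew
test, since chance extensions dilute skew; inverted repeats with arms ≥ 6
bp and spacer ≤ 3 bp (cruciform); ≥ 3 A- or T-tracts of 3–6 bp phased 10±1
bp center-to-center (bent DNA); alternating purine-pyrimidine runs of
GC/CA/GT steps ≥ 10 bp (Z-DNA); and four G≥3 tracts with 1–7 bp loops plus
the C-strand mirror (G-quadruplex). Overlapping calls of one structure are
merged; any N breaks every pattern; an allele is flagged only when a
predicted span overlaps the allele interval by ≥ 1 bp — calls confined to
the margins are ignored.

A note on specificity testing: dinucleotide-shuffled controls preserve
composition exactly, and for some classes composition nearly implies the
pattern (a dinucleotide shuffle of a GC repeat must keep almost every G→C
step, so it cannot disperse a Z-forming run). The test suite therefore
certifies controls with an independent brute-force pattern oracle and
demands the detectors stay silent on controls the oracle declares
pattern-free — detectors must never call a structure the oracle does not
confirm.

## Regression layer

Interruption counts are modeled with Poisson GLMs (log link) including
motif GC fraction and motif length (bp) as covariates unless overridden,
with a log-exposure offset: log allele length for noncoding purity models,
log mutational-space exposure for coding models. Binary purity uses
binomial GLMs with logit link. Fits use iteratively reweighted least
squares (statsmodels); p-values are Wald by default with likelihood-ratio
tests behind a flag (the two agree closely on healthy fits, and the suite
pins the fitted coefficients to an independent Newton-Raphson maximizer to
six significant figures). The joint coding model is a Poisson GLM over the
long-format (locus × consequence class) table with a missense indicator,
the constraint score, their interaction, and the class exposure offset.
Rows with missing values are dropped per model with counts logged;
non-convergence and separation set `converged=False` with diagnostics
rather than raising. Model comparison is by AIC on the identical row set;
related tests are Bonferroni-corrected with family sizes declared in
config (10 binding proteins; 6 structures × 2 element classes = 12). No
overdispersion correction is applied by default; a quasi-Poisson rescaling
is available for sensitivity analysis.

## Synthetic data

The generator emulates the structure of population STR genotype data. Loci
draw motifs from a genome-like pool (dinucleotides dominant, AT-rich
motifs common), allele lengths of 8–25 motif copies (the short-read
spannable range), and annotation columns: chromatin classes at roughly
genome-like proportions (~78% heterochromatin, sub-percent strong
enhancers and promoters), open-chromatin peaks enriched in enhancers,
LOEUF roughly lognormal clipped to [0.05, 2], a constrained/neutral locus
score, and binding-site proximity. Interruption counts are Poisson with
log rate = planted linear predictor (baseline 8×10⁻³ per bp, GC and motif
length effects, log-length offset, plus configurable annotation effects);
each count is then realized as an allele sequence by substituting
well-separated bases of the pure tiling, and the arrangement is verified
against the purity metric so the planted count is exactly what the
pipeline measures. Diploid genotypes are drawn at Hardy-Weinberg
proportions around the major allele with ~3% missing calls. Coding cohorts
plant silent and missense interruptions per codon with class rates
proportional to the class exposure times `exp(β · LOEUF)` (defaults
β_silent = −0.25, β_missense = +0.1, matching the directions of the
planted-constraint hypothesis). Count-level "design tables" plant
coefficients directly in each headline model shape for fast coverage
testing; the sequence-level generators realize the same counts, and their
agreement is tested separately. All outputs are byte-identical under a
fixed seed.

What the generator does *not* emulate: linkage between loci, mutation-rate
heterogeneity beyond the modeled covariates, genotyping error, compound
repeats, population structure, or background selection. Passing tests
therefore demonstrate that the pipeline recovers effects present in data
of this structure — not that consortium-scale human datasets would yield
particular coefficients.

## Forward simulation of anti-mutator dynamics

A haploid Wright-Fisher population of N alleles at one STR locus evolves
under multiplicative fitness: `(1 − s_length)` per motif of deviation from
the optimum (initial) length, `(1 − s_missense)` and `(1 − s_silent)` per
interruption of each class. Slippage hits an allele with probability
`mu_slip × longest_pure_stretch / motif_len` per generation — interruptions
shorten the pure tract and thereby act as cis-linked anti-mutators — and
adds or removes one motif with equal odds (expansion is forced at the
two-copy minimum). Each base added by expansion becomes an interruption
with probability `gain_rate`; interruptions also arise by single-base
substitution at rate `point_rate` per allele per generation, the mechanism
by which a stabilizing interruption appears on an allele of unperturbed
length. Contractions spanning an interruption delete it. A new
interruption's consequence (silent vs missense) is drawn once from the
motif codon's mutational-space proportions (1:7 for CAG) and carried with
the allele; reversions are ignored.

Defaults are desk-scale calibrations, not human parameter estimates:
N = 1000, 500 generations, 200 replicates, CAG×15 starting allele,
`mu_slip = 10⁻²` per pure motif copy, `gain_rate = 10⁻³` per added base
(the low end of the empirically supported range), `point_rate = 3×10⁻³`.
These were chosen so the two qualitative predictions separate cleanly
within a few CPU-minutes: under length constraint (s_length = 0.2) silent
interruptions reach higher final frequencies than under neutrality, while
under coding constraint (s_missense = 0.5 ≫ s_length) missense
interruptions are purged. Both comparisons are tested one-sided
(Mann-Whitney, p < 0.01 over 200 replicates).

## Pipeline

End-to-end runs are pure functions of (inputs, config, seed): the filter
cascade, purity scoring or codon audits, annotation joins, and the
configured model battery, with per-stage row counts in a machine-readable
manifest, the effective config serialized next to the outputs, and long
format model tables materialized so any model can be refit standalone.
Every excluded locus lands in exactly one exclusion-reason tally and the
tallies plus the passing count equal the input count. Exit codes: 0
success, 2 config error, 3 input error, 4 model non-convergence (partial
outputs kept). Filter thresholds default to missingness > 25%, HWE
P < 10⁻⁶, impurity > 25%.

## Known limitations

* The pure-ancestor assumption overestimates interruption counts; the
  analyses only require that the overestimate not covary with constraint.
* Purity minimization over motif phases can only reduce distances relative
  to a fixed-phase implementation; the choice is uniform across loci.
* The non-B thresholds reproduce published pattern-level definitions, not
  any specific tool's output byte-for-byte, and pattern matching ignores
  thermodynamics and cell-type context.
* The Wright-Fisher model is haploid with multiplicative fitness and a
  single locus; diploidy, dominance, linkage and demography are out of
  scope.
* Multi-step evolutionary paths between the pure ancestor and the observed
  allele are not modeled; each codon is compared directly.
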