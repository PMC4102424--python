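# Methods

## Detection model

A microsatellite seed is a maximal perfect tandem repeat of a *primitive*
1–4 bp motif (a motif that is not itself a repeat of a shorter word; a run
of `ATAT…` is a dinucleotide, never a tetranucleotide). Seeds are anchored
at the start of their maximal periodic tract and trimmed to whole units, so
a tract of 13 bp with period 2 yields a 6-unit seed; this makes seed
coordinates unique and scan order irrelevant. Unit thresholds are
configuration, shipped as two presets:

* `primate` — 9/5/4/3 units for mono–tetra motifs, used for
  comparative-genomics scans. The threshold comparison is inclusive (≥).
* `population` — locus length windows 8–10, 10–18, 12–24, 16–28 bp. The
  lower bounds are the slippage-mutability thresholds; the upper bounds
  reflect how far short-read indel calls remain reliable. The
  tetranucleotide lower bound (16 bp = 4 units) intentionally differs from
  the primate-mode 3-unit threshold; both presets are kept verbatim rather
  than reconciled.

Extension is iterative and bidirectional. On each flank the nearest run of
≥ 2 complete units of the same rotation class (so `[CA]_k` extends
`[AC]_n`) is absorbed; up to `motif.size` intervening bases are allowed and
become an interruption. A candidate terminal addition of exactly one unit
is rejected. Phase-shifted same-class runs merge without an interruption
when every base belongs to a complete unit. When a seed of a *different*
motif class lies within `motif.size` bp of the final span, the locus is
compound and discarded from downstream analyses (both members of the pair
are flagged). N bases are hard breaks: never part of a seed, never an
interruption. The motif class used for extension is the same-strand
rotation class; the strand-symmetric canonical class (rotations of motif
and reverse complement, e.g. `[A/T]_n`, `[G/C]_n`) is used only for
grouping and reporting.

Interruption position classes follow the midpoint convention: *middle* when
midpoint/length ∈ [0.375, 0.625), *fringe* when < 0.25 or ≥ 0.75, else
*other*; the three bands are mutually exclusive and leave symmetric gaps.

## Ortholog filtering and mutability

Orthologous locus pairs pass eight screens, applied in a fixed order with a
first-failure rejection log: (1) ≥ 25 bp from the nearest other locus;
(2) no flank base with PHRED < 20; (3) no low-complexity 20 bp flank;
(4) flank identity ≥ 85%; (5) identical motif (rotation class); (6) ≤ 2
interruptions in every species; (7) identical interrupting bases;
(8) identical interruption context (the repeat bases immediately flanking
the interruption). "Low complexity" is not precisely defined in the
original procedure; here it is a mono- or dinucleotide run of ≥ 8 bp or a
trinucleotide Shannon entropy below 1.5 bits, both configurable.

Mutability is the mean squared repeat-number difference between the two
species (units²), computed on two species at a time, never pooled across
motif sizes. Confidence bands are percentile bootstrap intervals (default
B = 1000) over loci; bins with fewer than 20 loci are reported but flagged
low-confidence. Fold-changes between cohorts use an independent two-cohort
percentile bootstrap of the ratio of mutabilities; the acceptance analysis
uses B = 2000 following the usual recommendation that percentile-based
intervals need more resamples than standard-error estimates.

## Interruption calling

Variants must be normalized, left-aligned and biallelic (multi-allelics are
rejected with instructions to decompose). A variant is an interruption call
in a population when: the allele frequency there is ≥ 0.05 (inclusive); the
affected span lies inside the locus excluding the first and last repeat
*unit* (the whole unit, not just the terminal base — insertions may attach
immediately after the first unit or before the last); for indels the net
length change is not ≡ 0 (mod motif size) — this reads "whole-motif
indel" as net length, so 2× and 3× unit indels are also excluded, and it
implies mononucleotide loci can only be interrupted by SNPs; and the
resulting allele is no longer a perfect tandem of the motif (a periodicity
check after applying the variant).

Fate: the variant is applied to the locus sequence and the longest residual
whole-unit run of the motif class is measured in bp. At or above the
population-mode lower bound for that motif size → *degeneration*; below →
*death*. The bound source is configurable (population bp windows by
default; primate unit thresholds via the preset).

Exonic annotation translates the affected codon for SNPs (strand- and
frame-aware, standard codon table): stop gained → nonsense, amino-acid
change → nonsynonymous, silent → synonymous; indels with net length not
divisible by 3 inside a CDS → frameshift (in-frame interruption indels are
reported nonsynonymous — they necessarily alter the protein); exonic but
non-CDS → noncoding. Gene lists are deduplicated since one gene can carry
several interruptions.

Disease-locus tabulation parses annotated repeat-structure strings
(`(CAG)_6 CAA (CAG)_9`), applies each qualifying variant, and re-annotates
the alternative allele against the locus motif in fixed phase; the
reference allele carries the residual frequency so per-population
frequencies sum to 1. Variants overlapping but not contained in the
annotated span are excluded and returned flagged.

## Population-genetic statistics

* `H = 2pq` per population; `F_ST = (H_T − H_S)/H_T` with unweighted means
  (per the estimation procedure's wording); `H_T = 0` is reported as
  undefined (null), never silently dropped, so locus counts reconcile.
  Numerically the estimator is computed as `Var(p)/(P̄ Q̄)`, the exact
  algebraic equivalent of `(H_T − H_S)/H_T`; the variance form is
  non-negative by construction and avoids the catastrophic cancellation the
  direct difference suffers when all frequencies sit near fixation.
* Heterozygosity histograms use 25 left-closed bins of width 0.02 over
  [0, 0.5], last bin closed; values above 0.5 are rejected (impossible for
  biallelic 2pq).
* The two-sample KS comparison uses the pooled bootstrap: D is the exact
  sup-distance between ECDFs (tie-safe); the null distribution resamples
  both sample sizes with replacement from the pooled data (implemented as
  multinomial draws over the pooled support, which is exactly equivalent
  and fully vectorized); the p-value is the add-one Monte Carlo estimate
  `(1 + #{D* ≥ D})/(B + 1)`, mildly conservative and never zero. Default
  B = 10,000.
* LD `r²` is the squared haplotype correlation computed from phased 0/1
  vectors only (unphased EM estimation is out of scope); monomorphic
  vectors give an undefined (null) result. Max-`r²` partner selection
  searches ± 500 kb; ties break by distance, then coordinate; `r² = 1`
  within 1e−12 is flagged perfect LD.

## Polymerase error-frequency calculus

`MF = FUdR^R Cm^R colonies / Cm^R colonies`. `Pol EF = MF_observed −
MF_ssDNA background − MF_outside target`, floored at 0 with a warning.

Each sequenced mutant is globally aligned to its template
(match 1 / mismatch −2 / gap open −4 / extend −0.5); indels are then
canonically placed at the 3′ end of their repeat run (rightward shifting),
making unit-based vs interruption calls deterministic regardless of where
the aligner placed the gap. Each substituted base is one event (adjacent
substitutions become separate events tied by the tandem grouper); each
contiguous indel is one event. Events inside the repeat tract whose
inserted/deleted sequence is whole units of the motif class are *unit-based
indels*; all other in-repeat events are *interruption* substitutions,
insertions or deletions (so deleting the interrupting base of an
interrupted allele is an interruption-deletion even when its length equals
the motif size). Events outside the tract are coding-region events.
Detectability: all frameshifts (net length ≢ 0 mod 3); substitutions in
coding sequence when the amino acid changes or a stop appears; within the
repeat, only when a stop is created. Events ≤ 1 nt apart share a tandem
group.

The multiple-event correction is referenced to prior work and not restated
in the source text; it is reconstructed here as
`Pol EF_est = Pol EF × (detectable nontandem event groups across mutants,
tandem groups counting once) / (number of mutants)`, reduces to `Pol EF`
when every mutant carries one group, and is isolated behind a single
function and tested only for this stated limiting behaviour.
Class-specific frequencies use detectable events in both numerator and
denominator — `EF_class = (detectable events in class / all detectable
events) × Pol EF_est` — so the per-class EFs of an exhaustive partition sum
exactly to `Pol EF_est`. Spectrum reports, by contrast, include
undetectable interruptions (they hitchhike in products carrying another,
selectable error) and additionally report the fraction of mutants with ≥ 2
interruptions.

The bundled reporter template is synthetic: hand-built, repeat-free,
stop-free in-frame coding flanks around a configurable repeat tract,
standing in for a real reporter construct so desk-scale assays are
self-contained.

## Synthetic data: what it emulates and what it does not

Generators are deterministic under (seed, parameters) and serialize truth
sufficient to score any pipeline output without re-running the pipeline.

* **Genomes.** Planted loci are separated by ≥ 30 bp flanks,
  rejection-sampled against plain string rules (no periodic run within two
  units of any seed threshold; no phase continuation or absorbable ≥2-unit
  run at either junction; interruption gaps that parse back to exactly the
  planted gap), so detection is unambiguous by construction — the checks
  are independent string predicates, not calls into the scanner.
* **Ortholog cohorts.** Each lineage accrues ±1-unit slippage steps with
  probability r per generation (perfect loci) or r/k (interrupted loci),
  giving mutability exactly 2gr and a planted fold-change of exactly k.
  The divisor k stands in for the mechanism — interruptions dividing the
  tract into shorter, less slippage-prone runs — without modelling tract
  lengths explicitly; length-dependence of slippage, directional bias, and
  multi-step mutations are not emulated. Default study size for fold
  recovery is 12,000 pairs per cohort, large enough that the interrupted
  cohort still carries hundreds of informative loci at k = 100.
* **Population variant sets.** Perfect loci in the population windows
  receive planted interruption variants with per-population frequencies
  realizing a requested sharing plan, plus three decoy classes (AF < 0.05
  everywhere; terminal-unit SNPs; whole-motif indels) and optional exact
  frequency vectors for differentiation statistics. With LD pairs enabled,
  phased diploid haplotypes are emitted with a perfect-LD SNP partner in
  the flank plus noise SNPs. Real features not emulated: genotype
  uncertainty, linkage beyond the planted pairs, demography, and
  multi-allelic sites.
* **Mutant collections.** Event-class counts are apportioned exactly
  (largest remainder), so planted spectra are recovered exactly by
  classification — recovery tests certify the classifier, not sampling
  noise; colony counts realize the requested MF triple exactly up to
  rounding at 2×10⁵ colonies.

Passing tests on these data certify the algorithms and their bookkeeping at
desk scale; they do not certify performance on real genomes, where
alignment error, sequencing bias at long repeats, and filter interplay
dominate.

## Numerical and design choices

* Coordinates are 0-based half-open internally and in BED output; VCF
  positions are 1-based; locus tables carry a dedicated 1-based column;
  conventions are asserted at I/O boundaries.
* Bootstrap and KS procedures take explicit seeds and are bit-reproducible;
  stratified runs derive per-bin seeds from one generator.
* Overlapping seeds of different motif classes discard both loci; ties on
  identical spans resolve by canonical motif order.
* `F_ST` is clipped to ≤ 1 after the variance-form computation (1-ulp
  protection); empty cohorts, zero colonies, empty samples and monomorphic
  haplotypes raise or return explicit nulls rather than NaN.
* The umbrella pipeline compares heterozygosity of interruption alleles
  against that of the remaining (non-interrupting) variants in the same
  callset; at desk scale this is the natural perfect-vs-interrupted
  contrast the variant set supports.

## Known limitations

Penta-/hexanucleotide motifs are out of scope. Detection is pure-Python
and desk-scale; genome-scale runs would need the scan vectorized or
compiled. The ortholog filters consume pre-extracted pair tables — raw
multiple-alignment parsing is out of scope. The multiple-event correction
formula is an interpretation (flagged above). LD requires phased
haplotypes.
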