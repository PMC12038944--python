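# Methods

This note documents the models behind `founderdel`: what each generator
emulates, the estimators and their numerical details, the defaults and why,
and what passing tests do and do not establish about real data.

## The synthetic locus

`locus.build_locus` produces one genomic segment with the structure that
makes founder-deletion breakpoint analysis interesting: two repeat copies of
`repeat_len` (default 120 bp) placed exactly `deletion_len` (default
5,200 bp) apart, differing at `n_divergent` (default 15) offsets and
identical over a `core_len` (default 23 bp) core.  The canonical deletion
runs from the first core position of copy A to the first core position of
copy B, so excising it fuses the copies into a single chimeric repeat and
both breakpoints sit inside the identical core.  Consequences, by
construction:

- the deleted sequence is identical for `core_len + 1` left-breakpoint
  placements (microhomology length = core length);
- whenever `n_divergent ≥ 2`, the offsets immediately flanking the core are
  forced to be divergent, so the homology run is *exactly* the core — without
  this the run could extend by chance and the planted homology length would
  only be a lower bound;
- four of the five exons lie inside the deletion, the fifth downstream.

The deletion length is fixed at exactly 5,200 bp (the emulated event is
"about 5.2 kb"; a fixed value keeps every test deterministic).  Flanks default
to 1,200 bp, giving a 7,720-bp reference — large enough that 150-bp reads
anchor uniquely, small enough that exact DP alignment of a full read set
takes seconds.

The package treats one locus (`locus.packaged_locus()`, the default geometry
at a fixed seed) as *the* locus, the way a real pipeline targets one genomic
region; cohort and read seeds remain free.

**Reads.** `simulate_reads` draws fragment starts uniformly, inserts
Normal(300, 30) clipped to [read_len, hap_len], mate 2 from the reverse
strand, substitution errors only at a uniform per-base rate, constant
quality.  Expected pairs = coverage × length / (2 × read_len).  No indels,
PCR duplicates, quality structure, or coverage bias — the error model exists
to exercise robustness of counting, not to imitate an instrument.

## Alignment and breakpoint calling

`align.align_read` computes the *exact* optimum over (a) affine-gap local
alignments (match +1, mismatch −2, gap open −4, extend −1) and, when long
deletions are allowed, (b) prefix+suffix splits with one reference gap of at
least 50 bp at a flat −6 penalty.  The implementation vectorizes the DP rows
(the within-row gap recurrence becomes a running maximum); an
exact-substring shortcut handles the error-free common case, and is exact
because a full-length gap-free match attains the maximum possible score.
Ties resolve to the leftmost reference placement, then the plus strand, then
the contiguous form.  The leftmost rule matters at the junction: a read
overhanging the breakpoint by a few bases can tie between "contiguous with
one or two mismatches" and "split across the deletion", and the split's
upstream prefix is the leftmost — and biologically correct — explanation.

A known residual of the flat −6 penalty: a read whose overhang past the
homologous core contains exactly one divergent position scores strictly
higher contiguously (150 − 3) than split (150 − 6).  On loci whose divergent
offsets sit sparsely around the core, enough such reads can stack to leave
one spurious column even under deletion-aware alignment; on the packaged
locus the divergences adjacent to the core are close enough that these reads
never reach the pileup depth threshold.

`genotype_deletion` counts junction-informative reads: *spanning* (split
placement normalizes to the locus deletion) versus *reference-junction*
(contiguous across a breakpoint window widened by the homology length plus a
10-bp margin, with no mismatches inside the window — reads ending inside the
homologous core are ambiguous and count for neither allele).  Genotype
banding on the spanning fraction: ≥ 0.85 `del/del`, ≤ 0.15 `ref/ref`,
otherwise `ref/del`; fewer than 8 informative reads is a no-call.  With
sequencing errors the mismatch-free window requirement removes some true
reference support, biasing the spanning fraction upward; the bands are wide
enough that genotypes at ≥30× are unaffected.

`resolve_microhomology` normalizes each spanning read's placement to the
leftmost equivalent coordinate, requires all reads to imply the same deleted
sequence, and reports the admissible-placement interval; its length minus
one is the homology length.  `pileup_variants` is a substitution-only pileup
over gap-free blocks (depth ≥ 8, alt fraction ≥ 0.25 — het-like signals
clear 0.25 easily at fraction ≈ 1 inside the deletion).  Artefact flagging
is the set difference unaware − aware, annotated against the planted
divergent positions mapped into both repeat copies.

## The cohort generator

One founder haplotype (alt allele at every tag site, carrying the deletion)
is dropped into an exchangeable background at frequency 0.00214, chosen so
heterozygous carriers arise at ≈ 0.0043 ≈ 1/234 of individuals and the tag
MAF ≈ 0.0021 — the regime of a strongly enriched founder allele in a
500k-person biobank.  Recombination erodes the founder block: over `G`
generations (default 20) each inter-site interval of `d` bp survives with
probability (1−r)^{G·d} (r = 10⁻⁸/bp/generation), and a site retains the
founder allele only if every interval between it and the deletion survived.
This produces monotone LD decay with distance at trivial cost; it is not a
coalescent and makes no attempt at real demographic history, relatedness, or
chip ascertainment.  The default site panel spans ~69 kb upstream with
background alt frequencies from 0.79 down to 0 — the two rare proxies exist
(by default) only on the founder haplotype; `with_off_background_proxy`
plants a low off-background rate to model an imperfect tag.

**Imputation noise.** Each haplotype allele flips independently with the
configured error rate; per-call confidence is GP ~ 1 − Beta(1, 99) (mean
0.99) for correct calls and Uniform(0.4, 0.9) for calls with any flipped
allele.  This reproduces the *qualitative* contract a GP confirmation rule
relies on — wrong calls sit visibly below right ones — not any panel's real
error structure.  Note the interaction with the strict GP > 0.99 rule: it
removes every wrong call but also ~37 % of correct ones (the Beta(1,99)
mass below 0.01); the rule is a confirmation step, not a recall-preserving
filter.

**Phenotypes.** Event times are exponential with individual hazard
λ·∏HRᵢ^{xᵢ} (λ = 0.002/person-year from age 40, administrative censoring
after 60 years ⇒ ~16 % events under the defaults), which is the simplest
generator consistent with proportional hazards — only HR recovery matters.
Default hazard ratios: carrier 2.14, APOE-proxy 2.30, sex 1.13; covariates
Bernoulli(0.3)/Bernoulli(0.5), independent of carrier status, matching the
design in which the carrier effect is APOE-independent.  Binary endpoints
come from a logistic model, baseline prevalence 0.05, odds ratios per
endpoint; the phenome-scan default is 50 endpoints with 2 causal at OR 2.1 —
a desk-scale stand-in for a thousands-of-endpoints registry scan.
Regions are multinomial; carriers can be placed with probability ∝ region
size × target regional MAF to generate regional-enrichment contrasts.

## Estimators

- **Firth logistic.** Newton iterations on the Jeffreys-penalized score
  U(β) = Xᵀ(y − p + h(½ − p)), h the hat diagonal of the weighted design,
  with step-halving on the penalized likelihood; SE from the Fisher
  information at the optimum, Wald intervals and p-values.  The
  `penalty_weight` knob (1 = Firth) exists to verify convergence to the MLE
  as the penalty vanishes.  The genome-wide line is annotated at 5×10⁻⁸; no
  multiplicity correction beyond reporting.
- **Cox.** Efron-ties partial likelihood, fully vectorized (suffix sums for
  risk sets, one expanded row per tied-event factor), Newton–Raphson with
  step-halving; convergence when the Newton step is below 10⁻¹⁰ or the
  gradient is flat at the likelihood's scale (tolerance 10⁻⁸, at most 50
  iterations); monotone likelihood (|β| drifting, exploding SE) is flagged
  `converged=False`, never raised.  SE from observed information; Wald
  intervals.  Age is the time scale, as in an age-at-first-diagnosis design.
- **Kaplan–Meier / logrank.** Plain product-limit with right censoring
  (steps at event times only) and the basic two-group logrank χ².
- **Case/control AF** is allele count over twice the class size; **derived
  carrier MAF** rounds half-away-from-zero to 4 decimals, matching how such
  tables are printed.  **Enrichment** rounds half-away-from-zero to 2
  decimals; a zero reference frequency with nonzero target yields an
  infinity sentinel, kept and sorted last in reports (absent-in-reference
  alleles are the strongest founder signals); 0/0 is 1.00 by convention.
- **HWE.** q = √prevalence; carriers 2q(1−q), or 2q when the conventional
  approximation is requested.  From prevalence 10⁻⁶…2×10⁻⁶ this gives
  carriers ≈ 1:500…1:354; a folk value of 1:300 is not reachable from HWE
  and is treated as an external estimate, not a target.

Proxy discovery defines the minor allele in the target population and
excludes sites with target MAF ≥ 0.5 from candidacy ("homozygous for the
minor allele" presumes rarity).  The MAF-match filter compares a candidate's
target MAF with carrier_frequency/2 at a default relative tolerance of 0.25
— a qualitative "matches the carrier frequency" judgment needs a number, and
25 % separates the ~0.003 proxies from common variants by two orders of
magnitude while absorbing sampling noise.

## Verification strategy, and what it shows

Every estimator is checked two ways: frozen hand-computable examples, and an
independent oracle — a naive exhaustive DP for the aligner, coarse-to-fine
grid maximization of the (penalized) likelihoods for Firth and Cox,
statsmodels/lifelines as external references, binomial/closed-form
expectations for the generators.  Closed-loop tests (generator → estimator)
confirm OR/HR recovery and null p-value calibration at biobank scale.
Passing these establishes internal correctness under the stated models; it
does not establish robustness to indel sequencing errors, realistic
imputation error structure, population stratification, relatedness, or
informative censoring — all deliberately outside the generators.

Problem sizes used by the default test run and the acceptance script were
chosen as the smallest at which the targeted behaviour is unambiguous: full
tiling coverage (2,371 reads) for the artefact analysis, 30× for genotyping,
N = 2×10⁵…5×10⁵ individuals and 10–20 seeds for recovery and calibration
checks.
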