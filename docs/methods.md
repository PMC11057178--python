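# Methods

## Assessment model

`priobench` assesses ranked causal-variant predictions against an answer key
of solved rare-disease probands. The unit of matching is the normalized
variant key (contig without `chr` prefix, 1-based position, uppercased
ref/alt, GRCh38). Variant identity is exact string identity after this
normalization: no indel left-alignment or allele minimalization is attempted,
because all parties in a challenge share one canonical VCF and silently
repairing representations would credit matches the assessment should not.
When an answer goes unmatched, predictions on the same contig within 10 bases
of a required variant are logged as near misses — representation drift is
surfaced for manual review, never auto-credited.

An answer-key entry carries one or two required variants and a match mode
generalizing two special cases rather than hard-coding proband identities:

* `ALL_OF` with two variants — a compound-heterozygous answer. Only a
  biallelic prediction whose unordered pair equals the required set matches.
  A correct allele with a wrong partner, or a single allele alone, earns
  nothing. Whether the original assessments credited single-allele hits at
  reduced weight is not knowable from published descriptions; strict mode is
  the default and `partial_credit=True` exposes the relaxed reading for
  exploration only.
* `ANY_OF` with two variants — a cis-pair equivalence group (two candidate
  variants on one haplotype, either possibly causal). A prediction of either
  member or of the full pair matches. Before metrics are computed, the
  best-ranked hit on the group is retained and all other hits are removed
  from the proband's list; surviving records keep their original ranks. The
  retained record is by construction the better-ranked one, so its band is
  unaffected by the renumbering question, and keeping original ranks leaves
  unrelated records' bands untouched.

Rank is the order of appearance in the submission file, not EPCR order:
submitters rank by causal likelihood and the file order is authoritative.
EPCR/rank disagreement is reported as a warning and never repaired, since
re-sorting would silently move records across scoring bands.

## Metrics

**Mean rank points** awards 100/50/25/10/5 points for a first correct
prediction at rank ≤5/≤10/≤20/≤50/≤100 and 0 for a miss, averaged over all
solved entries. The denominator is fixed at the number of solved entries
(probands a model skipped count as misses); this convention reproduces every
published score that is recomputable from published cumulative band counts,
which a floating denominator does not. The metric depends only on band
membership, which is what makes those scores exactly recomputable.

**F-max** sweeps the F-measure over every unique submitted EPCR value among
the solved-proband records. The recall denominator is solved entries, not
variants (a biallelic answer is one positive), and only solved-proband
records enter precision — predictions for unsolved probands are out of scope
for both numerator and denominator. F is piecewise constant between unique
EPCR values, so the sweep over unique values attains the global maximum; the
test suite checks this against a 10⁴-point dense-grid brute force. On ties
the largest tying threshold is reported: the published rule is unstated, and
the smallest call set is the conservative clinical choice. Mean and SD of
calls per proband at the threshold are over all solved probands, zero-call
probands included, SD with the n−1 denominator.

**Bootstrap SE** resamples solved probands with replacement (default
B = 1000), recomputing the statistic per replicate; F-max is re-swept on each
replicate over the union grid of unique EPCRs (every replicate's unique
values are a subset, and F's piecewise constancy makes the union grid
attain each replicate's maximum). For the mean, the bootstrap SE converges to
√(population variance / n); the suite checks the 13×100 + 1×0 vector against
its closed form 6.883 at B = 10⁵. Published SEs from the setting this
emulates can exceed that analytic limit slightly (e.g. a printed 7.3 against
a limit of ≈6.9 for the top configuration), consistent with an unstated
estimator variant (denominator or percentile flavor); this package documents
its estimator precisely rather than guessing at another's.

**Secondary summaries.** Detection counts per answer-key entry count models
(not probands) in the same cumulative bands. Concordance between two models
is the mean, over probands where at least one submitted, of the Jaccard index
of their top-k (default 5) variant-set collections; the formula is a design
choice (published assessments do not state one) and is isolated in a single
function so overlap-coefficient or pooled variants can be swapped in. The
stratified comparison computes mean rank points separately over
incomplete-data families (proband-only + duo) and complete ones (trio +
quad), and the per-model pairs feed a two-sided paired Student's t-test
(scipy's `ttest_rel`; degenerate all-zero differences → t = 0, p = 1;
zero-variance nonzero differences → ±∞ with p = 0).

**Model ranking** in reports is by competition ranking (tied values share a
rank; the next distinct value's rank counts the tied block), which is the
tie behavior visible in published metric tables; NA F-max rows rank after
every numeric value. Report rows are ordered by descending mean rank points,
ties broken by descending F-max.

## Submission cleaning

Parsing is never fatal except for an unreadable file; malformed lines
(wrong field count, unparsable variant, EPCR outside [0, 1] or non-numeric,
self-paired biallelic) are dropped with per-line diagnostics. Cleaning
removes within-proband duplicate variant sets (keeping the better-ranked
copy), truncates at 100 predictions per proband, and renumbers ranks
consecutively; it is idempotent and order-preserving. "Incomplete" records
are operationalized as: missing field, unparsable variant, missing EPCR.

## Synthetic challenge generator

The generator emulates the structure of a 30-family benchmark cohort —
defaults: 14 solved / 16 unsolved, completeness mix 2 proband-only / 3 duos /
23 trios / 2 quads, inheritance quotas 9 de novo, 2 recessive homozygous,
1 recessive compound het, 1 X-linked recessive, 1 sex-limited dominant (the
cis-pair equivalence entry rides on the latter). Quotas are apportioned by
largest remainder and shuffled, so composition is exact and assignment is
random. Decoy variants (pool 10⁴, disjoint from causal variants) are
uniform over contigs 1–22 + X with positions in [1, 2.5×10⁸] and random SNV
alleles; allele-frequency spectra, gene context and genotype data are
deliberately absent because no assessment metric consumes them. HPO terms
come from a small fixed vocabulary and are carried but unused by metrics —
phenotype matching is the predictors' job, not the assessor's.

A model's skill is (i) a probability vector over the outcome bands
(rank 1–5, 6–10, 11–20, 21–50, 51–100, miss) and (ii) Beta laws for causal
and decoy EPCRs. Per solved proband a band is drawn, the causal record (the
full pair for ALL_OF answers, one random member for ANY_OF) is placed
uniformly within the band among decoys, and the pooled EPCR draws are sorted
non-increasing so file order, rank and EPCR agree (a `miscalibrated` flag
skips the sort to exercise the warning path). The analytic expected mean rank
points is the dot product of the band probabilities with
(100, 50, 25, 10, 5, 0), which makes generated challenges an oracle for
metric recovery.

**What passing the recovery tests shows and does not show.** Recovery of the
expected score and of a skill ordering on synthetic data validates the
plumbing — matching, band accounting, denominators, seeding — under the
generator's assumptions (iid band draws per proband, decoys never matching,
clean submissions). It says nothing about performance on real submissions,
where variant-representation drift, shared decoys between models, and
manual curation come into play.

**Skill ladder for the recovery experiment.** The ten graded profiles have
expected scores 100, 75, 50, 37.5, 25, 17.5, 10, 7.5, 5, 0: the six
single-band profiles (zero band-membership variance) plus four 50/50 mixtures
of adjacent bands. The ladder was designed so that every adjacent pair's
expected-score gap is at least ≈2.5× the combined Monte-Carlo SD at
n = 14 solved probands (the worst pair, 100 vs 75, has gap 25 against an SD
of √(625/14) ≈ 6.7), making strict full-order recovery the overwhelmingly
likely outcome per replicate by construction rather than by tuning.

## Numerical and interface choices

* All randomness flows from one top-level seed through `numpy` seed
  sequences; reruns with the same seed and inputs are byte-identical.
* Reports round rank points to one decimal and F-max quantities to two, the
  conventional display precision; full precision is retained internally and
  in the JSON bundle.
* The proband in a PED family is the first affected individual (file order)
  who is not a parent of another member; further affected non-parents must
  share a listed parent with the proband (siblings) or the family is rejected
  as ambiguous. Standard 6-column PED has no proband flag, and quads
  legitimately contain two affected members, so a convention is required.
* Completeness: quad = both parents + ≥1 sibling, trio = both parents,
  duo = one parent, otherwise proband-only (a sibling without parental data
  does not upgrade the class, since phasing needs parental genotypes).
* Answer-key and submission dialects (tab-separated, documented in the module
  docstrings) are this package's own: the corresponding files of real
  challenges are not published, so the dialect is declared, not recovered.

## Problem sizes

The recovery experiment uses 100 replicates of a 30-family cohort with ten
models of 100 predictions per proband (~3×10⁶ records per run), and the
bootstrap convergence check uses 10⁵ replicates on the vectorized path; both
were sized to give comfortable statistical resolution (Monte-Carlo SE ≈ 0.7
points per model; bootstrap estimator noise ≪ 0.1) while completing in tens
of seconds on one CPU.

## Known limitations

* Published F-max values, their SEs, the concordance distribution, and the
  stratified t-test p-value of any real benchmark require the unpublished
  submission EPCRs and are not reproduction targets; the property-based
  checks above stand in for them.
* Variant matching is deliberately exact; cross-representation equivalence
  (left-alignment, MNV decomposition) is out of scope.
* The generator does not simulate reads, genotype likelihoods, annotation, or
  any specific participant method.
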