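# priobench

Assessment toolkit for rank-based benchmarking of rare-disease
variant-prioritization models.

## The problem

In community benchmarks of genome interpretation, prediction teams are given
variant calls and HPO phenotype terms for a cohort of rare-disease families
and asked to rank candidate causal variants for each proband — up to 100
predictions per proband, each a single variant or a proposed
compound-heterozygous pair, each carrying an *estimated probability of causal
relationship* (EPCR) in [0, 1]. An independent assessor then scores every
model against an answer key of causal variants established for the solved
families. `priobench` implements that assessor: submission parsing and
cleaning, answer-key matching with the special biallelic and cis-pair rules,
the two headline metrics with bootstrapped standard errors, and the secondary
summaries (detection counts, top-k concordance, stratification by familial
completeness). A synthetic challenge generator exercises the entire pipeline,
since real benchmark cohorts are typically under controlled access.

## Metrics

For a cohort with `n` solved probands (answer-key entries):

**Mean rank points.** Let `r_i` be the rank of the first correct prediction
for entry `i` (∞ if missed). With the band schedule
`w(r) = 100·1[r≤5] + 50·1[5<r≤10] + 25·1[10<r≤20] + 10·1[20<r≤50] + 5·1[50<r≤100]`,

    MRP = (1/n) Σᵢ w(rᵢ)

The denominator is always `n`; skipped probands count as misses.

**F-max.** For threshold `t`, the call set is every solved-proband record with
EPCR ≥ t; `TP(t)` counts entries whose matching record is called (at most one
per entry), `P(t) = TP/|calls|`, `R(t) = TP/n`, and

    F-max = max over unique submitted EPCR values t of  2·P(t)·R(t) / (P(t)+R(t))

Ties are broken toward the largest threshold (the smallest call set). The
reported companion quantities are the attaining threshold and the mean ± SD
number of calls per proband at that threshold.

**Bootstrap SE.** Both metrics get a standard error from `B = 1000`
resamples of the solved probands with replacement, recomputing the statistic
(F-max is re-swept) on each replicate.

**Matching rules.** A correct causal variant paired with a non-causal partner
in a biallelic prediction is incorrect; a single allele of a
compound-heterozygous answer earns no credit (a `partial_credit` switch
relaxes this for exploration). For a cis-pair equivalence answer, either
member counts, and only the model's best-ranked hit on the group is retained
— other hits are removed before any metric is computed.

## Worked example

```python
import priobench as pb

ch = pb.generate_challenge(pb.ChallengeConfig(seed=11))   # 14 solved / 16 unsolved
good = pb.generate_model_submission(
    ch, pb.SkillProfile(band_probs=(0.7, 0.2, 0.1, 0, 0, 0)), seed=1,
    team_id="good", model_id="model1")

outcomes = pb.score_model(good, ch.answer_key)
mrp = pb.mean_rank_points(outcomes)
se = pb.bootstrap_se_mean_rank_points(outcomes, B=1000, seed=0)
f = pb.fmax_sweep(good, ch.answer_key)
fse = pb.bootstrap_se_fmax(good, ch.answer_key, B=1000, seed=0)
print(f"{good.name}: bands={pb.rank_band_counts(outcomes)} "
      f"mean_rank_points={mrp:.1f}±{se:.1f} "
      f"F-max={f.fmax:.2f}±{fse:.2f} @ EPCR≥{f.threshold:.2f} "
      f"({f.mean_calls_per_proband:.2f}±{f.sd_calls_per_proband:.2f} calls/proband)")
```

prints

```
good/model1: bands=(4, 12, 14, 14, 14, 14) mean_rank_points=92.9±4.6 F-max=0.31±0.10 @ EPCR≥0.78 (0.86±0.66 calls/proband)
```

Reading: the model placed the causal variant(s) at rank 1 for 4 of the 14
solved probands, inside the top five for 12, and found all 14 within the top
ten, for a mean of 92.9 rank points (bootstrap SE 4.6). Thresholding its EPCR
values at 0.78 maximizes the F-measure at 0.31 with 0.86 calls per proband on
average — the decoy records outnumber causal ones at any threshold, so F-max
is far below 1 even for a model that ranks well.

The same pipeline is available from the shell:

```bash
priobench simulate --config challenge.yaml --out challenge/
priobench validate --sub challenge/submissions/good.tsv
priobench assess --key challenge/answer_key.tsv --ped challenge/families.ped \
                 --hpo challenge/hpo.tsv --subs challenge/submissions --out report/
```

`assess` writes a model-per-row metric table, per-entry detection counts
across models, the pairwise top-5 concordance matrix, the stratified
incomplete-vs-complete family comparison with a paired t-test, and a JSON
bundle of full F curves.

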