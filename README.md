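# claimscc

Case–control analysis of longitudinal insurance-claims data, built as a
reusable, tested pipeline:

1. **Claims model** (`claimscc.claims`) — readers/writers for the
   three-table claims layout (yearly qualification table, claim
   statements with principal/additional diagnoses, disease-detail
   table), diagnosis-code truncation, and configurable code-prefix sets.
2. **Episode builder** (`claimscc.episodes`) — groups delivery-coded
   visits into delivery events (24-week separation), pairs each with
   its earliest pregnancy diagnosis (44-week maximum gestation, 4-week
   postpartum bound), assigns delivery mode with cesarean priority,
   applies abortion/stillbirth and qualification-completeness
   exclusions, and tallies every exclusion in a conserved ledger.
3. **Exposure windows** (`claimscc.exposures`) — per-case 3-character
   diagnosis profiles for the antenatal window (study A) and the
   pre-conception year (study B), eligibility filtering, and per-code
   2×2 tables.
4. **Exact statistics** (`claimscc.exact`) — two-sided Fisher exact test
   reporting the conditional-MLE odds ratio and exact CI (replicating
   R `fisher.test`'s solver conventions bit-for-bit, sparse tables
   included), a seeded Monte-Carlo exact test for r×c tables, Welch's
   t-test from summaries, and the Cochran–Armitage trend test.
5. **Matching** (`claimscc.matching`) — logistic propensity scores on
   age band + income group, greedy 1:10 nearest-neighbor matching
   without replacement with shuffled-order tie-breaking, repeated
   re-matching (1,000× by default), and stability classification
   (risk/protective when significant in >90% of repetitions with a
   consistent mean OR).
6. **Adjusted models** (`claimscc.conditional`) — stratified conditional
   logistic regression (Newton on the conditional likelihood) adjusted
   for preterm delivery, delivery mode, multiple gestation, and
   antenatal duration, averaged over significant repetitions.
7. **Synthetic claims** (`claimscc.simulate`) — a generator emitting the
   full relational layout with planted episodes, known true odds
   ratios, covariate confounding, and injectable exclusions, so every
   stage is testable without any real data.
8. **Reports/CLI** (`claimscc.report`, `claimscc.cli`) — end-to-end
   orchestration producing demographics, unmatched OR tables, stability
   and adjusted tables, the exclusion ledger, and a factor-network edge
   list; fully reproducible from a single master seed.

## CLI

```bash
# generate a synthetic cohort (three TSV tables + ground-truth TSV)
claimscc simulate --seed 1 --out-dir data/ --n-women 5000

# construct delivery cases and the exclusion ledger
claimscc build-cases --qualification data/qualification.tsv \
    --statement data/statement.tsv --disease data/disease.tsv \
    --out-dir cases/

# full analysis (studies A and B, 1:10 matching, 1000 repetitions)
claimscc analyze --qualification data/qualification.tsv \
    --statement data/statement.tsv --disease data/disease.tsv \
    --study both --n-reps 1000 --seed 7 --out-dir report/

# rebuild the factor network from a stability table
claimscc report --stability A report/stability_A.tsv --out network.tsv
```

Code sets and generator parameters are YAML-configurable
(`--code-config`, `claimscc simulate --config`); see
`claimscc.claims.CodeSets` and `claimscc.simulate.SimConfig` for the
documented defaults.

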