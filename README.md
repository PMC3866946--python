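# endoscore

Endometriosis surgical scoring and diagnostic-accuracy analysis for IVF
outcome prediction.

The package implements, as a tested and reusable pipeline:

- **r-AFS scoring** (`endoscore.afs`) — revised AFS (1985) point scores
  for implants (site x depth x size), cul-de-sac obliteration and
  adnexal adhesions, mapped to stages I–IV. The point values live in
  literal, reviewable lookup tables.
- **EFI** (`endoscore.efi`) — the 0–10 Endometriosis Fertility Index
  from historical factors (age, infertility duration, prior pregnancy)
  and surgical factors (least-function score with the absent-ovary
  doubling rule, r-AFS lesion and total score bands).
- **ROC analysis** (`endoscore.roc`) — empirical ROC curves for integer
  prognostic indices, Mann–Whitney AUC, Hanley–McNeil or bootstrap SE,
  Wald 95% CI with a normal test against 0.5, and the Youden-optimal
  cut-off.
- **Two-group comparison battery** (`endoscore.stats`) — uncorrected
  Pearson chi-square for rates, pooled t for normal variables,
  tie-corrected Mann–Whitney z for non-normal ones, and a formatted
  per-variable comparison report with recomputed percentages.
- **Paired diagnostic sample size** (`endoscore.samplesize`) — the
  McNemar-type paired-proportions formula driven by a pilot 2x2 table.
- **Synthetic cohorts** (`endoscore.simulate`) — deterministic,
  seed-driven generation of clinical history, surgical findings,
  function ratings and IVF cycle outcomes, with the pregnancy model
  `logit P = b0 + b1*EFI` calibrated to target group rates, so the
  whole pipeline is testable without patient data.

## CLI

The console script `endoscore` exposes
`simulate | score | roc | compare | samplesize | report`
(exit codes: 0 ok, 1 validation error, 2 runtime error):

```bash
# generate a 199-patient cohort (optionally: --config examples/default_cohort.yaml)
endoscore simulate --n 199 --seed 1 --out cohort/

# per-patient r-AFS + EFI scores
endoscore score --clinical cohort/clinical.csv --surgical cohort/surgical.csv \
    --ratings cohort/ratings.csv --out scores.csv

# ROC/AUC with Youden cut-off for one index
endoscore roc --scores index_outcome.csv --se-method hanley --out roc.json

# comparison battery between EFI (or r-AFS stage) groups
endoscore compare --cohort merged.csv --by efi --cutoff 6 --out comparison.csv

# paired-design sample size from a pilot 2x2
endoscore samplesize --a 44 --b 47 --c 23 --d 47 --alpha 0.05 --power 0.90

# end-to-end: simulate, score, ROC for both indices, comparison tables
endoscore report --out report/ --seed 1 --n 199
```

## Conventions worth knowing

- The EFI "lesion score" includes cul-de-sac points by default; switch
  with `lesion_score_includes_culdesac=False` (the source form does not
  pin the convention down).
- Cut-off semantics: "cut-off = 6" classifies `index >= 6` as positive.
- Both indices are analysed with the same higher-index-predicts-positive
  direction; an uninformative index can therefore show AUC < 0.5.
- Band edges are inclusive toward the higher-scoring band (age 35.0 and
  3.0 infertile years score the higher band).
- Percentages in all outputs are derived from counts, never read from
  inputs.
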