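# bifluent

Condition-aware scoring and statistics for bilingual verbal-fluency
transcripts: per-response correctness under single-language, self-switch,
and forced-switch task rules (with one-phoneme tolerance), semantic and
phonemic cluster/switch metrics, fluency difference scores, and the
downstream statistical battery (mixed repeated-measures ANOVA, planned
contrasts with Benjamini-Hochberg correction, varimax PCA with
regression-method factor scores, backward stepwise regression).

A synthetic cohort generator produces participants, questionnaire metrics
(planted latent-factor structure), assessment scores, and raw transcripts
with the statistical structure the pipeline expects, so everything is
testable end to end without participant data.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including a
~2-minute Monte-Carlo recovery suite over 200 simulated cohorts.

## CLI

```sh
# 1. simulate a cohort with the packaged calibrated spec
bifluent simulate --seed 1 --out sim/

# 2. score the transcripts (packaged English/Spanish lexicon by default)
bifluent score --transcripts sim/transcripts.tsv \
               --participants sim/participants.tsv --out scored/

# 3. run the statistical battery from a declarative plan
bifluent analyze --table scored/analysis_table.csv \
                 --participants sim/participants.tsv \
                 --plan src/bifluent/data/analysis_default.yaml --out stats/
```

Input formats (all TSV, UTF-8):

- transcripts: `participant_id group task condition target administration
  position token produced_language [phonemes]`, one produced token per row;
  conditions are `NS-L1 NS-L2 SS FS` (category task) and `LF-L1 LF-L2`
  (letter task);
- lexicon: `form language concept_id category subcategories phonemes` with
  `#phonemes:` / `#vowels:` header lines declaring the phoneme inventory;
  subcategory tags are data, so users can substitute their own taxonomy.

## Layout

- `src/bifluent/lexicon.py` — bilingual lexicon, phoneme inventory, lookup
- `src/bifluent/scoring.py` — response correctness and condition rules
- `src/bifluent/clusters.py` — cluster partitioning and switch counting
- `src/bifluent/fluency.py` — fluency difference scores, analysis table
- `src/bifluent/cohort.py` — synthetic cohort generator
- `src/bifluent/stats.py` — ANOVA / contrasts / PCA / stepwise regression
- `src/bifluent/plans.py`, `cli.py`, `pipeline.py` — plan runner and glue
- `src/bifluent/data/` — packaged lexicon, calibrated cohort spec,
  default analysis plan
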