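# morphrep

Component-based construction and analysis of gestural repertoires from coded
behavioural event tables. Gesture use is recorded as *tokens* (one row per
instance of a gesture action, with four categorical modifiers: body part,
contact with recipient, lateral use, repetition). The pipeline builds the
action-level repertoire and its frequency statistics, then detects
finer-grained units ("morphs") inside each action by fitting multinomial
latent-class mixtures to the modifier vectors, and reports individual
repertoire sizes and gesturing rates, behavioural-context distributions, and
inter-rater agreement.

## What it does

- **`morphrep.io`** — read/validate/write the three input tables (tokens,
  individuals, observation effort; UTF-8 CSV with fixed column order) and
  cross-referential dataset validation.
- **`morphrep.synthetic`** — seeded generators of datasets with planted
  latent structure (per-action mixtures of modifier configurations, optional
  per-modifier noise, unclear-level injection, planted accumulation-curve
  asymptote), plus a second-rater simulator driven by confusion matrices.
  `reference_profile()` is a fully calibrated configuration reproducing the
  filter-cascade and summary structure of the study this pipeline mirrors.
- **`morphrep.repertoire`** — repertoire threshold (default: at least 3
  observations per action), per-action contribution table (counts, rounded
  percentages, cumulative percentages, deviation from the uniform-use
  expectation), regular-use prefix (~70% of tokens), accumulation curves
  with optional permutation (rarefaction) envelopes, overall tokens/hour.
- **`morphrep.lca`** — morph detection: per-action EM fits of k-class
  multinomial mixtures over the modifier levels (distinct-vector
  compression, deterministic + random restarts), BIC model selection (ties
  to smaller k), hard assignment with a minimum of 5 observations per morph,
  morph naming `<Action>.<i>_<K>`, and the
  unimorphic / polymorphic / unspecified partition of the repertoire.
- **`morphrep.individuals`** — IRS_1/IRS_3 repertoire sizes, IGR_obs/IGR_vid
  gesturing rates (undefined, never zero, on empty denominators), four
  age/sex/parity maturation classes with the majority-token rule for
  within-season boundary crossings, and per class-by-sex summaries.
- **`morphrep.contexts`** — communication-level signaller-context
  distribution with pooling of contexts below 1% into "Other".
- **`morphrep.reliability`** — proportional (largest-remainder) subsampling
  and percentage agreement / unweighted Cohen's kappa per coded variable.
- **`morphrep.pipeline`** — orchestration of all stages into one report
  bundle (JSON summary + CSV tables).

## CLI

```sh
# generate a synthetic dataset (tokens/individuals/effort/truth CSVs)
morphrep simulate --out data/ --seed 1

# run the full analysis and write the report bundle
morphrep run --tokens data/tokens.csv --individuals data/individuals.csv \
             --effort data/effort.csv --out report/ --seed 1
```

Thresholds can be overridden with `--min-tokens`, `--action-min`,
`--morph-min`, `--k-max`, `--restarts`, `--regular-use-target`,
`--permutations`, or a YAML config via `--config`.

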