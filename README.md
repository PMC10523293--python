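# housinglens

Multi-source identification of housing instability in EHR-shaped data.

Housing instability is documented inconsistently in electronic health
records: sometimes as a billing code, sometimes as a shelter address in the
demographics table, and often only in free-text clinical notes.  This
package detects evidence of housing instability from all three channels,
fuses it per patient, and reports how much each source contributes:

- **`codes`** — ICD-10-CM prefix matching: SUD cohort assignment
  (stimulant / opioid / both), poisoning episodes (T40\*, T43.6\*), and
  Z59\* housing-evidence flags.
- **`addresses`** — address normalization (USPS-style suffix abbreviation,
  unit stripping), exact + fuzzy matching against a curated
  community-resource directory, literal-"homeless" address lines, and
  generic-address flagging (counted, never treated as evidence).
- **`notes`** — lexicon keyword matching with window-based negation /
  history / third-party qualification, and shelter-by-name matching.
- **`linker`** — deterministic dictionary NER over a concept vocabulary
  with a normalized-exact knowledgebase linker (spans that cannot be coded
  are counted as `recognized_unlinked`); an adapter seam accepts an
  external recognizer.
- **`fusion`** — per-patient source sets, 7-region Venn partitioning,
  coverage percentages (1 d.p., round-half-up), and census-tract
  codes-only vs all-sources comparison.
- **`stats`** — Fleiss' Kappa, chi-squared with adjusted standardized
  residuals, exact RxC Fisher tests (enumeration with a seeded Monte-Carlo
  fallback), and the stratified adjudication sampler.
- **`synthetic`** — a seeded synthetic EHR generator with planted ground
  truth (per-source documentation sensitivities, negated / historical /
  third-party mention templates, shelter addresses, generic addresses), so
  the whole pipeline is testable without real data.
- **`pipeline` / `cli`** — end-to-end orchestration and the report bundle.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes per-module unit tests, property tests for the fusion and
statistics invariants, and `tests/test_acceptance.py`, which checks the
reporting arithmetic against published-count fixtures, runs the 20-seed
planted-parameter recovery, and exercises the vignette sentences.

## CLI

```sh
housinglens generate --n-patients 500 --seed 1 --out data/
housinglens detect   --data data/ --out det/
housinglens fuse     --flags det/flags.csv --patients data/patients.csv --out fus/
housinglens stats    --mentions det/mentions.csv --notes data/notes.jsonl --out adj/
housinglens report   --mode synthetic --n-patients 500 --seed 1 --out bundle/
```

`report` (alias `all`) writes the full bundle: demographics and
evidence-by-source tables, note-method contributions, Venn counts,
tract deltas, concordance outputs, and — in synthetic mode — per-channel
precision/recall against the planted truth.  Every artifact carries the
config hash and seed; identical config + seed reproduces byte-identical
bundles.

Channel behavior is configurable per run (`--no-fuzzy`, `--no-historical`,
`--third-party`, `--no-residential-treatment`, `--no-ner`), or via a YAML
`RunConfig` passed with `--config`.

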