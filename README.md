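# protscreen

A tested, reusable pipeline for isobaric-label (TMT-style) proteomics
discovery analysis and its downstream decision steps:

1. **simulate** — synthetic peptide-level reporter-intensity experiments with a
   known ground truth (spiked differential proteins, peptide-level noise,
   missing values), targeted re-measurement of a protein panel, and
   right-censored survival cohorts whose hazard switches at a known marker
   threshold.
2. **quant** — peptide centering (each peptide divided by its cross-sample
   mean) followed by per-sample median rollup to protein relative values,
   plus the MS2 spectra-utilization summary.
3. **screen** — per-protein fold change (ratio of group means), a two-sided
   Welch t-test on log2 values (rank-sum optional), and the joint
   fold-change/significance up/down/ns call (fc > 1.3 and p ≤ 0.05 by
   default; down at fc < 1/1.3).
4. **select** — recursive feature elimination with a linear-margin (SVM)
   ranker and a random-forest ranker, plus an intersection/union consensus
   rule.
5. **concord** — direction agreement and Spearman rank correlation between
   discovery and targeted-validation fold changes for a protein panel.
6. **cutpoint** — best-cutoff survival dichotomization: a vectorized log-rank
   scan over candidate marker cutpoints, Kaplan–Meier estimates, and a
   permutation-corrected p-value for the selection-biased maximal statistic.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end criteria (formula oracle
equivalence, screening recovery and null calibration, RFE spike-in recovery
at the 123 → 29 scale, cutpoint parameter recovery and permutation-p
calibration, small-instance log-rank exactness).

## CLI

All verbs are available under one entry point:

```bash
protscreen simulate tmt --n-proteins 1000 --seed 1 --out-dir run/
protscreen quant --in run/peptides.tsv --groups run/groups.tsv --out run/proteins.tsv
protscreen screen --in run/proteins.tsv --groups run/groups.tsv --out run/diff.tsv
protscreen select --in run/proteins.tsv --groups run/groups.tsv \
    --features run/up.txt --target 29 --seed 7 --out run/selection.txt
protscreen concord --discovery run/diff.tsv --validation run/diff_prm.tsv \
    --panel run/panel.txt --out run/concord.tsv
protscreen simulate survival --n-patients 400 --seed 1 --out-dir run/
protscreen cutpoint --in run/cohort.tsv --permutations 1000 --seed 7 --out run/cut.tsv
protscreen run-all --seed 1 --out-dir run/        # full synthetic chain
protscreen spectra 83412 363519                   # utilization percentage
```

`run-all` executes simulate → quant → screen → select → concord, writes every
intermediate TSV plus `manifest.json`, and is byte-identical under the same
config and seed. A commented configuration template is in
[`config.example.yaml`](config.example.yaml); pass it with
`protscreen run-all --config my.yaml`.

### File schemas (tab-separated, absent cells empty)

| file | columns |
| --- | --- |
| peptides.tsv | `protein_id`, `peptide_id`, one column per sample |
| groups.tsv | `sample_id`, `group` |
| proteins.tsv | `protein_id`, `n_peptides`, one column per sample |
| diff.tsv | `protein_id`, `fc`, `log2fc`, `p_value`, `neg_log10_p`, `call` |
| cohort.tsv | `patient_id`, `time`, `event`, `marker` |
| ledger.tsv | `protein_id`, `true_direction`, `true_fc` |

## Notes

- The naive p-value reported by `best_cutpoint` is anti-conservative because
  the cutoff is chosen to maximize the statistic; `corrected_cutpoint_p`
  provides a permutation-calibrated alternative and the CLI reports both.
- With 3-vs-3 designs, cross-validated selection of the RFE subset size is
  unstable, so `target_size` is an explicit required parameter.
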