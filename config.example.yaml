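# protscreen run-all configuration template.
# Every key is optional; defaults shown. Unknown keys are rejected.

schema_version: 1
out_dir: protscreen_run   # all stage outputs and manifest.json land here
seed: 0                   # master seed for simulation and the forest ranker

# --- simulation ------------------------------------------------------------
n_proteins: 1000
frac_up: 0.1              # fraction of proteins spiked up in the treated group
frac_down: 0.05           # fraction spiked down
effect_fc: 2.0            # true fold change of spiked proteins (> 1)
peptides_per_protein_mean: 3.0
n_per_group: 3            # samples per group (control / treated)
peptide_cv: 0.1           # coefficient of variation of peptide-level noise
missing_rate: 0.0         # fraction of cells set absent at random

# --- quantification / screening ---------------------------------------------
min_peptides: 1           # proteins with fewer peptides are dropped
fc_threshold: 1.3         # up if fc > threshold, down if fc < 1/threshold
alpha: 0.05               # significance level (p <= alpha, inclusive)
test: welch_t_log2        # or: wilcoxon

# --- feature selection --------------------------------------------------------
target_size: 29           # RFE stops at exactly this many features
rfe_step: 1               # features dropped per elimination round
consensus_mode: intersection  # or: union
n_trees: 200              # random-forest size for the forest ranker

# --- targeted validation -----------------------------------------------------
panel_size: 17            # head of the consensus shortlist re-measured
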