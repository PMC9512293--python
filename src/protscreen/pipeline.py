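"""One-command pipeline runner: simulate -> quant -> screen -> select -> concord.

Configuration is a flat YAML mapping validated against the known keys
(unknown keys are rejected; every default, including seeds, is
materialized on load so a saved config reproduces the run exactly).
Every stage writes its TSV outputs under ``out_dir`` and the run ends
with an atomically written JSON manifest of paths, parameters, row
counts and warnings.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .concordance import concordance
from .errors import ConfigError, ProtscreenError
from .features import (
    make_forest_ranker,
    consensus_select,
    rank_features_linear_margin,
    recursive_eliminate,
)
from .quant import quantify
from .screen import ScreenConfig, screen, summarize_calls
from .simulate import (
    GROUP_CONTROL,
    GROUP_TREATED,
    TmtSimConfig,
    simulate_prm_panel,
    simulate_tmt_experiment,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Flat parameter set for a full synthetic run."""

    schema_version: int = SCHEMA_VERSION
    out_dir: str = "protscreen_run"
    seed: int = 0
    # simulation
    n_proteins: int = 1000
    frac_up: float = 0.1
    frac_down: float = 0.05
    effect_fc: float = 2.0
    peptides_per_protein_mean: float = 3.0
    n_per_group: int = 3
    peptide_cv: float = 0.1
    missing_rate: float = 0.0
    # quant / screen
    min_peptides: int = 1
    fc_threshold: float = 1.3
    alpha: float = 0.05
    test: str = "welch_t_log2"
    # feature selection
    target_size: int = 29
    rfe_step: int = 1
    consensus_mode: str = "intersection"
    n_trees: int = 200
    # validation
    panel_size: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, str], counts: dict[str, int]) -> None:
        self.stages[stage] = {"outputs": outputs, "counts": counts}

    def write(self, path) -> None:
        tmp = str(path) + ".tmp"
        Path(tmp).write_text(json.dumps(
            {"config": self.config, "stages": self.stages, "warnings": self.warnings},
            indent=2,
        ))
        os.replace(tmp, path)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full synthetic chain; idempotent under identical config."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    counter = _WarningCounter()
    logging.getLogger("protscreen").addHandler(counter)
    try:
        _run_stages(config, out, manifest)
    except ProtscreenError:
        raise
    finally:
        manifest.warnings = counter.messages
        logging.getLogger("protscreen").removeHandler(counter)
        manifest.write(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest) -> None:
    sim_cfg = TmtSimConfig(
        n_proteins=config.n_proteins,
        frac_up=config.frac_up,
        frac_down=config.frac_down,
        effect_fc=config.effect_fc,
        peptides_per_protein_mean=config.peptides_per_protein_mean,
        n_per_group=config.n_per_group,
        peptide_cv=config.peptide_cv,
        missing_rate=config.missing_rate,
        seed=config.seed,
    )

    # --- simulate ---------------------------------------------------------
    table, ledger = simulate_tmt_experiment(sim_cfg)
    pio.write_peptide_table(table, out / "peptides.tsv")
    pio.write_groups(table.groups, out / "groups.tsv")
    pio.write_ledger(ledger, out / "ledger.tsv")
    config.to_yaml(out / "config.yaml")
    manifest.record(
        "simulate",
        {k: str(out / f"{k}.tsv") for k in ("peptides", "groups", "ledger")},
        {"n_peptides": table.n_peptides, "n_proteins": len(ledger)},
    )

    # --- quant ------------------------------------------------------------
    proteins = quantify(table, min_peptides=config.min_peptides)
    pio.write_protein_table(proteins, out / "proteins.tsv")
    manifest.record(
        "quant", {"proteins": str(out / "proteins.tsv")}, {"n_proteins": len(proteins.values)}
    )

    # --- screen -----------------------------------------------------------
    screen_cfg = ScreenConfig(
        fc_threshold=config.fc_threshold, alpha=config.alpha, test=config.test
    )
    diff = screen(proteins, GROUP_TREATED, GROUP_CONTROL, screen_cfg)
    pio.write_diff_table(diff, out / "diff.tsv")
    manifest.record("screen", {"diff": str(out / "diff.tsv")}, summarize_calls(diff))

    # --- select (on the screened up-set) ----------------------------------
    up_set = diff.index[diff["call"] == "up"].tolist()
    if config.target_size > len(up_set):
        raise ConfigError(
            f"feature_select: target_size {config.target_size} exceeds the "
            f"{len(up_set)}-protein up-set"
        )
    matrix = np.log2(proteins.values.loc[up_set].to_numpy(float)).T
    if np.isnan(matrix).any():
        col_mean = np.nanmean(matrix, axis=0)
        matrix = np.where(np.isnan(matrix), col_mean[None, :], matrix)
    labels = np.array(
        [proteins.groups[s] == GROUP_TREATED for s in proteins.samples], dtype=int
    )
    svm_res = recursive_eliminate(
        rank_features_linear_margin, matrix, labels, up_set,
        target_size=config.target_size, step=config.rfe_step, method="svm_rfe",
    )
    forest_res = recursive_eliminate(
        make_forest_ranker(n_trees=config.n_trees, seed=config.seed),
        matrix, labels, up_set,
        target_size=config.target_size, step=config.rfe_step, method="forest_rfe",
    )
    shortlist = consensus_select(svm_res, forest_res, mode=config.consensus_mode)
    pio.write_feature_list(svm_res.selected, out / "selected_svm.txt")
    pio.write_feature_list(forest_res.selected, out / "selected_forest.txt")
    pio.write_feature_list(shortlist, out / "selected_consensus.txt")
    manifest.record(
        "select",
        {m: str(out / f"selected_{m}.txt") for m in ("svm", "forest", "consensus")},
        {"n_up_in": len(up_set), "n_consensus": len(shortlist)},
    )

    # --- concord (targeted re-measurement of the shortlist head) ----------
    panel = (shortlist or up_set)[: config.panel_size]
    prm_table = simulate_prm_panel(ledger, panel, sim_cfg)
    prm_proteins = quantify(prm_table, min_peptides=config.min_peptides)
    prm_diff = screen(prm_proteins, GROUP_TREATED, GROUP_CONTROL, screen_cfg)
    pio.write_diff_table(prm_diff, out / "diff_prm.tsv")
    report = concordance(diff, prm_diff, panel, alpha=config.alpha)
    report.per_protein.to_csv(out / "concordance.tsv", sep="\t")
    manifest.record(
        "concord",
        {"diff_prm": str(out / "diff_prm.tsv"), "concordance": str(out / "concordance.tsv")},
        {
            "panel_size": report.panel_size,
            "n_validated_significant": report.n_validated_significant,
            "sign_agreement_pct": int(round(100 * report.sign_agreement_rate)),
        },
    )
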