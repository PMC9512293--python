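"""Synthetic-data generators with known ground truth.

Three generators cover the pipeline's inputs: a peptide-level
reporter-intensity experiment for a two-group design (with a spiked
subset of truly differential proteins), a targeted re-measurement of a
protein panel under independent noise, and a right-censored survival
cohort whose hazard changes at a known marker threshold.

Intensity model: protein baseline abundance is log-normal; each peptide
carries a fixed log-normal ionization-efficiency multiplier; sample-level
noise is multiplicative log-normal parameterized by a coefficient of
variation.  Missingness is completely at random and encoded as NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .tables import PEPTIDE_KEY, PROTEIN_KEY, PeptideTable, SurvivalCohort

GROUP_CONTROL = "control"
GROUP_TREATED = "treated"

UP, DOWN, NULL = "up", "down", "null"

# spread of the fixed per-peptide ionization-efficiency multiplier (natural log)
_EFFICIENCY_LOG_SD = 0.5


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TmtSimConfig:
    """Parameters for the two-group discovery experiment."""

    n_proteins: int = 1000
    frac_up: float = 0.1
    frac_down: float = 0.05
    effect_fc: float = 2.0
    peptides_per_protein_mean: float = 3.0
    n_per_group: int = 3
    baseline_log_mean: float = 14.0
    baseline_log_sd: float = 1.5
    peptide_cv: float = 0.1
    missing_rate: float = 0.0
    total_spectra: int = 363519
    effective_rate: float = 0.229
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        for name in ("frac_up", "frac_down"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_up + self.frac_down > 1.0:
            raise ConfigError("frac_up + frac_down must not exceed 1")
        if self.effect_fc <= 1.0:
            raise ConfigError("effect_fc must be > 1")
        if self.peptides_per_protein_mean <= 0:
            raise ConfigError("peptides_per_protein_mean must be positive")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.peptide_cv < 0:
            raise ConfigError("peptide_cv must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.total_spectra < 1:
            raise ConfigError("total_spectra must be >= 1")
        if not 0.0 < self.effective_rate <= 1.0:
            raise ConfigError("effective_rate must lie in (0, 1]")


@dataclass(frozen=True)
class SurvSimConfig:
    """Parameters for the piecewise-constant-hazard survival cohort."""

    n_patients: int = 400
    true_cutoff: float = 1.0
    hazard_low: float = 0.05
    hazard_high: float = 0.20
    censor_rate: float = 0.2
    marker_mean: float = 1.0
    marker_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ConfigError("n_patients must be >= 2")
        if self.hazard_low <= 0 or self.hazard_high <= 0:
            raise ConfigError("hazard_low and hazard_high must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must lie in [0, 1)")
        if self.marker_sd <= 0:
            raise ConfigError("marker_sd must be positive")


def _spiked_counts(config: TmtSimConfig) -> tuple[int, int]:
    n_up = _round_half_up(config.frac_up * config.n_proteins)
    n_down = _round_half_up(config.frac_down * config.n_proteins)
    return n_up, n_down


def make_ledger(config: TmtSimConfig) -> pd.DataFrame:
    """Ground-truth ledger: one row per protein with direction and true fold change.

    Spiked assignments depend only on the counts implied by the config,
    not on the random stream, so the ledger is deterministic.
    """
    n_up, n_down = _spiked_counts(config)
    direction = np.array(
        [UP] * n_up + [DOWN] * n_down + [NULL] * (config.n_proteins - n_up - n_down)
    )
    true_fc = np.where(
        direction == UP,
        config.effect_fc,
        np.where(direction == DOWN, 1.0 / config.effect_fc, 1.0),
    )
    return pd.DataFrame(
        {
            PROTEIN_KEY: [f"PROT{i + 1:05d}" for i in range(config.n_proteins)],
            "true_direction": direction,
            "true_fc": true_fc,
        }
    ).set_index(PROTEIN_KEY)


def _sample_names(config: TmtSimConfig) -> tuple[list[str], pd.Series]:
    names = [f"ctrl_{i + 1}" for i in range(config.n_per_group)] + [
        f"net_{i + 1}" for i in range(config.n_per_group)
    ]
    groups = pd.Series(
        [GROUP_CONTROL] * config.n_per_group + [GROUP_TREATED] * config.n_per_group,
        index=names,
        name="group",
    )
    return names, groups


def _draw_intensities(
    config: TmtSimConfig, ledger: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw one peptide-level intensity table under the hierarchical model."""
    n_prot = len(ledger)
    lam = max(config.peptides_per_protein_mean - 1.0, 0.0)
    pep_counts = 1 + rng.poisson(lam, size=n_prot)
    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=n_prot)
    )

    prot_ids = np.repeat(ledger.index.to_numpy(), pep_counts)
    pep_ids = np.concatenate(
        [np.arange(1, c + 1) for c in pep_counts]
    )
    pep_labels = [f"{p}_pep{j}" for p, j in zip(prot_ids, pep_ids)]
    n_pep = len(prot_ids)

    efficiency = np.exp(rng.normal(0.0, _EFFICIENCY_LOG_SD, size=n_pep))
    base = np.repeat(baselines, pep_counts) * efficiency  # per-peptide expected level

    names, _ = _sample_names(config)
    n_samples = 2 * config.n_per_group
    expected = np.tile(base[:, None], (1, n_samples))

    # spiked effects act on every treated-group column of the protein's peptides
    fc_per_pep = np.repeat(ledger["true_fc"].to_numpy(), pep_counts)
    expected[:, config.n_per_group:] *= fc_per_pep[:, None]

    if config.peptide_cv > 0:
        # mean-preserving multiplicative log-normal noise at the stated CV
        sigma = math.sqrt(math.log1p(config.peptide_cv**2))
        noise = np.exp(
            rng.normal(-0.5 * sigma**2, sigma, size=(n_pep, n_samples))
        )
        intensities = expected * noise
    else:
        intensities = expected.copy()

    if config.missing_rate > 0:
        mask = rng.random((n_pep, n_samples)) < config.missing_rate
        intensities[mask] = np.nan

    index = pd.MultiIndex.from_arrays(
        [prot_ids, pep_labels], names=[PROTEIN_KEY, PEPTIDE_KEY]
    )
    return pd.DataFrame(intensities, index=index, columns=names)


def simulate_tmt_experiment(
    config: TmtSimConfig,
) -> tuple[PeptideTable, pd.DataFrame]:
    """Simulate the discovery experiment.

    Returns the peptide intensity table (one row per (protein, peptide),
    one column per sample) and the ground-truth ledger.  Identical
    configs give bit-identical outputs.
    """
    ledger = make_ledger(config)
    rng = np.random.default_rng(config.seed)
    data = _draw_intensities(config, ledger, rng)
    _, groups = _sample_names(config)
    table = PeptideTable(
        data,
        groups,
        total_spectra=config.total_spectra,
        effective_spectra=_round_half_up(config.total_spectra * config.effective_rate),
    )
    return table, ledger


def simulate_prm_panel(
    ledger: pd.DataFrame, panel, config: TmtSimConfig
) -> PeptideTable:
    """Re-measure a protein panel with an independent noise draw.

    True effects come from the ledger; baselines, peptide counts and
    noise are drawn from a stream decoupled from the discovery run.
    """
    panel = list(panel)
    if len(panel) == 0:
        raise ValidationError("empty panel: nothing to measure")
    unknown = sorted(set(panel) - set(ledger.index))
    if unknown:
        raise ValidationError(f"panel proteins not in ledger: {unknown}")
    sub = ledger.loc[panel]
    # child-seeded stream so the draw is independent of the discovery draw
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    data = _draw_intensities(config, sub, rng)
    _, groups = _sample_names(config)
    return PeptideTable(data, groups)


def simulate_survival_cohort(config: SurvSimConfig) -> SurvivalCohort:
    """Simulate exponential event times whose rate switches at a marker cutoff.

    Markers are Gaussian; subjects with marker >= ``true_cutoff`` get
    ``hazard_high``, others ``hazard_low``.  A fixed fraction of subjects
    is censored at a uniform fraction of their latent event time.
    """
    rng = np.random.default_rng(config.seed)
    marker = rng.normal(config.marker_mean, config.marker_sd, size=config.n_patients)
    rate = np.where(marker >= config.true_cutoff, config.hazard_high, config.hazard_low)
    latent = rng.exponential(1.0 / rate)
    censored = rng.random(config.n_patients) < config.censor_rate
    time = np.where(censored, latent * rng.random(config.n_patients), latent)
    event = (~censored).astype(int)
    return SurvivalCohort(time=time, event=event, marker=marker)


def simulate_feature_matrix(
    n_features: int,
    n_informative: int,
    n_per_class: int,
    effect: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class Gaussian feature matrix with a known informative subset.

    Informative features (the first ``n_informative`` columns, shuffled)
    have their class-1 mean shifted by ``effect``.  Returns
    ``(X, y, informative_mask)``.
    """
    if n_informative > n_features:
        raise ConfigError("n_informative must not exceed n_features")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X = rng.normal(0.0, noise_sd, size=(n, n_features))
    order = rng.permutation(n_features)
    informative = np.zeros(n_features, dtype=bool)
    informative[order[:n_informative]] = True
    X[np.ix_(y == 1, informative)] += effect
    return X, y, informative


def null_config(config: TmtSimConfig) -> TmtSimConfig:
    """Copy of a config with no spiked proteins (for calibration checks)."""
    return replace(config, frac_up=0.0, frac_down=0.0)
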