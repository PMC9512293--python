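"""Peptide centering, protein median rollup, and the spectra-utilization summary.

The quantification chain has two steps.  Each peptide's intensities are
first divided by that peptide's mean over observed samples, giving
relative values whose observed-sample mean is exactly 1.  Per-protein
relative values are then the per-sample median over the protein's
peptides observed in that sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import PROTEIN_KEY, PeptideTable, ProteinTable

logger = logging.getLogger(__name__)


def center_peptides(table: PeptideTable) -> PeptideTable:
    """Divide each peptide row by its mean over observed samples.

    Zeros are coerced to absent (with a warning) before centering, since
    a zero would poison the row mean and every downstream ratio.
    Peptides with no observed values are dropped with a warning.
    """
    data = table.intensities.astype(float)
    n_zero = int((data == 0).sum().sum())
    if n_zero:
        logger.warning("coercing %d zero intensities to absent", n_zero)
        data = data.replace(0.0, np.nan)

    observed = data.notna().sum(axis=1)
    empty = observed == 0
    if empty.any():
        logger.warning(
            "dropping %d peptides with no observed intensities: %s",
            int(empty.sum()),
            data.index[empty][:5].tolist(),
        )
        data = data.loc[~empty]

    row_means = data.mean(axis=1, skipna=True)
    rel = data.div(row_means, axis=0)
    return PeptideTable(
        rel, table.groups, table.total_spectra, table.effective_spectra
    )


def rollup_proteins(rel: PeptideTable, min_peptides: int = 1) -> ProteinTable:
    """Per-sample median over each protein's observed peptide relative values.

    Proteins supported by fewer than ``min_peptides`` peptides are
    excluded and logged.  Even peptide counts use the conventional
    midpoint median.
    """
    if min_peptides < 1:
        raise ValidationError("min_peptides must be >= 1")
    grouped = rel.intensities.groupby(level=PROTEIN_KEY, sort=True)
    values = grouped.median()
    n_peptides = grouped.size().rename("n_peptides")

    thin = n_peptides < min_peptides
    if thin.any():
        logger.warning(
            "excluding %d proteins with < %d peptides", int(thin.sum()), min_peptides
        )
        values = values.loc[~thin]
        n_peptides = n_peptides.loc[~thin]
    return ProteinTable(values=values, groups=rel.groups, n_peptides=n_peptides)


def quantify(
    table: PeptideTable, min_peptides: int = 1
) -> ProteinTable:
    """Convenience chain: center peptides then roll up to proteins."""
    return rollup_proteins(center_peptides(table), min_peptides=min_peptides)


def spectra_utilization(effective: int, total: int) -> float:
    """Percentage of effective MS2 spectra among all collected, one decimal."""
    if total <= 0:
        raise ValidationError("total spectra must be > 0")
    if effective < 0 or effective > total:
        raise ValidationError("effective must lie in [0, total]")
    return round(100.0 * effective / total, 1)
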