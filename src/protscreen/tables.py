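"""Core tabular containers passed between pipeline stages.

All containers are thin wrappers over pandas objects with contract
validation at construction time.  Intensity tables are indexed by
``(protein_id, peptide_id)`` with one column per sample; absent
measurements are encoded as NaN, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

PROTEIN_KEY = "protein_id"
PEPTIDE_KEY = "peptide_id"


@dataclass
class PeptideTable:
    """Peptide-level intensities (or relative values) with group labels.

    Parameters
    ----------
    intensities
        DataFrame indexed by a ``(protein_id, peptide_id)`` MultiIndex,
        one float column per sample.  NaN marks an absent cell.
    groups
        Series mapping sample id -> group label.  Every intensity column
        must appear in the mapping.
    total_spectra, effective_spectra
        Optional MS2 spectrum counts carried along for the utilization
        summary.
    """

    intensities: pd.DataFrame
    groups: pd.Series
    total_spectra: int | None = None
    effective_spectra: int | None = None

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if not isinstance(idx, pd.MultiIndex) or idx.names != [PROTEIN_KEY, PEPTIDE_KEY]:
            raise ValidationError(
                "intensities must be indexed by (protein_id, peptide_id)"
            )
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate (protein, peptide) keys: {dupes}")
        missing = [s for s in self.intensities.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing}")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("negative intensities are not allowed")
        counts = self.groups.loc[list(self.intensities.columns)].value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValidationError(f"groups with < 2 samples: {small}")
        self.groups = self.groups.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_peptides(self) -> int:
        return len(self.intensities)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def restrict_proteins(self, proteins) -> "PeptideTable":
        keep = self.intensities.index.get_level_values(PROTEIN_KEY).isin(set(proteins))
        return PeptideTable(
            self.intensities.loc[keep],
            self.groups,
            self.total_spectra,
            self.effective_spectra,
        )


@dataclass
class ProteinTable:
    """Per-protein relative values per sample, with peptide support counts."""

    values: pd.DataFrame  # index protein_id, one column per sample
    groups: pd.Series
    n_peptides: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.name != PROTEIN_KEY:
            self.values = self.values.rename_axis(PROTEIN_KEY)
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate protein ids")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples missing from group map: {missing}")
        if self.n_peptides is None:
            self.n_peptides = pd.Series(1, index=self.values.index, name="n_peptides")
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals[np.isfinite(vals)] <= 0):
            raise ValidationError("protein relative values must be > 0 where defined")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]


@dataclass
class SurvivalCohort:
    """Right-censored time-to-event records with one continuous marker."""

    time: np.ndarray
    event: np.ndarray
    marker: np.ndarray
    patient_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.marker = np.asarray(self.marker, dtype=float)
        n = len(self.time)
        if len(self.event) != n or len(self.marker) != n:
            raise ValidationError("time, event and marker must have equal length")
        if n == 0:
            raise ValidationError("empty cohort")
        if np.any(self.time < 0):
            raise ValidationError("negative survival times")
        if not np.isin(self.event, (0, 1)).all():
            raise ValidationError("event indicators must be 0 or 1")
        if np.any(~np.isfinite(self.marker)):
            raise ValidationError("absent marker values are not allowed")
        if self.patient_id is None:
            self.patient_id = np.array([f"P{i + 1}" for i in range(n)])

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "time": self.time,
                "event": self.event,
                "marker": self.marker,
            }
        )
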