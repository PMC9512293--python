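"""TSV readers/writers for every table the pipeline exchanges.

Schemas
-------
peptides.tsv : protein_id, peptide_id, <one column per sample>; empty field = absent
groups.tsv   : sample_id, group
proteins.tsv : protein_id, n_peptides, <one column per sample>
diff.tsv     : protein_id, fc, log2fc, p_value, neg_log10_p, call
cohort.tsv   : patient_id, time, event, marker
ledger.tsv   : protein_id, true_direction, true_fc
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .tables import PEPTIDE_KEY, PROTEIN_KEY, PeptideTable, ProteinTable, SurvivalCohort


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}", line=1)


def read_groups(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "group"], path)
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        line = int(df.index[df["sample_id"] == dup][-1]) + 2
        raise SchemaError(f"{path}: duplicate sample_id '{dup}'", line=line)
    return df.set_index("sample_id")["group"]


def write_groups(groups: pd.Series, path) -> None:
    groups.rename_axis("sample_id").rename("group").to_frame().to_csv(path, sep="\t")


def read_peptide_table(path, groups_path) -> PeptideTable:
    """Load and validate a peptide intensity TSV plus its groups TSV.

    Rejects duplicate (protein, peptide) keys and negative intensities
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, [PROTEIN_KEY, PEPTIDE_KEY], path)
    keys = df[[PROTEIN_KEY, PEPTIDE_KEY]]
    dup_mask = keys.duplicated()
    if dup_mask.any():
        row = int(np.flatnonzero(dup_mask)[0])
        key = tuple(keys.iloc[row])
        raise SchemaError(f"{path}: duplicate key {key}", line=row + 2)
    sample_cols = [c for c in df.columns if c not in (PROTEIN_KEY, PEPTIDE_KEY)]
    if not sample_cols:
        raise SchemaError(f"{path}: no sample columns", line=1)
    for col in sample_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SchemaError(
                f"{path}: negative intensity in column '{col}'", line=row + 2
            )
        df[col] = vals
    data = df.set_index([PROTEIN_KEY, PEPTIDE_KEY])[sample_cols]
    return PeptideTable(data, read_groups(groups_path))


def write_peptide_table(table: PeptideTable, path) -> None:
    table.intensities.to_csv(path, sep="\t")


def read_protein_table(path, groups_path) -> ProteinTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, [PROTEIN_KEY, "n_peptides"], path)
    if df[PROTEIN_KEY].duplicated().any():
        dup = df[PROTEIN_KEY][df[PROTEIN_KEY].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate protein_id '{dup}'")
    df = df.set_index(PROTEIN_KEY)
    n_peptides = df.pop("n_peptides").astype(int)
    return ProteinTable(
        values=df.astype(float), groups=read_groups(groups_path), n_peptides=n_peptides
    )


def write_protein_table(table: ProteinTable, path) -> None:
    out = table.values.copy()
    out.insert(0, "n_peptides", table.n_peptides)
    out.to_csv(path, sep="\t")


def read_diff_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, [PROTEIN_KEY, "fc", "p_value", "call"], path)
    return df.set_index(PROTEIN_KEY)


def write_diff_table(result: pd.DataFrame, path) -> None:
    result.rename_axis(PROTEIN_KEY).to_csv(path, sep="\t")


def read_cohort(path) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["time", "event", "marker"], path)
    ids = df["patient_id"].to_numpy() if "patient_id" in df.columns else None
    return SurvivalCohort(
        time=df["time"].to_numpy(float),
        event=df["event"].to_numpy(int),
        marker=df["marker"].to_numpy(float),
        patient_id=ids,
    )


def write_cohort(cohort: SurvivalCohort, path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def read_ledger(path) -> pd.DataFrame:
    # keep_default_na: "null" is a direction label, not a missing value
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["true_fc"] = df["true_fc"].astype(float)
    _require_columns(df, [PROTEIN_KEY, "true_direction", "true_fc"], path)
    return df.set_index(PROTEIN_KEY)


def write_ledger(ledger: pd.DataFrame, path) -> None:
    ledger.rename_axis(PROTEIN_KEY).to_csv(path, sep="\t")


def read_feature_list(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_feature_list(features, path) -> None:
    Path(path).write_text("\n".join(features) + "\n")
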