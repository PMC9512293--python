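"""Discovery-vs-validation agreement for a protein panel.

Direction agreement means both fold changes fall strictly on the same
side of 1 (a fold change of exactly 1 on either side counts as
non-agreeing).  Rank correlation is Spearman over log2 fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceReport:
    per_protein: pd.DataFrame  # panel order: discovery_fc, validation_fc, direction_agrees
    sign_agreement_rate: float
    rank_correlation: float
    n_validated_significant: int
    missing: list[str] = field(default_factory=list)

    @property
    def panel_size(self) -> int:
        return len(self.per_protein)


def concordance(
    discovery: pd.DataFrame,
    validation: pd.DataFrame,
    panel,
    alpha: float = 0.05,
) -> ConcordanceReport:
    """Compare per-protein fold changes between two screening results.

    ``discovery`` and ``validation`` are screening result frames indexed
    by protein id with at least ``fc`` (and optionally ``call`` /
    ``p_value``) columns.  Panel proteins missing from either frame are
    listed under ``missing`` and excluded from all rates.
    """
    panel = list(panel)
    if not panel:
        raise ValidationError("empty panel")
    if len(set(panel)) != len(panel):
        raise ValidationError("panel contains duplicate protein ids")

    present, missing = [], []
    for prot in panel:
        if prot in discovery.index and prot in validation.index:
            present.append(prot)
        else:
            missing.append(prot)
    if missing:
        logger.warning("%d panel proteins missing from a result set: %s", len(missing), missing)
    if not present:
        raise ValidationError("no panel protein present in both result sets")

    d_fc = discovery.loc[present, "fc"].to_numpy(float)
    v_fc = validation.loc[present, "fc"].to_numpy(float)
    agrees = ((d_fc > 1) & (v_fc > 1)) | ((d_fc < 1) & (v_fc < 1))

    per_protein = pd.DataFrame(
        {
            "discovery_fc": d_fc,
            "validation_fc": v_fc,
            "direction_agrees": agrees,
        },
        index=pd.Index(present, name="protein_id"),
    )

    if len(present) >= 2:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(np.log2(d_fc), np.log2(v_fc)).statistic
        rho = float(rho) if np.isfinite(rho) else 0.0
    else:
        rho = float("nan")

    if "call" in validation.columns:
        n_sig = int((validation.loc[present, "call"] != "ns").sum())
    elif "p_value" in validation.columns:
        n_sig = int((validation.loc[present, "p_value"] <= alpha).sum())
    else:
        n_sig = 0

    return ConcordanceReport(
        per_protein=per_protein,
        sign_agreement_rate=float(agrees.mean()),
        rank_correlation=rho,
        n_validated_significant=n_sig,
        missing=missing,
    )
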