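import numpy as np
import pandas as pd
import pytest

from protscreen.tables import PEPTIDE_KEY, PROTEIN_KEY, PeptideTable, ProteinTable


def make_peptide_table(rows: dict, groups: dict) -> PeptideTable:
    """Build a PeptideTable from {(protein, peptide): [intensities]}.

    Sample names are s1..sn; ``groups`` maps sample -> label.
    """
    index = pd.MultiIndex.from_tuples(rows.keys(), names=[PROTEIN_KEY, PEPTIDE_KEY])
    n = len(next(iter(rows.values())))
    cols = [f"s{i + 1}" for i in range(n)]
    data = pd.DataFrame(list(rows.values()), index=index, columns=cols, dtype=float)
    return PeptideTable(data, pd.Series(groups))


def make_protein_table(rows: dict, groups: dict) -> ProteinTable:
    n = len(next(iter(rows.values())))
    cols = [f"s{i + 1}" for i in range(n)]
    values = pd.DataFrame(list(rows.values()), index=pd.Index(rows.keys(), name=PROTEIN_KEY),
                          columns=cols, dtype=float)
    return ProteinTable(values=values, groups=pd.Series(groups))


@pytest.fixture
def groups6() -> dict:
    return {f"s{i + 1}": ("control" if i < 3 else "treated") for i in range(6)}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
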