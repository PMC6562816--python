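"""Packaged reference table: the 52-gene progression signature input.

``table1_progression.tsv`` transcribes the published progression table
for the murine KRAS/MYC lung adenocarcinoma model: genes upregulated in
p-Erk-high versus p-Erk-low tumour regions, with normalised read-count
ranges, mean fold change, FDR, and human-NSCLC amplification /
overexpression annotations.  One row (Ptges) prints identical read
ranges for both region classes in the source; it is transcribed as
printed.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .signature import DEGeneRecord, HumanEvidence, load_de_table, load_evidence_table

__all__ = [
    "table1_path",
    "load_table1",
    "load_table1_de",
    "load_table1_evidence",
]


def table1_path() -> Path:
    """Filesystem path of the packaged progression table (8-column TSV)."""
    return Path(resources.files("luadsig.data") / "table1_progression.tsv")


def load_table1() -> pd.DataFrame:
    """The packaged progression table as a raw DataFrame (52 rows)."""
    return pd.read_csv(table1_path(), sep="\t")


def load_table1_de() -> list[DEGeneRecord]:
    """DE-record view of the packaged table (symbol, ranges, FC, FDR)."""
    return load_de_table(table1_path())


def load_table1_evidence() -> dict[str, HumanEvidence]:
    """Human-evidence view of the packaged table (amp / overexpression)."""
    return load_evidence_table(table1_path())
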