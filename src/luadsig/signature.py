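"""Derivation of the tumour-progression gene signature.

A differential-expression (DE) table contrasts laser-captured p-Erk-high
tumour regions against matched p-Erk-low regions of the same murine
KRAS/MYC-driven lung adenocarcinomas.  Each gene carries a mean fold
change (FC), a false-discovery rate (FDR) and the normalised read-count
ranges observed in the two region classes.  The signature is the subset
of upregulated genes that (i) clear an FC cutoff, (ii) clear an FDR
cutoff and (iii) show independent evidence of amplification and/or
overexpression in human NSCLC cohorts.  Applied with the default
thresholds (FC >= 2.5, FDR < 0.05, evidence required) to the packaged
progression table this yields the 52-gene signature.

The FC threshold is inclusive (the packaged table retains a gene at
exactly 2.50) and the FDR threshold is exclusive (the table's maximum
FDR is 4.9e-02).  Read-count normalisation happens upstream; the ranges
are carried as annotation only.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AmpStatus",
    "Flag",
    "DEGeneRecord",
    "HumanEvidence",
    "SignatureEntry",
    "SignatureSummary",
    "SignatureError",
    "load_de_table",
    "load_evidence_table",
    "derive_signature",
    "summarize_signature",
    "signature_frame",
]

DE_COLUMNS = ("gene_symbol", "gene_name", "reads_perk_neg", "reads_perk_pos", "mean_fc", "fdr")
EVIDENCE_COLUMNS = ("gene_symbol", "amp_nsclc", "overex_nsclc")

# ranges are printed "a–b"; tolerate en dash, em dash and plain hyphen
_RANGE_RE = re.compile(r"^\s*(\d+)\s*[–—-]\s*(\d+)\s*$")


class SignatureError(ValueError):
    """Raised on malformed signature inputs (named row/gene in message)."""


class AmpStatus(enum.Enum):
    """Amplification evidence in human NSCLC cohorts.

    ``AMPLIFIED`` covers the plain 1-5%-of-cases annotation;
    ``AMPLIFIED_HIGH`` carries an explicit ">N%" frequency;
    ``AMPLIFIED_LOW`` is the "<1%" annotation; ``SCC_ONLY`` marks
    amplification observed in squamous cell carcinoma only.
    """

    AMPLIFIED = "amplified"
    AMPLIFIED_HIGH = "amplified_high"
    AMPLIFIED_LOW = "amplified_low"
    NOT_AMPLIFIED = "not_amplified"
    SCC_ONLY = "scc_only"
    NO_DATA = "no_data"


class Flag(enum.Enum):
    YES = "yes"
    NO = "no"
    NO_DATA = "no_data"


@dataclass(frozen=True)
class DEGeneRecord:
    """One gene's progression-associated expression change."""

    gene_symbol: str
    gene_name: str
    reads_neg_range: tuple[float, float]
    reads_pos_range: tuple[float, float]
    mean_fc: float
    fdr: float

    def __post_init__(self) -> None:
        for label, (lo, hi) in (
            ("reads_neg_range", self.reads_neg_range),
            ("reads_pos_range", self.reads_pos_range),
        ):
            if lo < 0 or hi < 0:
                raise SignatureError(f"{self.gene_symbol}: negative count in {label}")
            if lo > hi:
                raise SignatureError(f"{self.gene_symbol}: {label} min > max")
        if not self.mean_fc > 0:
            raise SignatureError(f"{self.gene_symbol}: mean_fc must be > 0, got {self.mean_fc}")
        if not 0.0 <= self.fdr <= 1.0:
            raise SignatureError(f"{self.gene_symbol}: fdr outside [0, 1], got {self.fdr}")


@dataclass(frozen=True)
class HumanEvidence:
    """Amplification / overexpression annotation for one gene."""

    gene_symbol: str
    amp_status: AmpStatus
    overexpressed: Flag
    amp_percent: float | None = None  # the ">N%" frequency, when annotated


@dataclass(frozen=True)
class SignatureEntry:
    """A gene surviving all signature filters (DE record joined to evidence)."""

    record: DEGeneRecord
    evidence: HumanEvidence | None

    @property
    def gene_symbol(self) -> str:
        return self.record.gene_symbol

    @property
    def mean_fc(self) -> float:
        return self.record.mean_fc

    @property
    def fdr(self) -> float:
        return self.record.fdr


@dataclass(frozen=True)
class SignatureSummary:
    n_genes: int
    max_fc: float
    max_fc_gene: str
    min_fc: float
    min_fc_gene: str
    min_fdr: float
    min_fdr_gene: str
    max_fdr: float
    max_fdr_gene: str


def _parse_range(text: str, gene: str, column: str) -> tuple[float, float]:
    m = _RANGE_RE.match(str(text))
    if not m:
        raise SignatureError(f"{gene}: cannot parse range {text!r} in column {column}")
    lo, hi = float(m.group(1)), float(m.group(2))
    return lo, hi


def parse_amp_status(text: str) -> tuple[AmpStatus, float | None]:
    """Map a printed amplification annotation to its enum value.

    Accepted forms: ``Y``, ``Y(SCC)``, ``Y > 7%``, ``<1%``, ``N``,
    ``No data`` (case-insensitive, whitespace-tolerant).
    """
    t = str(text).strip()
    low = t.lower()
    if low in ("n", "no"):
        return AmpStatus.NOT_AMPLIFIED, None
    if low in ("no data", "nodata", "na", ""):
        return AmpStatus.NO_DATA, None
    if low.startswith("<"):
        return AmpStatus.AMPLIFIED_LOW, None
    m = re.match(r"^y\s*>\s*(\d+(?:\.\d+)?)\s*%$", low)
    if m:
        return AmpStatus.AMPLIFIED_HIGH, float(m.group(1))
    if re.match(r"^y\s*\(\s*scc\s*\)$", low):
        return AmpStatus.SCC_ONLY, None
    if low == "y" or low == "yes":
        return AmpStatus.AMPLIFIED, None
    raise SignatureError(f"unrecognised amplification annotation {text!r}")


def parse_flag(text: str) -> Flag:
    low = str(text).strip().lower()
    if low in ("y", "yes"):
        return Flag.YES
    if low in ("n", "no"):
        return Flag.NO
    if low in ("no data", "nodata", "na", ""):
        return Flag.NO_DATA
    raise SignatureError(f"unrecognised yes/no annotation {text!r}")


def load_de_table(path: str | Path) -> list[DEGeneRecord]:
    """Read a DE table (TSV with header) into validated records.

    Required columns: ``gene_symbol``, ``gene_name``, ``reads_perk_neg``,
    ``reads_perk_pos`` (ranges encoded ``a–b``, en dash or hyphen),
    ``mean_fc``, ``fdr``.  Extra columns are ignored, so the packaged
    8-column progression table parses directly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise SignatureError(f"DE table {path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        gene = str(row["gene_symbol"]).strip()
        try:
            fc = float(row["mean_fc"])
            fdr = float(row["fdr"])
        except ValueError as exc:
            raise SignatureError(f"{gene}: non-numeric mean_fc/fdr") from exc
        records.append(
            DEGeneRecord(
                gene_symbol=gene,
                gene_name=str(row["gene_name"]).strip(),
                reads_neg_range=_parse_range(row["reads_perk_neg"], gene, "reads_perk_neg"),
                reads_pos_range=_parse_range(row["reads_perk_pos"], gene, "reads_perk_pos"),
                mean_fc=fc,
                fdr=fdr,
            )
        )
    return records


def load_evidence_table(path: str | Path) -> dict[str, HumanEvidence]:
    """Read a human-evidence table (TSV) into a gene -> evidence map.

    Required columns: ``gene_symbol``, ``amp_nsclc``, ``overex_nsclc``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SignatureError(f"evidence table {path}: missing columns {missing}")
    out: dict[str, HumanEvidence] = {}
    for _, row in df.iterrows():
        gene = str(row["gene_symbol"]).strip()
        amp, pct = parse_amp_status(row["amp_nsclc"])
        out[gene] = HumanEvidence(
            gene_symbol=gene,
            amp_status=amp,
            overexpressed=parse_flag(row["overex_nsclc"]),
            amp_percent=pct,
        )
    return out


def has_human_evidence(ev: HumanEvidence, strict: bool = False) -> bool:
    """Evidence rule: amplification and/or overexpression in human NSCLC.

    Default mode counts any positive amplification annotation —
    including SCC-only and "<1%" — as evidence, matching the packaged
    table (which retains e.g. Porcn at "<1%" with no overexpression
    call).  Strict mode counts SCC-only and "<1%" amplification only
    when the overexpression flag is also "yes".
    """
    amp_ok = ev.amp_status not in (AmpStatus.NOT_AMPLIFIED, AmpStatus.NO_DATA)
    if strict and ev.amp_status in (AmpStatus.SCC_ONLY, AmpStatus.AMPLIFIED_LOW):
        amp_ok = False
    return amp_ok or ev.overexpressed is Flag.YES


def derive_signature(
    de: Iterable[DEGeneRecord],
    ev: Mapping[str, HumanEvidence] | None = None,
    fc_min: float = 2.5,
    fdr_max: float = 0.05,
    require_evidence: bool = True,
    strict_evidence: bool = False,
) -> list[SignatureEntry]:
    """Apply the three signature filters and return the retained genes.

    A gene is retained when ``mean_fc >= fc_min`` (inclusive) and
    ``fdr < fdr_max`` (exclusive) and — unless ``require_evidence`` is
    off — its human-evidence record passes :func:`has_human_evidence`.
    Output is ordered by descending fold change, ties broken
    alphabetically by symbol.

    Raises :class:`SignatureError` if ``require_evidence`` is set and a
    gene passing the numeric filters has no evidence record.
    """
    de = list(de)
    entries: list[SignatureEntry] = []
    for rec in de:
        if not (rec.mean_fc >= fc_min and rec.fdr < fdr_max):
            continue
        evidence = None
        if require_evidence:
            if ev is None or rec.gene_symbol not in ev:
                raise SignatureError(
                    f"no human-evidence record for gene {rec.gene_symbol!r} "
                    "(required when require_evidence=True)"
                )
            evidence = ev[rec.gene_symbol]
            if not has_human_evidence(evidence, strict=strict_evidence):
                continue
        elif ev is not None:
            evidence = ev.get(rec.gene_symbol)
        entries.append(SignatureEntry(record=rec, evidence=evidence))
    entries.sort(key=lambda e: (-e.mean_fc, e.gene_symbol))
    return entries


def summarize_signature(sig: Sequence[SignatureEntry]) -> SignatureSummary:
    """Extrema of fold change and FDR over a non-empty signature."""
    if not sig:
        raise SignatureError("cannot summarise an empty signature")
    by_fc = sorted(sig, key=lambda e: (e.mean_fc, e.gene_symbol))
    by_fdr = sorted(sig, key=lambda e: (e.fdr, e.gene_symbol))
    return SignatureSummary(
        n_genes=len(sig),
        max_fc=by_fc[-1].mean_fc,
        max_fc_gene=by_fc[-1].gene_symbol,
        min_fc=by_fc[0].mean_fc,
        min_fc_gene=by_fc[0].gene_symbol,
        min_fdr=by_fdr[0].fdr,
        min_fdr_gene=by_fdr[0].gene_symbol,
        max_fdr=by_fdr[-1].fdr,
        max_fdr_gene=by_fdr[-1].gene_symbol,
    )


def signature_frame(sig: Sequence[SignatureEntry]) -> pd.DataFrame:
    """Tabular view of a signature, one row per retained gene."""
    rows = []
    for e in sig:
        rows.append(
            {
                "gene_symbol": e.gene_symbol,
                "gene_name": e.record.gene_name,
                "mean_fc": e.mean_fc,
                "fdr": e.fdr,
                "amp_status": e.evidence.amp_status.value if e.evidence else "",
                "overexpressed": e.evidence.overexpressed.value if e.evidence else "",
            }
        )
    return pd.DataFrame(rows, columns=["gene_symbol", "gene_name", "mean_fc", "fdr", "amp_status", "overexpressed"])
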