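"""Arrayed siRNA viability-screen scoring and gene-level hit calling.

Cells are reverse-transfected with four individual siRNAs per gene in
technical replicate, grown for ~72 h, DAPI-stained and nuclei-counted
by high-content imaging.  Each siRNA's effect is expressed as percent
suppression of viability (SoV) relative to the non-targeting negative
control:

    SoV = 100 * (1 - mean nuclei count of the siRNA
                     / mean nuclei count of NEG_CONTROL wells)

Per cell line, the mean SoV over all library siRNAs (M) sets the
positive-call threshold: an siRNA scores positive when SoV > M
(strict).  Genes are then classified across cell lines: a gene is an
``all_lines`` hit when at least one siRNA is positive in every screened
line, a ``two_of_three`` hit when its best siRNA is positive in all
lines but one, and a consistent hit when at least ``k_consistent``
(default 3) *identical* siRNAs are positive in every line — the rule
that flagged FMO1, KIF23, KRT19 and SLC2A1 in the screen this module
models.

Technical replicates are averaged to a single count mean per siRNA
before the ratio is formed; control wells are excluded from M by
default.  Negative SoV (growth promotion) is preserved, never clipped.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "NEG_CONTROL",
    "POS_CONTROL",
    "PLATE_COLUMNS",
    "ScreenError",
    "ScreenThreshold",
    "GeneCall",
    "HitClass",
    "ScreenQC",
    "load_plate_table",
    "validate_plate_table",
    "compute_sov",
    "dataset_threshold",
    "call_positive",
    "classify_genes",
    "screen_qc",
    "score_screen",
    "calls_frame",
]

NEG_CONTROL = "NEG_CONTROL"
POS_CONTROL = "POS_CONTROL"
CONTROLS = (NEG_CONTROL, POS_CONTROL)

PLATE_COLUMNS = ("cell_line", "target", "sirna_id", "replicate_id", "nuclei_count")


class ScreenError(ValueError):
    """Raised on malformed plate data or inconsistent screen inputs."""


class HitClass(enum.Enum):
    ALL_LINES = "all_lines"
    TWO_OF_THREE = "two_of_three"
    NONE = "none"


@dataclass(frozen=True)
class ScreenThreshold:
    """Per-cell-line positive-call threshold M (mean library SoV)."""

    cell_line: str
    m: float


@dataclass(frozen=True)
class GeneCall:
    """Cross-line hit classification of one gene."""

    gene: str
    per_sirna_lines_positive: dict[int, int] = field(hash=False)
    hit_class: HitClass
    consistent_hit: bool
    n_lines: int


@dataclass(frozen=True)
class ScreenQC:
    """Control behaviour of one cell line's screen."""

    cell_line: str
    neg_control_sov: float
    pos_control_sov: float
    m: float
    passed: bool  # positive control must suppress more than the library mean


def validate_plate_table(plate: pd.DataFrame) -> pd.DataFrame:
    """Check the plate-table contract and normalise dtypes.

    Library rows must carry ``sirna_id`` in 1..4 (any positive integer
    set is accepted); control rows may leave it empty.  Every cell line
    needs at least one NEG_CONTROL well.
    """
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ScreenError(f"plate table: missing columns {missing}")
    plate = plate.copy()
    plate["sirna_id"] = pd.to_numeric(plate["sirna_id"], errors="coerce").astype("Int64")
    plate["nuclei_count"] = pd.to_numeric(plate["nuclei_count"])
    if (plate["nuclei_count"] < 0).any():
        bad = plate.loc[plate["nuclei_count"] < 0].iloc[0]
        raise ScreenError(f"negative nuclei_count for {bad['target']} in {bad['cell_line']}")
    lib = plate[~plate["target"].isin(CONTROLS)]
    if lib["sirna_id"].isna().any():
        bad = lib.loc[lib["sirna_id"].isna(), "target"].iloc[0]
        raise ScreenError(f"library target {bad!r} without sirna_id")
    for line, grp in plate.groupby("cell_line"):
        if not (grp["target"] == NEG_CONTROL).any():
            raise ScreenError(f"cell line {line!r} has no {NEG_CONTROL} wells")
    return plate


def load_plate_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a plate CSV (header; '#' comment lines ignored)."""
    return validate_plate_table(pd.read_csv(path, comment="#"))


def compute_sov(plate: pd.DataFrame, cell_line: str) -> pd.DataFrame:
    """Percent suppression of viability per siRNA of one cell line.

    Returns one row per (target, sirna_id) — controls pooled over wells,
    library siRNAs averaged over technical replicates — with columns
    ``cell_line, target, sirna_id, mean_count, sov, is_control``.  The
    ``positive`` flag is set later by :func:`call_positive`.
    """
    plate = validate_plate_table(plate)
    sub = plate[plate["cell_line"] == cell_line]
    if sub.empty:
        raise ScreenError(f"no wells for cell line {cell_line!r}")
    neg_mean = sub.loc[sub["target"] == NEG_CONTROL, "nuclei_count"].mean()
    if neg_mean == 0:
        raise ScreenError(f"{cell_line}: NEG_CONTROL mean nuclei count is 0")
    grouped = (
        sub.groupby(["target", "sirna_id"], dropna=False)["nuclei_count"]
        .mean()
        .reset_index(name="mean_count")
    )
    grouped["sov"] = 100.0 * (1.0 - grouped["mean_count"] / neg_mean)
    grouped["cell_line"] = cell_line
    grouped["is_control"] = grouped["target"].isin(CONTROLS)
    return grouped[["cell_line", "target", "sirna_id", "mean_count", "sov", "is_control"]]


def dataset_threshold(
    sovs: pd.DataFrame, cell_line: str, include_controls: bool = False
) -> ScreenThreshold:
    """The dataset-mean threshold M of one cell line.

    M is the arithmetic mean SoV over all library siRNAs of the line;
    control wells are excluded by default (including the pan-lethal
    positive control would inflate M).
    """
    sub = sovs[sovs["cell_line"] == cell_line]
    if not include_controls:
        sub = sub[~sub["is_control"]]
    if sub.empty:
        raise ScreenError(f"no library SoV records for cell line {cell_line!r}")
    return ScreenThreshold(cell_line=cell_line, m=float(sub["sov"].mean()))


def call_positive(sovs: pd.DataFrame, threshold: ScreenThreshold) -> pd.DataFrame:
    """Score each siRNA positive when SoV > M (strict inequality)."""
    if (sovs["cell_line"] != threshold.cell_line).any():
        other = sovs.loc[sovs["cell_line"] != threshold.cell_line, "cell_line"].iloc[0]
        raise ScreenError(
            f"threshold for {threshold.cell_line!r} applied to records of {other!r}"
        )
    out = sovs.copy()
    out["positive"] = out["sov"] > threshold.m
    return out


def classify_genes(
    calls: pd.DataFrame, n_lines: int | None = None, k_consistent: int = 3
) -> list[GeneCall]:
    """Cross-line gene classification from per-line positive calls.

    ``calls`` concatenates the :func:`call_positive` output of every
    screened line (library rows only are considered).  Every gene must
    have been screened with the same siRNA ids in every line.  A
    consistent hit needs >= ``k_consistent`` siRNAs that are *each*
    positive in all lines — the same siRNAs across lines by
    construction of the count.
    """
    lib = calls[~calls["is_control"]] if "is_control" in calls.columns else calls
    lines = sorted(lib["cell_line"].unique())
    if n_lines is None:
        n_lines = len(lines)
    results: list[GeneCall] = []
    for gene, grp in lib.groupby("target", sort=True):
        missing = sorted(set(lines) - set(grp["cell_line"].unique()))
        if missing:
            raise ScreenError(f"gene {gene!r} missing from lines {missing}")
        per_sirna = (
            grp.groupby("sirna_id")["positive"].agg(["sum", "count"]).astype(int)
        )
        short = per_sirna[per_sirna["count"] < n_lines]
        if not short.empty:
            raise ScreenError(
                f"gene {gene!r}: siRNAs {sorted(short.index)} not screened in all {n_lines} lines"
            )
        lines_positive = {int(s): int(v) for s, v in per_sirna["sum"].items()}
        best = max(lines_positive.values(), default=0)
        if best == n_lines:
            hit_class = HitClass.ALL_LINES
        elif best == n_lines - 1:
            hit_class = HitClass.TWO_OF_THREE
        else:
            hit_class = HitClass.NONE
        n_full = sum(1 for v in lines_positive.values() if v == n_lines)
        results.append(
            GeneCall(
                gene=str(gene),
                per_sirna_lines_positive=lines_positive,
                hit_class=hit_class,
                consistent_hit=n_full >= k_consistent,
                n_lines=n_lines,
            )
        )
    return results


def screen_qc(sovs: pd.DataFrame, threshold: ScreenThreshold) -> ScreenQC:
    """Control report for one line; fails when POS_CONTROL SoV <= M."""
    sub = sovs[sovs["cell_line"] == threshold.cell_line]
    neg = sub[sub["target"] == NEG_CONTROL]
    pos = sub[sub["target"] == POS_CONTROL]
    if neg.empty or pos.empty:
        missing = [c for c, d in ((NEG_CONTROL, neg), (POS_CONTROL, pos)) if d.empty]
        raise ScreenError(f"{threshold.cell_line}: missing control class(es) {missing}")
    pos_sov = float(pos["sov"].mean())
    return ScreenQC(
        cell_line=threshold.cell_line,
        neg_control_sov=float(neg["sov"].mean()),
        pos_control_sov=pos_sov,
        m=threshold.m,
        passed=pos_sov > threshold.m,
    )


def score_screen(
    plate: pd.DataFrame, k_consistent: int = 3, include_controls_in_m: bool = False
) -> tuple[pd.DataFrame, dict[str, ScreenThreshold], list[GeneCall], list[ScreenQC]]:
    """Full screen pipeline: SoV -> M -> positives -> gene calls -> QC.

    Returns the concatenated per-line SoV/positive table, per-line
    thresholds, gene classifications and QC reports.
    """
    plate = validate_plate_table(plate)
    per_line = []
    thresholds: dict[str, ScreenThreshold] = {}
    qc: list[ScreenQC] = []
    for line in sorted(plate["cell_line"].unique()):
        sovs = compute_sov(plate, line)
        thr = dataset_threshold(sovs, line, include_controls=include_controls_in_m)
        called = call_positive(sovs, thr)
        thresholds[line] = thr
        per_line.append(called)
        if (sovs["target"] == POS_CONTROL).any():
            qc.append(screen_qc(called, thr))
    calls = pd.concat(per_line, ignore_index=True)
    genes = classify_genes(calls, k_consistent=k_consistent)
    return calls, thresholds, genes, qc


def calls_frame(genes: list[GeneCall]) -> pd.DataFrame:
    """Tabular view of gene calls (one row per gene)."""
    rows = []
    for g in genes:
        row = {
            "gene": g.gene,
            "hit_class": g.hit_class.value,
            "consistent_hit": g.consistent_hit,
            "n_lines": g.n_lines,
        }
        for sirna, count in sorted(g.per_sirna_lines_positive.items()):
            row[f"sirna_{sirna}_lines_positive"] = count
        rows.append(row)
    return pd.DataFrame(rows)
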