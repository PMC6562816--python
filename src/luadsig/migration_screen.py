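"""Scratch-wound migration analysis with loss-of-viability deconfounding.

Confluent monolayers are scratch-wounded and imaged by time-lapse
microscopy; each well yields a percent-wound-closure trajectory plus an
end-of-assay cell count.  Per cell line the analysis:

1. fixes the assay endpoint as the earliest time at which the mean
   closure of non-targeting control wells reaches a target (default
   90%), falling back with a warning to the last timepoint if it never
   does;
2. averages closure at that endpoint over replicates per siRNA, keeps
   the siRNAs whose means fall within one sample standard deviation of
   the four-siRNA mean (this set is provably non-empty for n >= 2), and
   averages the retained siRNAs to a per-gene mean closure;
3. expresses the gene's migration defect as percent suppression
   relative to control closure, and its loss of viability (LoV) as the
   percent reduction in endpoint cell count relative to control;
4. flags the gene as viability-confounded when LoV is both above an
   absolute floor (default 25%) and at least a fixed fraction (default
   0.75) of the migration suppression — the operational form of "LoV
   accounts for the observed suppression of wound closure".

Cell lines whose controls never approach the closure target (lines
that fail to migrate) are excluded from the batch analysis with a
warning.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .viability_screen import NEG_CONTROL

__all__ = [
    "SERIES_COLUMNS",
    "MigrationError",
    "NonMigratingLineWarning",
    "EndpointFallbackWarning",
    "MigrationGeneSummary",
    "Phenotype",
    "load_series_table",
    "select_endpoint",
    "compute_lov",
    "filter_within_sd",
    "closure_at",
    "summarize_gene_migration",
    "flag_confounded",
    "analyze_migration",
    "summaries_frame",
]

SERIES_COLUMNS = (
    "cell_line",
    "target",
    "sirna_id",
    "replicate_id",
    "time_h",
    "closure_pct",
    "endpoint_cell_count",
)


class MigrationError(ValueError):
    """Raised on malformed wound-series data."""


class EndpointFallbackWarning(UserWarning):
    """Controls never reached the closure target; last timepoint used."""


class NonMigratingLineWarning(UserWarning):
    """A cell line was excluded because its controls failed to migrate."""


class Phenotype(enum.Enum):
    MIGRATION = "migration"          # suppressed, not explained by LoV
    CONFOUNDED = "confounded"        # suppressed, explained by LoV
    VIABILITY_ONLY = "viability_only"  # high LoV without migration suppression
    NONE = "none"


@dataclass(frozen=True)
class MigrationGeneSummary:
    """Per-gene, per-line migration and viability summary."""

    cell_line: str
    gene: str
    endpoint_h: float
    per_sirna_mean_closure: dict[int, float]
    retained_sirnas: tuple[int, ...]
    mean_closure: float
    control_mean_closure: float
    mean_lov: float
    suppression: float
    suppressed: bool
    confounded: bool

    @property
    def phenotype(self) -> Phenotype:
        if self.suppressed:
            return Phenotype.CONFOUNDED if self.confounded else Phenotype.MIGRATION
        if self.confounded:
            return Phenotype.VIABILITY_ONLY
        return Phenotype.NONE


def load_series_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format wound-series CSV (header; '#' comments ignored).

    One row per well per timepoint; ``endpoint_cell_count`` may be
    filled on every row of a well or only on one.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise MigrationError(f"series table: missing columns {missing}")
    return df


def _well_series(df: pd.DataFrame, t0_tolerance: float = 5.0) -> pd.DataFrame:
    """Validate per-well trajectories: ascending times, closure(0) ~ 0."""
    for (line, target, sirna, rep), grp in df.groupby(
        ["cell_line", "target", "sirna_id", "replicate_id"], dropna=False
    ):
        t = grp["time_h"].to_numpy(dtype=float)
        if not np.all(np.diff(np.sort(t)) > 0):
            raise MigrationError(
                f"duplicate timepoints in well ({line}, {target}, siRNA {sirna}, rep {rep})"
            )
        grp = grp.sort_values("time_h")
        if grp["time_h"].iloc[0] == 0 and abs(grp["closure_pct"].iloc[0]) > t0_tolerance:
            warnings.warn(
                f"well ({line}, {target}, siRNA {sirna}, rep {rep}): "
                f"closure at t=0 is {grp['closure_pct'].iloc[0]:.1f}%, expected ~0",
                UserWarning,
                stacklevel=3,
            )
    return df


def select_endpoint(
    control: pd.DataFrame, target_closure: float = 90.0
) -> tuple[float, bool]:
    """Earliest time at which mean control closure reaches the target.

    ``control`` holds the NEG_CONTROL rows of one cell line.  Returns
    ``(endpoint_h, reached)``; when the target is never reached the
    last common timepoint is returned with an
    :class:`EndpointFallbackWarning`.
    """
    if control.empty:
        raise MigrationError("no control series supplied for endpoint selection")
    mean_by_time = control.groupby("time_h")["closure_pct"].mean().sort_index()
    crossed = mean_by_time[mean_by_time >= target_closure]
    if not crossed.empty:
        return float(crossed.index[0]), True
    last = float(mean_by_time.index[-1])
    warnings.warn(
        f"control closure never reached {target_closure:.0f}% "
        f"(max {mean_by_time.max():.1f}%); using last timepoint {last:g} h",
        EndpointFallbackWarning,
        stacklevel=2,
    )
    return last, False


def compute_lov(counts, control_mean_count: float):
    """Percent loss of viability from endpoint cell counts.

    ``lov = 100 * (1 - mean(counts) / control_mean_count)``; negative
    values (overgrowth relative to control) are preserved.
    """
    if control_mean_count <= 0:
        raise MigrationError("control mean endpoint count must be > 0")
    return float(100.0 * (1.0 - np.mean(counts) / control_mean_count))


def filter_within_sd(values: Sequence[float]) -> tuple[list[float], list[int]]:
    """Keep values within one sample SD (ddof=1) of the mean of all.

    Returns ``(retained_values, retained_indices)``.  For any finite
    sample of n >= 2 at least one value lies within one sample SD of
    the mean, so the retained set is never empty; with SD = 0 (all
    values equal) everything is retained.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise MigrationError(f"need at least 2 per-siRNA values, got {vals.size}")
    mean = vals.mean()
    sd = vals.std(ddof=1)
    mask = np.abs(vals - mean) <= sd
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        # mathematically impossible (the closest point is always within one
        # sample SD); reachable only through floating underflow at subnormal
        # scales — fall back to the value nearest the mean
        idx = np.array([int(np.argmin(np.abs(vals - mean)))])
    return vals[idx].tolist(), idx.tolist()


def closure_at(well: pd.DataFrame, endpoint_h: float) -> float:
    """Closure of one well at the endpoint (linear interpolation)."""
    w = well.sort_values("time_h")
    return float(
        np.interp(endpoint_h, w["time_h"].to_numpy(float), w["closure_pct"].to_numpy(float))
    )


def _endpoint_counts(df: pd.DataFrame) -> pd.Series:
    """One endpoint cell count per well (first non-null per well)."""
    return (
        df.dropna(subset=["endpoint_cell_count"])
        .groupby(["target", "sirna_id", "replicate_id"], dropna=False)["endpoint_cell_count"]
        .first()
    )


def flag_confounded(
    suppression: float, mean_lov: float, lov_floor: float = 25.0, lov_ratio: float = 0.75
) -> bool:
    """LoV explains the migration defect: above floor and >= ratio x suppression."""
    return mean_lov >= lov_floor and mean_lov >= lov_ratio * suppression


def summarize_gene_migration(
    gene_df: pd.DataFrame,
    endpoint_h: float,
    control_mean_closure: float,
    control_mean_count: float,
    s_min: float = 20.0,
    lov_floor: float = 25.0,
    lov_ratio: float = 0.75,
    lov_on_retained: bool = True,
) -> MigrationGeneSummary:
    """Summarise one gene of one cell line at the fixed endpoint.

    Closure per siRNA is the replicate mean at the endpoint; the
    within-one-SD filter selects the retained siRNAs, whose mean gives
    the gene's closure and (by default, switchable) its LoV.
    Suppression is relative to control closure; ``suppressed`` applies
    the ``s_min`` cut and ``confounded`` the two-parameter LoV rule.
    """
    if gene_df.empty:
        raise MigrationError("empty gene series")
    gene = str(gene_df["target"].iloc[0])
    line = str(gene_df["cell_line"].iloc[0])
    if control_mean_closure <= 0:
        raise MigrationError(f"{line}: control mean closure must be > 0")

    per_sirna_closure: dict[int, float] = {}
    per_sirna_lov: dict[int, float] = {}
    counts = _endpoint_counts(gene_df)
    for sirna, sgrp in gene_df.groupby("sirna_id"):
        reps = [closure_at(w, endpoint_h) for _, w in sgrp.groupby("replicate_id")]
        per_sirna_closure[int(sirna)] = float(np.mean(reps))
        well_counts = counts.xs(sirna, level="sirna_id").to_numpy(float)
        per_sirna_lov[int(sirna)] = compute_lov(well_counts, control_mean_count)

    sirnas = sorted(per_sirna_closure)
    _, kept_idx = filter_within_sd([per_sirna_closure[s] for s in sirnas])
    retained = tuple(sirnas[i] for i in kept_idx)
    mean_closure = float(np.mean([per_sirna_closure[s] for s in retained]))
    lov_pool = retained if lov_on_retained else tuple(sirnas)
    mean_lov = float(np.mean([per_sirna_lov[s] for s in lov_pool]))
    suppression = float(100.0 * (1.0 - mean_closure / control_mean_closure))
    return MigrationGeneSummary(
        cell_line=line,
        gene=gene,
        endpoint_h=endpoint_h,
        per_sirna_mean_closure=per_sirna_closure,
        retained_sirnas=retained,
        mean_closure=mean_closure,
        control_mean_closure=control_mean_closure,
        mean_lov=mean_lov,
        suppression=suppression,
        suppressed=suppression >= s_min,
        confounded=flag_confounded(suppression, mean_lov, lov_floor, lov_ratio),
    )


def analyze_migration(
    series: pd.DataFrame,
    target_closure: float = 90.0,
    s_min: float = 20.0,
    lov_floor: float = 25.0,
    lov_ratio: float = 0.75,
    lov_on_retained: bool = True,
    exclude_nonmigrating: bool = True,
) -> list[MigrationGeneSummary]:
    """Batch migration analysis across cell lines.

    Per line: endpoint from the negative controls, then one summary per
    gene.  Lines whose controls never reach ``target_closure`` are
    skipped with a :class:`NonMigratingLineWarning` (set
    ``exclude_nonmigrating=False`` to analyse them at the last
    timepoint instead).
    """
    _well_series(series)
    out: list[MigrationGeneSummary] = []
    for line in sorted(series["cell_line"].unique()):
        sub = series[series["cell_line"] == line]
        control = sub[sub["target"] == NEG_CONTROL]
        if control.empty:
            raise MigrationError(f"cell line {line!r} has no {NEG_CONTROL} series")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EndpointFallbackWarning)
            endpoint, reached = select_endpoint(control, target_closure)
        if not reached:
            if exclude_nonmigrating:
                warnings.warn(
                    f"cell line {line!r}: controls failed to migrate "
                    f"(never reached {target_closure:.0f}% closure); line excluded",
                    NonMigratingLineWarning,
                    stacklevel=2,
                )
                continue
            warnings.warn(
                f"cell line {line!r}: controls never reached {target_closure:.0f}%; "
                f"using last timepoint {endpoint:g} h",
                EndpointFallbackWarning,
                stacklevel=2,
            )
        ctrl_closure = float(
            np.mean([closure_at(w, endpoint) for _, w in control.groupby(
                ["sirna_id", "replicate_id"], dropna=False)])
        )
        ctrl_count = float(_endpoint_counts(control).mean())
        for gene, gdf in sub[sub["target"] != NEG_CONTROL].groupby("target", sort=True):
            out.append(
                summarize_gene_migration(
                    gdf,
                    endpoint,
                    control_mean_closure=ctrl_closure,
                    control_mean_count=ctrl_count,
                    s_min=s_min,
                    lov_floor=lov_floor,
                    lov_ratio=lov_ratio,
                    lov_on_retained=lov_on_retained,
                )
            )
    return out


def summaries_frame(summaries: list[MigrationGeneSummary]) -> pd.DataFrame:
    """Tabular view, one row per gene x cell line."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "cell_line": s.cell_line,
                "gene": s.gene,
                "endpoint_h": s.endpoint_h,
                "mean_closure": s.mean_closure,
                "control_mean_closure": s.control_mean_closure,
                "suppression": s.suppression,
                "mean_lov": s.mean_lov,
                "n_retained_sirnas": len(s.retained_sirnas),
                "suppressed": s.suppressed,
                "confounded": s.confounded,
                "phenotype": s.phenotype.value,
            }
        )
    return pd.DataFrame(rows)
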