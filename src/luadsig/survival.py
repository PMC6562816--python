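"""Median-split expression-survival association.

For each gene, patients are dichotomised at the median expression into
High (strictly above the median) and Low (at or below — ties go Low so
the High group is strictly elevated).  The two groups are compared by

* the Kaplan-Meier product-limit estimator of overall survival,
* the two-group logrank test (chi-square with 1 df), and
* a univariate Cox proportional-hazards fit of the High-vs-Low
  indicator, reporting the hazard ratio HR = exp(beta) with a 95% Wald
  confidence interval.

Ties between event times use Efron's approximation by default
(Breslow's by config).  The Cox fit is a one-parameter Newton iteration
on the partial likelihood written out explicitly below; a monotone
partial likelihood (all events separate the groups) is detected and
flagged with an unbounded confidence interval rather than reported as a
finite estimate.  KM curves and the logrank test are delegated to
lifelines.

A gene measured by several probes is summarised by the median
hazard ratio over probes; on even probe counts the lower median is used
so the reported CI and p value always belong to an actually fitted
probe.  Significance is fixed at logrank p < 0.05 with no
multiple-testing correction; a Benjamini-Hochberg FDR column is emitted
alongside for reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SurvivalError",
    "KMCurve",
    "CoxResult",
    "SurvivalAssociation",
    "median_split",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "summarize_probes",
    "batch_associate",
    "load_cohort_table",
    "plot_km",
]

ALL_SUBGROUP = "all"
_Z95 = float(stats.norm.ppf(0.975))


class SurvivalError(ValueError):
    """Raised on degenerate survival inputs."""


# ---------------------------------------------------------------------------
# median split
# ---------------------------------------------------------------------------

def median_split(values: Mapping[str, float] | pd.Series) -> tuple[list[str], list[str]]:
    """Partition patients into High (> median) and Low (<= median).

    Returns ``(high_ids, low_ids)``.  Raises when fewer than 2 patients
    or when all values are identical (degenerate split).
    """
    s = pd.Series(values, dtype=float)
    if len(s) < 2:
        raise SurvivalError("median split needs at least 2 patients")
    med = float(np.median(s.to_numpy()))
    if float(s.max()) == float(s.min()):
        raise SurvivalError("all expression values identical; median split is degenerate")
    high = s.index[s > med].tolist()
    low = s.index[s <= med].tolist()
    return high, low


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Right-continuous product-limit survival step function."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time

    def at(self, t: float) -> float:
        """S(t); 1.0 before the first event, step-down thereafter."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    __call__ = at


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimate from times and event indicators."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise SurvivalError("cannot estimate survival from an empty sample")
    if np.any(t <= 0):
        raise SurvivalError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(t[e])
    surv = np.array([float(sf.loc[:x].iloc[-1]) for x in event_times])
    return KMCurve(times=event_times, survival=surv)


# ---------------------------------------------------------------------------
# logrank
# ---------------------------------------------------------------------------

def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group logrank test; returns (chi-square statistic, p value)."""
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, bool)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise SurvivalError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise SurvivalError("no events in either group; logrank test undefined")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# univariate Cox (binary group indicator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    monotone: bool  # complete separation: estimate diverges, CI unbounded


def _cox_tie_blocks(group, times, events):
    """Per distinct event time: (n0, n1 at risk; d0, d1 events)."""
    z = np.asarray(group, dtype=int)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    blocks = []
    for tj in np.unique(t[e]):
        at_risk = t >= tj
        dead = e & (t == tj)
        blocks.append(
            (
                int(np.sum(at_risk & (z == 0))),
                int(np.sum(at_risk & (z == 1))),
                int(np.sum(dead & (z == 0))),
                int(np.sum(dead & (z == 1))),
            )
        )
    return blocks


def _cox_score_info(beta: float, blocks, ties: str) -> tuple[float, float]:
    """Score U(beta) and observed information I(beta) of the partial
    likelihood for a single binary covariate.

    Per event time with risk counts (n0, n1) and death counts (d0, d1),
    Efron's approximation contributes d terms with risk sums depleted by
    l/d of the deaths (l = 0..d-1); Breslow's uses the full risk sum d
    times.  Each term has the form log(a + b*x) with x = exp(beta),
    a and b the group-0 / group-1 effective risk counts.
    """
    x = np.exp(beta)
    score = 0.0
    info = 0.0
    for n0, n1, d0, d1 in blocks:
        d = d0 + d1
        score += d1  # sum of covariates over deaths
        for l in range(d):
            frac = l / d if ties == "efron" else 0.0
            a = n0 - frac * d0
            b = n1 - frac * d1
            denom = a + b * x
            mu = b * x / denom          # E[z | risk set]
            score -= mu
            info += mu * (1.0 - mu)     # Var[z | risk set]
    return score, info


def cox_univariate(
    group: Sequence[int],
    times: Sequence[float],
    events: Sequence[bool],
    ties: str = "efron",
    alpha: float = 0.05,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Cox proportional-hazards fit of a binary group indicator.

    ``group`` is 0/1 (e.g. Low/High expression).  Returns the hazard
    ratio exp(beta) maximising the partial likelihood (Efron or Breslow
    tie handling) with a Wald ``1 - alpha`` CI.  When the likelihood is
    monotone (events completely separate the groups) the fit is flagged
    and the CI reported unbounded on the diverging side.
    """
    if ties not in ("efron", "breslow"):
        raise SurvivalError(f"unknown tie handling {ties!r}")
    z = np.asarray(group, dtype=int)
    e = np.asarray(events, dtype=bool)
    if not set(np.unique(z)) <= {0, 1}:
        raise SurvivalError("group indicator must be 0/1")
    if e[z == 0].sum() == 0 or e[z == 1].sum() == 0:
        raise SurvivalError("both groups need at least one event")
    blocks = _cox_tie_blocks(z, times, e)

    beta = 0.0
    z_crit = float(stats.norm.ppf(1 - alpha / 2))
    for _ in range(max_iter):
        score, info = _cox_score_info(beta, blocks, ties)
        if info <= 0:
            break
        step = score / info
        # damp huge steps; divergence is detected by |beta| instead
        step = float(np.clip(step, -5.0, 5.0))
        beta += step
        if abs(step) < tol or abs(beta) > 25.0:
            break

    monotone = abs(beta) > 20.0
    score, info = _cox_score_info(beta, blocks, ties)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    if monotone:
        hr = float(np.exp(np.sign(beta) * np.inf))  # 0.0 or inf
        ci = (0.0, float("inf"))
        return CoxResult(hr=hr, ci_low=ci[0], ci_high=ci[1], beta=beta, se=se, monotone=True)
    hr = float(np.exp(beta))
    return CoxResult(
        hr=hr,
        ci_low=float(np.exp(beta - z_crit * se)),
        ci_high=float(np.exp(beta + z_crit * se)),
        beta=float(beta),
        se=se,
        monotone=False,
    )


# ---------------------------------------------------------------------------
# gene-level association
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalAssociation:
    """Median-split association of one gene in one patient subgroup."""

    gene: str
    subgroup: str
    n: int
    hr: float
    ci_low: float
    ci_high: float
    logrank_p: float
    significant: bool
    probe: str | None = None
    monotone: bool = False

    @property
    def harmful(self) -> bool:
        return self.significant and self.hr > 1.0


def _associate_one(
    expr: pd.Series,
    times: pd.Series,
    events: pd.Series,
    gene: str,
    subgroup: str,
    alpha: float,
    ties: str,
    probe: str | None = None,
) -> SurvivalAssociation:
    high, low = median_split(expr)
    grp = expr.index.isin(high).astype(int)
    stat, p = logrank_test(
        times[expr.index[grp == 1]], events[expr.index[grp == 1]],
        times[expr.index[grp == 0]], events[expr.index[grp == 0]],
    )
    cox = cox_univariate(grp, times[expr.index], events[expr.index], ties=ties)
    return SurvivalAssociation(
        gene=gene,
        subgroup=subgroup,
        n=len(expr),
        hr=cox.hr,
        ci_low=cox.ci_low,
        ci_high=cox.ci_high,
        logrank_p=p,
        significant=p < alpha,
        probe=probe,
        monotone=cox.monotone,
    )


def summarize_probes(assocs: Sequence[SurvivalAssociation]) -> SurvivalAssociation:
    """Median-HR summary of a multi-probe gene.

    Probes are ranked by HR; the median probe (lower median on even
    counts) supplies the reported HR, CI and p so the summary always
    corresponds to one real fit.
    """
    if not assocs:
        raise SurvivalError("no probe associations to summarise")
    ranked = sorted(assocs, key=lambda a: a.hr)
    chosen = ranked[(len(ranked) - 1) // 2]
    return SurvivalAssociation(
        gene=chosen.gene,
        subgroup=chosen.subgroup,
        n=chosen.n,
        hr=chosen.hr,
        ci_low=chosen.ci_low,
        ci_high=chosen.ci_high,
        logrank_p=chosen.logrank_p,
        significant=chosen.significant,
        probe=chosen.probe,
        monotone=chosen.monotone,
    )


def load_cohort_table(path) -> pd.DataFrame:
    """Read a cohort TSV: patient_id, time_months, event, subgroup, then
    one column per probe/gene."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["patient_id", "time_months", "event", "subgroup"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurvivalError(f"cohort table: missing columns {missing}")
    if (df["time_months"] <= 0).any():
        bad = df.loc[df["time_months"] <= 0, "patient_id"].iloc[0]
        raise SurvivalError(f"non-positive survival time for patient {bad!r}")
    return df.set_index("patient_id")


def batch_associate(
    cohort: pd.DataFrame,
    panel: Sequence[str],
    subgroups: Sequence[str] | None = None,
    probe_map: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    min_patients: int = 20,
    ties: str = "efron",
) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """One association per gene x subgroup, plus per-subgroup counts.

    ``cohort`` is indexed by patient with columns ``time_months``,
    ``event``, ``subgroup`` and one column per probe/gene.  ``panel``
    lists gene symbols; ``probe_map`` (probe column -> gene) routes
    multi-probe genes through :func:`summarize_probes`.  The special
    subgroup ``"all"`` is the whole cohort.  Subgroups below
    ``min_patients`` are skipped with a warning.  Returns the
    association table (with a BH-FDR column per subgroup) and counts of
    significant / harmful (HR > 1) / protective (HR < 1) genes.
    """
    if subgroups is None:
        subgroups = [ALL_SUBGROUP] + sorted(cohort["subgroup"].dropna().unique())
    probe_cols: dict[str, list[str]] = {}
    for g in panel:
        if probe_map:
            cols = [p for p, gg in probe_map.items() if gg == g]
        else:
            cols = []
        probe_cols[g] = cols or [g]
    missing = [c for cols in probe_cols.values() for c in cols if c not in cohort.columns]
    if missing:
        raise SurvivalError(f"cohort table lacks expression columns {missing}")

    rows: list[SurvivalAssociation] = []
    counts: dict[str, dict[str, int]] = {}
    for sg in subgroups:
        sub = cohort if sg == ALL_SUBGROUP else cohort[cohort["subgroup"] == sg]
        if len(sub) < min_patients:
            warnings.warn(
                f"subgroup {sg!r} has {len(sub)} patients (< {min_patients}); skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        times, events = sub["time_months"], sub["event"].astype(bool)
        sg_rows: list[SurvivalAssociation] = []
        for gene in panel:
            per_probe = [
                _associate_one(sub[c].astype(float), times, events, gene, sg, alpha, ties, probe=c)
                for c in probe_cols[gene]
            ]
            sg_rows.append(per_probe[0] if len(per_probe) == 1 else summarize_probes(per_probe))
        rows.extend(sg_rows)
        counts[sg] = {
            "n_significant": sum(a.significant for a in sg_rows),
            "n_harmful": sum(a.significant and a.hr > 1 for a in sg_rows),
            "n_protective": sum(a.significant and a.hr < 1 for a in sg_rows),
        }

    table = pd.DataFrame(
        {
            "gene": [a.gene for a in rows],
            "subgroup": [a.subgroup for a in rows],
            "n": [a.n for a in rows],
            "hr": [a.hr for a in rows],
            "ci_low": [a.ci_low for a in rows],
            "ci_high": [a.ci_high for a in rows],
            "logrank_p": [a.logrank_p for a in rows],
            "significant": [a.significant for a in rows],
            "probe": [a.probe for a in rows],
            "monotone": [a.monotone for a in rows],
        }
    )
    if not table.empty:
        table["fdr_bh"] = np.nan
        for sg in table["subgroup"].unique():
            mask = table["subgroup"] == sg
            table.loc[mask, "fdr_bh"] = multipletests(
                table.loc[mask, "logrank_p"], method="fdr_bh"
            )[1]
    return table, counts


def plot_km(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
    ax=None,
    labels: tuple[str, str] = ("Low", "High"),
):
    """Two-group KM plot (High in red, Low in black); returns the axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    g = np.asarray(group, int)
    for val, label, colour in ((0, labels[0], "black"), (1, labels[1], "red")):
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == val], event_observed=e[g == val], label=label)
        kmf.plot_survival_function(ax=ax, color=colour, ci_show=False)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival")
    return ax
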