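"""Seeded generators for every input the pipeline consumes.

Each generator emulates one of the study's data layers with planted
ground truth so every downstream stage can be exercised and its
recovery measured without external data:

* ``gen_de_table``       — a differential-expression table plus
  human-evidence annotations with a planted signature: planted genes
  satisfy all three signature predicates (FC >= 2.5, FDR < 0.05, human
  evidence), decoys violate at least one.
* ``gen_screen``         — siRNA viability-screen plates: nuclei counts
  from an overdispersed (negative-binomial) count model, planted
  essential genes suppressed on exactly 3 of 4 siRNAs (the same 3 in
  every cell line), plus non-targeting negative and pan-lethal positive
  controls.
* ``gen_migration``      — scratch-wound closure trajectories from
  three-parameter logistic curves with additive noise: planted
  migration suppressors (reduced closure, normal viability), planted
  viability-confounded genes (reduced closure *and* high loss of
  viability) and neutral genes; optionally one discordant siRNA per
  affected gene to exercise the within-one-SD filter.
* ``gen_survival_cohort`` — a patient cohort with standard-normal
  expression per gene and exponential event times whose hazard is
  multiplied by the planted HR for patients above that gene's median
  (so the planted HR is exactly the median-split estimand when a single
  gene is planted); censoring is independent uniform on (0, tau) with
  tau solved so the expected censored fraction matches the config.

All randomness flows from ``SimulationConfig.seed`` through
``numpy.random.SeedSequence`` children (one fixed child per generator),
so identical configs give identical outputs.  Writers stamp the seed
into a ``#`` header comment of every file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "gen_de_table",
    "gen_screen",
    "gen_migration",
    "gen_survival_cohort",
    "gen_all",
    "write_table",
]

_DE_CHILD, _SCREEN_CHILD, _MIGRATION_CHILD, _SURVIVAL_CHILD = 0, 1, 2, 3


class SimulationError(ValueError):
    """Raised on inconsistent simulation configs."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for all generators.

    Defaults mirror the modelled screens: a 52-gene signature drawn from
    ~500 detected genes; 3 NSCLC cell lines screened with 4 siRNAs per
    gene in technical quadruplicate at ~2000 nuclei per control well
    with ~10% count CV; planted essential genes losing 40 SoV points on
    3 of 4 siRNAs; two migration lines with logistic wound closure over
    46 h / 20 h; survival cohorts of 1000 patients per subgroup with
    exponential event times (median ~35 months untreated) and 20%
    uniform censoring.
    """

    seed: int = 0

    # --- DE table / signature ---
    n_genes: int = 500
    n_signature: int = 52
    fc_log_loc: float = 0.5      # log-normal location of the FC excess over 2.5
    fc_log_scale: float = 0.8
    base_count_mean: float = 300.0

    # --- viability screen ---
    n_screen_genes: int = 52
    n_essential: int = 4
    n_lines: int = 3
    n_sirnas: int = 4
    n_replicates: int = 4
    n_neg_control_wells: int = 8
    n_pos_control_wells: int = 4
    control_count_mean: float = 2000.0
    count_dispersion: float = 0.01   # NB: var = mu + dispersion * mu^2  (~10% CV)
    essential_sov: float = 40.0      # SoV points removed by an effective siRNA
    effective_sirna_fraction: float = 0.75  # 3 of 4 siRNAs effective
    pos_control_sov: float = 80.0

    # --- migration screen ---
    n_migration_genes: int = 30
    n_suppressors: int = 3
    n_confounded: int = 2
    migration_lines: tuple[str, ...] = ("LINE_A", "LINE_B")
    migration_duration_h: tuple[float, ...] = (46.0, 20.0)
    migration_replicates: int = 3
    closure_plateau: float = 98.0
    closure_rate: float = 0.35       # logistic rate, 1/h (scaled per line duration)
    closure_noise_sd: float = 2.0
    suppressor_plateau_fraction: float = 0.4
    suppressor_lov: float = 5.0
    confounded_lov: float = 55.0
    lov_noise_sd: float = 3.0
    migration_endpoint_count: float = 2000.0
    discordant_sirna: bool = False   # one of 4 siRNAs behaves like control

    # --- survival cohort ---
    n_patients: int = 1000
    survival_subgroups: tuple[str, ...] = ("adeno",)
    n_panel_genes: int = 50
    n_harmful: int = 5
    harmful_hr: float = 2.0
    baseline_hazard: float = 0.02    # events per month; median ~ 35 months
    censoring_fraction: float = 0.2
    n_multiprobe: int = 0            # first n harmful genes get 3 probes each
    probe_noise_sd: float = 0.3

    def validate(self) -> "SimulationConfig":
        if self.n_signature > self.n_genes:
            raise SimulationError("n_signature cannot exceed n_genes")
        if not 0 <= self.censoring_fraction < 1:
            raise SimulationError("censoring_fraction must be in [0, 1)")
        if self.control_count_mean <= 0:
            raise SimulationError("control_count_mean must be > 0")
        if not 0 <= self.effective_sirna_fraction <= 1:
            raise SimulationError("effective_sirna_fraction must be in [0, 1]")
        if self.n_essential > self.n_screen_genes:
            raise SimulationError("n_essential cannot exceed n_screen_genes")
        if self.n_suppressors + self.n_confounded > self.n_migration_genes:
            raise SimulationError("planted migration genes exceed n_migration_genes")
        if self.n_harmful > self.n_panel_genes:
            raise SimulationError("n_harmful cannot exceed n_panel_genes")
        return self

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw).validate()

    def rng(self, child: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(4)[child])


def write_table(df: pd.DataFrame, path: str | Path, seed: int, sep: str = "\t") -> Path:
    """Write a table with a seed-stamping '#' header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# seed = {seed}\n")
        df.to_csv(fh, sep=sep, index=False)
    return path


# ---------------------------------------------------------------------------
# DE table
# ---------------------------------------------------------------------------

def gen_de_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Synthesise a DE table, evidence table and planted-truth table.

    Planted signature genes draw FC >= 2.5, FDR < 0.05 and passing
    evidence; each decoy violates at least one predicate (chosen at
    random, possibly several).  Returns ``(de, evidence, truth)``.
    """
    config.validate()
    rng = config.rng(_DE_CHILD)
    n, k = config.n_genes, config.n_signature
    genes = [f"G{i:04d}" for i in range(1, n + 1)]
    planted = set(genes[:k])

    rows, ev_rows, truth = [], [], []
    amp_pass = ["Y", "Y > 7%", "Y(SCC)", "<1%"]
    for g in genes:
        is_planted = g in planted
        if is_planted:
            fc = 2.5 + float(rng.lognormal(config.fc_log_loc, config.fc_log_scale))
            fdr = float(10 ** rng.uniform(-26, np.log10(0.049)))
            amp = str(rng.choice(amp_pass))
            overex = "Y"
        else:
            # violate a random non-empty subset of the three predicates
            viol = rng.random(3) < 0.6
            if not viol.any():
                viol[rng.integers(3)] = True
            fc = float(rng.uniform(1.0, 2.45)) if viol[0] else 2.5 + float(
                rng.lognormal(config.fc_log_loc, config.fc_log_scale)
            )
            fdr = float(rng.uniform(0.05, 0.5)) if viol[1] else float(
                10 ** rng.uniform(-26, np.log10(0.049))
            )
            if viol[2]:
                amp, overex = ("N", "N") if rng.random() < 0.5 else ("No data", "N")
            else:
                amp, overex = str(rng.choice(amp_pass)), "Y"
        base = rng.poisson(config.base_count_mean) + 1
        neg_lo, neg_hi = sorted(rng.poisson([base * 0.7, base * 1.3]) + 1)
        pos_lo, pos_hi = sorted(rng.poisson([base * 0.7 * fc, base * 1.3 * fc]) + 1)
        rows.append(
            {
                "gene_symbol": g,
                "gene_name": f"synthetic gene {g}",
                "reads_perk_neg": f"{neg_lo}–{neg_hi}",
                "reads_perk_pos": f"{pos_lo}–{pos_hi}",
                "mean_fc": round(fc, 2),
                "fdr": fdr,
            }
        )
        ev_rows.append({"gene_symbol": g, "amp_nsclc": amp, "overex_nsclc": overex})
        truth.append({"gene_symbol": g, "planted": is_planted})
    return pd.DataFrame(rows), pd.DataFrame(ev_rows), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# viability screen
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def gen_screen(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesise screen plates and the planted-truth table.

    Essential genes have ``essential_sov`` removed from the well mean on
    the first ``round(effective_sirna_fraction * n_sirnas)`` siRNAs —
    the same siRNA ids in every cell line, matching the concordance rule
    under test.  Returns ``(plate, truth)``.
    """
    config.validate()
    rng = config.rng(_SCREEN_CHILD)
    n_eff = int(round(config.effective_sirna_fraction * config.n_sirnas))
    genes = [f"SCR{i:03d}" for i in range(1, config.n_screen_genes + 1)]
    essentials = set(genes[: config.n_essential])
    lines = [f"CL{i}" for i in range(1, config.n_lines + 1)]

    rows = []
    for line in lines:
        for ctrl, n_wells, sov in (
            ("NEG_CONTROL", config.n_neg_control_wells, 0.0),
            ("POS_CONTROL", config.n_pos_control_wells, config.pos_control_sov),
        ):
            mu = config.control_count_mean * (1 - sov / 100.0)
            counts = _nb_counts(rng, mu, config.count_dispersion, size=n_wells)
            for rep, c in enumerate(counts, start=1):
                rows.append(
                    {"cell_line": line, "target": ctrl, "sirna_id": "",
                     "replicate_id": rep, "nuclei_count": int(c)}
                )
        for gene in genes:
            for sirna in range(1, config.n_sirnas + 1):
                sov = config.essential_sov if (gene in essentials and sirna <= n_eff) else 0.0
                mu = config.control_count_mean * (1 - sov / 100.0)
                counts = _nb_counts(rng, mu, config.count_dispersion, size=config.n_replicates)
                for rep, c in enumerate(counts, start=1):
                    rows.append(
                        {"cell_line": line, "target": gene, "sirna_id": sirna,
                         "replicate_id": rep, "nuclei_count": int(c)}
                    )
    truth = pd.DataFrame(
        {
            "gene": genes,
            "essential": [g in essentials for g in genes],
            "effective_sirnas": [
                ",".join(map(str, range(1, n_eff + 1))) if g in essentials else ""
                for g in genes
            ],
        }
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# migration screen
# ---------------------------------------------------------------------------

def _logistic_closure(t: np.ndarray, plateau: float, rate: float, midpoint: float) -> np.ndarray:
    """Three-parameter logistic wound closure, normalised so c(0) = 0."""
    raw = 1.0 / (1.0 + np.exp(-rate * (t - midpoint)))
    raw0 = 1.0 / (1.0 + np.exp(rate * midpoint))
    return plateau * (raw - raw0) / (1.0 - raw0)


def gen_migration(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesise wound-closure series and the planted-truth table.

    Gene classes: ``suppressor`` (plateau scaled by
    ``suppressor_plateau_fraction``, LoV ~ ``suppressor_lov``),
    ``confounded`` (same reduced closure, LoV ~ ``confounded_lov``),
    ``neutral`` (control-like).  With ``discordant_sirna`` set, siRNA 4
    of every non-neutral gene behaves like control so the within-one-SD
    filter has something to drop.  Returns ``(series, truth)``.
    """
    config.validate()
    rng = config.rng(_MIGRATION_CHILD)
    genes = [f"MIG{i:03d}" for i in range(1, config.n_migration_genes + 1)]
    classes = {}
    for i, g in enumerate(genes):
        if i < config.n_suppressors:
            classes[g] = "suppressor"
        elif i < config.n_suppressors + config.n_confounded:
            classes[g] = "confounded"
        else:
            classes[g] = "neutral"

    rows = []
    for line, duration in zip(config.migration_lines, config.migration_duration_h):
        times = np.arange(0.0, duration + 1e-9, 2.0)
        midpoint = duration * 0.35
        rate = config.closure_rate * (46.0 / duration)  # comparable shape per line
        control_curve = _logistic_closure(times, config.closure_plateau, rate, midpoint)

        def emit(target, sirna, rep, plateau, lov):
            curve = _logistic_closure(times, plateau, rate, midpoint)
            noise = rng.normal(0.0, config.closure_noise_sd, size=times.size)
            closure = np.clip(curve + noise, 0.0, 110.0)
            closure[0] = 0.0
            count = config.migration_endpoint_count * (1 - lov / 100.0)
            count = max(0.0, rng.normal(count, count * 0.05))
            for t, c in zip(times, closure):
                rows.append(
                    {"cell_line": line, "target": target, "sirna_id": sirna,
                     "replicate_id": rep, "time_h": t, "closure_pct": round(float(c), 3),
                     "endpoint_cell_count": int(count)}
                )

        for rep in range(1, config.migration_replicates + 1):
            for sirna in range(1, config.n_sirnas + 1):
                emit("NEG_CONTROL", sirna, rep, config.closure_plateau, 0.0)
        for g in genes:
            cls = classes[g]
            for sirna in range(1, config.n_sirnas + 1):
                discordant = (
                    config.discordant_sirna and cls != "neutral" and sirna == config.n_sirnas
                )
                if cls == "neutral" or discordant:
                    plateau, lov0 = config.closure_plateau, 0.0
                elif cls == "suppressor":
                    plateau = config.closure_plateau * config.suppressor_plateau_fraction
                    lov0 = config.suppressor_lov
                else:  # confounded
                    plateau = config.closure_plateau * config.suppressor_plateau_fraction
                    lov0 = config.confounded_lov
                for rep in range(1, config.migration_replicates + 1):
                    lov = float(rng.normal(lov0, config.lov_noise_sd))
                    emit(g, sirna, rep, plateau, lov)

    truth = pd.DataFrame({"gene": genes, "class": [classes[g] for g in genes]})
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# survival cohort
# ---------------------------------------------------------------------------

def _uniform_censor_tau(rates: np.ndarray, fraction: float) -> float:
    """Upper bound tau of Uniform(0, tau) censoring giving the target
    expected censored fraction for exponential event times."""

    def censored_fraction(tau: float) -> float:
        lt = rates * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt))

    lo, hi = 1e-9, 1e9
    return float(brentq(lambda tau: censored_fraction(tau) - fraction, lo, hi, xtol=1e-8))


def gen_survival_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Synthesise a survival cohort, truth table and probe map.

    Expression is standard normal per gene; each patient's exponential
    hazard is the baseline multiplied by the planted HR of every
    harmful gene for which the patient sits above that gene's median.
    Censoring is independent Uniform(0, tau), tau solved so the
    expected censored fraction equals ``censoring_fraction``.  The
    first ``n_multiprobe`` harmful genes are additionally emitted as 3
    correlated probe columns each.  Returns
    ``(cohort, truth, probe_map)``.
    """
    config.validate()
    rng = config.rng(_SURVIVAL_CHILD)
    genes = [f"SURV{i:03d}" for i in range(1, config.n_panel_genes + 1)]
    harmful = genes[: config.n_harmful]
    log_hr = {g: (np.log(config.harmful_hr) if g in harmful else 0.0) for g in genes}

    frames = []
    for sg in config.survival_subgroups:
        n = config.n_patients
        expr = pd.DataFrame(
            rng.standard_normal((n, len(genes))),
            columns=genes,
            index=[f"{sg[:2].upper()}{i:05d}" for i in range(1, n + 1)],
        )
        eta = np.zeros(n)
        for g in harmful:
            high = (expr[g] > expr[g].median()).to_numpy()
            eta += log_hr[g] * high
        rates = config.baseline_hazard * np.exp(eta)
        event_time = rng.exponential(1.0 / rates)
        if config.censoring_fraction > 0:
            tau = _uniform_censor_tau(rates, config.censoring_fraction)
            censor_time = rng.uniform(0.0, tau, size=n)
            time = np.minimum(event_time, censor_time)
            event = event_time <= censor_time
        else:
            time, event = event_time, np.ones(n, dtype=bool)
        df = pd.DataFrame(
            {
                "patient_id": expr.index,
                "time_months": np.maximum(time, 1e-6),
                "event": event.astype(int),
                "subgroup": sg,
            }
        )
        probe_map = {}
        expr_cols: dict[str, np.ndarray] = {}
        for g in genes:
            if g in harmful[: config.n_multiprobe]:
                for j in range(1, 4):
                    col = f"{g}_probe{j}"
                    expr_cols[col] = expr[g].to_numpy() + rng.normal(
                        0, config.probe_noise_sd, size=n
                    )
                    probe_map[col] = g
            else:
                expr_cols[g] = expr[g].to_numpy()
                probe_map[g] = g
        frames.append(pd.concat([df, pd.DataFrame(expr_cols)], axis=1))
    cohort = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "planted_hr": [float(np.exp(log_hr[g])) for g in genes],
            "harmful": [g in harmful for g in genes],
        }
    )
    return cohort, truth, probe_map


# ---------------------------------------------------------------------------
# one-stop generation
# ---------------------------------------------------------------------------

def gen_all(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate every input + truth file under ``outdir``; returns paths."""
    config.validate()
    outdir = Path(outdir)
    de, ev, de_truth = gen_de_table(config)
    plate, screen_truth = gen_screen(config)
    series, mig_truth = gen_migration(config)
    cohort, surv_truth, probe_map = gen_survival_cohort(config)
    paths = {
        "de": write_table(de, outdir / "de_table.tsv", config.seed),
        "evidence": write_table(ev, outdir / "evidence.tsv", config.seed),
        "de_truth": write_table(de_truth, outdir / "de_truth.tsv", config.seed),
        "plate": write_table(plate, outdir / "screen_plates.csv", config.seed, sep=","),
        "screen_truth": write_table(screen_truth, outdir / "screen_truth.tsv", config.seed),
        "series": write_table(series, outdir / "wound_series.csv", config.seed, sep=","),
        "migration_truth": write_table(mig_truth, outdir / "migration_truth.tsv", config.seed),
        "cohort": write_table(cohort, outdir / "cohort.tsv", config.seed),
        "survival_truth": write_table(surv_truth, outdir / "survival_truth.tsv", config.seed),
        "probe_map": write_table(
            pd.DataFrame(
                {"probe": list(probe_map), "gene": [probe_map[p] for p in probe_map]}
            ),
            outdir / "probe_map.tsv",
            config.seed,
        ),
    }
    return paths
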