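# Methods

This note records the statistical procedures, parameter choices and
simulator models behind `luadsig`, including the decisions taken where
the underlying screen protocols leave the formalisation open.

## Signature derivation

A gene enters the progression signature when all three predicates hold:

* `mean_fc >= fc_min` — default 2.5, **inclusive**: the packaged
  progression table retains a gene at exactly 2.50, so the cutoff must
  admit the boundary;
* `fdr < fdr_max` — default 0.05, **exclusive**: the table's largest
  retained FDR is 4.9e-02;
* human evidence of amplification and/or overexpression in NSCLC,
  implemented as a logical OR over the two annotation columns. Any
  positive amplification annotation counts — including "SCC only" and
  "<1% of cases" — because the packaged table retains genes (e.g.
  Porcn, Vcam1) whose only evidence is a <1% amplification call. A
  `strict_evidence` switch demotes SCC-only and <1% amplification to
  "evidence only if the overexpression flag is also yes"; on the
  packaged table this drops Dlk1, Porcn and Vcam1 (52 → 49 genes).

Ordering is by descending fold change with alphabetical tie-break, so
output is reproducible under permutation of the input. Read-count
ranges are annotation only: the upstream normalisation is not modelled,
and differential-expression calling (fold changes, FDRs) is consumed as
a trusted input, never recomputed. Range strings accept en dash, em
dash or hyphen separators. One row of the packaged table (Ptges) prints
identical ranges for both region classes in the source and is
transcribed as printed.

## Viability screen

Technical replicates are averaged to a single mean nuclei count per
siRNA *before* the ratio against the negative-control mean is formed;
per-replicate SoV values are recoverable from the plate table but the
published statistic is a ratio of means. The positive-call threshold
`M` is the arithmetic mean SoV over **library** siRNAs only: including
the pan-lethal positive control would inflate `M` (a config switch
restores the literal all-wells mean). Calls use the strict inequality
`SoV > M`. Negative SoV (growth promotion) is preserved; no
winsorising, plate-position or edge-effect correction is applied, as no
such correction is part of the modelled protocol.

Gene classification counts, per siRNA, the number of cell lines in
which that siRNA is positive. Because the count is per siRNA identity,
"k siRNAs positive in all lines" automatically enforces that the *same*
siRNAs act in every line. `k_consistent` defaults to 3 of 4,
generalising the three-of-four concordance rule. Screen QC requires the
positive control to beat `M`; the pooled negative control scores
exactly 0 against itself by construction.

## Migration screen

The endpoint is fixed per cell line as the earliest timepoint at which
the mean negative-control closure reaches `target_closure` (default
90%), then applied to every gene of that line. If controls never reach
the target, `select_endpoint` falls back to the last timepoint with a
warning; at the batch level such non-migrating lines are excluded
entirely (again with a warning), since per-gene suppression against a
non-closing control is not interpretable.

Per-siRNA closure is the replicate mean at the endpoint (linear
interpolation between sampled timepoints). The within-one-SD filter
retains values with `|v − mean| <= SD` using the sample SD (n−1
denominator); for any n ≥ 2 at least one value satisfies this, so the
retained set is provably non-empty (a guard covers the one reachable
exception, floating-point underflow at subnormal magnitudes). The
per-gene LoV average uses the same retained siRNA set as the closure
average by default — mixing filtered closure with unfiltered LoV would
compare different siRNA populations — with `lov_on_retained=False`
restoring the all-four average.

The confound rule is this module's explicit operationalisation of "LoV
accounts for the suppression of wound closure", which has no published
formula: a gene is *confounded* when `LoV >= lov_floor` (default 25%,
an absolute materiality floor) **and** `LoV >= lov_ratio ×
suppression` (default 0.75, requiring cell loss commensurate with the
migration defect). `suppressed` applies a separate cut, suppression ≥
20% of control closure (no numeric threshold is published; 20% sits
well above the closure noise of the simulated assay). The two flags
combine into four phenotypes: `migration`, `confounded`,
`viability_only` (high LoV without migration suppression) and `none`.

## Survival association

* **Median split.** High is strictly above the median; ties go Low,
  keeping the High group strictly elevated. An all-identical
  expression vector is a degenerate split and raises.
* **Kaplan–Meier and logrank** are delegated to lifelines (standard
  estimators); the returned KM curve is wrapped as an explicit
  right-continuous step function.
* **Univariate Cox** is implemented in-package as a one-parameter
  Newton iteration on the partial likelihood of a binary covariate,
  because the design calls for both Efron (default; better under heavy
  ties) and Breslow tie handling behind one interface. Score and
  observed information are accumulated per distinct event time from
  the group-wise risk/death counts; steps are damped to ±5 on the
  log-HR scale, and |β| > 20 after damped iteration is reported as a
  monotone likelihood (complete separation) with an unbounded CI
  instead of a spurious finite estimate. The 95% CI is Wald,
  `exp(β̂ ± z₀.₉₇₅·SE)`. The implementation agrees with lifelines'
  Efron fit to ~1e-6 on tied data (cross-checked in the tests, where
  hand-derived closed forms serve as independent oracles).
* **Multi-probe genes** are summarised by the median HR over probes;
  on even counts the *lower* median is taken so the reported CI and p
  always belong to an actually fitted probe.
* **Significance** is logrank p < 0.05 with no multiple-testing
  correction, matching the modelled analysis; a Benjamini–Hochberg FDR
  column is emitted per subgroup for users who want it. Subgroups
  below 20 patients are skipped with a warning.

Numeric hazard ratios published for this signature derive from an
external meta-analysis database (cohort composition unknown and
version-dependent); they are out of numeric scope here, and the module
instead re-implements the analysis so it can be run on any cohort
table.

## Synthetic data

The generators define the study conditions for all recovery tests; all
randomness flows from one seed through fixed `SeedSequence` children
(one per generator), so identical configs give byte-identical files.

* **DE table** — planted signature genes draw FC ≥ 2.5 (2.5 plus a
  log-normal excess), FDR log-uniform on [1e-26, 0.049] and passing
  evidence; each decoy violates a random non-empty subset of the three
  predicates. Defaults: 500 genes, 52 planted.
* **Screen** — nuclei counts are negative-binomial with
  `var = μ + 0.01·μ²` (≈10% CV at the control mean of 2000), the
  simplest overdispersed count model with realistic plate variance.
  Essential genes (default 4 of 52) lose 40 SoV points on siRNAs 1–3 —
  the same identities in all 3 lines — mirroring the 3-of-4 concordance
  structure; the positive control is planted at 80 SoV.
* **Migration** — closure follows a three-parameter logistic in time
  (normalised so closure(0) = 0), the simplest monotone-with-plateau
  shape, over a 46 h grid for one line and 20 h for the other, with
  2%-point Gaussian noise. Suppressors and confounded genes share a
  reduced plateau (40% of control, ≈60% suppression at the endpoint);
  confounded genes additionally carry LoV ≈ 55% (comfortably above
  both arms of the confound rule), suppressors LoV ≈ 5%. An optional
  discordant siRNA behaves like control to exercise the one-SD filter.
* **Survival** — expression is standard normal per gene; event times
  are exponential with the baseline hazard (0.02/month, median ≈ 35
  months) multiplied by the planted HR for patients above that gene's
  median, so the planted HR is exactly the median-split estimand when
  one gene is planted. With several harmful genes planted the hazard is
  multiplicative over genes, and each gene's *marginal* median-split HR
  is mildly attenuated by Cox non-collapsibility; recovery tests on
  multi-gene cohorts therefore assert significance and direction rather
  than a tight interval, and the precise HR-recovery check uses a
  single-gene cohort. Censoring is independent Uniform(0, τ) with τ
  solved numerically so the expected censored fraction matches the
  config (default 20%).

Truth files list the planted class of every gene, sufficient to score
all downstream recovery without re-reading the config.

### What the simulations do not emulate

Plate spatial effects, transfection-efficiency gradients, siRNA
off-target structure, non-logistic wound-healing kinetics,
non-proportional hazards, correlated expression between genes, and
cohort heterogeneity. Passing recovery tests therefore demonstrates
correctness of the scoring rules under their stated assumptions, not
robustness to these real-data artefacts.

## Problem sizes and reproducibility

The test suite and examples run screen recovery at the full default
geometry (52 genes × 4 siRNAs × 4 replicates × 3 lines), migration at
6–30 genes × 2 lines, null-rate checks at 200 genes × 400 patients and
HR recovery at n = 2000 patients — sizes at which the planted effects
are identifiable with wide margins while the whole suite completes in
well under a minute. Null-rate assertions use 3σ binomial bands around
the nominal rates; the null-screen consistent-hit bound (≤ 2 of 52)
follows from the ~0.7% per-gene null probability of the 3-of-4
all-lines rule.

## Known limitations

* The signature stage trusts upstream DE statistics; no recomputation
  or shrinkage is attempted.
* The confound rule and the `suppressed` cut are explicit
  operationalisations with configurable parameters, not published
  constants.
* The Cox fit covers the univariate binary-covariate case only (the
  estimand of this analysis); it is not a general Cox regression.
* Evidence annotations are consumed as given; no external database
  queries are made.
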