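# Methods

## The classifier

A sample's dysbiosis score is S = ½(N_SIG2/45 − N_SIG1/37 + 1), where
N_SIG1 and N_SIG2 count the *unique* catalog species detectable in the
sample. The formula is deliberately unweighted: every species contributes
1/37 or 1/45 regardless of abundance, which makes the score a pure
presence/absence ecology statistic, robust to the heavy-tailed abundance
noise of shotgun profiling. S is bounded in [0, 1] with 0.5 the neutral
point (including the degenerate empty sample, which classifies as
dysbiotic since 0.5 ≤ 0.535).

"Detectable" is operationalized as relative abundance strictly greater
than a configurable `detection_threshold` (percent), default 0 — i.e. any
nonzero MetaPhlAn call counts. The same threshold defines "lack" of
*Akkermansia* in the gray-zone rule, keeping presence semantics symmetric.
Boundary inclusivity follows the decision rule exactly: S ≤ 0.535 ⇒
SIG1+, S ≥ 0.791 ⇒ SIG2+, gray-zone *A. muciniphila* dysbiotic only when
strictly above 4.799 %. Catalog matching is by canonical species name
with an SGB-code fallback (SGB9226 identifies the relevant *A.
muciniphila* clade when tables carry SGB-level rows).

The default catalog ships the species named publicly for each group plus
representative members of the named genera, padded to the exact 37/45
sizes with entries flagged `"placeholder": true`. The full published
lists can be substituted by supplying a JSON catalog file; nothing in the
code depends on the placeholder identities. *Akkermansia* is held outside
both SIG sets: it acts only as the gray-zone arbiter, which avoids
double-counting it in N_SIG2 (configurable by editing the catalog file).

## Compositional handling

Abundance tables are percent-scale compositions; all association and
differential statistics run on centered log-ratio (CLR) values. Zeros are
handled with a fixed additive pseudocount (default 1e−5 %) rather than
multiplicative replacement — the simplest reproducible choice, and its
magnitude is far below typical detection limits so CLR values of observed
taxa are essentially unaffected. Tables whose per-sample sums look like
proportions (≈ 1) are auto-rescaled to percent with a logged warning.

## Co-abundance network

Edges are Spearman rank correlations between CLR abundances of taxa
passing a prevalence filter (default present in ≥ 10 % of samples),
retained when Benjamini–Hochberg-adjusted two-sided p ≤ α (default
0.05). Rank correlation on CLR is a standard, reproducible co-abundance
choice that tolerates the compositional constraint; it is intentionally
simple and documented so a different estimator can be swapped behind the
same interface. Ward-linkage agglomeration runs on d = 1 − ρ, the
conventional (approximate, not exactly Euclidean) correlation distance;
the tree can be cut to k clusters (default 10, matching the number of
major clusters the original analysis reports) or at a height. SciPy's
linkage is deterministic for fixed input, so partitions are reproducible.

## Cohort statistics

- Classification contrast: primary labels (SIG1+/GRAY/SIG2+) per group;
  the headline test is Fisher's exact two-sided test on the 2×2 collapse
  (SIG2+ vs not), reading "not eubiotic" as the clinically adverse pole.
  A Monte-Carlo exact test on the full 2×3 table (probability ordering
  under fixed margins) is available as an option. Odds ratios use the
  conditional MLE, with a Haldane–Anscombe 0.5 correction for the point
  estimate when a cell is empty.
- SIG balance is reported as n_SIG1 − n_SIG2 (positive = SIG1 dominance).
- The SIG-count/survival association is a Spearman correlation of counts
  against recorded follow-up time over all samples regardless of
  censoring — mirroring the published analysis — with an `events_only`
  option as the statistically safer variant (censoring-ignoring
  correlations bias toward zero and can flip sign under differential
  censoring; the caveat is deliberate).
- The median-split analysis dichotomizes at the cohort median SIG1 count
  (or a supplied threshold), with Kaplan–Meier estimation and the
  log-rank test from lifelines, right-censoring respected.
- Volcano differentials: per-taxon two-sided Wilcoxon rank-sum on CLR
  between SIG1-high (> median) and SIG1-low samples, effect = CLR mean
  difference, BH correction across taxa.

### Dysbiosis subtypes

The Type 1 / Type 2 split is qualitative in its source; the cutoffs here
are explicit operationalizations and prominently configurable. With
sig2_retention = N_SIG2/45 and oral_fraction = detected-oral-SIG1 /
detected-SIG1: **Type 1** (modest SIG2 loss with oral spillover) requires
retention ≥ 0.4 and oral_fraction ≥ 0.5; **Type 2** (SIG2 collapse
dominated by gut anaerobes) requires retention < 0.15 and oral_fraction
< 0.5. Profiles between the regimes, and every non-SIG1+ sample, stay
unclassified. Using the "modest" cutoff (0.4) as Type 1's retention floor
— rather than the collapse cutoff — keeps all three parameters meaningful
and keeps the two subtypes disjoint by a margin.

## Synthetic cohorts

The generator emulates the features the retrospective analysis depends
on, at the published cohort sizes (5346 healthy / 955 cancer by default):

- **Label structure.** Each sample draws a latent community state —
  eubiotic (SIG1/SIG2 prevalence 0.05/0.85), intermediate (0.30/0.60), or
  dysbiotic (0.50/0.25) — and catalog taxa are detected independently at
  the state's prevalences. The states pin the score inside one label band
  with > 98 % probability (binomial sd of S is ≈ 0.03–0.05, small against
  the 0.26-wide band structure), so the state mixture weights *are* the
  calibration targets. Defaults: healthy (4 % dysbiotic, 28 %
  intermediate, 68 % eubiotic), cancer (34/43/23) — the published label
  fractions. A single group-level prevalence cannot reproduce this
  three-way split (its score spread is ~5× too narrow), which is why the
  latent state exists. Setting explicit per-group prevalence vectors
  bypasses the mixture.
- **Abundances.** Detected taxa draw log-normal abundances (ln-mean −2,
  ln-sd 1.5, percent scale — median 0.14 %, right-skewed like real
  profiles); 150 filler taxa at 30 % prevalence make rank and prevalence
  filtering non-trivial. Rows that would exceed 100 % are rescaled with
  the *Akkermansia* value held fixed so its stratum is preserved.
- **Akkermansia trichotomy.** Per-group (absent, normal, over) mixture,
  default healthy (0.25, 0.65, 0.10) and cancer (0.45, 0.40, 0.15);
  normal draws uniform in (0, 4.799], over uniform in (4.799, 15]. Only
  the 4.799 boundary is fixed by the decision rule; the 15 % ceiling and
  the mixtures are plausible defaults, not estimates.
- **Survival.** Exponential times with hazard = baseline · exp(β ·
  N_SIG1), baseline 0.02/month, β = 0.15 per detected SIG1 taxon (so ten
  extra SIG1 species multiply the hazard by ~4.5), progression hazard 2×
  the death hazard with progression capped at death, administrative
  censoring at 60 months plus 10 % random censoring. β > 0 means higher
  burden ⇒ shorter survival; the sign convention is explicit to prevent
  silent inversion. Both groups receive survival times from the same
  model; analyses filter to the cancer group.

What the generator does *not* emulate: real taxon-taxon correlation
inside a state (detections are conditionally independent), between-SIG
abundance gradients, cancer-type heterogeneity, longitudinal sampling,
or a realistic censoring mechanism. One consequence worth flagging: the
latent state couples SIG2 counts negatively to SIG1 counts, so simulated
SIG2 counts correlate *positively* with survival — stronger than the
near-null SIG2 association reported on real cohorts. Passing tests
demonstrate that the pipeline recovers planted effects, not that real
cohorts will show them.

`planted_block_table` provides Gaussian-copula draws with block
correlation structure mapped through a log-normal for network tests; the
monotone map preserves rank correlations exactly, and samples are not
closed to a fixed total (closure would destroy the rank structure of a
perfectly correlated block), only rescaled in the rare overflow case.

## Numerical and design notes

- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical configs are byte-identical.
- Problem sizes in the test suite (e.g. 100-seed parameter-recovery runs
  at n = 400/group, 20-seed calibration at n = 2000/group, 1000-replicate
  log-rank null at n = 100) were chosen to make the Monte-Carlo bands
  tight relative to the assertions while keeping the suite around a
  minute of runtime.
- Fisher, BH, Kaplan–Meier/log-rank, Ward linkage, CLR, and rank tests
  delegate to scipy/statsmodels/lifelines/scikit-bio; the test suite
  cross-checks them against independently hand-coded oracles
  (hypergeometric tail enumeration, BH step-up, closed-form CLR,
  brute-force rescoring).
- Degenerate inputs fail loudly with typed errors: constant ranks or
  fully censored cohorts raise `UndefinedStatisticError`, empty split
  arms `DegenerateSplitError`, malformed catalogs `CatalogError` naming
  the violated invariant.

## Known limitations

The shipped catalog's placeholder entries mean absolute scores on *real*
data are not meaningful until the full published lists are substituted;
all pipeline logic, thresholds, and statistics are unaffected by the
substitution. The 2×3 exact contrast is Monte-Carlo, not exhaustive. The
Spearman survival correlation ignores censoring by design (documented
above). The distilled reduced-taxon score variant and per-taxon weighted
scores are out of scope.
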