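# sigscore

Gut dysbiosis scoring for cancer-microbiome studies, built around two
antagonistic *species interaction groups* (SIGs) profiled from stool
shotgun metagenomes: **SIG1**, 37 species associated with worse outcome
under cancer immunotherapy (an oral-spillover cluster — *Veillonella*,
*Streptococcus*, *Bifidobacterium dentium* — and a cluster of gut-resident
obligate anaerobes such as *Enterocloster* spp., *Hungatella hathewayi*,
*Clostridium innocuum*), and **SIG2**, 45 gut-resident butyrate producers
associated with better outcome (*Faecalibacterium* spp., *Eubacterium
rectale*, *Coprococcus comes*, *Roseburia inulinivorans*, ...).

The package is for microbiome/onco-immunology researchers who have
species-level relative-abundance tables (MetaPhlAn-style merged TSV) and
want per-sample dysbiosis labels plus the cohort-level statistics that
link SIG1 burden to survival.

## The score

For a sample in which $N_{SIG1}$ of the 37 SIG1 and $N_{SIG2}$ of the 45
SIG2 species are detectable,

$$S = \frac{1}{2}\left(\frac{N_{SIG2}}{45} - \frac{N_{SIG1}}{37} + 1\right) \in [0, 1].$$

Samples with $S \le 0.535$ are **SIG1+** (dysbiotic); $S \ge 0.791$ are
**SIG2+** (eubiotic). Scores in the gray zone between are settled by the
*Akkermansia muciniphila* (SGB9226) trichotomy: samples that lack it or
carry it above 4.799 % relative abundance are SIG1+, samples with normal
levels are SIG2+.

Around the classifier the package provides:

- **catalog** — the SIG1/SIG2 reference lists with validation and a JSON
  substitution path (the shipped default pads the publicly named species
  with clearly flagged placeholders to the exact 37/45 sizes);
- **ingest** — MetaPhlAn-style TSV parsing with rank filtering and the
  centered log-ratio (CLR) transform for compositional analyses;
- **network** — signed co-abundance networks (Spearman on CLR, BH-filtered
  edges) and Ward-linkage partitioning into major clusters;
- **cohort** — Fisher-exact label contrasts, SIG balance histograms,
  Spearman SIG-count/survival correlation, Kaplan–Meier median-split
  analysis with log-rank tests, rank-sum volcano differentials, and
  Type 1 / Type 2 compositional-dysbiosis subtyping;
- **simulate** — a calibrated synthetic-cohort generator (label mixtures,
  Akkermansia trichotomy, proportional-hazards survival) so the whole
  pipeline is testable without patient data;
- **pipeline / cli** — a one-call retrospective driver and a thin
  `sigscore` command-line wrapper.

## Worked example

```python
from sigscore import SimulationConfig, run_retrospective_analysis, simulate_cohort

sim = simulate_cohort(SimulationConfig(seed=7, n_healthy=400, n_cancer=400))
report = run_retrospective_analysis(sim.table, sim.clinical)
```

Running `python examples/retrospective_analysis.py` (which is exactly this)
prints:

```
label counts (healthy/cancer x SIG1+/GRAY/SIG2+):
         SIG1+  GRAY  SIG2+
healthy     20   111    269
cancer     149   162     89
Fisher exact p = 1.79e-38, odds ratio = 7.15
SIG1 count vs overall survival: Spearman rho = -0.637 (p = 6.13e-47, n = 400)
median split at n_sig1 > 13: log-rank p = 1.19e-39; median OS 2.7 vs 13.6 months
```

Healthy samples are predominantly eubiotic while cancer samples skew
dysbiotic or gray (the Fisher contrast), the number of detected SIG1
species correlates negatively with overall survival, and patients above
the median SIG1 burden die markedly faster — the three cohort-level
signals the generator plants and the pipeline recovers. The other
scripts in `examples/` walk through scoring, network clustering, and the
generator's calibration individually.

A command-line session over files looks like:

```bash
sigscore simulate --config cfg.json --seed 5 --out-prefix cohort
sigscore score --input cohort_abundance.tsv --out scores.tsv
sigscore analyze --input cohort_abundance.tsv --clinical cohort_clinical.csv --out-dir report/
```

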