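# refstab

Reference-gene (housekeeping-gene) stability validation for RT-qPCR
quantification-cycle data.

## The problem

Relative RT-qPCR quantification (the ΔΔCt framework) reports a target
gene's expression as a ratio against one or more internal controls. If the
chosen housekeeping gene (HKG) is itself unstable — it responds to the
treatment, is co-regulated with the target, or is expressed at a wildly
different abundance — every downstream fold-change inherits that error.
Good practice (the MIQE guidelines) therefore demands that candidate
references be validated empirically, with at least two and preferably
three genes in the final normalization set.

`refstab` implements the four standard stability algorithms, the classical
inter-group statistics, a geometric-mean-rank consensus, and a stepwise
exclusion workflow that turns them into a concrete recommendation. A
seeded synthetic Ct generator reproduces a typical cell-culture study
design (six treatment groups × six biological replicates, six candidate
HKGs plus one regulated target), so the full pipeline runs and is testable
without any external data.

## Methods implemented

With relative quantities RQ = E^(Ct_cal − Ct) (E the amplification
efficiency, Ct_cal a per-gene calibrator):

- **geNorm** — pairwise variation V_jk = SD_samples[log2(RQ_j/RQ_k)];
  stability M_j = mean_k≠j V_jk; iterative removal of the highest-M gene
  down to the final pair, plus the V_k/k+1 normalization-factor curve.
- **NormFinder-style model** — log-scale expression is sample-centred and
  decomposed per gene × group into an intragroup variance σ²_ig (corrected
  for the centring contamination) and a shrunken intergroup deviation
  d̃_ig; stability ρ_i = mean_g(|d̃_ig| + √(σ²_ig/n_g)).
- **BestKeeper** — descriptive statistics on raw Ct (geometric/arithmetic
  mean, min/max, dispersion as mean absolute deviation, CV% =
  100·dispersion/mean), the per-sample geometric-mean index, OLS
  regression of each gene on the index, and Pearson correlation of each
  candidate against the target gene.
- **Pairwise ΔCt (Silver et al.)** — SD over samples of per-sample Ct
  differences for every gene pair; a gene's score is the mean of its pair
  SDs; per-gene Mann–Whitney comparisons summarised as compact letters.
- **Inter-group statistics** — per-group Shapiro–Wilk, one-way ANOVA per
  gene, Tukey HSD (or unadjusted t) post hoc tests.
- **Consensus** — geometric mean of the per-method ranks (RefFinder
  convention), computed after the exclusion filters:
  abundance gap to the target > 5 cycles ⇒ exclude; strong significant
  target correlation ⇒ exclude; significant inter-group ANOVA ⇒ exclude;
  per-method guideline thresholds reported as advisory flags.

## Worked example

```python
from refstab import default_3t3l1_config, simulate_ct, run_workflow

# six-group adipocyte study with two planted confounds: Actb co-regulated
# with the PPARG target (r = 0.76) and GAPDH shifted +0.6 cycles in the
# four treated groups
cfg = default_3t3l1_config(actb_coupling=0.76, gapdh_shift=0.6)
table, truth = simulate_ct(cfg, seed=1)

report = run_workflow(table)
print("status:", report.status)
print("survivors:", report.survivors)
print("best gene:", report.best_gene)
print("best triplet:", report.best_triplet)
print(report.consensus.to_frame().round(2))
```

prints

```
status: ok
survivors: ['36B4', 'HMBS', 'HPRT']
best gene: HPRT
best triplet: ['HPRT', '36B4', 'HMBS']
      geomean_rank  final_rank
36B4          2.21           2
HMBS          2.71           3
HPRT          1.00           1
```

The workflow excluded 18S (mean Ct 7.4 cycles below the target — it
amplifies in a much earlier phase of the reaction), Actb (Pearson r ≈ 0.7
against the target: not a neutral control) and GAPDH (ANOVA p ≈ 7e-08
across treatment groups), then ranked the three survivors by the geometric
mean of their geNorm, NormFinder, BestKeeper and ΔCt ranks. HPRT is
unanimously first (geomean rank 1.00); the recommended normalization
triplet is HPRT + 36B4 + HMBS. `report.decision_log` holds every exclusion
with its evidence, and `render_report(report, "out/")` writes the
Markdown/JSON/CSV bundle plus the consensus bar chart.

The same pipeline is available from the shell:

```bash
refstab simulate --seed 1 --out ct.csv
refstab run --ct ct.csv --target PPARG --out out/
refstab report --in out/
```

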