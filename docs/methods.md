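# Methods

This note documents the models, conventions and design choices behind
`refstab`, in the spirit of the methods documentation of packages like
statsmodels or scanpy: what is computed, under which assumptions, which
knobs matter, and what the synthetic data can and cannot show.

## Data model and transforms

The single input currency is a complete samples × genes matrix of
quantification cycles (Ct) with one group label per sample and an
optionally designated target gene. Ct is a log-domain quantity: at 100 %
amplification efficiency one cycle is one doubling of template. Methods
that operate on expression (geNorm, NormFinder) first transform to
relative quantities

    RQ_gs = E_g ^ (Ct_cal,g − Ct_gs)

with per-gene efficiency E_g (default 2.0; overridable per gene, e.g.
1.98–1.99 for chemistries validated at 98–99 %). The default calibrator is
the per-gene minimum Ct, which maps each gene into (0, 1]. The calibrator
is pure bookkeeping: geNorm uses ratios, ΔCt uses differences and
NormFinder centres per sample, so all three are provably invariant to it
(tested as such). BestKeeper and the ΔCt method deliberately operate on
raw Ct.

Missing Ct cells are rejected by default; an explicit `drop-sample` mode
removes the whole sample instead. No imputation is offered, because every
downstream statistic is an SD or a correlation and silent imputation would
bias exactly those.

Standard-curve efficiency is estimated by least squares of Ct on
log10(input) over a serial dilution; efficiency% = (10^(−1/slope) − 1)·100,
accepted when it lies in [90, 110] % with R² ≥ 0.99.

## geNorm

Pairwise variation V_jk is the n−1 sample SD of log2(RQ_j/RQ_k); M_j is
the mean of V_jk over the active set. The ranking procedure repeatedly
excludes the highest-M gene and recomputes M on the survivors until two
remain; the survivors keep ranks 1–2 ordered by full-panel M (a 2-gene M
is a shared value and cannot separate them). Ties are broken by (lower
full-panel M, then input order) so output is deterministic. The n−1
denominator follows common reimplementations; with a fixed sample count
the n/n−1 choice rescales every V equally and cannot change any rank.
Guideline cutoffs: M < 1.0 for heterogeneous panels, < 0.5 for homogeneous
ones. The V_k/k+1 curve (SD of log2 of the ratio of successive
geometric-mean normalization factors, threshold 0.15) indicates how many
references are worth including.

## NormFinder-style stability

Log2 quantities are sample-centred (subtracting each sample's mean over
genes removes shared loading effects), then per gene i and group g:

1. raw group mean m_ig and n−1 variance s²_ig of the centred values;
2. intragroup variance corrected for the −1/n share of every gene's noise
   that centring mixes in: σ̂²_ig = max((s²_ig − S_g/(n(n−1))) · n/(n−2), 0)
   with S_g = Σ_i s²_ig — hence the requirement of ≥ 3 genes in group mode;
3. intergroup deviation d_ig = m_ig − mean_g m_ig; its systematic variance
   γ̂²_i = max(Σ_g d²_ig/(G−1) − mean_g(σ̂²_ig/n_g), 0); shrinkage
   d̃_ig = d_ig · γ̂²_i/(γ̂²_i + σ̂²_ig/n_g);
4. stability ρ_i = mean_g(|d̃_ig| + √(σ̂²_ig/n_g)).

The zero clamps are required because method-of-moments variance estimates
go negative at small replicate counts. With one group the score reduces to
the corrected intragroup SD. This formulation is frozen as normative for
the package: it is validated by its properties (scale/shift invariance,
monotonicity in planted noise and shifts, variance recovery at large n),
not by numeric agreement with any closed-source implementation, whose
internal constants are not public. The conventional "< 0.15 is good"
cutoff is exposed as configuration and used only as an advisory flag,
since its scale equivalence to this estimator cannot be established.

## BestKeeper

Descriptive statistics are computed on raw Ct. The dispersion labelled
"std dev [±CP]" is the mean absolute deviation from the arithmetic mean
(the BestKeeper tool's convention); the classical n−1 SD is available via
`convention="sd"`. CV% = 100 · dispersion / arithmetic mean — an identity
that ties the printed CV cells of a descriptive table to its own SD and
mean cells. The index is the per-sample geometric mean Ct over the
candidate panel (all candidates by default, configurable). Each gene is
regressed on the index by OLS, and Pearson r is converted to a two-sided
p via t = r√((n−2)/(1−r²)). Guideline thresholds (SD < 1 cycle, CV < 2 %,
r ≥ 0.9) are advisory flags only: the index-r cutoff in particular is
commonly violated by panels that practitioners nevertheless accept, so it
never excludes a gene by itself.

## Pairwise ΔCt

For each ordered pair, per-sample signed differences δ_s = Ct_a,s − Ct_b,s
are summarised by their n−1 SD; a gene's score is the mean of its pair
SDs. The reported "mean ΔCt" is the mean of |δ_s|: for well-separated
pairs this equals the gap between mean Cts, while for near-coincident
pairs the absolute value keeps the figure positive (SD stays on signed
differences — taking absolute values first would bias the SD toward zero
at small gaps). Because δ subtracts two genes within the same sample, any
shared per-sample effect cancels exactly.

Per-gene SD sets are compared pairwise with two-sided Mann–Whitney tests:
the exact null distribution when both sets have ≤ 8 values (ties left
uncorrected in the exact branch), the tie-corrected normal approximation
above. Results are summarised by an insert-and-absorb compact letter
display ordered by ascending mean SD. With six candidates each gene
contributes only five pair SDs, and one contaminating value is enough to
push an exact 5-vs-5 test over p = 0.05, so letter patterns at this design
size are coarse — a single fully separated noise class is detected
reliably, finer splits are not.

## Inter-group statistics

Per gene: Shapiro–Wilk per group (groups with < 3 values or zero spread
are flagged untestable rather than failed), classical one-way
fixed-effects ANOVA on raw Ct, and Tukey HSD post hoc p-values (an
unadjusted two-sided t-test mode reproduces the star annotations commonly
drawn on group-mean plots; Tukey is the default because it controls the
family-wise error). A constant gene has an undefined F and is reported
stable with a note. Normality failures do not silently switch the test:
the ANOVA is what the workflow uses, matching standard practice for
6-replicate designs.

## The stepwise workflow

Order of operations: (1) all four methods on the full candidate panel;
(2) abundance filter — exclude genes whose mean Ct is more than 5 cycles
from the target's (strict inequality; such genes amplify in a different
reaction phase); (3) co-regulation filter — exclude genes with |r| ≥ 0.65
and p < α against the target; an index-regression slope > 1.2 raises an
advisory non-independence flag but never excludes alone; (4) exclude genes
with significant inter-group ANOVA; (5) advisory threshold audit;
(6) recompute the four methods on the survivors and aggregate by geometric
mean rank (average ranks on ties inside each method); (7) recommend the
top 1/2/3 survivors. Filters run on the full panel before any aggregation,
so exclusions cannot depend on aggregation order; recomputing ranks on the
survivor panel makes the recommendations invariant to deleting an excluded
gene from the input. With fewer than three survivors the report degrades
to pair/single recommendations; with fewer than two it returns an
"insufficient stable genes" status (CLI exit code 3).

The co-regulation cutoff deserves a note. The workflow must separate a
moderate, acceptable target correlation (r ≈ 0.5) from a disqualifying
co-regulation (r ≈ 0.76). The default 0.65 is the Fisher-z midpoint of
those two reference points — the maximum-margin separator, with
approximately equal misclassification risk against both cases given the
sampling error of r at n = 36 (SE ≈ 0.08 on the z scale). A cutoff placed
at 0.7, nearly on top of the disqualifying case, would miss it roughly one
time in four at this sample size. The value is configurable.

## Synthetic data generator

The generator draws

    Ct_gs = baseline_g + shift_g,group(s) + b_s
            + √(sd_g² − sd_b²) · (ℓ_g·u_s + √(1 − ℓ_g²)·z_gs)

with b_s ~ N(0, sd_b) a per-sample effect shared by all genes (RT-input /
pipetting variation; it creates the positive inter-gene correlation the
BestKeeper index presumes and cancels in ΔCt and geNorm ratios), u_s a
standardized latent shared by co-regulated genes and the target, and z
independent noise. The bracket is scaled so each gene's total marginal SD
equals its configured SD exactly, whatever the variance split. A coupled
gene's loading ℓ_g is solved in closed form from its requested Pearson
coupling against the target (which loads the latent fully), so the
realized correlation converges to the requested coefficient. Noise is
Gaussian on the Ct scale, consistent with dispersion being reported in
cycles.

Defaults emulate a six-group (untreated control, broth control, four
treatment supernatants) × six-replicate adipocyte study: candidate
baselines 14.52/18.72/17.11/24.71/23.14/18.47 cycles and SDs
0.31/0.20/0.21/0.19/0.16/0.33 for 18S/36B4/GAPDH/HMBS/HPRT/Actb, a PPARG
target 7.5 cycles above 18S with SD 0.75 (a regulated gene disperses
several-fold more than the references; this size also keeps the spurious
gene–target correlation induced by the shared sample effect below 0.1),
and sample-effect SD 0.1 cycles. Two optional stressors build the
confounded validation scenario: `actb_coupling` (Pearson co-regulation of
Actb with the target) and `gapdh_shift` (+cycles applied to GAPDH in the
four treated groups).

What the generator does **not** emulate: plate/batch effects, technical
replicates, fluorescence-curve artefacts, Cq-calling error,
heteroscedasticity across the dynamic range, and non-Gaussian outliers.
Passing tests therefore demonstrate correctness of the statistical
machinery under the assumed noise model, not robustness to every artefact
of real plates.

A note on resolution: the middle of the default panel differs by only
0.01 cycles of SD (36B4 0.20 vs GAPDH 0.21). At n = 36 the sampling error
of an SD estimate is ≈ 0.025 cycles, so the exact ordering of those genes
is genuinely not identifiable run-to-run — only the well-separated
features (the lowest-noise gene near the top, the two noisiest genes at
the bottom) are stable, and the test suite asserts exactly those.

## Numerical conventions and problem sizes

- All SDs use the n−1 denominator; dispersion in the BestKeeper block is
  MAD by design (see above).
- Rank ties inside a method take average ranks; deterministic tie-breaks
  (input order) everywhere a total order is needed.
- Monte-Carlo suites use fixed seed sets; study-scale simulations run 100
  independent draws of the 36-sample design, calibration checks use ~1,000
  verdicts, and large-n recovery checks use 10,000 samples — sizes at
  which the asserted margins are comfortably outside Monte-Carlo noise.
- Degenerate inputs (constant genes, proportional panels, zero-variance
  indices, < 3 values per group) are either exact fixed points of the
  statistics or flagged explicitly; they never raise unhandled errors.

## Known limitations

- The NormFinder-style estimator is a faithful variance-decomposition of
  the published idea but is not numerically interchangeable with the
  original spreadsheet add-in.
- BestKeeper "x-fold" columns (efficiency-power transforms of min/max
  ranges) are not implemented; their published definition is not precise
  enough to reproduce.
- The compact letter display reflects the low power of exact Mann–Whitney
  at five SDs per gene; it should be read as a coarse grouping, not a
  fine-grained significance map.
- Efficiency correction applies globally per gene; per-plate or per-run
  efficiency drift is out of scope.
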