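# Methods

## Differential exosomal abundance

Label-free intensities are analysed on the log2 scale; fold change is the
difference of log2 group means, i.e. a geometric-mean ratio, which is the
natural effect scale for multiplicative peak-intensity data. The
per-protein test is a two-sided Welch *t* (unequal variances), chosen over
the pooled-variance *t* because label-free replicate variances routinely
differ between conditions. Thresholds are inclusive: up-regulated means
log2fc ≥ log2(2) and *p* ≤ 0.05. No multiple-testing correction is applied
by default — the 2-fold/0.05 screen is a nomination filter, not an
inferential claim — but Benjamini–Hochberg is available
(`significant_sets(..., adjust="bh")`).

Missing intensities are never imputed. A protein with fewer than
`min_obs = 2` observed values in either group is flagged
`insufficient_data` and carried through with NaN statistics rather than
dropped, so downstream set arithmetic always sees the full protein
universe. Degenerate zero-variance rows (all replicates identical in both
groups, which occurs in noise-free simulations) take the limiting value of
the statistic: *p* = 1 when the means agree, *p* = 0 otherwise.

Proteins altered concordantly in every resistant-vs-parental comparison
form the common up/down sets; a protein up in one comparison and down in
another is counted separately as discordant and excluded from both common
sets. Venn region counts are direction-agnostic and partition the union of
altered proteins.

## Membrane filter and receptor intersection

Gene symbols are normalized by trimming and uppercasing only; no alias or
ortholog mapping is attempted because the inputs are assumed to share a
symbol namespace. Genes absent from the membrane annotation are dropped
with a warning, not an error — annotation coverage is never complete.

A multimeric receptor complex is a candidate as soon as one subunit is
evidenced in the up-regulated membrane set, with a `complete` flag telling
whether all subunits were detected. Partial complexes are retained because
an exosome-surface complex can be informative even when one subunit falls
below MS detection (the ITGA2B–ITGB3 situation).

## Tissue specificity and organ mapping

Genes whose maximum nTPM across all tissues is below 1 are removed as
unexpressed; the threshold is inclusive and gene-level (a single filtered
gene universe) rather than per-tissue hole-punching. Multimeric ligand
expression is aggregated per tissue as the **minimum** across subunits — a
complex cannot exceed its limiting subunit. The arithmetic mean is
available behind `rule="mean"` for sensitivity analysis.

A ligand is tissue-specific when its aggregated expression has a unique
argmax tissue; maxima equal within relative tolerance 1e-9 are ties and
the ligand stays unassigned, because "specific" demands a single tissue.
Ligands with subunits removed by the nTPM filter are reported
`below_threshold`, and subunits never present in the atlas `missing_gene`,
so funnel attrition is auditable. Organ names are matched
case-insensitively after trimming.

An organ edge requires three facts simultaneously: the pair is in the
database, the receptor side is an evidenced candidate, and the ligand is
assigned to that organ. Edge exports are lexicographically sorted and
written with fixed float formatting so identical runs are byte-identical.

## Biomarker panel

Per-particle marker load is ELISA concentration (pg/ml) divided by
particle concentration (particles/ml), units pg/particle. AUC is the rank
(Mann–Whitney) estimator with half-credit ties, identical to exhaustive
pairwise counting; the ROC curve is traced over all observed thresholds.
The AUC *p*-value (null AUC = 0.5) uses the tie-corrected normal
approximation of the Mann–Whitney statistic; a DeLong-variance *z* test is
available behind `p_method="delong"`. Confidence intervals are stratified
percentile bootstrap (default B = 2000, seeded). The positive class (BrM)
is declared explicitly and the AUC is reported as-is, never flipped — a
near-0.5 marker should be visible as such.

The combined panel is a maximum-likelihood logistic model fitted by
Newton–Raphson (max 100 iterations, gradient tolerance 1e-8) with an L2
ridge of 1e-6 on the non-intercept coefficients purely for numerical
stability under quasi-separation; at this magnitude the penalty is
invisible at the reported precision. Markers are z-score standardized
before fitting — predicted probabilities, and hence the combined ROC, are
invariant to this, but coefficients become unit-free log-odds per SD. The
headline combined ROC uses in-sample predicted probabilities; honest
performance is reported separately by stratified k-fold cross-validation
(held-out probabilities pooled into one ROC) and stratified bootstrap:
percentile CI from the replicate AUCs and Harrell's optimism correction
(mean excess of each bootstrap model's in-bootstrap AUC over its AUC on
the original cohort, subtracted from the apparent AUC).

Cohort summary tables report "n (p)" per group with one-decimal half-up
percentage rounding, matching clinical-table convention; the computation
uses decimal arithmetic so .x5 boundaries round up exactly.

## Synthetic data

The generator emulates the measured study inputs at their native scale:
~1,500 detected exosomal proteins across one parental and two resistant
lines with 3 replicates each; 744 concordantly altered proteins (half up,
half down) plus 50 + 50 line-specific plants at a log2 effect of 2;
a 621-ligand catalogue with 12 multimeric ligands among ~780 receptor
genes and 900 pairs; a 20,141-gene × 40-tissue atlas with 10% of
background genes below the nTPM filter; and a 3 × 27-patient serum cohort
with marker AUC targets 0.80 (ITGB3) and 0.73 (L1CAM).

Intensities are generated on log2 (base level N(18, 2), replicate noise
N(0, 0.4) by default) and exponentiated; missingness (10% by default) is
completely at random, since no missingness mechanism is identifiable from
the study design. Planted organ-pair ligands peak strictly in their
designated tissue; decoy ligands attached to otherwise-unused planted
receptors peak in a dedicated non-organ tissue so they can never create
false organ edges; background pairs use receptors outside the proteomics
namespace. This construction makes planted-recovery precision structural
and recall a genuine function of the differential-testing stage.

Cohort markers use a Gaussian copula: latent unit-variance normals with
correlation 0.5 (reproducing the observed positive ITGB3–L1CAM
association without asserting a mechanism), the BrM group shifted by
δ = √2·Φ⁻¹(AUC_target), then exponentiated to positive loads and
multiplied by log-normal particle counts to give concentrations — so
per-particle normalization recovers the calibrated scale exactly. The
closed forms used by the calibration tests are AUC = Φ(δ/√2) per marker
and Φ(√(δᵀΣ⁻¹δ)/√2) for the equal-covariance combined panel. Per-particle
load and particle count are independent by default; an optional
dependence coefficient exists because that dependence is unknown in
patients. One integer seed drives all sub-generators through spawned
streams.

What the generator does **not** emulate: peptide-level structure,
intensity-dependent missingness, batch effects, heavy-tailed ELISA error,
non-binormal marker shapes, or any correlation between the proteomics and
cohort modules. Passing planted-recovery tests therefore demonstrates
correctness of the computational chain under its stated model, not
robustness to real-data pathologies.

"Separable regime" in the recovery tests means replicate noise ≤ effect/4
with ≥ 3 replicates and no missingness; there the per-protein miss
probability of the Welch screen is ~1e-4 and planted recovery is exact
with a fixed seed. Default noise (0.4) and missingness (0.1) are
deliberately harder and produce realistic partial recovery.

## Numerical and design choices

- Problem sizes in tests and the acceptance script: full study-scale
  fixtures for the tropism chain; n = 10,000/group for calibration and
  coefficient-recovery checks; B = 100–500 bootstrap replicates where a
  distributional property, not a CI at final precision, is being checked.
- The package exposes the panel as a model/results pair
  (`BiomarkerPanel.fit() -> PanelResults` with `summary()`), the
  statistical core of the package; the tropism chain is deterministic set
  algebra and stays functional.
- All JSON outputs are key-sorted and timestamps are omitted, so rerunning
  a configuration is byte-identical.
- TSV is used throughout (UTF-8, header row, "." decimal, "+"-joined
  subunits); intensity files mark missing values as empty or `NA`.

## Known limitations

- The Welch screen at 3 replicates has low power at small effects; the
  published-scale fold-change threshold dominates behaviour.
- The tie tolerance (relative 1e-9) is meant for float noise; atlases with
  genuinely quantized nTPM values will declare more ties than a
  rank-based specificity score would.
- Optimism correction assumes the bootstrap world mirrors the sampling
  world; with 27 patients/group the corrected AUC remains optimistic
  relative to external validation.
- The logistic panel is linear in standardized per-particle loads;
  threshold or interaction effects between markers are out of model.
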