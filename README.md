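# exotropy

Tools for two linked analyses around tumour-exosome organotropism in lung
cancer:

1. **Nomination of brain-tropic exosomal surface proteins.** Starting from
   label-free LC-MS/MS intensities of exosomes from a parental cell line and
   drug-resistant, EMT-shifted derivatives, the pipeline finds proteins
   concordantly up-regulated in the resistant lines (Welch *t* on log2
   intensities, fold change ≥ 2, *P* ≤ 0.05), keeps the membrane-annotated
   subset, intersects it with the receptor side of a CellChatDB-style
   ligand–receptor catalogue, assigns every database ligand to the single
   tissue where its nTPM expression peaks (HPA-consensus-style atlas,
   genes with max nTPM < 1 excluded, multimeric complexes aggregated by the
   per-tissue minimum of their subunits), and emits per-organ
   receptor–ligand edge lists — the computational funnel that points at
   integrins and L1CAM as brain-directed exosomal receptors.

2. **A serum-exosome diagnostic panel.** ELISA marker concentrations are
   normalized to exosome particle counts (pg/particle), discrimination of
   the brain-metastasis (BrM) group is measured by the rank
   (Mann–Whitney) AUC with bootstrap CIs, and markers are combined through
   a maximum-likelihood logistic model whose per-patient predicted
   probabilities give the combined ROC, validated internally by stratified
   cross-validation and bootstrap resampling (percentile CI and
   optimism-corrected AUC).

Because the original raw inputs (mass spectra, patient sera, database
snapshots) are not distributable, the package includes a first-class
synthetic-data generator that emulates all five inputs with planted,
machine-readable ground truth: planted differential proteins, planted
organ-specific ligand–receptor pairs, and binormal markers calibrated so a
marker with target AUC has mean shift δ = √2·Φ⁻¹(AUC) between groups
(hence theoretical AUC Φ(δ/√2)). Every pipeline stage is tested by
parameter recovery against that ground truth.

## Worked example

```python
from exotropy.simulate import SimulationConfig, gen_cohort
from exotropy.panel import fit_logistic_panel, roc_auc, normalize_per_particle

cfg = SimulationConfig(seed=3)                  # 3 x 27-patient cohort,
cohort, truth = gen_cohort(cfg)                 # targets ITGB3 0.80, L1CAM 0.73
sub = cohort[cohort["group"].isin(["stage1", "stage4_BrM"])].reset_index(drop=True)
sub = normalize_per_particle(sub, ["ITGB3", "L1CAM"])
for mk in ("ITGB3", "L1CAM"):
    r = roc_auc(sub[mk + "_per_particle"], sub["group"], "stage4_BrM",
                n_boot=500, seed=0)
    print(f"{mk}: AUC {r.auc:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f}, "
          f"p {r.p_value:.4f})")
res = fit_logistic_panel(sub, ["ITGB3", "L1CAM"], "stage4_BrM")
print(res.summary())
```

prints

```
ITGB3: AUC 0.826 (95% CI 0.711-0.925, p 0.0000)
L1CAM: AUC 0.771 (95% CI 0.641-0.899, p 0.0007)
Biomarker panel logistic model
  positive class: stage4_BrM
  n = 54 (pos 27, neg 27)
  converged in 7 Newton iterations (grad 5.21e-11)

  term                coef   std err
  intercept         0.3941    0.4156
  ITGB3             1.9359    0.7916
  L1CAM             0.3654    0.3744

  combined in-sample AUC: 0.840
```

The single-marker AUCs scatter around their calibration targets (0.80 and
0.73) at n = 27/group; the coefficients are log-odds per standard deviation
of per-particle marker load; the combined AUC is the ROC of the logistic
model's predicted probabilities.

The tropism side runs the same way from generated fixtures or from
user-supplied TSV files; `exotropy simulate`, `diff`, `tropism`, `panel`,
`run` and `report` expose the stages on the command line, e.g.

```bash
exotropy simulate --outdir data --seed 11
exotropy run --config run.yaml --seed 11
```

where `run.yaml` lists the five input paths, thresholds (fold change, *P*,
min nTPM), the organ list and panel settings. Each run writes
`altered_sets.json`, `receptor_candidates.tsv`, `ligand_assignment.tsv`,
`tropism_edges.tsv`, `panel.json` and a `manifest.json` that records
inputs, thresholds, seed and per-stage funnel counts; reruns of the same
manifest are byte-identical.

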