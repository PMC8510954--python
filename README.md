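# hgpradiomics

A reusable, fully testable CT-radiomics pipeline for distinguishing two
histopathological growth-pattern classes (desmoplastic vs replacement)
of liver metastases, with the patient CTs replaced by a synthetic cohort
generator that reproduces the statistical structure the analysis relies
on: two texture classes, multiple segmentation observers with calibrated
Dice agreement, an automated observer that misses a fraction of lesions,
scanner batch effects, and patient-grouped lesions.

## Pipeline

```
simulate ──► extract ──► harmonize ──► search ──► evaluate ──► report
(cohort)    (564-dim     (ICC filter,  (random    (100x random  (metric
             feature      ComBat)       workflow   80/20 splits,  tables,
             bank)                      ensemble)  corrected CIs) ROC bands)
```

| module | what it does |
| --- | --- |
| `synthetic_cohort` | volumes + per-observer lesion masks + acquisition/clinical metadata; Dice-calibrated boundary perturbation; CNN-like observer with fallback substitution |
| `roi_masks` | Dice coefficient, pairwise observer agreement tables, ring / normal-parenchyma / union ROI derivation |
| `feature_bank` | the 564-feature vector per ROI (histogram, shape, GLCM, Gabor, LoG, vesselness, local phase, LBP) with a packaged, versioned manifest |
| `robustness` | ICC(2,1) feature reliability, reliability-threshold selection, ComBat location/scale harmonization by manufacturer or protocol |
| `model_search` | random search over scaling/selection/imbalance/classifier workflows (8 classifier families), ranked by internal 5x 85/15 patient-grouped validation, top-k probability ensemble |
| `evaluation_stats` | 100x stratified patient-grouped 80/20 evaluation, multi-observer training augmentation, AUC/accuracy/sensitivity/specificity with corrected-resampled-t 95% CIs, fixed-width ROC bands, univariate statistics |
| `cli_report` | single-config orchestration with per-stage caching and a run manifest |

## CLI

```bash
hgprad simulate --n-patients 20 --seed 1 --out results/       # cohort + metadata
hgprad extract volume.nii.gz mask.nii.gz --out features.csv   # one ROI -> 564 features
hgprad all --config config.json                               # full pipeline
hgprad evaluate --config config.json --n-candidates 1000 --ensemble-k 10
hgprad manifest                                               # print the feature manifest
```

A config is a JSON/YAML document:

```json
{
  "cohort": {"n_patients": 40, "seed": 7, "texture_effect": 1.5},
  "designs": [{"name": "multi"}, {"name": "single-CNN"},
              {"name": "multi-icc", "robustness_option": "icc>0.75"}],
  "search": {"n_candidates": 1000, "ensemble_k": 10},
  "n_iterations": 100,
  "seed": 0,
  "out_dir": "results"
}
```

Outputs (feature tables, ICC table, per-design metric summaries with
95% CIs, ROC bands, report) are plain CSV/JSON, all registered in
`run_manifest.json`; a rerun with the same config reuses cached stages.

## Conventions

* Arrays are `(z, y, x)`; axial slices are `arr[z]`; spacing is mm per axis.
* Texture features are computed in 2D per axial slice and aggregated
  (mean, sd) across slices; gray levels are equal-width binned over the
  ROI range; Gabor frequencies are cycles/pixel.
* The positive class is `dHGP`; decision threshold 0.5.
* The packaged `data/manifest.json` fixes feature names and order;
  changing it is a breaking change.
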