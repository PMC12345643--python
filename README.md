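# habitatpipe

Multiparametric PET/MRI tumor **habitat** analysis for preclinical solid
tumors: quantitative parametric mapping, cross-modality registration,
pooled hierarchical clustering into physiological subregions, spatial-
interaction statistics, and validation against matched histology — all
testable end-to-end on a digital phantom with known ground truth.

## The problem

A single imaging metric (tumor volume, mean ADC, mean SUV) hides the
spatial heterogeneity that drives therapy resistance. Combining voxel-wise
quantitative maps from several modalities — water diffusivity (ADC from
DW-MRI), vascular exchange (Ktrans, v_e from DCE-MRI), glucose metabolism
([18F]FDG-PET) and proliferation ([18F]FLT-PET) — and clustering the pooled
voxels reveals *habitats*: spatially coherent subregions with a shared
physiological signature (high-vascularity HV, hypoxic-responding HRSP,
transitional TZ, active-tumor ATMR, responding RSP). Tracking habitat
composition over time can expose treatment response days before any volume
change. This package implements that pipeline for small-animal PET/CT +
MRI studies, for imaging scientists who want a tested, reproducible
reference implementation.

## Core models

* ADC: `S(b) = S0 · exp(−b·ADC)`, log-linear least squares over
  b = 0/150/500/800 s/mm², with artifact-slice exclusion
  (slice mean > tumor median + 2 SD).
* T1: `S = S0 · (1 − e^(−TR/T1))`, nonlinear least squares over
  TR = 255…5500 ms.
* Extended Tofts:
  `C_t(t) = v_p·C_p(t) + Ktrans ∫₀ᵗ C_p(τ)·e^(−(Ktrans/v_e)(t−τ)) dτ`,
  with a muscle-calibrated population AIF, SPGR signal↔concentration
  conversion, and physiological filtering (Ktrans 0–5 min⁻¹, v_e, v_p 0–1,
  ≥25% enhancement over baseline).
* PET: `SUV = activity / (injected dose / body weight)`, brought onto the
  MRI grid by slice reframing, anti-aliased down-sampling and affine
  Mattes-mutual-information registration (Dice-validated).
* Habitats: Ward-linkage agglomerative clustering of the pooled, z-scored
  five-feature matrix (ADC, Ktrans, v_e, FDG-SUV, FLT-SUV); k selected by
  mean silhouette over 2–8; clusters characterised high/low against the
  centroid median and named from a signature table.
* Spatial interaction (MSI): neighbor-pair fractions between habitat
  labels vs. a volume-preserving randomized null, summarised as z-scores.
* Histology: stain-density maps (H&E, CD31, Ki67, GLUT1) box-smoothed,
  down-sampled and clustered with the same core; pimonidazole withheld to
  validate hypoxia localisation; histology clusters matched to imaging
  habitats by exhaustive permutation over composition correlations.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

Run a complete synthetic study — 4 subjects, 5 planted habitats, 37%
necrotic core — through simulation, fitting, clustering and validation:

```python
from habitatpipe import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=2, n_subjects=4, n_timepoints=1, k=5,
                     misalign_pet=False)
report = run_pipeline(cfg, "runs/demo")
print(report["cluster"]["pooled_ari_vs_truth"])   # 0.978
print(report["cluster"]["names"])
# {'1': 'HRSP', '2': 'ATMR', '3': 'TZ', '4': 'HV', '5': 'RSP'}
print(report["fit"]["s00_tp0"]["dce_exclusion_fraction"])  # 0.308
print(report["validate"]["r2"])
# {'1': 0.995, '2': 0.979, '3': 0.997, '4': 0.971, '5': 0.908}
```

Reading the output: the pooled adjusted Rand index of 0.978 says the
clustering recovered the planted habitat partition almost exactly from the
fitted (noisy) maps. The DCE filter excluded ~31% of tumor voxels — the
non-enhancing necrotic core. The recovered cluster centroids map cleanly
onto the five phenotypes; e.g. cluster 4 (HV) has Ktrans ≈ 0.46 min⁻¹ and
v_e ≈ 0.46 (planted: 0.44 / 0.45), cluster 2 (ATMR) has FDG-SUV ≈ 1.6 with
low Ktrans. The per-habitat R² values (0.91–0.997) are the correlations
between imaging habitat volume percentages on the central slice and the
matched histology habitat area percentages across subjects.

The same stages are exposed individually (`habitatpipe.phantom`,
`.mapping`, `.registration`, `.habitats`, `.msi`, `.histology`, `.stats`)
and on the command line:

```bash
habitatpipe run --seed 2 --out runs/demo
habitatpipe fit adc --in dwi.nii --out adc.nii --b-values 0,150,500,800
habitatpipe msi --labels habitat_labels.nii --n-perm 1000 --seed 17 --out msi.json
```

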