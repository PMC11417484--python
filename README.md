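# cardiomass

Regional left-ventricular (LV) mass from short-axis cardiac MRI segmentation
masks, and what those regional masses mean for disease risk.

Clinically, LV hypertrophy is usually assessed through *total* LV mass, yet
focal patterns — disproportionate thickening of the apex or of the
interventricular septum — carry their own risk. `cardiomass` implements the
measurement and analysis chain needed to study this at cohort scale:

1. **Quantification** (`cardiomass.regional_mass`): from a labelled
   short-axis stack (background / LV cavity / LV myocardium / RV cavity),
   compute total LV mass, apical mass and septal mass in grams.
2. **Cohort building** (`cardiomass.cohort`): sex-specific 90th-percentile
   hypertrophy flags, the eight-cell category partition
   (global / isolated apical / isolated septal / combined), prevalent-case
   removal and phenotype correlation summaries.
3. **Survival modelling** (`cardiomass.association`): Cox
   proportional-hazards families — categorical hypertrophy vs control,
   per-SD continuous masses, and joint models pairing total LV mass with one
   regional mass.
4. **Genetics, desk scale** (`cardiomass.genetics`): per-variant
   covariate-adjusted linear association scan with MAF/INFO filters, greedy
   LD clumping (p < 5e-8, r² > 0.6, ±500 kb), additive polygenic scoring and
   PRS-quantile outcome models.
5. **Synthetic ground truth** (`cardiomass.simulate`): annular phantoms with
   closed-form masses, cohorts with known hazard ratios, genotype panels
   with known allele frequencies, LD and effect sizes — so every stage is
   validated end-to-end without any restricted data.

## The measurement

For a slice with `n` myocardial pixels, pixel area `a` (mm²), slice
thickness `t` and inter-slice gap `g` (mm), the slice mass is

```
m = n · a · (t + g) · ρ,   ρ = 1.055 g/cm³ (myocardial density)
```

Total LV mass sums every slice; **apical mass** sums the four most apex-ward
slices containing myocardium. For the **septum**, each slice's RV insertion
points are recovered as the endpoints of the smallest circular angular
interval (about the LV centroid) containing every myocardial pixel
8-adjacent to the RV; septal mass sums the myocardial pixels whose angle
falls inside that interval.

## Worked example

The numbered drivers under `analysis/` exercise each stage and write tables
under `results/`. Phantom accuracy (`python analysis/01_phantom_accuracy.py`):

```
mean relative error vs analytic truth, by pixel spacing (mm):
         rel_err_total  rel_err_apical  rel_err_septal
0.5              0.159           0.153           1.103
1.0              0.359           0.319           2.380
2.0              0.638           1.004           4.387

90-deg arc -> septal fraction 25.02% of slice mass; insertion angles within
0.45 deg (pixel resolution 1.02 deg); 90-deg rotation shifts angles by 90 deg
exactly.
```

Errors are percentages of the closed-form annulus mass and shrink as the
grid is refined; septal mass converges more slowly because the insertion
angles are only resolved to one pixel. Hazard-ratio recovery
(`python analysis/03_cox_recovery.py`) on one simulated 35 000-subject
cohort whose generative category hazards are set to literature-scale values:

```
          group  hazard_ratio  ci_low  ci_high  true_hr  n_group
       combined          5.10    3.75     6.95     5.00      260
         global          9.65    8.84    10.54     9.28     3501
isolated_apical          2.88    2.44     3.39     2.69     1714
isolated_septal          4.65    3.93     5.50     4.41     1031
   per_sd_total          2.28    2.18     2.38     2.27    35000
```

Each fitted 95% CI covers its generative truth; across 200 replicate
cohorts at n = 5000 the empirical coverage is 94–96% for every model family.

A full demo pipeline (200 phantoms → quantification → 5000-subject cohort →
Cox → 500-variant scan → clumping → PRS) runs via
`python analysis/02_demo_pipeline.py`, or from the CLI:

```bash
cardiomass run --config run.yaml     # stage-wise: simulate / quantify /
                                     # cohort / cox / scan / clump / prs-*
```

Reruns with the same config and seed are byte-identical.

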